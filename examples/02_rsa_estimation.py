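"""Second-by-second RSA from a sliding-window spectrum, with a known answer.

Renders a beat series whose intervals carry a pure respiratory tone
(amplitude 0.05 s at 0.25 Hz), so the true band power is A^2/2 and the true
RSA level is ln(A^2/2) = -6.68.  Also shows the edge rule: a 30-s window
assigned to its 15th second leaves 14 missing seconds at the start and 15 at
the end of a 300-s task.
"""

import numpy as np

from hrvdyn import estimate_rsa, render_beats
from hrvdyn.preprocess import interpolate_uniform

A, F = 0.05, 0.25
beats = render_beats(np.full(300, 0.8), resp_amp=A, resp_freq=F, seed=1)
rsa = estimate_rsa(interpolate_uniform(beats, fs=4))

observed = np.nonzero(~rsa.missing)[0]
print(f"RSA defined for seconds {observed[0]}..{observed[-1]} "
      f"of 0..{rsa.n - 1}")
print(f"  -> {observed[0]} missing at the start, "
      f"{rsa.n - 1 - observed[-1]} at the end")

mid = rsa.values[100:200]
print(f"mid-task RSA: mean {mid.mean():.3f} ln(s^2) "
      f"(analytic ln(A^2/2) = {np.log(A**2 / 2):.3f})")
print("doubling the modulation amplitude should add "
      f"ln 4 = {np.log(4):.3f}:")
beats2 = render_beats(np.full(300, 0.8), resp_amp=2 * A, resp_freq=F, seed=1)
rsa2 = estimate_rsa(interpolate_uniform(beats2, fs=4))
print(f"  observed shift {rsa2.values[150] - rsa.values[150]:.3f}")
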