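"""Event-coded behavior to per-second indicators and 5-s local densities.

A coded interaction is a list of utterance initiation timestamps with a
category (positive or negative).  The per-second indicator marks seconds in
which at least one event starts; the local density at each second counts the
indicator-1 seconds in the centered 5-s window (0..5), giving a smooth-ish
intensity measure the dynamic model can use.
"""

import numpy as np

from hrvdyn import EventLog, events_to_indicator, local_density, task_totals

log = EventLog(
    subject="demo",
    times=np.array([10.4, 10.9, 12.2, 14.8, 40.0, 41.5, 42.9]),
    categories=np.array(
        ["positive"] * 4 + ["negative"] * 3, dtype=object
    ),
)

totals = task_totals(log)
print(f"task totals: {totals['positive']} positive, "
      f"{totals['negative']} negative events")

ind = events_to_indicator(log, task_length=60, category="positive")
dens = local_density(ind)
print("positive indicator seconds:", np.nonzero(ind)[0].tolist())
print("local density around the 10-15 s burst:")
for t in range(8, 18):
    print(f"  second {t:2d}: indicator {ind[t]}, density {dens[t]}")
print("note: the two events inside second 10 collapse to one indicator,")
print("and density at second 12 counts the indicator seconds 10, 12, 14.")
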