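"""Second-by-second respiratory sinus arrhythmia (RSA) from a 4 Hz IBI series.

RSA at a given second is the natural log of IBI spectral power inside the
adult respiration band (0.12-0.40 Hz), estimated from a 30-s Hamming-tapered
window that slides forward 1 s at a time.  Each window's estimate represents
the window's 15th second, so a gap-free task loses the first 14 and last 15
seconds, and a missing 30-s segment wipes out estimates from 15 s before it
until 14 s after it.

Normalization is pinned so that an in-band sinusoid of amplitude ``A`` (s)
yields band power ``A**2 / 2`` (s^2) regardless of the taper: one-sided
periodogram scaled by ``1 / (fs * sum(w**2))``, band power as the sum of PSD
bins in the band times the bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import UniformSeries

__all__ = ["RSASeries", "estimate_rsa", "propagate_gap_missingness"]

#: adult respiration frequency band, Hz
DEFAULT_BAND = (0.12, 0.40)
#: spectral window length, s
DEFAULT_WINDOW = 30
#: 0-based second of the window that the estimate represents (its 15th second)
CENTER_OFFSET = 14
#: floor under band power before taking the log, s^2
LOG_FLOOR = 1e-12


@dataclass
class RSASeries:
    """Per-second RSA estimates (ln of band power) with a missing mask.

    ``floored[s]`` marks seconds where band power fell below the log floor
    (e.g. a constant input); such values are finite but uninformative.
    """

    values: np.ndarray
    missing: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND
    window_s: int = DEFAULT_WINDOW
    floored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.floored is None:
            self.floored = np.zeros(self.values.size, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.values.size)


def _band_power(
    windows: np.ndarray, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Band power of each row of ``windows`` (demean, Hamming, periodogram)."""
    nper = windows.shape[-1]
    taper = np.hamming(nper)
    demeaned = windows - windows.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(demeaned * taper, axis=-1)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(taper**2))
    # one-sided doubling, excluding DC and (for even n) the Nyquist bin
    psd[..., 1 : (nper + 1) // 2] *= 2.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    tol = 1e-12
    in_band = (freqs >= band[0] - tol) & (freqs <= band[1] + tol)
    df = fs / nper
    return psd[..., in_band].sum(axis=-1) * df


def estimate_rsa(
    series4hz: UniformSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    window_s: int = DEFAULT_WINDOW,
    log_floor: float = LOG_FLOOR,
) -> RSASeries:
    """Sliding-window spectral RSA from a 4 Hz inter-beat-interval series.

    For each 1-s step, the window covering seconds ``[w, w + window_s)`` is
    demeaned, Hamming-tapered, and Fourier transformed; the natural log of the
    in-band power is assigned to second ``w + 14``.  A window containing any
    missing 4 Hz sample yields a missing second.
    """
    fs = series4hz.fs
    if fs != 4:
        raise ValueError(f"RSA estimation expects a 4 Hz series, got fs={fs}")
    n_sec = int(series4hz.n // fs)
    nper = int(window_s * fs)
    values = np.full(n_sec, np.nan)
    missing = np.ones(n_sec, dtype=bool)
    floored = np.zeros(n_sec, dtype=bool)
    if series4hz.n < nper:
        warnings.warn(
            f"series shorter than the {window_s}-s window; all RSA missing",
            stacklevel=2,
        )
        return RSASeries(values, missing, band, window_s, floored)

    vals = np.nan_to_num(series4hz.values[: n_sec * int(fs)])
    miss = series4hz.missing[: n_sec * int(fs)]
    win_vals = sliding_window_view(vals, nper)[:: int(fs)]
    win_miss = sliding_window_view(miss, nper)[:: int(fs)]
    ok = ~win_miss.any(axis=-1)
    if ok.any():
        power = _band_power(win_vals[ok], fs, band)
        sec = np.nonzero(ok)[0] + CENTER_OFFSET
        values[sec] = np.log(np.maximum(power, log_floor))
        floored[sec] = power < log_floor
        missing[sec] = False
    return RSASeries(values, missing, band, window_s, floored)


def propagate_gap_missingness(
    gap: tuple[float, float],
    n_seconds: int,
    window_s: int = DEFAULT_WINDOW,
    center_offset: int = CENTER_OFFSET,
) -> np.ndarray:
    """Seconds whose RSA estimate is lost to a gap ``[g1, g2)`` on the clock.

    Second ``s`` is lost whenever its window span ``[s - 14, s + 16)``
    intersects the gap; for an integer-aligned gap that is every second from
    ``g1 - 15`` through ``g2 + 13`` inclusive, clipped to the task.
    """
    g1, g2 = gap
    lead = window_s - 1 - center_offset  # seconds of window after its center
    first = int(np.floor(g1 - lead - 1)) + 1
    last = int(np.ceil(g2 + center_offset)) - 1
    return np.arange(max(first, 0), min(last, n_seconds - 1) + 1)
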