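"""Band-limited log-variance HRV (the Porges–Bohrer V̂ metric) and time-domain companions.

V̂ is computed from a corrected IBI series in four steps:

(a) linear interpolation of the heart-period series at 10 Hz,
(b) a 241-point linear-phase FIR bandpass restricted to the spontaneous
    respiration band 0.12–0.40 Hz,
(c) the variance of the band-limited signal within each 30-s epoch,
(d) the natural logarithm of each epoch variance, averaged over epochs.

The band restriction isolates respiratory sinus arrhythmia — the
vagally mediated heart-period oscillation at the breathing frequency —
and the log transform brings the variance distribution close to normal,
so V̂ is reported in ln(ms²). RMSSD and pNN50, the standard time-domain
vagal indices, are provided as companions; on stationary data they are
highly correlated with V̂.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import IBISeries, SampledSeries

__all__ = ["HRVResult", "interpolate_ibi", "bandpass_fir", "design_fir", "vhat",
           "rmssd", "pnn50"]

BAND_HZ = (0.12, 0.40)
FIR_TAPS = 241
RESAMPLE_HZ = 10.0
EPOCH_S = 30.0


@dataclass
class HRVResult:
    """Per-epoch band-limited log variances and summary HRV indices."""

    epoch_ln_var: np.ndarray      # ln(ms^2), one value per epoch
    vhat: float                   # mean of epoch_ln_var, ln(ms^2)
    rmssd: float                  # ms
    pnn50: float                  # percent
    n_epochs: int
    band_hz: tuple = BAND_HZ
    fir_taps: int = FIR_TAPS
    resample_hz: float = RESAMPLE_HZ


def interpolate_ibi(ibi: IBISeries, rate_hz: float = RESAMPLE_HZ) -> SampledSeries:
    """Linearly interpolate the heart-period series on a uniform grid.

    Each interval's value is anchored at the beat terminating it; between
    anchors the signal is linear, and it is held constant before the first
    and after the last anchor so the grid covers the full record span.
    """
    if ibi.duration_s < 60:
        raise ValueError(f"record span {ibi.duration_s:.1f} s < 60 s minimum")
    anchors_s = ibi.beat_times_ms[1:] / 1000.0
    t0 = ibi.beat_times_ms[0] / 1000.0
    t_end = ibi.beat_times_ms[-1] / 1000.0
    grid = t0 + np.arange(int(np.floor((t_end - t0) * rate_hz)) + 1) / rate_hz
    values = np.interp(grid, anchors_s, ibi.intervals_ms)
    return SampledSeries(fs_hz=rate_hz, values=values, t0_s=t0)


def design_fir(band_hz: tuple = BAND_HZ, taps: int = FIR_TAPS,
               fs_hz: float = RESAMPLE_HZ) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) bandpass FIR coefficients."""
    if taps % 2 == 0:
        raise ValueError("taps must be odd for a type-I linear-phase bandpass")
    lo, hi = band_hz
    if not (0 < lo < hi < fs_hz / 2):
        raise ValueError(f"band {band_hz} must satisfy 0 < low < high < fs/2 = {fs_hz / 2}")
    return sps.firwin(taps, [lo, hi], pass_zero=False, fs=fs_hz, window="hamming")


def bandpass_fir(x: np.ndarray, band_hz: tuple = BAND_HZ, taps: int = FIR_TAPS,
                 fs_hz: float = RESAMPLE_HZ) -> np.ndarray:
    """Apply the respiration-band FIR filter with zero net group delay.

    Edge transients are handled by reflection padding (one filter length
    at each end) which is trimmed from the output; the symmetric kernel
    is applied centred, so the output is phase-aligned with the input and
    of the same length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= taps:
        raise ValueError(f"signal length {len(x)} must exceed the filter length {taps}")
    h = design_fir(band_hz, taps, fs_hz)
    pad = min(taps, len(x) - 1)
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    y = sps.convolve(padded, h, mode="same")
    return y[pad:pad + len(x)]


def vhat(ibi: IBISeries, epoch_s: float = EPOCH_S, band_hz: tuple = BAND_HZ,
         taps: int = FIR_TAPS, rate_hz: float = RESAMPLE_HZ) -> HRVResult:
    """Compute V̂: epoch-averaged ln of band-limited heart-period variance.

    The full record is interpolated and filtered once, then segmented
    into ``floor(span / epoch_s)`` consecutive epochs (a 180-s record
    yields six 30-s epochs); filtering before segmentation keeps the
    ~24-s filter transient out of every epoch. Raises ``ValueError`` when
    any epoch shows no measurable variability (the log would be
    undefined; a constant heart period does not occur in valid data).
    """
    if ibi.duration_s < 2 * epoch_s:
        raise ValueError(f"record must span at least two epochs ({2 * epoch_s:.0f} s)")
    sampled = interpolate_ibi(ibi, rate_hz)
    filtered = bandpass_fir(sampled.values - np.mean(sampled.values),
                            band_hz, taps, rate_hz)
    per_epoch = int(round(epoch_s * rate_hz))
    n_epochs = len(filtered) // per_epoch
    ln_vars = np.empty(n_epochs)
    for e in range(n_epochs):
        v = float(np.var(filtered[e * per_epoch:(e + 1) * per_epoch]))
        if v <= 1e-12:
            raise ValueError(f"no measurable variability in epoch {e}")
        ln_vars[e] = np.log(v)
    return HRVResult(
        epoch_ln_var=ln_vars,
        vhat=float(np.mean(ln_vars)),
        rmssd=rmssd(ibi),
        pnn50=pnn50(ibi),
        n_epochs=n_epochs,
        band_hz=tuple(band_hz),
        fir_taps=taps,
        resample_hz=rate_hz,
    )


def _successive_diffs(ibi: IBISeries) -> np.ndarray:
    if ibi.n_intervals < 3:
        raise ValueError("need at least 3 intervals")
    return np.diff(ibi.intervals_ms)


def rmssd(ibi: IBISeries) -> float:
    """Root mean square of successive interval differences, in ms."""
    d = _successive_diffs(ibi)
    return float(np.sqrt(np.mean(d**2)))


def pnn50(ibi: IBISeries) -> float:
    """Percentage of successive interval differences exceeding 50 ms."""
    d = _successive_diffs(ibi)
    return float(100.0 * np.mean(np.abs(d) > 50.0))
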