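"""ECG processing: R-peak detection, IBI extraction, and rhythm-artifact correction.

The chain is ``detect_r_peaks`` → ``to_ibi`` → ``detect_artifacts`` →
``correct_artifacts``. Artifact handling follows the classical
ectopy-correction conventions for heart-period series: an interval is
suspect when it deviates from the local median of its neighbours by more
than a fixed threshold (300 ms by default); an abnormally long interval
(missed beat) is corrected by integer division into equal sub-intervals,
and a run of abnormally short intervals (spurious detection) by
summation. Every correction conserves total elapsed time exactly and is
recorded in the series' ``correction_log`` so that the processing history
can be audited in place of manual inspection of the raw trace.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import ECGRecord, IBISeries

__all__ = ["detect_r_peaks", "to_ibi", "detect_artifacts", "correct_artifacts"]

DEFAULT_ARTIFACT_THRESHOLD_MS = 300.0
_NEIGHBOR_WINDOW = 5  # unflagged intervals forming the local median reference
_MAX_CORRECTION_PASSES = 3


# -- R-peak detection ---------------------------------------------------------

def detect_r_peaks(ecg: ECGRecord, min_refractory_ms: float = 250.0) -> np.ndarray:
    """Detect R-peak times (ms) in a single-lead ECG.

    A derivative-energy detector in the Pan–Tompkins tradition: the
    amplitude-normalised trace is band-passed (5–40 Hz), differentiated,
    squared and smoothed; candidate peaks above an adaptive threshold are
    refined to the local maximum of the raw trace. Detection is invariant
    under amplitude scaling. Raises ``ValueError`` for recordings that are
    too short, flat, or yield no physiologically stable beat sequence.
    """
    if ecg.duration_s < 10:
        raise ValueError("record too short for R-peak detection (< 10 s)")
    x = ecg.samples
    scale = np.std(x)
    if scale == 0 or not np.isfinite(scale):
        raise ValueError("unusable recording: flat or non-finite signal")
    x = (x - np.mean(x)) / scale

    high = min(40.0, 0.45 * ecg.fs_hz)
    sos = sps.butter(3, [5.0, high], btype="bandpass", fs=ecg.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    energy = np.gradient(filtered) ** 2
    win = max(3, int(round(0.12 * ecg.fs_hz)))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")

    thr = 0.2 * np.percentile(energy, 99)
    refractory = int(round(min_refractory_ms * ecg.fs_hz / 1000.0))
    cand, _ = sps.find_peaks(energy, height=thr, distance=max(refractory, 1))
    # QRS complexes concentrate derivative energy far above the background;
    # peaks drawn from the noise floor itself show a contrast near 1
    background = np.median(energy)
    if len(cand) == 0 or background <= 0 or \
            np.median(energy[cand]) / background < 10.0:
        raise ValueError("unusable recording: no stable beats above the noise floor")
    # refine each candidate to the raw-signal maximum nearby (R is positive)
    half = int(round(0.04 * ecg.fs_hz))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    if len(peaks) > 1:  # re-impose the refractory period after refinement
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] >= refractory:
                keep.append(p)
            elif x[p] > x[keep[-1]]:
                keep[-1] = p
        peaks = np.array(keep)

    if len(peaks) < 10:
        raise ValueError(f"unusable recording: only {len(peaks)} beats detected")
    ibis = np.diff(peaks) / ecg.fs_hz * 1000.0
    med = np.median(ibis)
    iqr = np.percentile(ibis, 75) - np.percentile(ibis, 25)
    if not (250.0 <= med <= 2000.0) or iqr / med >= 0.5:
        raise ValueError("unusable recording: no stable beat sequence detected")
    return ecg.start_time_s * 1000.0 + peaks / ecg.fs_hz * 1000.0


def to_ibi(beat_times_ms) -> IBISeries:
    """Convert beat timestamps to an IBI series, intervals rounded to 1 ms."""
    beat_times_ms = np.asarray(beat_times_ms, dtype=float)
    if beat_times_ms.ndim != 1 or len(beat_times_ms) < 2:
        raise ValueError("need at least two beat times")
    if np.any(np.diff(beat_times_ms) <= 0):
        raise ValueError("beat times must be strictly increasing")
    intervals = np.rint(np.diff(beat_times_ms))
    if np.any(intervals <= 0):
        raise ValueError("rounded interval of 0 ms; beats too close together")
    return IBISeries(beat_times_ms, intervals)


# -- artifact detection -------------------------------------------------------

def _local_median(values: np.ndarray, flags: np.ndarray, k: int,
                  window: int = _NEIGHBOR_WINDOW) -> float:
    """Median of the ``window`` unflagged intervals nearest to index ``k``."""
    idx = [i for i in np.argsort(np.abs(np.arange(len(values)) - k), kind="stable")
           if i != k and not flags[i]]
    ref = idx[:window]
    if not ref:
        return float(values[k])
    return float(np.median(values[ref]))


def detect_artifacts(ibi: IBISeries,
                     threshold_ms: float = DEFAULT_ARTIFACT_THRESHOLD_MS) -> IBISeries:
    """Flag intervals deviating from their local median by more than the threshold.

    The reference median is computed from the nearest unflagged intervals,
    so an artifact cannot mask itself; flags are assigned greedily,
    worst-deviation first, until no interval exceeds the threshold.
    """
    if ibi.n_intervals < 3:
        raise ValueError("need at least 3 intervals for artifact detection")
    values = ibi.intervals_ms
    flags = np.zeros(len(values), dtype=bool)
    if not np.isfinite(threshold_ms):
        out = ibi.copy()
        out.artifact_flags = flags
        return out
    while True:
        dev = np.array([
            0.0 if flags[k] else abs(values[k] - _local_median(values, flags, k))
            for k in range(len(values))
        ])
        worst = int(np.argmax(dev))
        if dev[worst] > threshold_ms:
            flags[worst] = True
        else:
            break
    out = ibi.copy()
    out.artifact_flags = flags
    return out


# -- artifact correction ------------------------------------------------------

def _split_even(total: float, k: int, integral: bool) -> list[float]:
    """Split ``total`` into ``k`` near-equal parts that sum to it exactly."""
    if integral:
        t = int(round(total))
        base, rem = divmod(t, k)
        return [float(base + 1)] * rem + [float(base)] * (k - rem)
    return [total / k] * k


def _fix_run(intervals: list[float], flags: list[bool], start: int, stop: int,
             integral: bool, log: list, offset_note: int) -> None:
    """Correct the flagged run ``intervals[start:stop]`` in place."""
    outside = np.array([v for i, v in enumerate(intervals) if not flags[i]])
    if len(outside) == 0:
        raise ValueError("cannot correct: every interval is flagged")
    flags_arr = np.array(flags)
    values_arr = np.array(intervals)
    m = _local_median(values_arr, flags_arr, (start + stop - 1) // 2)

    run = intervals[start:stop]
    if len(run) == 1 and run[0] > m:
        k = max(2, int(round(run[0] / m)))
        parts = _split_even(run[0], k, integral)
        log.append((start + offset_note, f"divide_{k}"))
    else:
        s = float(sum(run))
        lo, hi = start, stop
        # absorb an adjacent interval when the run sum is far below one beat
        while round(s / m) < 1 and (lo > 0 or hi < len(intervals)):
            cands = []
            if lo > 0 and not flags[lo - 1]:
                cands.append(("L", abs((s + intervals[lo - 1]) - m * max(1, round((s + intervals[lo - 1]) / m)))))
            if hi < len(intervals) and not flags[hi]:
                cands.append(("R", abs((s + intervals[hi]) - m * max(1, round((s + intervals[hi]) / m)))))
            if not cands:
                break
            side = min(cands, key=lambda c: c[1])[0]
            if side == "L":
                lo -= 1
                s += intervals[lo]
            else:
                s += intervals[hi]
                hi += 1
        k = max(1, int(round(s / m)))
        parts = _split_even(s, k, integral)
        start, stop = lo, hi
        if k == 1:
            log.append((start + offset_note, f"sum_{stop - start}"))
        else:
            log.append((start + offset_note, f"sum_{stop - start}"))
            log.append((start + offset_note, f"divide_{k}"))
    intervals[start:stop] = parts
    flags[start:stop] = [False] * len(parts)


def correct_artifacts(ibi: IBISeries,
                      threshold_ms: float = DEFAULT_ARTIFACT_THRESHOLD_MS) -> IBISeries:
    """Correct flagged artifacts by integer division or summation.

    Long flagged intervals (missed beats) are divided into ``k`` equal
    sub-intervals with ``k = round(interval / local median)``; runs of
    short flagged intervals (spurious beats) are summed, absorbing an
    adjacent interval when the run is only a fragment of one true beat.
    Total elapsed time is conserved exactly (integer arithmetic on
    millisecond-resolution series). Up to three detect/correct passes are
    attempted; residual flags raise ``ValueError``. Correcting a clean
    series is the identity.
    """
    work = ibi if ibi.artifact_flags.any() else detect_artifacts(ibi, threshold_ms)
    integral = ibi.is_integral()
    t0 = float(ibi.beat_times_ms[0])
    log: list = list(ibi.correction_log)

    for _ in range(_MAX_CORRECTION_PASSES):
        if not work.artifact_flags.any():
            out = IBISeries.from_intervals(work.intervals_ms, t0_ms=t0)
            out.correction_log = log
            return out
        intervals = list(work.intervals_ms)
        flags = list(work.artifact_flags)
        # process runs right-to-left so earlier indices stay valid
        runs = []
        k = 0
        while k < len(flags):
            if flags[k]:
                j = k
                while j < len(flags) and flags[j]:
                    j += 1
                runs.append((k, j))
                k = j
            else:
                k += 1
        for start, stop in reversed(runs):
            _fix_run(intervals, flags, start, stop, integral, log, 0)
        work = detect_artifacts(
            IBISeries.from_intervals(np.array(intervals), t0_ms=t0), threshold_ms
        )

    if work.artifact_flags.any():
        residual = np.flatnonzero(work.artifact_flags).tolist()
        raise ValueError(f"unresolvable artifact pattern; residual flags at {residual}")
    out = IBISeries.from_intervals(work.intervals_ms, t0_ms=t0)
    out.correction_log = log
    return out
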