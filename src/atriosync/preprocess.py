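"""Denoising, ectopic handling and a threshold delineator.

Filters are linear-phase in effect: IIR designs applied forward-backward
(:func:`scipy.signal.filtfilt`) so activation fiducials are not shifted.
Ectopic beats are detected on the interval series and handled downstream at
the feature level by linear interpolation; the raw samples are left alone.
The delineator is a deliberately simple amplitude-threshold stand-in for
the expert-corrected delineation a clinical study would use: it needs an
approximate peak per activation and returns onset/peak/offset triplets.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

__all__ = [
    "remove_powerline",
    "remove_baseline_wander",
    "detect_ectopics",
    "interpolate_ectopics",
    "delineate",
]


def remove_powerline(
    samples: np.ndarray, fs: float, line_freq: float = 50.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch at the power-line frequency.

    ``q`` is the notch quality factor (centre frequency over -3 dB width);
    the default 30 gives a ~1.7 Hz-wide notch at 50 Hz, leaving the passband
    essentially untouched.
    """
    if fs <= 2.0 * line_freq:
        raise ValueError("sampling rate must exceed twice the line frequency")
    b, a = signal.iirnotch(line_freq, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(samples, dtype=float))


def remove_baseline_wander(
    samples: np.ndarray, fs: float, cutoff: float = 0.5, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass removing drift below ``cutoff`` Hz."""
    if not 0.0 < cutoff < fs / 2.0:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def detect_ectopics(
    annotations: np.ndarray,
    fs: float = 1000.0,
    threshold: float = 0.20,
    window: int = 11,
) -> np.ndarray:
    """Flag ectopic activations from their preceding inter-beat interval.

    Beat ``i`` is flagged when the interval ending at it deviates more than
    ``threshold`` (fraction) from the median of the ``window`` surrounding
    intervals (itself excluded).  A premature beat displaces one fiducial,
    so it shortens its own interval *and* lengthens the next one; a
    long-interval flag immediately following a short-interval flag is
    attributed to that same ectopic (compensatory pause) and suppressed, so
    one premature beat yields exactly one flag.

    Returns a boolean array aligned to the annotations (first beat has no
    preceding interval and is never flagged).
    """
    annotations = np.asarray(annotations)
    n = len(annotations)
    if n < 12:
        raise ValueError("need at least 12 annotations to detect ectopics")
    peaks = annotations[:, 1].astype(float)
    ivl = np.diff(peaks) / fs * 1000.0  # interval i ends at beat i+1
    m = len(ivl)
    half = window // 2
    flags = np.zeros(n, dtype=bool)
    short = np.zeros(m, dtype=bool)
    deviant = np.zeros(m, dtype=bool)
    for i in range(m):
        lo = max(0, min(i - half, m - window))
        neigh = np.delete(ivl[lo:lo + window], i - lo)
        med = np.median(neigh)
        if med <= 0:
            continue
        dev = (ivl[i] - med) / med
        if abs(dev) > threshold:
            deviant[i] = True
            short[i] = dev < 0
    for i in range(m):
        if not deviant[i]:
            continue
        if i > 0 and deviant[i - 1] and short[i - 1] and not short[i]:
            continue  # compensatory pause after a flagged premature beat
        flags[i + 1] = True
    return flags


def interpolate_ectopics(
    feature_sequence: np.ndarray, flags: np.ndarray
) -> np.ndarray:
    """Replace flagged entries by linear interpolation between neighbours.

    Flagged runs at either end are replaced by the nearest defined value so
    the output keeps the input length.  NaNs in unflagged positions are left
    untouched.
    """
    x = np.asarray(feature_sequence, dtype=float).copy()
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(x):
        raise ValueError("flags must match the feature sequence length")
    if flags.all():
        raise ValueError("cannot interpolate: every entry is flagged")
    if not flags.any():
        return x
    idx = np.arange(len(x))
    good = ~flags
    x[flags] = np.interp(idx[flags], idx[good], x[good])
    return x


def delineate(
    samples: np.ndarray,
    fs: float,
    approximate_peaks: np.ndarray,
    channel_kind: str = "surface",
    *,
    threshold_frac: float = 0.05,
    search_ms: float = 150.0,
    smooth_ms: float = 8.0,
) -> np.ndarray:
    """Threshold delineator: onset/peak/offset around approximate peaks.

    For each approximate peak the true peak is refined to the largest
    rectified excursion within +/-40 ms.  Onset and offset bound the
    sustained region where the smoothed rectified amplitude exceeds a
    threshold — ``threshold_frac`` of the local peak-to-baseline range, or
    three times the window-margin noise floor, whichever is larger — within
    a ``search_ms`` window on each side; brief sub-threshold dips (the
    zero-crossing between the lobes of a biphasic wave) are skipped.

    For monophasic surface P-waves the crossing is then corrected by
    quadratic-edge extrapolation (a smooth hump vanishes quadratically at
    its foot, so the threshold crossing sits well inside the true boundary;
    extrapolating the local slope to the baseline removes that bias).  For
    biphasic waves (``channel_kind='cs'``) the crossing itself is the
    boundary.  Activations whose window is flat or below the noise floor
    are skipped with a warning.

    Requires peaks separated by at least 200 ms.
    """
    x = np.asarray(samples, dtype=float)
    peaks = np.asarray(approximate_peaks, dtype=np.int64)
    if len(peaks) > 1 and np.any(np.diff(peaks) < 0.2 * fs):
        raise ValueError("approximate peaks must be separated by >= 200 ms")
    if np.any((peaks < 0) | (peaks >= len(x))):
        raise ValueError("approximate peaks outside the signal")

    w = int(round(search_ms * fs / 1000.0))
    refine = int(round(40 * fs / 1000.0))
    ksmooth = max(1, int(round(smooth_ms * fs / 1000.0)))
    kernel = np.ones(ksmooth) / ksmooth
    out = []
    for p0 in peaks:
        lo = max(0, p0 - refine)
        hi = min(len(x), p0 + refine + 1)
        seg = x[lo:hi]
        base = np.median(x[max(0, p0 - w):min(len(x), p0 + w + 1)])
        peak = lo + int(np.argmax(np.abs(seg - base)))
        a = max(0, peak - w)
        b = min(len(x), peak + w + 1)
        r = np.abs(x[a:b] - base)
        if ksmooth > 1:
            r = np.convolve(r, kernel, mode="same")
        rng_amp = r[peak - a]
        if rng_amp <= 0:
            warnings.warn("flat delineation window; activation skipped")
            continue
        # noise floor from the quiet outer margins of the search window
        margin = np.concatenate([r[:max(1, w // 5)], r[-max(1, w // 5):]])
        noise_floor = 3.0 * float(np.median(margin))
        thr = max(threshold_frac * rng_amp, noise_floor)
        if thr >= rng_amp:
            warnings.warn("activation below noise floor; skipped")
            continue
        above = r >= thr
        extrapolate = channel_kind != "cs"
        onset = a + _boundary(above, peak - a, r, thr, backwards=True,
                              extrapolate=extrapolate)
        offset = a + _boundary(above, peak - a, r, thr, backwards=False,
                               extrapolate=extrapolate)
        onset = min(onset, peak - 1)
        offset = max(offset, peak + 1)
        if onset >= 0 and offset < len(x):
            out.append((onset, peak, offset))
    return np.array(out, dtype=np.int64).reshape(-1, 3)


def _boundary(above: np.ndarray, peak: int, r: np.ndarray, thr: float,
              backwards: bool, extrapolate: bool) -> int:
    """Boundary of the sustained above-threshold run containing ``peak``.

    Scans away from the peak; sub-threshold dips up to 15 samples (the
    inter-lobe zero-crossing of a biphasic wave) are skipped when activity
    resumes beyond them.  With ``extrapolate`` the crossing is pushed
    outward by ``2 r / slope`` — exact for an edge that vanishes
    quadratically at its foot — with the local slope from a short linear
    fit; the extension is capped at 30 samples.
    """
    step = -1 if backwards else 1
    n = len(above)
    i = peak
    last_above = peak
    gap = 0
    max_gap = 15
    while 0 <= i + step < n:
        i += step
        if above[i]:
            last_above = i
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    j = last_above
    if not extrapolate:
        return j
    half = 6
    lo, hi = max(0, j - half), min(n, j + half + 1)
    if hi - lo >= 3:
        k = np.arange(lo, hi)
        slope = np.polyfit(k, r[lo:hi], 1)[0] * (1 if backwards else -1)
        if slope > 0:
            ext = int(round(min(2.0 * r[j] / slope, 30.0)))
            j = min(max(j + step * ext, 0), n - 1)
    return j
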