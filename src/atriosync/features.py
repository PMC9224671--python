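"""Per-activation morphology features, rate-variability summaries, and
heart-rate adjustment.

Morphological features per activation (inclusive ``[onset, offset]`` sample
window): duration (ms), maximum signed amplitude ``ampmax`` (mV),
peak-to-peak amplitude ``pp`` (mV), quadratic mean ``rms`` (mV), area of the
positive part ``posar`` (mV*ms, trapezoidal), and slope rates ``s5 s10 s20
smax`` (mV/ms) measured from the onset to 5/10/20% of the duration and to
the peak.

Heart-rate adjustment (HRA) scales interval-dependent features by
``sf_i = 1000 / IBI_i`` where ``IBI_i`` is the interval between activation
``i`` and its predecessor: durations and areas are multiplied by ``sf``,
slope rates divided by it.  The first activation of a recording has no IBI;
its HRA fields are NaN and it is excluded from pairwise statistics.

Atrial rate variability (ARV) summarises the activation interval series
with SDNN (sample standard deviation, ddof=1), VARNN (= SDNN**2) and RMSSD
(root mean square of successive interval differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import AnnotatedRecording

__all__ = [
    "MORPH_FEATURES",
    "HRA_FEATURES",
    "ARV_FEATURES",
    "ARVSummary",
    "FeatureSeries",
    "duration",
    "amplitude_features",
    "positive_area",
    "slope_rate",
    "compute_ibi",
    "hra_adjust",
    "arv_summary",
    "extract_features",
]

MORPH_FEATURES = ("duration", "ampmax", "pp", "rms", "posar",
                  "s5", "s10", "s20", "smax")
#: Features with an HRA variant: duration and area scale with sf, slopes
#: scale with 1/sf.
HRA_FEATURES = ("hra_duration", "hra_posar",
                "hra_s5", "hra_s10", "hra_s20", "hra_smax")
ARV_FEATURES = ("sdnn", "varnn", "rmssd")

_SLOPE_FRACTIONS = {"s5": 0.05, "s10": 0.10, "s20": 0.20}


@dataclass
class ARVSummary:
    sdnn: float   # ms
    varnn: float  # ms^2
    rmssd: float  # ms
    n_intervals: int


@dataclass
class FeatureSeries:
    """Per-activation feature table plus the recording-level ARV summary."""

    table: pd.DataFrame
    arv: ARVSummary
    channel_kind: str
    phase: str | None = None
    patient_id: str | None = None

    def medians(self) -> pd.Series:
        """Recording-level per-feature medians (NaNs excluded)."""
        return self.table.median()


def duration(annotation: np.ndarray, fs: float) -> float:
    """Activation duration in ms: (offset - onset) / fs * 1000."""
    onset, _, offset = annotation
    if not onset < offset:
        raise ValueError("onset must precede offset")
    return (offset - onset) / fs * 1000.0


def amplitude_features(samples: np.ndarray, annotation: np.ndarray
                       ) -> tuple[float, float, float]:
    """(ampmax, pp, rms) over the inclusive annotation window.

    ``ampmax`` is the maximum *signed* sample; for nonnegative activations
    (lead-II P-waves) it coincides with the peak-to-peak amplitude.
    """
    onset, _, offset = annotation
    win = np.asarray(samples[onset:offset + 1], dtype=float)
    if win.size == 0:
        raise ValueError("empty annotation window")
    ampmax = float(win.max())
    pp = float(win.max() - win.min())
    rms = float(np.sqrt(np.mean(win * win)))
    return ampmax, pp, rms


def positive_area(samples: np.ndarray, annotation: np.ndarray, fs: float) -> float:
    """Trapezoidal area of the positive part of the activation, in mV*ms."""
    onset, _, offset = annotation
    win = np.clip(np.asarray(samples[onset:offset + 1], dtype=float), 0.0, None)
    return float(np.trapezoid(win, dx=1000.0 / fs))


def slope_rate(samples: np.ndarray, annotation: np.ndarray, fs: float,
               at: str = "max") -> float:
    """Signed slope rate from the onset to a point of the activation, mV/ms.

    ``at`` is one of ``'5%' '10%' '20%' 'max'``: amplitude change from the
    onset to the sample at that fraction of the duration (round half up), or
    to the annotated peak, divided by the elapsed time in ms.  A rounding
    that lands on the onset itself is advanced by one sample.
    """
    onset, peak, offset = annotation
    key = at.rstrip("%")
    if key == "max":
        ti = int(peak)
    else:
        frac = float(key) / 100.0
        ti = onset + int(np.floor(frac * (offset - onset) + 0.5))
        if ti <= onset:
            ti = onset + 1
    dt_ms = (ti - onset) / fs * 1000.0
    return float((samples[ti] - samples[onset]) / dt_ms)


def compute_ibi(annotations: np.ndarray, fs: float) -> np.ndarray:
    """Peak-to-peak inter-beat intervals in ms, aligned to activations.

    Element ``i`` is the interval between activation ``i`` and ``i-1``; the
    first element is NaN.
    """
    annotations = np.asarray(annotations)
    if len(annotations) < 2:
        raise ValueError("need at least two annotations")
    peaks = annotations[:, 1].astype(float)
    d = np.diff(peaks)
    if np.any(d <= 0):
        raise ValueError("activation peaks must be strictly increasing")
    out = np.empty(len(annotations))
    out[0] = np.nan
    out[1:] = d / fs * 1000.0
    return out


def hra_adjust(table: pd.DataFrame) -> pd.DataFrame:
    """Add the scaling factor ``sf = 1000/ibi`` and HRA feature columns.

    Rows without an IBI get NaN HRA fields and are excluded from pairwise
    statistics downstream.
    """
    if "ibi" not in table:
        raise ValueError("table must carry an 'ibi' column")
    out = table.copy()
    sf = 1000.0 / out["ibi"]
    out["sf"] = sf
    if "duration" in out:
        out["hra_duration"] = out["duration"] * sf
    if "posar" in out:
        out["hra_posar"] = out["posar"] * sf
    for s in ("s5", "s10", "s20", "smax"):
        if s in out:
            out[f"hra_{s}"] = out[s] / sf
    return out


def arv_summary(ibi_sequence: np.ndarray) -> ARVSummary:
    """SDNN / VARNN / RMSSD of an (ectopic-interpolated) interval series."""
    ivl = np.asarray(ibi_sequence, dtype=float)
    ivl = ivl[np.isfinite(ivl)]
    if len(ivl) < 3:
        raise ValueError("need at least 3 defined intervals")
    sdnn = float(np.std(ivl, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(ivl) ** 2)))
    return ARVSummary(sdnn=sdnn, varnn=sdnn * sdnn, rmssd=rmssd,
                      n_intervals=len(ivl))


def extract_features(
    recording: AnnotatedRecording,
    *,
    phase: str | None = None,
    patient_id: str | None = None,
    ectopic_flags: np.ndarray | None = None,
) -> FeatureSeries:
    """Full per-activation feature table for one recording.

    When the recording carries no samples, only interval-derived features
    (duration, ibi, sf, hra_duration) are produced.  ``ectopic_flags``
    override the recording's own flags; flagged entries are linearly
    interpolated per feature column before the ARV summary and before HRA,
    so a premature beat does not contaminate either (the interval of the
    beat *after* a flagged one is also interpolated: both intervals are
    displaced by the same premature fiducial).
    """
    ann = recording.annotations
    fs = recording.fs
    n = len(ann)
    data: dict[str, np.ndarray] = {}
    data["duration"] = (ann[:, 2] - ann[:, 0]) / fs * 1000.0
    if recording.samples is not None:
        x = recording.samples
        amp = np.array([amplitude_features(x, a) for a in ann])
        data["ampmax"], data["pp"], data["rms"] = amp[:, 0], amp[:, 1], amp[:, 2]
        data["posar"] = np.array([positive_area(x, a, fs) for a in ann])
        for name, frac in _SLOPE_FRACTIONS.items():
            data[name] = np.array([slope_rate(x, a, fs, at=f"{frac * 100:g}%")
                                   for a in ann])
        data["smax"] = np.array([slope_rate(x, a, fs, at="max") for a in ann])
    data["ibi"] = compute_ibi(ann, fs)

    table = pd.DataFrame(data)
    flags = ectopic_flags if ectopic_flags is not None else recording.ectopic_flags
    if flags is not None and np.any(flags):
        flags = np.asarray(flags, dtype=bool)
        # A premature fiducial displaces its own cycle and the compensatory
        # one after it; the successor beat's interval-dependent features are
        # equally non-normal, so both beats are interpolated (the standard
        # normal-to-normal convention).
        ext = flags | np.roll(flags, 1)
        ext[0] = flags[0]
        for col in table.columns:
            table[col] = _interp_flagged(table[col].to_numpy(), ext)
    table = hra_adjust(table)
    arv = arv_summary(table["ibi"].to_numpy()[1:])
    return FeatureSeries(table=table, arv=arv,
                         channel_kind=recording.channel_kind,
                         phase=phase, patient_id=patient_id)


def _interp_flagged(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Interpolate flagged entries, tolerating NaNs elsewhere (kept)."""
    x = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(x) & ~flags
    if not ok.any():
        return x
    idx = np.arange(len(x))
    x[flags] = np.interp(idx[flags], idx[ok], x[ok])
    return x
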