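"""On-disk formats: recordings as CSV, annotations as JSON lines, cohort
manifests as JSON.

A recording CSV has columns ``sample_index, amplitude_mV``; an annotation
file has one JSON object per line with 0-based sample indices ``onset,
peak, offset`` and ``is_ectopic``.  A manifest maps every patient and phase
to its two channels' file pairs, plus provenance (generator config, seed,
package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import AnnotatedRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_manifest",
    "read_manifest",
]


def write_recording(rec: AnnotatedRecording, csv_path: str | Path,
                    ann_path: str | Path) -> None:
    csv_path, ann_path = Path(csv_path), Path(ann_path)
    if rec.samples is not None:
        pd.DataFrame({
            "sample_index": np.arange(len(rec.samples)),
            "amplitude_mV": rec.samples,
        }).to_csv(csv_path, index=False, float_format="%.6f")
    flags = (rec.ectopic_flags if rec.ectopic_flags is not None
             else np.zeros(rec.n_activations, dtype=bool))
    with open(ann_path, "w") as fh:
        for (onset, peak, offset), ect in zip(rec.annotations, flags):
            fh.write(json.dumps({"onset": int(onset), "peak": int(peak),
                                 "offset": int(offset),
                                 "is_ectopic": bool(ect)}) + "\n")


def read_recording(csv_path: str | Path | None, ann_path: str | Path,
                   fs: float, channel_kind: str) -> AnnotatedRecording:
    samples = None
    if csv_path is not None and Path(csv_path).exists():
        samples = pd.read_csv(csv_path)["amplitude_mV"].to_numpy(dtype=float)
    ann, flags = [], []
    with open(ann_path) as fh:
        for line in fh:
            d = json.loads(line)
            ann.append((d["onset"], d["peak"], d["offset"]))
            flags.append(bool(d.get("is_ectopic", False)))
    return AnnotatedRecording(samples=samples, fs=fs, channel_kind=channel_kind,
                              annotations=np.array(ann, dtype=np.int64),
                              ectopic_flags=np.array(flags, dtype=bool))


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
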