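"""Core record containers shared across the pipeline.

An :class:`AnnotatedRecording` is one channel of one five-minute acquisition:
the raw samples (mV, optional when only fiducial-level analysis is wanted)
plus per-activation delineation marks.  Annotations are stored as an
``(n, 3)`` integer array of 0-based sample indices ``[onset, peak, offset]``
with inclusive windows, the convention used everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Ablation phases, in acquisition order: baseline, after isolation of the
#: left pulmonary veins, and after the complete procedure.
PHASES = ("pre", "lpvi", "post")

#: Phase transitions over which ablation-induced variation is computed.
TRANSITIONS = (("pre", "lpvi"), ("pre", "post"), ("lpvi", "post"))

SURFACE = "surface"  # ECG lead II
CS = "cs"            # bipolar coronary-sinus electrogram
CHANNELS = (SURFACE, CS)


@dataclass
class AnnotatedRecording:
    """One channel's samples and activation annotations.

    Parameters
    ----------
    samples
        Signal in mV at sampling rate ``fs``, or ``None`` when the recording
        carries annotations only (fiducial-level analyses).
    fs
        Sampling rate in Hz.
    channel_kind
        ``"surface"`` (lead II, positive monophasic P-waves) or ``"cs"``
        (bipolar coronary-sinus channel, biphasic local activation waves).
    annotations
        ``(n, 3)`` int array of ``[onset, peak, offset]`` sample indices,
        strictly ordered within each activation and non-overlapping between
        consecutive activations.
    ectopic_flags
        Boolean flag per activation; ``None`` means unknown.
    """

    samples: np.ndarray | None
    fs: float
    channel_kind: str
    annotations: np.ndarray
    ectopic_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.annotations = np.asarray(self.annotations, dtype=np.int64)
        if self.annotations.ndim != 2 or self.annotations.shape[1] != 3:
            raise ValueError("annotations must be an (n, 3) array")
        if self.ectopic_flags is not None:
            self.ectopic_flags = np.asarray(self.ectopic_flags, dtype=bool)
            if len(self.ectopic_flags) != len(self.annotations):
                raise ValueError("ectopic_flags length mismatch")
        self.validate()

    @property
    def n_activations(self) -> int:
        return len(self.annotations)

    @property
    def onsets(self) -> np.ndarray:
        return self.annotations[:, 0]

    @property
    def peaks(self) -> np.ndarray:
        return self.annotations[:, 1]

    @property
    def offsets(self) -> np.ndarray:
        return self.annotations[:, 2]

    def peak_times_ms(self) -> np.ndarray:
        """Activation peak times in milliseconds from the recording start."""
        return self.peaks / self.fs * 1000.0

    def validate(self) -> None:
        a = self.annotations
        if len(a) == 0:
            return
        if not (np.all(a[:, 0] < a[:, 1]) and np.all(a[:, 1] < a[:, 2])):
            raise ValueError("each annotation must satisfy onset < peak < offset")
        if len(a) > 1 and not np.all(a[1:, 0] > a[:-1, 2]):
            raise ValueError("annotations overlap or are out of order")
        if np.any(a < 0):
            raise ValueError("negative sample index in annotations")
        if self.samples is not None and np.any(a[:, 2] >= len(self.samples)):
            raise ValueError("annotation index beyond end of samples")
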