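"""Core data containers shared across the pipeline.

Amplitude units are arbitrary throughout: surface-EMG hardware reports
uncalibrated microvolt-scale voltages and every downstream stage is either
amplitude-equivariant (filtering, energy thresholds recalibrated on the same
scale) or amplitude-invariant (min-max normalised spectrograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four gesture classes. ``falling`` is the positive class for
#: sensitivity/specificity; the remaining three are "daily activities".
GESTURES = ("walking", "squatting", "sitting", "falling")

#: Muscles sampled by the four electrode channels (lower-limb flexors and
#: extensors involved in gait, squatting and postural recovery).
CHANNEL_NAMES = (
    "rectus_femoris",
    "vastus_medialis",
    "tibialis_anterior",
    "gastrocnemius",
)

DEFAULT_FS_HZ = 1500.0


def gesture_index(label: str) -> int:
    """Integer code (0..3) of a gesture label; raises on unknown labels."""
    try:
        return GESTURES.index(label)
    except ValueError:
        raise ValueError(f"unknown gesture label {label!r}; expected one of {GESTURES}") from None


@dataclass
class EmgRecording:
    """A labelled multichannel sEMG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal values in arbitrary units. Must be finite.
    fs_hz : float
        Sampling rate, default 1500 Hz. Must exceed 1000 Hz so the
        10-500 Hz band lies below Nyquist.
    subject_id : int
        Identity of the volunteer, used for leave-one-subject-out splitting.
    gesture : str or None
        One of :data:`GESTURES`, or None when unlabelled.
    channel_names : tuple of str
        Muscle names, one per column of ``samples``.
    bursts : list of (int, int)
        Ground-truth activity intervals as half-open sample ranges
        ``[start, end)``. Empty for real data without annotations.
    rec_id : str
        Stable identifier used in manifests and reports.
    """

    samples: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ
    subject_id: int = 0
    gesture: str | None = None
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    bursts: list[tuple[int, int]] = field(default_factory=list)
    rec_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a non-empty (n_samples, n_channels) matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs_hz <= 1000.0:
            raise ValueError("fs_hz must exceed 1000 Hz (10-500 Hz band below Nyquist)")
        if self.gesture is not None:
            gesture_index(self.gesture)
        for s, e in self.bursts:
            if not (0 <= s < e <= self.n_samples):
                raise ValueError(f"burst interval ({s}, {e}) outside recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class ActiveSegment:
    """A detected activity interval, half-open in samples: ``[start, end)``."""

    start_sample: int
    end_sample: int
    rec_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError("segment bounds must satisfy 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample
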