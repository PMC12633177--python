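"""Core containers shared across the pipeline stages.

A dyadic recording holds, for each of the two interacting subjects, a raw
intensity array of shape ``(n_channels, n_wavelengths, n_samples)`` together
with per-channel metadata.  Channels are either *long* separation
(source-detector pairs sampling cortex plus scalp) or *short* separation
(sampling scalp only, used as nuisance regressors).  Task annotations mark
the experimental blocks (rest, tangram, video, conversation) in seconds from
recording start, as half-open windows ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical order of task blocks in the paradigm
TASK_ORDER = ("rest", "tangram", "video", "conversation")

#: subject roles within a dyad
SUBJECTS = ("child", "mother")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one source-detector channel of one subject."""

    subject: str
    source: int
    detector: int
    separation: str  # "long" | "short"
    region: str = ""

    def __post_init__(self) -> None:
        if self.separation not in ("long", "short"):
            raise ValueError(
                f"separation must be 'long' or 'short', got {self.separation!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.subject}:S{self.source}-D{self.detector}"


@dataclass(frozen=True)
class TaskAnnotation:
    """One task block, ``[start, end)`` in seconds from recording start."""

    task: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"annotation {self.task!r}: end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_annotations(
    annotations: list[TaskAnnotation], duration_s: float | None = None
) -> None:
    """Check ordering, non-overlap and containment of task annotations.

    Annotations must appear in temporal order, must not overlap, and — when
    their task names are all drawn from the canonical paradigm — must follow
    the paradigm order rest -> tangram -> video -> conversation.
    """
    prev_end = -np.inf
    order = {t: i for i, t in enumerate(TASK_ORDER)}
    prev_rank = -1
    for ann in annotations:
        if ann.start < prev_end:
            raise ValueError(
                f"annotations out of order or overlapping at {ann.task!r} "
                f"(start {ann.start} < previous end {prev_end})"
            )
        prev_end = ann.end
        if ann.task in order:
            if order[ann.task] < prev_rank:
                raise ValueError(
                    f"task {ann.task!r} violates paradigm order {TASK_ORDER}"
                )
            prev_rank = order[ann.task]
        if duration_s is not None and ann.end > duration_s + 1e-9:
            raise ValueError(
                f"annotation {ann.task!r} extends past recording end "
                f"({ann.end} > {duration_s})"
            )


@dataclass
class SubjectRecording:
    """Raw intensity of one subject: ``(n_channels, n_wavelengths, n_samples)``."""

    intensity: np.ndarray
    channels: list[ChannelInfo]
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (n_channels, n_wavelengths, n_samples)")
        if self.intensity.shape[0] != len(self.channels):
            raise ValueError("channel metadata does not match intensity array")
        if self.intensity.shape[1] != len(self.wavelengths):
            raise ValueError("intensity must carry one series per wavelength")
        seen = set()
        for ch in self.channels:
            key = (ch.source, ch.detector)
            if key in seen:
                raise ValueError(f"duplicate source-detector pair {key}")
            seen.add(key)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    def channel_indices(self, separation: str) -> list[int]:
        return [
            i for i, ch in enumerate(self.channels) if ch.separation == separation
        ]


@dataclass
class DyadRecording:
    """Paired recording of one child-mother dyad."""

    dyad_id: str
    fs: float
    subjects: dict[str, SubjectRecording]
    annotations: list[TaskAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.subjects) != set(SUBJECTS):
            raise ValueError(f"subjects must be exactly {SUBJECTS}")
        lengths = {s.n_samples for s in self.subjects.values()}
        if len(lengths) != 1:
            raise ValueError("subjects must share the same number of samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        validate_annotations(self.annotations, self.duration_s)

    @property
    def n_samples(self) -> int:
        return next(iter(self.subjects.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_intensity(self) -> None:
        """Raise if any intensity sample is non-positive or non-finite."""
        for name, sub in self.subjects.items():
            bad = ~np.isfinite(sub.intensity) | (sub.intensity <= 0)
            if bad.any():
                ch, wl, idx = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-positive/non-finite intensity: subject {name!r}, "
                    f"channel {sub.channels[ch].label}, wavelength index {wl}, "
                    f"sample {idx}"
                )

    def task_window(self, task: str) -> TaskAnnotation:
        for ann in self.annotations:
            if ann.task == task:
                return ann
        raise KeyError(f"no annotation for task {task!r}")
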