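"""Core domain types shared by all pipeline stages.

A recording is a 1-D :class:`Sequence` of samples (a joint coordinate over
time, a velocity, or a synthesized acceleration magnitude) annotated with an
ordinal clinical severity rating.  Wrist-worn accelerometer recordings enter
as a :class:`TriaxialSequence` and are reduced to a Sequence by the
``accel`` module before analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence as TypingSequence

import numpy as np

#: the three admissible physical kinds of a 1-D sequence
KINDS = ("position", "velocity", "acceleration")

#: the six per-recording representation labels used for clustering
REP_TYPES = ("raw", "diff", "stft_raw", "stacf_raw", "stft_diff", "stacf_diff")

#: supported pairwise dissimilarity measures
DISTANCES = ("dtw", "acf", "euclid", "ar_pic", "lpc_cep")

#: supported agglomeration rules (mirroring the hclust naming convention)
LINKAGES = ("complete", "ward_d", "ward_d2")

SIDES = ("L", "R", "NA")


@dataclass(frozen=True)
class SequenceMeta:
    """Identity and annotation of one recording."""

    sequence_id: str
    subject_id: str = "NA"
    trial_id: str = "NA"
    side: str = "NA"
    task: str = ""
    #: clinical severity rating (e.g. a UPDRS item, possibly a rater average);
    #: ``None`` when no rating is available
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.score is not None and not (np.isfinite(self.score) and self.score >= 0):
            raise ValueError(f"score must be finite and >= 0, got {self.score!r}")


@dataclass
class Sequence:
    """One recording: ordered real samples at a fixed sampling rate."""

    values: np.ndarray
    fps: float
    kind: str
    meta: SequenceMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(
                f"sequence {self.meta.sequence_id!r}: need >= 2 samples, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sequence {self.meta.sequence_id!r}: non-finite samples")
        if not (self.fps > 0):
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.values.size

    def replace(self, **kw) -> "Sequence":
        return dataclasses.replace(self, **kw)


@dataclass
class TriaxialSequence:
    """A 3-axis accelerometer recording (device units)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fps: float
    meta: SequenceMeta

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.size
        if not (self.y.size == n and self.z.size == n):
            raise ValueError(
                f"sequence {self.meta.sequence_id!r}: axis length mismatch "
                f"({self.x.size}, {self.y.size}, {self.z.size})"
            )
        if n < 2:
            raise ValueError(f"sequence {self.meta.sequence_id!r}: need >= 2 samples")
        for name, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise ValueError(
                    f"sequence {self.meta.sequence_id!r}: axis {name} non-finite"
                )
        if not (self.fps > 0):
            raise ValueError(f"fps must be > 0, got {self.fps}")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``width`` frames advanced by ``shift`` frames.

    Windows are half-open ``[start, start + width)`` with 0-based starts at
    multiples of ``shift``; trailing samples that do not fill a window are
    dropped.
    """

    width: int
    shift: int

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError(f"window width must be >= 2, got {self.width}")
        if not (1 <= self.shift <= self.width):
            raise ValueError(
                f"shift must satisfy 1 <= shift <= width, got shift={self.shift} "
                f"width={self.width}"
            )

    def n_windows(self, n_samples: int) -> int:
        """Number of full windows in a sequence of ``n_samples`` samples."""
        if n_samples < self.width:
            raise ValueError(
                f"sequence of length {n_samples} is shorter than the window "
                f"width {self.width}; minimum length is {self.width}"
            )
        return (n_samples - self.width) // self.shift + 1


class LabeledDataset:
    """An ordered collection of same-task, same-kind sequences."""

    def __init__(self, sequences: TypingSequence[Sequence]):
        seqs = list(sequences)
        ids = [s.meta.sequence_id for s in seqs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        self.sequences: list[Sequence] = seqs

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    @property
    def ids(self) -> list[str]:
        return [s.meta.sequence_id for s in self.sequences]

    def scored(self) -> "LabeledDataset":
        """Subset with a clinical score present (order preserved)."""
        return LabeledDataset([s for s in self.sequences if s.meta.score is not None])

    def subset(self, predicate) -> "LabeledDataset":
        return LabeledDataset([s for s in self.sequences if predicate(s)])


@dataclass
class AnalysisConfig:
    """One analysis condition (or the defaults for a grid run)."""

    window: WindowSpec = field(default_factory=lambda: WindowSpec(45, 5))
    representation: str = "stacf_raw"
    distance: str = "dtw"
    linkage: str = "ward_d"
    n_clusters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in REP_TYPES:
            raise ValueError(f"representation must be one of {REP_TYPES}")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
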