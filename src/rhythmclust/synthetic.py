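"""Seeded generator of quasi-periodic movement sequences.

Emulates the two recording modalities the pipeline targets:

* **Tapping trajectories** (e.g. the vertical knee coordinate during
  repeated foot stomping): concatenated strokes, one per movement cycle,
  with per-cycle period and amplitude jitter, occasional motionless
  pauses, and additive sensor/pose-estimation noise.
* **3-axis accelerometer rotation analogues** (e.g. wrist
  pronation-supination): three phase-shifted sinusoids sharing one
  jittered phase track, plus per-axis offsets and noise.

Severity of rhythm disruption is controlled by the jitter/pause
parameters; :func:`gen_cohort` builds a labeled two-group dataset with
ordinal pseudo-clinical scores (0-3, monotone in irregularity by
construction) so that AUC recovery is a meaningful target.  All output is
a pure function of the parameters, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import LabeledDataset, Sequence, SequenceMeta, TriaxialSequence

#: stroke shapes; one cycle spans samples t = 0..period-1
_SHAPES = {
    "half_sine": lambda u: np.sin(np.pi * u),
    "sine": lambda u: np.sin(2.0 * np.pi * u),
    "sawtooth": lambda u: 1.0 - np.abs(2.0 * u - 1.0),
}


@dataclass(frozen=True)
class SynthParams:
    """Generator controls; jitter magnitudes are fractions of the nominal."""

    n_cycles: int = 8
    period: int = 30  # frames per movement cycle
    fps: float = 30.0
    amplitude: float = 1.0
    period_jitter_sd: float = 0.03
    amplitude_jitter_sd: float = 0.05
    pause_prob: float = 0.05
    pause_len: int = 15
    noise_sd: float = 0.02  # fraction of amplitude
    seed: int = 0
    shape: str = "half_sine"

    def __post_init__(self) -> None:
        if self.period < 4:
            raise ValueError(f"period must be >= 4 frames, got {self.period}")
        if self.n_cycles < 1:
            raise ValueError("need >= 1 cycle")
        for name in ("period_jitter_sd", "amplitude_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.pause_prob <= 1.0):
            raise ValueError("pause_prob must lie in [0, 1]")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {sorted(_SHAPES)}")


def _meta(p: SynthParams, sequence_id: str, score=None, **kw) -> SequenceMeta:
    return SequenceMeta(sequence_id=sequence_id, score=score, **kw)


def gen_tapping(p: SynthParams, meta: SequenceMeta | None = None) -> Sequence:
    """One tapping trajectory: jittered strokes, pauses, additive noise."""
    rng = np.random.default_rng(p.seed)
    shape = _SHAPES[p.shape]
    chunks = []
    for _ in range(p.n_cycles):
        per = max(4, int(round(p.period * (1.0 + rng.normal(0.0, p.period_jitter_sd)))))
        amp = p.amplitude * (1.0 + rng.normal(0.0, p.amplitude_jitter_sd))
        chunks.append(amp * shape(np.arange(per) / per))
        if rng.random() < p.pause_prob:
            chunks.append(np.zeros(p.pause_len))
    values = np.concatenate(chunks)
    values = values + rng.normal(0.0, p.noise_sd * p.amplitude, size=values.size)
    meta = meta or _meta(p, f"tap_{p.seed}", task="tapping")
    return Sequence(values, fps=p.fps, kind="position", meta=meta)


def gen_accel3(p: SynthParams, meta: SequenceMeta | None = None) -> TriaxialSequence:
    """One rotation-analogue 3-axis accelerometer recording.

    A single phase track advances 2*pi per (jittered) cycle; the three
    axes observe it at unevenly spaced phase offsets (0, pi/2, pi) with
    per-axis offsets and gains.  The offsets are deliberately not the
    symmetric 120-degree trio: after per-axis 0-1 normalization that trio
    has a constant sum of squares, which would make the downstream
    magnitude sequence degenerate; real sensors are never mounted that
    symmetrically either.
    """
    rng = np.random.default_rng(p.seed)
    increments = []
    for _ in range(p.n_cycles):
        per = max(4, int(round(p.period * (1.0 + rng.normal(0.0, p.period_jitter_sd)))))
        increments.append(np.full(per, 2.0 * np.pi / per))
    phase = np.cumsum(np.concatenate(increments))
    n = phase.size
    offsets = rng.uniform(-0.5, 0.5, size=3)
    gains = rng.uniform(0.7, 1.3, size=3)
    phase_offsets = (0.0, np.pi / 2.0, np.pi)
    axes = []
    for i in range(3):
        axis = offsets[i] + gains[i] * p.amplitude * np.sin(phase + phase_offsets[i])
        axis = axis + rng.normal(0.0, p.noise_sd * p.amplitude, size=n)
        axes.append(axis)
    meta = meta or _meta(p, f"accel_{p.seed}", task="pronation_supination")
    return TriaxialSequence(axes[0], axes[1], axes[2], fps=p.fps, meta=meta)


def _boosted(p: SynthParams, boost: float) -> SynthParams:
    return replace(
        p,
        period_jitter_sd=p.period_jitter_sd * boost,
        amplitude_jitter_sd=p.amplitude_jitter_sd * boost,
        pause_prob=min(1.0, p.pause_prob * boost),
    )


def gen_cohort(
    n_regular: int,
    n_irregular: int,
    base: SynthParams | None = None,
    irregular_boost: float = 6.0,
    seed: int = 0,
    n_cycles_range: tuple[int, int] = (2, 10),
    kind: str = "tapping",
):
    """Two-group labeled cohort: regular vs rhythm-disrupted members.

    Regular members use ``base`` with scores drawn from {0, 1}; irregular
    members have their jitter and pause parameters multiplied by
    ``irregular_boost`` and scores from {2, 3}.  Cycle counts are drawn
    uniformly from ``n_cycles_range`` so sequence lengths spread over
    roughly 57-329 frames at the default 30-frame period.  Member seeds
    derive deterministically from ``seed``.

    Returns a :class:`LabeledDataset` for ``kind='tapping'`` or a list of
    :class:`TriaxialSequence` for ``kind='accel'``.
    """
    if n_regular < 1 or n_irregular < 1:
        raise ValueError("both groups need >= 1 member")
    base = base or SynthParams()
    rng = np.random.default_rng(seed)
    lo, hi = n_cycles_range
    members = []
    total = n_regular + n_irregular
    for idx in range(total):
        irregular = idx >= n_regular
        params = _boosted(base, irregular_boost) if irregular else base
        params = replace(
            params,
            n_cycles=int(rng.integers(lo, hi + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        score = float(rng.integers(2, 4) if irregular else rng.integers(0, 2))
        meta = SequenceMeta(
            sequence_id=f"syn{idx:03d}",
            subject_id=f"sub{idx:03d}",
            trial_id="t1",
            side="L" if idx % 2 == 0 else "R",
            task="tapping" if kind == "tapping" else "pronation_supination",
            score=score,
        )
        if kind == "tapping":
            members.append(gen_tapping(params, meta=meta))
        elif kind == "accel":
            members.append(gen_accel3(params, meta=meta))
        else:
            raise ValueError(f"kind must be 'tapping' or 'accel', got {kind!r}")
    return LabeledDataset(members) if kind == "tapping" else members


#: parameters of the named 40-recording discrimination fixture
HEADLINE_SEED = 20201008
HEADLINE_BASE = SynthParams(period=30, fps=30.0, period_jitter_sd=0.03, pause_prob=0.05)
HEADLINE_BOOST = 6.0


def headline_cohort(seed: int = HEADLINE_SEED, irregular_boost: float = HEADLINE_BOOST):
    """The pinned 20 regular + 20 irregular tapping cohort."""
    return gen_cohort(20, 20, base=HEADLINE_BASE, irregular_boost=irregular_boost, seed=seed)
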