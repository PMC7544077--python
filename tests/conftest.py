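import numpy as np
import pytest

from rhythmclust import LabeledDataset, Sequence, SequenceMeta, WindowSpec


def make_seq(values, fps=30.0, kind="position", sid="s1", score=None, **meta_kw):
    meta = SequenceMeta(sequence_id=sid, score=score, **meta_kw)
    return Sequence(np.asarray(values, dtype=float), fps=fps, kind=kind, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def window45():
    return WindowSpec(45, 5)


@pytest.fixture
def small_dataset(rng):
    """Eight noisy quasi-periodic sequences with scores, lengths 57-120."""
    seqs = []
    for i in range(8):
        n = int(rng.integers(57, 121))
        period = int(rng.integers(20, 35))
        t = np.arange(n)
        vals = np.sin(2 * np.pi * t / period) + 0.1 * rng.normal(size=n)
        seqs.append(
            make_seq(
                vals,
                sid=f"s{i:02d}",
                score=float(i % 4),
                subject_id=f"sub{i}",
                side="L" if i % 2 == 0 else "R",
                task="tapping",
            )
        )
    return LabeledDataset(seqs)
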