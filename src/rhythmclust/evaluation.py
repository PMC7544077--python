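"""ROC/AUC scoring of cluster assignments against clinical ratings, AUC
comparison by DeLong's test, Benjamini-Hochberg adjustment, and the full
condition grid.

The clustering is unsupervised, so cluster labels are arbitrary: the AUC is
reported both raw (cluster 1 treated as the control class) and oriented
(``max(auc, 1 - auc)``), and grid summaries use the oriented value.  The
predictor is the clinical score; the response is cluster membership; ties
count 1/2 (scores are rater averages, so ties are common).

Comparing two representations compares AUCs computed from two *different*
binary responses over the same recordings, which the classical paired
DeLong test does not cover; the paired variant is therefore used only when
the two cluster partitions coincide, and the unpaired (independent
variances) variant otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import DISTANCES, LINKAGES, REP_TYPES, LabeledDataset, WindowSpec
from .clustering import ClusterAssignment, agglomerate, cut_two
from .distances import distance_matrix
from .representations import make_representation

logger = logging.getLogger(__name__)

#: default representation pairs for AUC comparison: each non-trivial
#: fingerprint against its source, and ACF against FFT within each family
DEFAULT_PAIRS = (
    ("raw", "stacf_raw"),
    ("stacf_raw", "stft_raw"),
    ("diff", "stacf_diff"),
    ("stacf_diff", "stft_diff"),
)


@dataclass
class AucResult:
    """AUC of clinical score against a binary cluster membership.

    Placement values (per-observation conditional exceedance rates) are
    retained so DeLong variances and covariances can be formed later.
    """

    auc_raw: float
    auc_oriented: float
    n1: int
    n2: int
    variance: float
    v10: np.ndarray  # placements of cluster-2 ("case") observations
    v01: np.ndarray  # placements of cluster-1 ("control") observations
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]


def roc_auc(scores, labels) -> AucResult:
    """Mann-Whitney AUC (ties 1/2) with DeLong variance from placements.

    ``scores`` and ``labels`` are aligned per-sequence arrays; labels are
    1/2 cluster memberships.  ``ids`` default to positional indices.
    """
    return roc_auc_ids(scores, labels, [str(i) for i in range(len(scores))])


def roc_auc_ids(scores, labels, ids) -> AucResult:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ids = list(ids)
    ok = np.isfinite(scores)
    if not ok.all():
        logger.info("dropping %d sequences without scores", int((~ok).sum()))
        scores, labels = scores[ok], labels[ok]
        ids = [i for i, keep in zip(ids, ok) if keep]
    cases = labels == 2
    controls = labels == 1
    m, n = int(cases.sum()), int(controls.sum())
    if m == 0 or n == 0:
        raise ValueError(
            f"both clusters must be non-empty after score filtering "
            f"(cluster1={n}, cluster2={m})"
        )
    x = scores[cases]  # cluster 2 treated as the case class
    y = scores[controls]
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return AucResult(
        auc_raw=auc,
        auc_oriented=max(auc, 1.0 - auc),
        n1=n,
        n2=m,
        variance=s10 / m + s01 / n,
        v10=v10,
        v01=v01,
        case_ids=tuple(i for i, c in zip(ids, cases) if c),
        control_ids=tuple(i for i, c in zip(ids, controls) if c),
    )


def auc_from_assignment(ds: LabeledDataset, assignment: ClusterAssignment) -> AucResult:
    scored = ds.scored()
    return roc_auc_ids(
        [s.meta.score for s in scored],
        assignment.label_array(scored.ids),
        scored.ids,
    )


def same_partition(a: AucResult, b: AucResult) -> bool:
    return set(a.case_ids) == set(b.case_ids) and set(a.control_ids) == set(b.control_ids)


def delong_test(a: AucResult, b: AucResult, paired: bool = False) -> tuple[float, float]:
    """Compare two AUCs; returns (z, two-sided p).

    Paired mode requires identical case/control partitions (placement
    covariance is then included); unpaired mode sums the independent
    variances.
    """
    if paired:
        if not same_partition(a, b):
            raise ValueError(
                "paired DeLong test requires identical case/control partitions; "
                "use paired=False for differing cluster assignments"
            )
        # align b's placements to a's id order
        order_case = [b.case_ids.index(i) for i in a.case_ids]
        order_ctrl = [b.control_ids.index(i) for i in a.control_ids]
        b10 = b.v10[order_case]
        b01 = b.v01[order_ctrl]
        m, n = len(a.case_ids), len(a.control_ids)
        s10 = float(np.cov(a.v10, b10, ddof=1)[0, 1]) if m > 1 else 0.0
        s01 = float(np.cov(a.v01, b01, ddof=1)[0, 1]) if n > 1 else 0.0
        var = a.variance + b.variance - 2.0 * (s10 / m + s01 / n)
    else:
        var = a.variance + b.variance
    diff = a.auc_raw - b.auc_raw
    if diff == 0.0:
        return 0.0, 1.0
    if var <= 0.0:
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / float(np.sqrt(var))
    return float(z), float(2.0 * norm.sf(abs(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GridResult:
    """AUC per (representation x distance x linkage) condition."""

    results: dict[tuple[str, str, str], AucResult] = field(default_factory=dict)
    assignments: dict[tuple[str, str, str], ClusterAssignment] = field(default_factory=dict)
    errors: dict[tuple[str, str, str], str] = field(default_factory=dict)
    n_dropped_unscored: int = 0


def run_grid(
    ds: LabeledDataset,
    window: WindowSpec,
    representations=REP_TYPES,
    distances=DISTANCES,
    linkages=LINKAGES,
    distance_kwargs: Optional[dict] = None,
) -> GridResult:
    """Evaluate every requested condition on a dataset.

    Per-condition failures (too-short sequences, degenerate distance
    matrices, single-cluster cuts ...) are recorded as error cells; the
    grid always completes.
    """
    distance_kwargs = distance_kwargs or {}
    scored = ds.scored()
    dropped = len(ds) - len(scored)
    if dropped:
        logger.info("dropping %d unscored sequences before evaluation", dropped)
    if len(scored) < 2:
        raise ValueError(f"need >= 2 scored sequences, got {len(scored)}")
    out = GridResult(n_dropped_unscored=dropped)
    scores = [s.meta.score for s in scored]
    ids = scored.ids

    for rep in representations:
        try:
            reps = [make_representation(s, rep, window) for s in scored]
        except ValueError as e:
            for dist, link in itertools.product(distances, linkages):
                out.errors[(rep, dist, link)] = str(e)
            continue
        for dist in distances:
            try:
                dmat = distance_matrix(reps, dist, **distance_kwargs.get(dist, {}))
            except ValueError as e:
                for link in linkages:
                    out.errors[(rep, dist, link)] = str(e)
                continue
            for link in linkages:
                key = (rep, dist, link)
                try:
                    tree = agglomerate(dmat, link)
                    assignment = cut_two(
                        tree, representation=rep, distance=dist, linkage=link
                    )
                    res = roc_auc_ids(scores, assignment.label_array(ids), ids)
                except ValueError as e:
                    out.errors[key] = str(e)
                    continue
                out.results[key] = res
                out.assignments[key] = assignment
    return out


@dataclass
class ComparisonRow:
    pair: str
    representation_a: str
    representation_b: str
    auc_a: float
    auc_b: float
    z: float
    p: float
    p_fdr: float = np.nan
    significant: bool = False


@dataclass
class ComparisonResult:
    rows: list[ComparisonRow]
    distance: str
    linkage: str
    alpha: float = 0.05


def compare_representations(
    grid: GridResult,
    distance: str,
    linkage: str,
    pairs=DEFAULT_PAIRS,
    alpha: float = 0.05,
) -> ComparisonResult:
    """DeLong-compare representation pairs at one (distance, linkage)
    condition, BH-adjusting the p-values across the pairs.

    The paired DeLong variant is used when the two cluster partitions
    coincide, the unpaired variant otherwise.
    """
    rows = []
    for rep_a, rep_b in pairs:
        key_a, key_b = (rep_a, distance, linkage), (rep_b, distance, linkage)
        for key in (key_a, key_b):
            if key not in grid.results:
                reason = grid.errors.get(key, "condition not in grid")
                raise ValueError(f"missing grid cell {key}: {reason}")
        a, b = grid.results[key_a], grid.results[key_b]
        z, p = delong_test(a, b, paired=same_partition(a, b))
        rows.append(
            ComparisonRow(
                pair=f"{rep_a}_vs_{rep_b}",
                representation_a=rep_a,
                representation_b=rep_b,
                auc_a=a.auc_raw,
                auc_b=b.auc_raw,
                z=z,
                p=p,
            )
        )
    adjusted = bh_adjust([r.p for r in rows])
    for row, q in zip(rows, adjusted):
        row.p_fdr = float(q)
        row.significant = bool(q < alpha)
    return ComparisonResult(rows=rows, distance=distance, linkage=linkage, alpha=alpha)
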