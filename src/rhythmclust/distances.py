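"""Pairwise dissimilarities between same-type representations.

Five measures are provided, all usable on pairs of unequal length (either
natively, as for DTW and the model-based measures, or by a documented
truncation rule for the plain Euclidean distance):

``dtw``
    Classic dynamic time warping: absolute-difference local cost, steps
    (i-1,j), (i,j-1), (i-1,j-1), no warping-window constraint,
    unnormalized accumulated cost.
``euclid``
    L2 distance after truncating both vectors to the shorter length.
``acf``
    L2 distance between the biased sample autocorrelations (lags
    1..max_lag) of the two vectors — invariant to positive affine
    transforms of either input.
``ar_pic``
    Piccolo-style distance: L2 between fitted AR coefficient vectors
    (AIC-selected order), the shorter zero-padded.
``lpc_cep``
    L2 between LPC cepstral coefficient vectors derived from the fitted
    AR models by the standard recursion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import DISTANCES

logger = logging.getLogger(__name__)

try:  # numba gives the DTW recursion C-loop speed; fall back to pure python
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

DEFAULT_ACF_MAX_LAG = 50
DEFAULT_AR_MAX_ORDER = 10
DEFAULT_N_CEP = 25


def _dtw_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(a[i - 1] - b[j - 1])
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return D[n, m]


_dtw_impl = njit(cache=True)(_dtw_py) if njit is not None else _dtw_py


def dist_dtw(a, b) -> float:
    """Unnormalized dynamic time warping distance."""
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw inputs must be non-empty")
    return float(_dtw_impl(a, b))


def dist_euclid(a, b) -> float:
    """L2 distance; unequal lengths are truncated to the shorter (logged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("euclidean inputs must be non-empty")
    if a.size != b.size:
        logger.debug(
            "euclidean distance on unequal lengths (%d, %d): truncating to shorter",
            a.size,
            b.size,
        )
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
    return float(np.linalg.norm(a - b))


def acf_vector(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of the whole vector, lags 1..max_lag."""
    x = np.asarray(x, dtype=float)
    if x.size <= max_lag:
        raise ValueError(f"need length > max_lag ({max_lag}), got {x.size}")
    x = x - x.mean()
    ss = float(np.dot(x, x))
    if ss == 0.0:
        return np.zeros(max_lag)
    full = np.correlate(x, x, mode="full")[x.size - 1 :] / ss
    return full[1 : max_lag + 1]


def dist_acf(a, b, max_lag: int = DEFAULT_ACF_MAX_LAG) -> float:
    """L2 distance between autocorrelation vectors (lags 1..max_lag).

    ``max_lag`` is capped at the shorter input length minus one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lag = min(max_lag, min(a.size, b.size) - 1)
    if lag < 1:
        raise ValueError("inputs too short for autocorrelation distance")
    return float(np.linalg.norm(acf_vector(a, lag) - acf_vector(b, lag)))


def ar_coefficients(x, max_order: int = DEFAULT_AR_MAX_ORDER) -> np.ndarray:
    """AR coefficients of ``x`` with order selected by AIC up to max_order.

    Returns the phi vector of ``x_t = c + sum_k phi_k x_{t-k} + e_t``;
    empty when AIC selects order 0.
    """
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError(f"AR fit needs >= 10 samples, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("AR fit failed: constant input")
    maxlag = min(max_order, x.size // 2 - 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = ar_select_order(x, maxlag=maxlag, ic="aic", trend="c")
            lags = sel.ar_lags
            if not lags:
                return np.zeros(0)
            res = AutoReg(x, lags=lags, trend="c").fit()
    except Exception as e:  # statsmodels raises various linalg errors
        raise ValueError(f"AR fit failed: {e}") from e
    return np.asarray(res.params[1:], dtype=float)


def padded_l2(a: np.ndarray, b: np.ndarray) -> float:
    """L2 distance after zero-padding the shorter coefficient vector."""
    n = max(a.size, b.size)
    pa = np.zeros(n)
    pa[: a.size] = a
    pb = np.zeros(n)
    pb[: b.size] = b
    return float(np.linalg.norm(pa - pb))


def dist_ar_pic(a, b, max_order: int = DEFAULT_AR_MAX_ORDER) -> float:
    """Piccolo distance: L2 between AIC-selected AR coefficient vectors."""
    return padded_l2(ar_coefficients(a, max_order), ar_coefficients(b, max_order))


def lpc_cepstrum(phi: np.ndarray, n_cep: int = DEFAULT_N_CEP) -> np.ndarray:
    """Cepstral coefficients c_1..c_n of the all-pole model 1/A(z).

    With ``A(z) = 1 - sum_k phi_k z^-k`` (i.e. LPC coefficients
    ``a_k = -phi_k``), the complex cepstrum of the minimum-phase filter
    ``1/A`` satisfies the standard recursion

        c_1 = -a_1
        c_n = -a_n - (1/n) sum_{k=max(1, n-p)}^{n-1} k c_k a_{n-k}

    where a_k = 0 for k > p.
    """
    a = -np.asarray(phi, dtype=float)
    p = a.size
    c = np.zeros(n_cep)
    for n in range(1, n_cep + 1):
        acc = -a[n - 1] if n <= p else 0.0
        for k in range(max(1, n - p), n):
            acc -= (k / n) * c[k - 1] * a[n - 1 - k]
        c[n - 1] = acc
    return c


def dist_lpc_cep(
    a, b, n_cep: int = DEFAULT_N_CEP, max_order: int = DEFAULT_AR_MAX_ORDER
) -> float:
    """L2 distance between LPC cepstral coefficient vectors."""
    ca = lpc_cepstrum(ar_coefficients(a, max_order), n_cep)
    cb = lpc_cepstrum(ar_coefficients(b, max_order), n_cep)
    return float(np.linalg.norm(ca - cb))


_DISPATCH = {
    "dtw": dist_dtw,
    "euclid": dist_euclid,
    "acf": dist_acf,
    "ar_pic": dist_ar_pic,
    "lpc_cep": dist_lpc_cep,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix over a set of recordings."""

    entries: np.ndarray
    method: str
    ids: list[str]

    def __post_init__(self) -> None:
        e = self.entries
        n = len(self.ids)
        if e.shape != (n, n):
            raise ValueError(f"matrix shape {e.shape} does not match {n} ids")
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite distances")
        if not np.allclose(e, e.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(e) != 0) or np.any(e < 0):
            raise ValueError("distances must be >= 0 with zero diagonal")


def distance_matrix(representations, method: str, **kwargs) -> DistanceMatrix:
    """All pairwise distances among same-type representations."""
    reps = list(representations)
    if len(reps) < 2:
        raise ValueError("need >= 2 representations")
    types = {r.rep_type for r in reps}
    if len(types) > 1:
        raise ValueError(f"mixed representation types: {sorted(types)}")
    if method not in DISTANCES:
        raise ValueError(f"method must be one of {DISTANCES}, got {method!r}")
    n = len(reps)
    d = np.zeros((n, n))
    vectors = [np.asarray(r.vector, dtype=float) for r in reps]
    for r, v in zip(reps, vectors):
        if not np.all(np.isfinite(v)):
            raise ValueError(
                f"representation vector of {r.source_id!r} contains non-finite values"
            )
    if method in ("ar_pic", "lpc_cep"):
        # the AR fit depends on one vector only: fit once per recording
        max_order = kwargs.get("max_order", DEFAULT_AR_MAX_ORDER)
        coeffs = []
        for r, v in zip(reps, vectors):
            try:
                coeffs.append(ar_coefficients(v, max_order))
            except ValueError as e:
                raise ValueError(f"AR fit failed for {r.source_id!r}: {e}") from e
        if method == "lpc_cep":
            n_cep = kwargs.get("n_cep", DEFAULT_N_CEP)
            feats = [lpc_cepstrum(c, n_cep) for c in coeffs]
        else:
            feats = coeffs
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = padded_l2(feats[i], feats[j])
    else:
        fn = _DISPATCH[method]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = fn(vectors[i], vectors[j], **kwargs)
    return DistanceMatrix(entries=d, method=method, ids=[r.source_id for r in reps])
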