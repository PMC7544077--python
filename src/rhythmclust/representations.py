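"""Per-recording representations: raw, difference, and averaged short-time
ACF / FFT fingerprints.

A sliding window is applied to the (optionally differenced) sequence; each
window is transformed either to its sample autocorrelation function (lags
``0..width-1``) or to its magnitude spectrum (bins ``1..width//2``, DC
excluded).  Stacking the per-window vectors as columns gives a short-time
matrix; averaging its rows gives a fixed-length periodicity fingerprint
whose length depends only on the window width, not on the recording length.
The averaged ACF fingerprint is invariant to positive affine rescaling of
the input, so recordings need no amplitude standardization; the magnitude
spectrum scales linearly with the input and serves as the non-invariant
comparison representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import REP_TYPES, Sequence, WindowSpec

logger = logging.getLogger(__name__)

#: kind promotion under first differencing
_DIFF_KIND = {"position": "velocity", "velocity": "acceleration", "acceleration": "acceleration"}


@dataclass
class ShortTimeMatrix:
    """Lag-or-frequency x window-index matrix from a sliding transform.

    ACF rows are lags ``0..width-1`` (entries in [-1, 1], lag-0 row 1, or
    NaN for degenerate constant windows); FFT rows are magnitude bins
    ``1..width//2`` (entries >= 0).
    """

    entries: np.ndarray
    transform: str  # "ACF" | "FFT"
    window: WindowSpec


@dataclass
class Representation:
    """One fixed-role feature vector per recording."""

    vector: np.ndarray
    rep_type: str
    source_id: str


def difference(seq: Sequence) -> Sequence:
    """First-difference a sequence (position -> velocity)."""
    if len(seq) < 3:
        raise ValueError(
            f"sequence {seq.meta.sequence_id!r}: need >= 3 samples to difference, "
            f"got {len(seq)}"
        )
    return seq.replace(values=np.diff(seq.values), kind=_DIFF_KIND[seq.kind])


def sliding_windows(values: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """All full windows of ``values`` as rows of a (n_windows, width) array."""
    values = np.asarray(values, dtype=float)
    n = spec.n_windows(values.size)  # raises for too-short input
    starts = np.arange(n) * spec.shift
    return np.stack([values[s : s + spec.width] for s in starts])


def window_acf(window: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation of one window, lags 0..W-1.

    ``r_k = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2`` so
    ``r_0 = 1``.  A constant (zero-variance) window has no defined ACF and
    yields an all-NaN vector with a logged warning.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError(f"window must have >= 2 samples, got {x.size}")
    x = x - x.mean()
    ss = float(np.dot(x, x))
    if ss == 0.0:
        logger.warning("constant window: autocorrelation undefined, returning NaN")
        return np.full(x.size, np.nan)
    return np.correlate(x, x, mode="full")[x.size - 1 :] / ss


def window_fft(window: np.ndarray) -> np.ndarray:
    """Magnitude spectrum of one mean-removed window, bins 1..W//2.

    Rectangular window, no zero padding; the DC bin is excluded because
    windows are demeaned and it carries no rhythm information.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError(f"window must have >= 2 samples, got {x.size}")
    spectrum = np.fft.rfft(x - x.mean())
    return np.abs(spectrum)[1 : x.size // 2 + 1]


def short_time_matrix(seq: Sequence, spec: WindowSpec, transform: str) -> ShortTimeMatrix:
    """Apply a windowed transform along the sequence and stack columns."""
    if transform not in ("ACF", "FFT"):
        raise ValueError(f"transform must be 'ACF' or 'FFT', got {transform!r}")
    fn = window_acf if transform == "ACF" else window_fft
    windows = sliding_windows(seq.values, spec)
    cols = [fn(w) for w in windows]
    return ShortTimeMatrix(entries=np.stack(cols, axis=1), transform=transform, window=spec)


def row_average(matrix: ShortTimeMatrix) -> np.ndarray:
    """Mean of each row across windows, skipping NaN (degenerate) columns."""
    m = matrix.entries
    if m.ndim != 2 or m.shape[1] < 1:
        raise ValueError("short-time matrix must have >= 1 column")
    valid = np.isfinite(m)
    counts = valid.sum(axis=1)
    if np.any(counts == 0):
        logger.warning(
            "%d rows have no valid window; averaged value is NaN", int((counts == 0).sum())
        )
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, np.nansum(np.where(valid, m, 0.0), axis=1), np.nan)
        return out / np.where(counts > 0, counts, 1)


def dominant_period_lag(acf_vec: np.ndarray, min_lag: int = 2) -> int:
    """Period estimate from an (averaged) autocorrelation vector.

    Any smooth signal has an autocorrelation shoulder near lag 0 that
    exceeds the period peak (which the biased estimator additionally
    attenuates by the overlap fraction), so a plain argmax lands on the
    shoulder.  The standard pitch-detection rule is used instead: advance
    past the initial shoulder to the first local minimum at or beyond
    ``min_lag``, then take the argmax of the remaining lags.
    """
    v = np.asarray(acf_vec, dtype=float)
    if v.size <= min_lag:
        raise ValueError(f"need more than {min_lag} lags, got {v.size}")
    k = min_lag
    while k + 1 < v.size and v[k + 1] < v[k]:
        k += 1
    return k + int(np.nanargmax(v[k:]))


def make_representation(seq: Sequence, rep_type: str, spec: WindowSpec) -> Representation:
    """Build one of the six clustering representations of a recording."""
    if rep_type not in REP_TYPES:
        raise ValueError(f"rep_type must be one of {REP_TYPES}, got {rep_type!r}")
    sid = seq.meta.sequence_id
    try:
        if rep_type == "raw":
            vec = seq.values.copy()
        elif rep_type == "diff":
            vec = difference(seq).values
        else:
            base = seq if rep_type.endswith("_raw") else difference(seq)
            transform = "ACF" if rep_type.startswith("stacf") else "FFT"
            vec = row_average(short_time_matrix(base, spec, transform))
    except ValueError as e:
        raise ValueError(f"representation {rep_type!r} of {sid!r} failed: {e}") from e
    return Representation(vector=vec, rep_type=rep_type, source_id=sid)
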