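"""Independent reference implementations used to verify the package.

Each oracle takes the most literal route available (direct summation,
exhaustive enumeration, textbook recursion) and shares no code with the
implementation it checks.
"""

import itertools

import numpy as np


def acf_direct(x, lags=None):
    """Biased sample ACF by direct double summation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    denom = sum((x[t] - xbar) ** 2 for t in range(n))
    lags = range(n) if lags is None else lags
    out = []
    for k in lags:
        num = sum((x[t] - xbar) * (x[t + k] - xbar) for t in range(n - k))
        out.append(num / denom)
    return np.array(out)


def dft_magnitudes(x):
    """Naive O(W^2) DFT magnitudes of the demeaned window, bins 1..W//2."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    W = x.size
    out = []
    for k in range(1, W // 2 + 1):
        acc = 0j
        for t in range(W):
            acc += x[t] * np.exp(-2j * np.pi * k * t / W)
        out.append(abs(acc))
    return np.array(out)


def dtw_exhaustive(a, b):
    """Minimum accumulated |.| cost over all monotone alignment paths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def rec(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        prev = []
        if i > 0:
            prev.append(rec(i - 1, j))
        if j > 0:
            prev.append(rec(i, j - 1))
        if i > 0 and j > 0:
            prev.append(rec(i - 1, j - 1))
        return cost + min(prev)

    return rec(a.size - 1, b.size - 1)


def lance_williams_reference(d, linkage):
    """Set-based agglomeration oracle, O(n^3) with explicit cluster dicts.

    Returns merges as (frozenset_a, frozenset_b, height) triples with the
    same linkage semantics as the package: complete = max update; ward_d =
    Ward recurrence on the given dissimilarities; ward_d2 = Ward recurrence
    on squared dissimilarities with square-root heights.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    work = {}
    clusters = [frozenset([i]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            val = d[i, j] ** 2 if linkage == "ward_d2" else d[i, j]
            work[frozenset([clusters[i], clusters[j]])] = val
    merges = []
    while len(clusters) > 1:
        best_pair, best_val = None, np.inf
        for ci, cj in itertools.combinations(clusters, 2):
            v = work[frozenset([ci, cj])]
            if v < best_val - 1e-15:
                best_pair, best_val = (ci, cj), v
            elif abs(v - best_val) <= 1e-15 and best_pair is not None:
                # tie: prefer the pair with the smallest member indices
                if sorted(map(min, (ci, cj))) < sorted(map(min, best_pair)):
                    best_pair = (ci, cj)
        ci, cj = best_pair
        height = np.sqrt(best_val) if linkage == "ward_d2" else best_val
        merged = ci | cj
        new_work = {}
        for ck in clusters:
            if ck in (ci, cj):
                continue
            dik = work[frozenset([ci, ck])]
            djk = work[frozenset([cj, ck])]
            dij = work[frozenset([ci, cj])]
            if linkage == "complete":
                val = max(dik, djk)
            else:
                si, sj, sk = len(ci), len(cj), len(ck)
                val = ((si + sk) * dik + (sj + sk) * djk - sk * dij) / (si + sj + sk)
            new_work[frozenset([merged, ck])] = val
        for key, val in work.items():
            if ci not in key and cj not in key:
                new_work[key] = val
        work = new_work
        merges.append((ci, cj, height))
        clusters = [c for c in clusters if c not in (ci, cj)] + [merged]
    return merges


def auc_pair_counting(case_scores, control_scores):
    """AUC by enumerating every case-control pair, ties counting 1/2."""
    total = 0.0
    for x in case_scores:
        for y in control_scores:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(case_scores) * len(control_scores))


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def cepstrum_fft(phi, n_cep, n_fft=16384):
    """Cepstrum of the all-pole filter 1/A via FFT of its log magnitude."""
    phi = np.asarray(phi, dtype=float)
    a = np.concatenate([[1.0], -phi])
    spectrum = np.fft.fft(a, n_fft)
    log_mag = np.log(np.abs(1.0 / spectrum))
    ceps = np.fft.ifft(log_mag).real
    return 2.0 * ceps[1 : n_cep + 1]
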