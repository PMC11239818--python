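"""Independent brute-force oracles for the test suite.

Everything here is written for clarity, not speed: explicit pair
enumeration for GLCMs, explicit concordant-pair counting for the AUC, full
2^n sign enumeration for the Wilcoxon signed-rank test, and a hypergeometric
sum for Fisher's exact test. These implementations deliberately share no
code with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def brute_glcm(quantized: np.ndarray, offset: tuple[int, int, int],
               n_levels: int, symmetric: bool = True) -> np.ndarray | None:
    """Co-occurrence matrix by explicit voxel-pair enumeration."""
    oi, oj, ok = offset
    counts = np.zeros((n_levels, n_levels))
    ni, nj, nk = quantized.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                a = quantized[i, j, k]
                if a == 0:
                    continue
                i2, j2, k2 = i + oi, j + oj, k + ok
                if not (0 <= i2 < ni and 0 <= j2 < nj and 0 <= k2 < nk):
                    continue
                b = quantized[i2, j2, k2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                if symmetric:
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def brute_glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence statistics by explicit double loops."""
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mux = sum((i + 1) * px[i] for i in range(L))
    muy = sum((j + 1) * py[j] for j in range(L))
    varx = sum((i + 1 - mux) ** 2 * px[i] for i in range(L))
    vary = sum((j + 1 - muy) ** 2 * py[j] for j in range(L))

    p_sum = Counter()
    p_diff = Counter()
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(probs) -> float:
        return -sum(p * math.log2(p) for p in probs if p > 0)

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(L) for j in range(L)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(L) for j in range(L)])

    diff_avg = sum(k * p for k, p in p_diff.items())
    corr_num = sum((i + 1) * (j + 1) * P[i, j] for i in range(L) for j in range(L)) - mux * muy
    sig = math.sqrt(varx * vary)

    return {
        "autocorrelation": sum((i + 1) * (j + 1) * P[i, j] for i in range(L) for j in range(L)),
        "joint_average": mux,
        "cluster_prominence": sum((i + j + 2 - mux - muy) ** 4 * P[i, j]
                                  for i in range(L) for j in range(L)),
        "cluster_shade": sum((i + j + 2 - mux - muy) ** 3 * P[i, j]
                             for i in range(L) for j in range(L)),
        "cluster_tendency": sum((i + j + 2 - mux - muy) ** 2 * P[i, j]
                                for i in range(L) for j in range(L)),
        "contrast": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "correlation": corr_num / sig if sig > 0 else 1.0,
        "difference_average": diff_avg,
        "difference_entropy": ent(p_diff.values()),
        "difference_variance": sum((k - diff_avg) ** 2 * p for k, p in p_diff.items()),
        "joint_energy": sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
        "joint_entropy": hxy,
        "imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "idm": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
        "idmn": sum(P[i, j] / (1 + ((i - j) / L) ** 2) for i in range(L) for j in range(L)),
        "id": sum(P[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L)),
        "idn": sum(P[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L)),
        "inverse_variance": sum(P[i, j] / (i - j) ** 2
                                for i in range(L) for j in range(L) if i != j),
        "maximum_probability": max(P[i, j] for i in range(L) for j in range(L)),
        "sum_average": sum(k * p for k, p in p_sum.items()),
        "sum_entropy": ent(p_sum.values()),
        "sum_squares": sum((i + 1 - mux) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "dissimilarity": sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L)),
        "homogeneity": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
    }


def brute_auc(values, labels) -> float:
    """Concordant-pair fraction with ties counted one half."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    score = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                score += 1.0
            elif p == n:
                score += 0.5
    return score / (len(pos) * len(neg))


def exact_wilcoxon_signed_rank_p(differences) -> float:
    """Two-sided exact signed-rank p by full 2^n sign enumeration.

    Zero differences must already be removed. Ties in |d| receive average
    ranks; the p-value is the probability under random signs of a W+ at
    least as extreme (two-sided, doubling the smaller tail, capped at 1).
    """
    d = [x for x in differences if x != 0]
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    w_all = []
    for signs in itertools.product((0, 1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mean_w = n * (n + 1) / 4.0
    tail = min((w_all >= w_obs).mean(), (w_all <= w_obs).mean())
    if w_obs == mean_w:
        return 1.0
    return float(min(1.0, 2.0 * tail))


def fisher_2x2_p(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
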