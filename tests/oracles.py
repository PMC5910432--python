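"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a statistic from first principles (segment-by-segment
integration, explicit pair enumeration, textbook formulas) without calling
the library code it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def trapezoid_dv200_oracle(
    sizes: np.ndarray, fluor: np.ndarray, window_min: float = 25.0, boundary: float = 200.0
) -> float:
    """DV200 by explicit per-segment trapezoid integration.

    Each linear segment of the trace is clipped to the analysis window and,
    if it straddles the boundary, split there by linear interpolation.
    """
    below = above = 0.0
    for i in range(len(sizes) - 1):
        x1, x2 = float(sizes[i]), float(sizes[i + 1])
        y1, y2 = float(fluor[i]), float(fluor[i + 1])
        if x2 <= window_min:
            continue
        if x1 < window_min:  # clip segment start at the window edge
            y1 = y1 + (y2 - y1) * (window_min - x1) / (x2 - x1)
            x1 = window_min
        segments = [(x1, y1, x2, y2)]
        if x1 < boundary < x2:
            ym = y1 + (y2 - y1) * (boundary - x1) / (x2 - x1)
            segments = [(x1, y1, boundary, ym), (boundary, ym, x2, y2)]
        for a, ya, b, yb in segments:
            area = (ya + yb) / 2.0 * (b - a)
            if a >= boundary:
                above += area
            else:
                below += area
    total = below + above
    if total <= 0:
        raise ZeroDivisionError("zero total signal")
    return 100.0 * above / total


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw covariance / sd definition."""
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def upgma_oracle(dist: np.ndarray) -> list[float]:
    """Average-linkage merge heights via naive cluster bookkeeping."""
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights: list[float] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, pair = np.inf, None
        for i_pos, i in enumerate(keys):
            for j in keys[i_pos + 1:]:
                d = float(
                    np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                )
                if d < best - 1e-15:
                    best, pair = d, (i, j)
        i, j = pair
        heights.append(best)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def concordance_oracle(
    a: pd.DataFrame, b: pd.DataFrame, cutoff: float
) -> dict[int, float]:
    """Per-basis concordance rates by explicit enumeration of every ratio pair.

    The match decision is re-derived on the log scale: a log-ratio inside
    [-log c, log c] is 'within'; otherwise direction is its sign.
    """
    n = a.shape[1]
    lc = math.log(cutoff)
    rates: dict[int, float] = {}
    for basis in range(n):
        ok_genes = 0
        for g in range(a.shape[0]):
            gene_ok = True
            for j in range(n):
                if j == basis:
                    continue
                la = math.log(a.iat[g, j]) - math.log(a.iat[g, basis])
                lb = math.log(b.iat[g, j]) - math.log(b.iat[g, basis])
                tol = 1e-12
                in_a = -lc - tol <= la <= lc + tol
                in_b = -lc - tol <= lb <= lc + tol
                if in_a and in_b:
                    continue
                if (not in_a) and (not in_b) and la * lb > 0:
                    continue
                gene_ok = False
                break
            ok_genes += gene_ok
        rates[basis + 1] = 100.0 * ok_genes / a.shape[0]
    return rates


def group_mean_concordance_oracle(
    m1c, m1o, m2c, m2o, cutoff: float
) -> float:
    """Percent of genes with matching case/control mean ratios on two platforms."""
    lc = math.log(cutoff)
    tol = 1e-12
    ok = 0
    n = len(m1c)
    for g in range(n):
        l1 = math.log(m1c[g] / m1o[g])
        l2 = math.log(m2c[g] / m2o[g])
        in1 = -lc - tol <= l1 <= lc + tol
        in2 = -lc - tol <= l2 <= lc + tol
        if (in1 and in2) or ((not in1) and (not in2) and l1 * l2 > 0):
            ok += 1
    return 100.0 * ok / n


def rank_bin_oracle(
    means_a: pd.Series, means_b: pd.Series, n_top: int, edges: tuple[int, ...]
) -> dict[str, int]:
    """Recount the rank-difference categories by explicit sorting."""

    def ranks(s: pd.Series) -> dict[str, int]:
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return {g: i + 1 for i, g in enumerate(order)}

    ra, rb = ranks(means_a), ranks(means_b)
    top = [g for g in ra if ra[g] <= n_top]
    counts = {"within_top_n": 0}
    prev = 0
    labels = []
    for e in edges:
        label = f"delta_le_{e}" if prev == 0 else f"delta_{prev + 1}_to_{e}"
        counts[label] = 0
        labels.append((prev, e, label))
        prev = e
    tail = f"delta_gt_{prev}"
    counts[tail] = 0
    for g in top:
        if rb[g] <= n_top:
            counts["within_top_n"] += 1
            continue
        d = abs(ra[g] - rb[g])
        for lo, hi, label in labels:
            if lo < d <= hi:
                counts[label] += 1
                break
        else:
            counts[tail] += 1
    return counts


def ttest_cohens_d_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and Cohen's d, textbook formulas."""
    n1, n2 = len(x), len(y)
    v1 = ((x - x.mean()) ** 2).sum() / (n1 - 1)
    v2 = ((y - y.mean()) ** 2).sum() / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    t = (x.mean() - y.mean()) / (sp * math.sqrt(1 / n1 + 1 / n2))
    d = (x.mean() - y.mean()) / sp
    return t, d
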