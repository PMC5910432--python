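"""Concordance statistics, rank comparisons, qPCR ranking and the DE filter.

FFPE-derived and fresh-frozen expression data form separate data entities
whose absolute signals cannot be compared directly.  The statistics here
therefore compare *relative* expression: fold-change ratios between
biological replicates (or between group means) computed independently in two
datasets are classified as concordant when they either both fall inside a
fold-change cut-off band or both exceed it in the same direction.  Rank-based
comparisons of the top-expressed genes and a delta-Cq ranking of qPCR data
provide complementary, scale-free views of agreement, and a fold-change +
t-test filter produces differential-expression gene lists for downstream
pathway analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

DEFAULT_CUTOFFS = (1.3, 1.5, 1.7, 2.0)


# ---------------------------------------------------------------------------
# Ratio-pair classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceConfig:
    """Fold-change cut-off c > 1 and the per-basis aggregation rule.

    ``aggregation="all"`` calls a gene concordant for one basis replicate only
    if every ratio pair against the remaining replicates matches;
    ``"per_pair"`` instead averages match rates over individual ratio pairs.
    """

    cutoff: float = 1.5
    aggregation: str = "all"  # "all" | "per_pair"

    def __post_init__(self) -> None:
        if not self.cutoff > 1.0:
            raise InvalidInputError(f"cutoff must be > 1, got {self.cutoff}")
        if self.aggregation not in ("all", "per_pair"):
            raise InvalidInputError(f"unknown aggregation {self.aggregation!r}")


def ratio_pair_matches(r1: float, r2: float, cutoff: float) -> bool:
    """True if a pair of linear fold-change ratios is concordant at ``cutoff``.

    Match: both inside the closed band [1/c, c] (no relevant change in either
    dataset), or both above c (shared up-regulation), or both below 1/c
    (shared down-regulation).  One ratio inside the band with the other
    outside, or opposite directions, is a mismatch.
    """
    lo, hi = 1.0 / cutoff, cutoff
    in1, in2 = lo <= r1 <= hi, lo <= r2 <= hi
    if in1 and in2:
        return True
    return (r1 > hi and r2 > hi) or (r1 < lo and r2 < lo)


@dataclass
class ConcordanceResult:
    """Per-basis and overall concordance rates at one fold-change cut-off.

    ``per_basis_rate`` maps each basis replicate index to the percentage of
    concordant genes; ``overall`` is the arithmetic mean over bases.  For the
    group-mean variant there is a single pseudo-basis ``0``.
    """

    cutoff: float
    per_basis_rate: dict[int, float]
    gene_flags: pd.DataFrame  # genes x bases, boolean concordance calls
    ratios: pd.DataFrame | None = None

    @property
    def overall(self) -> float:
        return float(np.mean(list(self.per_basis_rate.values())))


def _check_positive(df: pd.DataFrame, name: str) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise InvalidInputError(f"{name}: linear-scale signals must be strictly positive")
    return arr


def replicate_ratio_concordance(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    config: ConcordanceConfig = ConcordanceConfig(),
) -> ConcordanceResult:
    """Concordance of within-group replicate ratios between two groups.

    Inputs are linear-scale genes x replicates slices over the same gene set,
    with columns paired by position (replicate index).  For each basis
    replicate b, the ratio of every other replicate j to the basis is formed
    in each group; the pair (a_j/a_b, b_j/b_b) is classified by
    :func:`ratio_pair_matches`.  With the default ``"all"`` aggregation a
    gene is concordant for basis b iff all its pairs match; the per-basis
    rate is the percentage of concordant genes, and the overall rate is the
    mean over all n bases (each replicate serving as basis once).
    """
    if not group_a.index.equals(group_b.index):
        raise InvalidInputError("groups must share an identical gene index")
    n = group_a.shape[1]
    if group_b.shape[1] != n:
        raise InvalidInputError(
            f"paired design requires equal replicate counts, got {n} vs {group_b.shape[1]}"
        )
    if n < 2:
        raise InvalidInputError("need >= 2 replicates per group")
    a = _check_positive(group_a, "group_a")
    b = _check_positive(group_b, "group_b")

    c = config.cutoff
    lo, hi = 1.0 / c, c
    flags: dict[int, np.ndarray] = {}
    rates: dict[int, float] = {}
    for basis in range(n):
        others = [j for j in range(n) if j != basis]
        ra = a[:, others] / a[:, [basis]]
        rb = b[:, others] / b[:, [basis]]
        within = ((ra >= lo) & (ra <= hi)) & ((rb >= lo) & (rb <= hi))
        both_up = (ra > hi) & (rb > hi)
        both_down = (ra < lo) & (rb < lo)
        match = within | both_up | both_down
        if config.aggregation == "all":
            gene_ok = match.all(axis=1)
            flags[basis + 1] = gene_ok
            rates[basis + 1] = 100.0 * float(gene_ok.mean())
        else:
            flags[basis + 1] = match.all(axis=1)  # flags still report the strict call
            rates[basis + 1] = 100.0 * float(match.mean())
    gene_flags = pd.DataFrame(flags, index=group_a.index)
    return ConcordanceResult(cutoff=c, per_basis_rate=rates, gene_flags=gene_flags)


def group_mean_concordance(
    platform1_case: pd.DataFrame,
    platform1_control: pd.DataFrame,
    platform2_case: pd.DataFrame,
    platform2_control: pd.DataFrame,
    config: ConcordanceConfig = ConcordanceConfig(),
) -> ConcordanceResult:
    """Cross-platform concordance of case/control mean-expression ratios.

    For each gene shared between the platforms, the case-mean over
    control-mean ratio is formed on each platform; the ratio pair is
    classified by :func:`ratio_pair_matches` and the rate is the percentage
    of concordant genes.  Used for e.g. FFPE-microarray vs fresh-tissue
    RNA-Seq comparisons, where the two platforms are separate data entities.
    """
    shared = platform1_case.index.intersection(platform1_control.index)
    shared = shared.intersection(platform2_case.index).intersection(platform2_control.index)
    if shared.empty:
        raise InvalidInputError("no genes shared between the four slices")
    m1c = _check_positive(platform1_case.loc[shared], "platform1_case").mean(axis=1)
    m1o = _check_positive(platform1_control.loc[shared], "platform1_control").mean(axis=1)
    m2c = _check_positive(platform2_case.loc[shared], "platform2_case").mean(axis=1)
    m2o = _check_positive(platform2_control.loc[shared], "platform2_control").mean(axis=1)
    r1 = m1c / m1o
    r2 = m2c / m2o
    c = config.cutoff
    lo, hi = 1.0 / c, c
    match = (
        ((r1 >= lo) & (r1 <= hi) & (r2 >= lo) & (r2 <= hi))
        | ((r1 > hi) & (r2 > hi))
        | ((r1 < lo) & (r2 < lo))
    )
    gene_flags = pd.DataFrame({0: match}, index=shared)
    ratios = pd.DataFrame({"ratio_platform1": r1, "ratio_platform2": r2}, index=shared)
    rate = 100.0 * float(match.mean())
    return ConcordanceResult(
        cutoff=c, per_basis_rate={0: rate}, gene_flags=gene_flags, ratios=ratios
    )


# ---------------------------------------------------------------------------
# Rank-based comparison of the top-expressed genes
# ---------------------------------------------------------------------------

@dataclass
class RankComparison:
    """Ranks of dataset A's top-N genes in dataset B, with category bins.

    ``table`` has one row per top-N gene of A: its rank in A and in B and
    the absolute rank difference.  ``bins`` maps category labels to counts;
    the special category ``"within_top_n"`` counts A-top genes also found in
    B's top N, and the remaining genes are binned by absolute rank
    difference using the configured edges.  Counts sum to N.
    """

    n_top: int
    table: pd.DataFrame
    bins: dict[str, int]


def _dense_ranks(means: pd.Series) -> pd.Series:
    """Rank 1 = highest mean expression; ties broken by gene id (lexicographic)."""
    ordered = means.sort_index().sort_values(ascending=False, kind="stable")
    return pd.Series(np.arange(1, means.size + 1), index=ordered.index).loc[means.index]


def top_n_rank_comparison(
    means_a: pd.Series,
    means_b: pd.Series,
    n_top: int = 100,
    bin_edges: Sequence[int] = (400,),
) -> RankComparison:
    """Compare the top-N expressed genes of dataset A with their ranks in B.

    Genes are ranked by mean expression within each dataset (rank 1 =
    highest).  For A's top N, the comparison reports where each gene ranks
    in B.  Categories partition the top-N set: genes also inside B's top N
    form ``"within_top_n"``; the rest are binned by |rank difference| at the
    given ascending edges (``(400,)`` produces ``delta_le_400`` and
    ``delta_gt_400``).
    """
    if not means_a.index.sort_values().equals(means_b.index.sort_values()):
        raise InvalidInputError("datasets must cover the same gene universe")
    if n_top > means_a.size:
        raise InvalidInputError(f"n_top={n_top} exceeds the {means_a.size} available genes")
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise InvalidInputError("bin_edges must be strictly ascending")

    rank_a = _dense_ranks(means_a)
    rank_b = _dense_ranks(means_b)
    top = rank_a[rank_a <= n_top].sort_values().index
    table = pd.DataFrame(
        {
            "rank_a": rank_a.loc[top],
            "rank_b": rank_b.loc[top],
        },
        index=top,
    )
    table["abs_rank_diff"] = (table["rank_a"] - table["rank_b"]).abs()
    table["in_top_n_b"] = table["rank_b"] <= n_top

    bins: dict[str, int] = {"within_top_n": int(table["in_top_n_b"].sum())}
    rest = table.loc[~table["in_top_n_b"], "abs_rank_diff"]
    prev = 0
    for e in edges:
        label = f"delta_le_{e}" if prev == 0 else f"delta_{prev + 1}_to_{e}"
        bins[label] = int(((rest > prev) & (rest <= e)).sum())
        prev = e
    bins[f"delta_gt_{prev}"] = int((rest > prev).sum())
    return RankComparison(n_top=n_top, table=table, bins=bins)


# ---------------------------------------------------------------------------
# qPCR: Cq summaries and delta-Cq ranking
# ---------------------------------------------------------------------------

@dataclass
class CqTable:
    """Replicate qPCR quantification cycles per gene, with a reference gene.

    ``values`` is genes x replicates (NaN-padded when replicate counts
    differ); the reference gene (e.g. Gapdh) anchors delta-Cq normalization.
    """

    values: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr) <= 0:
            raise InvalidInputError("Cq values must be strictly positive")
        if self.reference_gene not in self.values.index:
            raise InvalidInputError(f"reference gene {self.reference_gene!r} absent from table")
        if self.values.index.duplicated().any():
            raise InvalidInputError("duplicate gene ids in Cq table")


def cq_summary(cq: CqTable) -> pd.DataFrame:
    """Geometric mean and sample SD of replicate Cq values per gene.

    The geometric mean is exp(mean(ln Cq)); the SD is the ordinary sample
    standard deviation on the Cq scale (NaN for single-replicate genes).
    """
    ln = np.log(cq.values)
    geo = np.exp(ln.mean(axis=1, skipna=True))
    sd = cq.values.std(axis=1, ddof=1, skipna=True)
    n = cq.values.notna().sum(axis=1)
    if (n < 1).any():
        raise InvalidInputError("every gene needs >= 1 replicate Cq")
    return pd.DataFrame({"geo_mean_cq": geo, "sd_cq": sd, "n_replicates": n})


def delta_cq_rank(cq: CqTable, include_reference: bool = False) -> pd.DataFrame:
    """Rank genes by abundance via delta-Cq against the reference gene.

    delta-Cq = mean(reference Cq) - mean(gene Cq); larger values mean fewer
    amplification cycles, i.e. higher transcript abundance.  Genes are
    sorted by delta-Cq descending, rank 1 = most abundant, ties broken by
    gene id.  The reference itself (delta-Cq 0 by construction) is excluded
    unless ``include_reference``.
    """
    means = cq.values.mean(axis=1, skipna=True)
    ref = float(means.loc[cq.reference_gene])
    if not np.isfinite(ref):
        raise InvalidInputError("reference gene has no valid Cq values")
    delta = ref - means
    if not include_reference:
        delta = delta.drop(cq.reference_gene)
    out = pd.DataFrame({"delta_cq": delta})
    out = out.sort_index().sort_values("delta_cq", ascending=False, kind="stable")
    out["rank"] = np.arange(1, out.shape[0] + 1)
    return out


# ---------------------------------------------------------------------------
# Differential-expression filter
# ---------------------------------------------------------------------------

def de_filter(
    matrix,
    case_group: str,
    control_group: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Fold-change + t-test filter producing a differential-expression list.

    Per gene: an unpaired two-tailed two-sample t-test on log2 signals
    (equal-variance pooling by default, Welch optional) and a linear
    fold-change 2**(case mean - control mean) reported as a signed value
    (down-regulation encoded as -1/ratio).  A gene is selected iff
    |signed fold-change| >= ``fc_threshold`` and p <= ``p_threshold``.
    No multiple-testing correction is applied.  Output is ordered by p value
    (unblemished tests first; genes with zero variance in both groups get
    NaN p and ``degenerate=True``).
    """
    case = matrix.group_slice_log2(case_group).to_numpy(dtype=float)
    ctrl = matrix.group_slice_log2(control_group).to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InvalidInputError("need >= 2 replicates per group")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical replicates trip scipy's cancellation warning; the
        # resulting degenerate statistics are flagged explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    ratio = np.exp2(diff)
    signed_fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    # zero variance in both groups leaves the t statistic undefined
    degenerate = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    degenerate |= ~np.isfinite(p)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    selected = (~degenerate) & (np.abs(signed_fc) >= fc_threshold) & (p <= p_threshold)
    out = pd.DataFrame(
        {
            "fold_change": signed_fc,
            "t": t,
            "p": p,
            "selected": selected,
            "degenerate": degenerate,
        },
        index=matrix.gene_ids,
    )
    return out.sort_values("p", kind="stable", na_position="last")
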