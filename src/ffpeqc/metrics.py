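"""Reproducibility and bias metrics on normalized expression matrices.

Covers the four per-matrix diagnostics used to judge whether FFPE-derived
arrays behave like their fresh-frozen counterparts:

* per-gene coefficient of variation (%CV) across biological replicates,
  with a cube-root-transformed t-test / Cohen's d comparison between groups;
* pairwise Pearson correlation of samples on log2 signals, summarized as
  intra- and inter-group averages;
* unsupervised hierarchical clustering of samples (average linkage on
  1 - Pearson r);
* transcriptome-wide 3'/5' signal ratios from exon-level probe-set tables,
  a positional readout of degradation-driven coverage bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import InvalidInputError, UndefinedMetricError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Coefficient of variation
# ---------------------------------------------------------------------------

@dataclass
class GeneVariationTable:
    """Per-gene %CV of one experimental group.

    ``cv_percent`` is indexed by gene id; genes whose group mean is zero (or
    not finite) are excluded and counted in ``n_excluded``.
    """

    cv_percent: pd.Series
    group: str
    n_excluded: int = 0

    @property
    def median(self) -> float:
        return float(self.cv_percent.median())


def cv_percent(
    matrix: ExpressionMatrix, group: str, on_log_scale: bool = False
) -> GeneVariationTable:
    """Per-gene coefficient of variation (100 x sd / mean) across replicates.

    The CV is conventionally a linear-scale quantity, so log2 inputs are
    exponentiated first; set ``on_log_scale=True`` to compute it on the log2
    signals instead.  Sample standard deviation uses the n-1 denominator.
    """
    samples = matrix.samples_in_group(group)
    if len(samples) < 2:
        raise InvalidInputError(f"group {group!r} needs >= 2 replicates, has {len(samples)}")
    values = (
        matrix.group_slice_log2(group) if on_log_scale else matrix.group_slice(group)
    ).to_numpy(dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    ok = np.isfinite(means) & np.isfinite(sds) & (means != 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("cv_percent(%s): excluded %d genes with zero/non-finite mean", group, n_excluded)
    cv = pd.Series(
        100.0 * sds[ok] / means[ok], index=matrix.gene_ids[ok], name="cv_percent"
    )
    return GeneVariationTable(cv_percent=cv, group=group, n_excluded=n_excluded)


@dataclass(frozen=True)
class EffectSize:
    """Two-sample comparison summary: t statistic, df, p value and Cohen's d."""

    t: float
    df: float
    p: float
    cohens_d: float


def cv_compare(table_a: GeneVariationTable, table_b: GeneVariationTable) -> EffectSize:
    """Compare two %CV distributions.

    Each CV value is cube-root transformed (a variance-stabilizing transform
    for the right-skewed CV distribution), then an unpaired two-tailed
    equal-variance t-test is run between the transformed sets.  Cohen's d is
    the difference of transformed means over the pooled standard deviation.
    """
    a = np.cbrt(table_a.cv_percent.to_numpy(dtype=float))
    b = np.cbrt(table_b.cv_percent.to_numpy(dtype=float))
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each CV table needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    pooled_sd = np.sqrt(pooled_var)
    d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    return EffectSize(t=float(t), df=float(df), p=float(p), cohens_d=float(d))


# ---------------------------------------------------------------------------
# Pearson correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise sample-sample Pearson coefficients on log2 signals.

    ``intra_group`` averages the within-group off-diagonal pairs per group;
    ``inter_group`` averages all between-group pairs per group pair.
    """

    r: pd.DataFrame
    intra_group: dict[str, float] = field(default_factory=dict)
    inter_group: dict[tuple[str, str], float] = field(default_factory=dict)


def pearson_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """All pairwise Pearson correlations between samples on log2 values."""
    log2 = matrix.to_log2().values
    if log2.shape[1] < 2:
        raise InvalidInputError("need >= 2 samples")
    arr = log2.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        bad = log2.columns[constant].tolist()
        raise UndefinedMetricError(f"constant sample vectors have undefined correlation: {bad}")
    r = pd.DataFrame(np.corrcoef(arr, rowvar=False), index=log2.columns, columns=log2.columns)

    groups = matrix.group_labels()
    intra: dict[str, float] = {}
    inter: dict[tuple[str, str], float] = {}
    for i, g in enumerate(groups):
        gs = matrix.samples_in_group(g)
        if len(gs) >= 2:
            block = r.loc[gs, gs].to_numpy()
            iu = np.triu_indices(len(gs), k=1)
            intra[g] = float(block[iu].mean())
        for h in groups[i + 1:]:
            hs = matrix.samples_in_group(h)
            inter[(g, h)] = float(r.loc[gs, hs].to_numpy().mean())
    return CorrelationMatrix(r=r, intra_group=intra, inter_group=inter)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus leaf labels (in input order)."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        """Serialize the merge tree to Newick, branch lengths from merge heights."""
        tree = to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hcluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of samples with distance 1 - Pearson r.

    Samples are ordered lexicographically before clustering so that
    distance ties resolve deterministically.
    """
    if matrix.values.shape[1] < 3:
        raise InvalidInputError("need >= 3 samples to cluster")
    order = sorted(matrix.sample_ids)
    corr = pearson_matrix(matrix).r.loc[order, order].to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=list(order))


# ---------------------------------------------------------------------------
# 3'/5' positional bias
# ---------------------------------------------------------------------------

@dataclass
class ThreePrimeRatioResult:
    """Per-gene log10(3'-most / 5'-most probe-set signal) with summary stats."""

    log10_ratio: pd.Series
    n_excluded_single_position: int

    def summary(self) -> dict[str, float]:
        q = self.log10_ratio.quantile([0.25, 0.5, 0.75])
        return {
            "median": float(q.loc[0.5]),
            "q1": float(q.loc[0.25]),
            "q3": float(q.loc[0.75]),
            "n_genes": int(self.log10_ratio.size),
        }


def three_prime_ratio(table: pd.DataFrame) -> ThreePrimeRatioResult:
    """Per-gene log10 ratio of the most 3'- to the most 5'-located probe set.

    ``table`` has columns ``gene_id``, ``position_index`` (1-based, in 5'->3'
    transcription order) and ``signal`` (> 0, linear scale).  Genes with a
    single position are excluded (counted), mirroring the restriction to
    genes with more than one exon.  A positive ratio indicates 3' signal
    excess, the signature of degradation combined with 3'-biased priming.
    """
    required = {"gene_id", "position_index", "signal"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"exon table needs columns {sorted(required)}")
    if (table["signal"] <= 0).any():
        raise InvalidInputError("exon-level signals must be strictly positive")

    ratios: dict[str, float] = {}
    n_single = 0
    for gene, sub in table.groupby("gene_id", sort=True):
        if sub.shape[0] < 2:
            n_single += 1
            continue
        sub = sub.sort_values("position_index")
        first = float(sub["signal"].iloc[0])
        last = float(sub["signal"].iloc[-1])
        ratios[str(gene)] = float(np.log10(last / first))
    if n_single:
        logger.info("three_prime_ratio: excluded %d single-position genes", n_single)
    series = pd.Series(ratios, name="log10_ratio", dtype=float)
    return ThreePrimeRatioResult(log10_ratio=series, n_excluded_single_position=n_single)
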