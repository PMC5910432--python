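"""Synthetic data generators for every input class the pipeline consumes.

The generators emulate a paired fresh-frozen (FF) / FFPE study design with
biological triplicates: log-normal expression signals with group-specific
replicate noise (FFPE inflated), a controllable fraction of genes whose
replicate fold-change direction disagrees between the groups, exon-level
probe-set tables with a positional 3'/5' signal gradient, capillary
electropherograms (intact rRNA peaks for FF-like RNA; a fragment smear with
a target DV200 and an optional high-molecular-weight cross-link peak for
FFPE-like RNA), and paired qPCR Cq tables with an FFPE offset of several
cycles.  Every generator is deterministic given its seed, and ground-truth
parameters are returned alongside the data so downstream estimators can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .concordance import CqTable
from .errors import InvalidParameterError
from .matrix import ExpressionMatrix
from .quality import Electropherogram

DEFAULT_RRNA_PEAKS = ((1900.0, 1.0), (4700.0, 2.0))  # 18S and 28S rRNA (nt, rel. height)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a paired two-group expression simulation.

    Replicate noise is applied on the log2 scale; ``noise_sd_b`` is typically
    larger than ``noise_sd_a`` to emulate the inflated replicate variability
    of FFPE material.  A fraction ``frac_discordant`` of genes receives an
    injected replicate fold-change of magnitude ``fc_injected`` whose
    direction is inverted in group B, deliberately violating replicate-ratio
    concordance for those genes.  ``group_offset_log2`` shifts all of group B
    by a constant (separate-data-entity effect); ratio-based statistics are
    invariant to it.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    base_log2_mean: float = 7.0
    base_log2_sd: float = 2.0
    noise_sd_a: float = 0.15
    noise_sd_b: float = 0.35
    frac_discordant: float = 0.0
    fc_injected: float = 4.0
    group_offset_log2: float = 0.0
    group_a_label: str = "FF"
    group_b_label: str = "FFPE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidParameterError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_replicates < 2:
            raise InvalidParameterError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if not 0.0 <= self.frac_discordant <= 1.0:
            raise InvalidParameterError("frac_discordant must be in [0, 1]")
        if self.noise_sd_a < 0 or self.noise_sd_b < 0:
            raise InvalidParameterError("noise sds must be >= 0")
        if self.fc_injected < 1.0:
            raise InvalidParameterError("fc_injected must be >= 1")


def simulate_expression_pair(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Simulate paired group-A / group-B expression matrices with ground truth.

    Each gene draws a base log2 level; replicates add group-specific Gaussian
    noise.  ``round(frac_discordant * n_genes)`` genes (chosen by a seeded
    shuffle) get the injected fold-change applied to replicate 2: multiplied
    by ``fc_injected`` in group A, divided by it in group B, so their
    replicate ratios point in opposite directions between groups.

    Returns the two matrices (log2 scale, one group each, columns paired by
    replicate index) and a ground-truth table recording each gene's base
    level and its discordance flag.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    genes = [f"gene_{i:05d}" for i in range(p.n_genes)]
    base = rng.normal(p.base_log2_mean, p.base_log2_sd, size=p.n_genes)

    n_disc = int(round(p.frac_discordant * p.n_genes))
    order = rng.permutation(p.n_genes)
    discordant = np.zeros(p.n_genes, dtype=bool)
    discordant[order[:n_disc]] = True

    shift = np.log2(p.fc_injected)
    inject = np.zeros((p.n_genes, p.n_replicates))
    inject[discordant, 1] = shift  # replicate 2 carries the structure

    a = base[:, None] + inject + rng.normal(0.0, p.noise_sd_a, (p.n_genes, p.n_replicates))
    b = (
        base[:, None]
        - inject
        + p.group_offset_log2
        + rng.normal(0.0, p.noise_sd_b, (p.n_genes, p.n_replicates))
    )

    def build(values: np.ndarray, label: str) -> ExpressionMatrix:
        cols = [f"{label}_{i + 1}" for i in range(p.n_replicates)]
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols),
            scale="log2",
            groups={c: label for c in cols},
            pairing={c: i + 1 for i, c in enumerate(cols)},
        )

    truth = pd.DataFrame(
        {"base_log2": base, "discordant": discordant},
        index=pd.Index(genes, name="gene_id"),
    )
    return build(a, p.group_a_label), build(b, p.group_b_label), truth


# ---------------------------------------------------------------------------
# Electropherogram traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceParams:
    """Parameters of a simulated capillary-electrophoresis trace.

    ``profile="ff"`` produces an intact-RNA trace: a low broad background
    with Gaussian 18S/28S rRNA peaks at the configured sizes and relative
    heights.  ``profile="ffpe"`` produces a degraded-RNA fragment smear — a
    gamma-shaped fragment-length density (shape ``smear_shape``, scale
    ``smear_scale`` nt) — rescaled across the 200 nt boundary so that the
    trace's measured DV200 equals ``target_dv200``, plus an optional
    high-molecular-weight Gaussian peak emulating cross-linked nucleic acids
    (typically centred at 3,000-4,000 nt).
    """

    profile: str = "ffpe"  # "ff" | "ffpe"
    target_dv200: float = 75.0
    rrna_peaks: tuple[tuple[float, float], ...] = DEFAULT_RRNA_PEAKS
    crosslink_peak: Optional[tuple[float, float]] = None  # (center nt, rel. height)
    smear_shape: float = 2.0
    smear_scale: float = 250.0
    size_min: float = 25.0
    size_max: float = 6000.0
    size_step: float = 5.0
    noise_sd: float = 0.0  # relative multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("ff", "ffpe"):
            raise InvalidParameterError(f"profile must be 'ff' or 'ffpe', got {self.profile!r}")
        if not 0.0 <= self.target_dv200 <= 100.0:
            raise InvalidParameterError("target_dv200 must be in [0, 100]")
        if not (self.size_min > 0 and self.size_max > self.size_min and self.size_step > 0):
            raise InvalidParameterError("size grid must be positive and increasing")
        if self.smear_shape <= 0 or self.smear_scale <= 0:
            raise InvalidParameterError("smear parameters must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def _size_grid(p: TraceParams) -> np.ndarray:
    grid = np.arange(p.size_min, p.size_max + p.size_step / 2, p.size_step, dtype=float)
    if 200.0 not in grid and p.size_min < 200.0 < p.size_max:
        grid = np.sort(np.append(grid, 200.0))
    return grid


def _gaussian(x: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


def simulate_electropherogram(params: TraceParams) -> Electropherogram:
    """Simulate an FF-like or FFPE-like electropherogram trace.

    FFPE traces are rescaled piecewise at the 200 nt boundary so that the
    DV200 measured on the returned trace (trapezoidal integration over the
    analysis window) equals ``target_dv200`` exactly in the noiseless case;
    multiplicative noise perturbs it slightly (zero fluorescence stays zero,
    so the boundary targets 0 and 100 remain exact even under noise).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    x = _size_grid(p)

    if p.profile == "ff":
        y = 0.05 * sstats.gamma.pdf(x, a=3.0, scale=600.0) / sstats.gamma.pdf(
            1200.0, a=3.0, scale=600.0
        )
        for center, height in p.rrna_peaks:
            y = y + _gaussian(x, center, height, width=0.03 * center)
    else:
        y = sstats.gamma.pdf(x, a=p.smear_shape, scale=p.smear_scale)
        if p.crosslink_peak is not None:
            center, height = p.crosslink_peak
            y = y + _gaussian(x, center, height * y.max(), width=150.0)
        y = _rescale_to_dv200(x, y, p.target_dv200)

    if p.noise_sd > 0:
        y = y * np.clip(1.0 + rng.normal(0.0, p.noise_sd, y.size), 0.0, None)
    return Electropherogram(sizes_nt=x, fluorescence=np.clip(y, 0.0, None))


def _rescale_to_dv200(x: np.ndarray, y: np.ndarray, target: float) -> np.ndarray:
    """Piecewise rescaling across the 200 nt boundary to hit a DV200 target.

    Points at or below 200 nt are scaled by alpha, points above by 1; alpha
    is solved so that the trapezoidal areas split exactly
    (100 - target) : target, accounting for the mixed trapezoid just above
    the boundary whose left edge carries the alpha-scaled value.
    """
    if target >= 100.0:
        return np.where(x > 200.0, y, 0.0)
    if target <= 0.0:
        return np.where(x < 200.0, y, 0.0)
    below = x <= 200.0
    above = x >= 200.0
    t_below = float(np.trapezoid(y[below], x[below]))
    t_above = float(np.trapezoid(y[above], x[above]))
    i200 = int(np.flatnonzero(x == 200.0)[0])
    h = y[i200] * (x[i200 + 1] - x[i200]) / 2.0  # boundary point's share of the above area
    frac = target / 100.0
    denom = frac * t_below - (1.0 - frac) * h
    if denom <= 0:
        alpha = 0.0
    else:
        alpha = max((1.0 - frac) * (t_above - h) / denom, 0.0)
    return np.where(below, alpha * y, y)


# ---------------------------------------------------------------------------
# Exon-level probe-set tables
# ---------------------------------------------------------------------------

def simulate_exon_table(
    n_genes: int,
    probe_sets_per_gene: int = 4,
    gradient_log10: float = 0.1,
    noise_sd: float = 0.1,
    seed: int = 0,
    base_log10_mean: float = 2.5,
    base_log10_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate an exon-level signal table with a positional 3'/5' gradient.

    Per gene, probe-set signals along the 5'->3' transcription order follow a
    linear log10 ramp from the gene's base level at position 1 to base +
    ``gradient_log10`` at the last position, plus Gaussian log10 noise; the
    expected log10(last/first) ratio therefore equals ``gradient_log10``.
    Returns a tidy DataFrame with columns ``gene_id``, ``position_index``,
    ``signal``.
    """
    if n_genes <= 0:
        raise InvalidParameterError("n_genes must be positive")
    if probe_sets_per_gene < 2:
        raise InvalidParameterError("probe_sets_per_gene must be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = rng.normal(base_log10_mean, base_log10_sd, n_genes)
    ramp = gradient_log10 * np.arange(probe_sets_per_gene) / (probe_sets_per_gene - 1)
    log10_sig = (
        base[:, None] + ramp[None, :] + rng.normal(0.0, noise_sd, (n_genes, probe_sets_per_gene))
    )
    return pd.DataFrame(
        {
            "gene_id": np.repeat([f"gene_{i:05d}" for i in range(n_genes)], probe_sets_per_gene),
            "position_index": np.tile(np.arange(1, probe_sets_per_gene + 1), n_genes),
            "signal": np.power(10.0, log10_sig).ravel(),
        }
    )


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

def simulate_cq_table(
    genes: Sequence[str],
    n_replicates: int = 3,
    ffpe_offset_cycles: float = 5.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_gene: Optional[str] = None,
    base_cq_range: tuple[float, float] = (18.0, 30.0),
) -> tuple[CqTable, CqTable]:
    """Simulate paired FF-like and FFPE-like qPCR Cq tables.

    Each gene draws a base Cq uniformly from ``base_cq_range``; FF replicates
    scatter around it with Gaussian cycle noise, FFPE replicates around base +
    ``ffpe_offset_cycles`` (formalin-degraded templates amplify several
    cycles later).  The reference gene defaults to the first gene listed.
    """
    genes = list(genes)
    if not genes:
        raise InvalidParameterError("need at least one gene")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if ffpe_offset_cycles < 0:
        raise InvalidParameterError("ffpe_offset_cycles must be >= 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    ref = reference_gene if reference_gene is not None else genes[0]
    rng = np.random.default_rng(seed)
    base = rng.uniform(*base_cq_range, len(genes))
    ff = base[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_replicates))
    ffpe = (
        base[:, None]
        + ffpe_offset_cycles
        + rng.normal(0.0, noise_sd, (len(genes), n_replicates))
    )
    cols = [f"rep_{i + 1}" for i in range(n_replicates)]
    idx = pd.Index(genes, name="gene_id")
    return (
        CqTable(values=pd.DataFrame(ff, index=idx, columns=cols), reference_gene=ref),
        CqTable(values=pd.DataFrame(ffpe, index=idx, columns=cols), reference_gene=ref),
    )
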