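"""End-to-end orchestration: quality -> metrics -> concordance report bundles.

A single configuration object describes either real input files (expression
TSV + sample sheet, trace CSVs, exon TSV, Cq CSVs) or a fully synthetic run
driven by one seed.  The pipeline executes every stage on whatever inputs
are available and writes a reproducible bundle: a machine-readable JSON
summary, per-metric TSVs, a Newick dendrogram, the selected
differential-expression gene list and a human-readable text report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import io as fio
from .concordance import (
    DEFAULT_CUTOFFS,
    ConcordanceConfig,
    cq_summary,
    de_filter,
    delta_cq_rank,
    replicate_ratio_concordance,
    top_n_rank_comparison,
)
from .errors import InvalidParameterError
from .matrix import ExpressionMatrix
from .metrics import cv_compare, cv_percent, hcluster, pearson_matrix, three_prime_ratio
from .quality import assess
from .simulate import (
    SimulationParams,
    TraceParams,
    simulate_cq_table,
    simulate_electropherogram,
    simulate_exon_table,
    simulate_expression_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline configuration: real input paths or simulation parameters.

    When ``expression_tsv`` is unset the pipeline simulates every input from
    ``seed`` and the ``simulation``/``trace``/exon/Cq parameter blocks.
    """

    out_dir: str = "ffpeqc_report"
    seed: int = 0
    log_level: str = "INFO"

    # real inputs (all optional)
    expression_tsv: Optional[str] = None
    sample_sheet_csv: Optional[str] = None
    exon_tsv: Optional[str] = None
    trace_csvs: dict[str, str] = field(default_factory=dict)  # label -> path
    cq_csvs: dict[str, str] = field(default_factory=dict)  # label -> path

    # simulation parameters (used when expression_tsv is None)
    simulation: dict[str, Any] = field(default_factory=dict)
    trace: dict[str, Any] = field(default_factory=dict)
    exon: dict[str, Any] = field(default_factory=dict)
    cq: dict[str, Any] = field(default_factory=dict)

    # analysis parameters
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    aggregation: str = "all"
    top_n: int = 100
    bin_edges: tuple[int, ...] = (400,)
    group_a: Optional[str] = None
    group_b: Optional[str] = None

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.cutoffs = tuple(float(c) for c in cfg.cutoffs)
        cfg.bin_edges = tuple(int(e) for e in cfg.bin_edges)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(data or {})


def _load_or_simulate_expression(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, str, str, Optional[pd.DataFrame]]:
    """Return a combined two-group matrix, the group labels and ground truth."""
    if config.expression_tsv is not None:
        if config.sample_sheet_csv is None:
            raise InvalidParameterError("expression_tsv requires sample_sheet_csv")
        matrix = fio.read_expression(config.expression_tsv, config.sample_sheet_csv)
        labels = matrix.group_labels()
        group_a = config.group_a or labels[0]
        group_b = config.group_b or labels[1 if len(labels) > 1 else 0]
        return matrix, group_a, group_b, None

    params = SimulationParams(**{"seed": config.seed, **config.simulation})
    mat_a, mat_b, truth = simulate_expression_pair(params)
    combined = ExpressionMatrix(
        values=pd.concat([mat_a.values, mat_b.values], axis=1),
        scale="log2",
        groups={**mat_a.groups, **mat_b.groups},
        pairing={**mat_a.pairing, **mat_b.pairing},
    )
    return combined, params.group_a_label, params.group_b_label, truth


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute quality -> metrics -> concordance and write the report bundle.

    Returns the JSON-serializable summary dictionary that is also written to
    ``<out_dir>/summary.json``.  Identical configs and seeds produce
    byte-identical bundles.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}

    # ---- stage 1: RNA quality ------------------------------------------
    if config.trace_csvs:
        traces = {label: fio.read_trace(p) for label, p in config.trace_csvs.items()}
    else:
        ff = simulate_electropherogram(TraceParams(profile="ff", seed=config.seed))
        ffpe = simulate_electropherogram(
            TraceParams(**{"profile": "ffpe", "seed": config.seed + 1, **config.trace})
        )
        traces = {"FF": ff, "FFPE": ffpe}
        for label, tr in traces.items():
            fio.write_trace(tr, out / f"trace_{label}.csv")
    quality_block: dict[str, Any] = {}
    for label in sorted(traces):
        res = assess(traces[label])
        quality_block[label] = {
            "dv200": round(res.dv200, 6),
            "category": res.category,
            "crosslink_peak": (
                None
                if res.crosslink_peak is None
                else {
                    "center_nt": res.crosslink_peak.center_nt,
                    "prominence": round(res.crosslink_peak.prominence, 4),
                }
            ),
        }
    summary["quality"] = quality_block

    # ---- stage 2: expression metrics -----------------------------------
    matrix, group_a, group_b, truth = _load_or_simulate_expression(config)
    fio.write_expression(matrix, out / "expression.tsv", out / "sample_sheet.csv")
    if truth is not None:
        truth.to_csv(out / "ground_truth.tsv", sep="\t")

    cv_a = cv_percent(matrix, group_a)
    cv_b = cv_percent(matrix, group_b)
    pd.DataFrame({group_a: cv_a.cv_percent, group_b: cv_b.cv_percent}).to_csv(
        out / "cv_percent.tsv", sep="\t"
    )
    effect = cv_compare(cv_a, cv_b)
    corr = pearson_matrix(matrix)
    corr.r.to_csv(out / "correlation.tsv", sep="\t")
    dendro = hcluster(matrix)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n", encoding="utf-8")

    summary["metrics"] = {
        "median_cv_percent": {group_a: round(cv_a.median, 6), group_b: round(cv_b.median, 6)},
        "cv_excluded_genes": {group_a: cv_a.n_excluded, group_b: cv_b.n_excluded},
        "cv_compare": {
            "t": round(effect.t, 6),
            "df": effect.df,
            "p": float(f"{effect.p:.6g}"),
            "cohens_d": round(effect.cohens_d, 6),
        },
        "pearson": {
            "intra_group": {g: round(v, 6) for g, v in corr.intra_group.items()},
            "inter_group": {f"{g}|{h}": round(v, 6) for (g, h), v in corr.inter_group.items()},
        },
    }

    # exon-level 3'/5' bias
    if config.exon_tsv is not None:
        exon = fio.read_exon_table(config.exon_tsv)
    else:
        exon = simulate_exon_table(
            **{"n_genes": 2000, "seed": config.seed + 2, **config.exon}
        )
        fio.write_exon_table(exon, out / "exon_table.tsv")
    ratio = three_prime_ratio(exon)
    ratio.log10_ratio.to_csv(out / "three_prime_ratio.tsv", sep="\t")
    summary["metrics"]["three_prime_ratio"] = {
        k: (round(v, 6) if isinstance(v, float) else v) for k, v in ratio.summary().items()
    }
    summary["metrics"]["three_prime_ratio"]["n_excluded_single_position"] = (
        ratio.n_excluded_single_position
    )

    # ---- stage 3: concordance -------------------------------------------
    slice_a = matrix.group_slice(group_a)
    slice_b = matrix.group_slice(group_b)
    conc_rows = []
    for cutoff in config.cutoffs:
        res = replicate_ratio_concordance(
            slice_a, slice_b, ConcordanceConfig(cutoff=cutoff, aggregation=config.aggregation)
        )
        conc_rows.append({"cutoff": cutoff, "overall_percent": round(res.overall, 6)})
    conc_df = pd.DataFrame(conc_rows)
    conc_df.to_csv(out / "concordance.tsv", sep="\t", index=False)
    summary["concordance"] = {
        f"{row['cutoff']:g}": row["overall_percent"] for row in conc_rows
    }

    ranks = top_n_rank_comparison(
        slice_a.mean(axis=1), slice_b.mean(axis=1), config.top_n, config.bin_edges
    )
    ranks.table.to_csv(out / "rank_comparison.tsv", sep="\t")
    summary["rank_comparison"] = {"n_top": ranks.n_top, "bins": ranks.bins}

    # qPCR
    if config.cq_csvs:
        cq_tables = {label: fio.read_cq_table(p) for label, p in config.cq_csvs.items()}
    else:
        cq_genes = ["Gapdh", "Pgk1", "Actb", "Gfap", "Mbp", "Mag", "Cx3cr1"]
        cq_ff, cq_ffpe = simulate_cq_table(
            cq_genes, **{"seed": config.seed + 3, **config.cq}
        )
        cq_tables = {"FF": cq_ff, "FFPE": cq_ffpe}
        fio.write_cq_table(cq_ff, out / "cq_FF.csv")
        fio.write_cq_table(cq_ffpe, out / "cq_FFPE.csv")
    cq_block: dict[str, Any] = {}
    for label in sorted(cq_tables):
        summ = cq_summary(cq_tables[label])
        summ.to_csv(out / f"cq_summary_{label}.tsv", sep="\t")
        ranking = delta_cq_rank(cq_tables[label])
        ranking.to_csv(out / f"delta_cq_rank_{label}.tsv", sep="\t")
        cq_block[label] = {
            "mean_geo_cq": round(float(summ["geo_mean_cq"].mean()), 6),
            "rank_order": ranking.index.tolist(),
        }
    summary["cq"] = cq_block

    # differential-expression filter between the two groups
    de = de_filter(matrix, case_group=group_b, control_group=group_a)
    de.to_csv(out / "de_table.tsv", sep="\t")
    selected = de.index[de["selected"]].tolist()
    (out / "de_genes.txt").write_text("\n".join(selected) + ("\n" if selected else ""), "utf-8")
    summary["de"] = {"n_selected": len(selected)}

    # ---- report bundle ---------------------------------------------------
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(_render_report(summary, group_a, group_b), "utf-8")
    return summary


def _render_report(summary: dict[str, Any], group_a: str, group_b: str) -> str:
    lines = ["FFPE RNA quality & concordance report", "=" * 40, ""]
    lines.append("RNA quality (DV200):")
    for label, block in summary["quality"].items():
        peak = block["crosslink_peak"]
        peak_txt = (
            f"; cross-link peak at {peak['center_nt']:.0f} nt" if peak else "; no cross-link peak"
        )
        lines.append(f"  {label}: DV200 = {block['dv200']:.1f}% ({block['category']}){peak_txt}")
    m = summary["metrics"]
    lines.append("")
    lines.append("Reproducibility:")
    for g, v in m["median_cv_percent"].items():
        lines.append(f"  median %CV [{g}]: {v:.2f}")
    cvc = m["cv_compare"]
    lines.append(
        f"  cube-root CV t-test: t({cvc['df']:.0f}) = {cvc['t']:.2f}, "
        f"p = {cvc['p']:.3g}, Cohen's d = {cvc['cohens_d']:.3f}"
    )
    for g, v in m["pearson"]["intra_group"].items():
        lines.append(f"  mean intra-group Pearson r [{g}]: {v:.4f}")
    for g, v in m["pearson"]["inter_group"].items():
        lines.append(f"  mean inter-group Pearson r [{g}]: {v:.4f}")
    tp = m["three_prime_ratio"]
    lines.append(f"  median log10 3'/5' ratio: {tp['median']:.3f} (n = {tp['n_genes']})")
    lines.append("")
    lines.append(f"Replicate-ratio concordance ({group_a} vs {group_b}):")
    for cutoff, rate in summary["concordance"].items():
        lines.append(f"  cut-off {cutoff}: {rate:.1f}% concordant")
    rk = summary["rank_comparison"]
    lines.append("")
    lines.append(f"Top-{rk['n_top']} rank comparison:")
    for label, count in rk["bins"].items():
        lines.append(f"  {label}: {count}")
    lines.append("")
    lines.append(f"Differential expression: {summary['de']['n_selected']} genes selected")
    return "\n".join(lines) + "\n"
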