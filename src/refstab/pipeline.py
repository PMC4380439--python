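"""One-command validation study: all methods, both efficiency modes.

``run_study`` evaluates geNorm, NormFinder, BestKeeper and the
comparative dCt method on a Cq matrix, in efficiency-corrected and
perfect-doubling (E=2) modes, compares the two rankings per method,
builds the comprehensive aggregate and the pairwise-variation curve,
and collects everything into a ``StudyReport`` that renders
deterministically to TSV, JSON or Markdown.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bestkeeper, deltact, genorm, normfinder
from .qpcr_data import CqMatrix, EfficiencyTable, compute_rq, log_rq
from .rank_compare import (
    RankComparison,
    StabilityRanking,
    compare,
    format_rank_label,
)

__all__ = ["StudyReport", "run_study", "render_report"]

SCHEMA_VERSION = "1.0"
GENORM_CAVEAT = (
    "The 0.15 pairwise-variation cutoff is a rule of thumb; a visual "
    "interpretation of the V(n, n+1) trend can also inform the choice "
    "of the number of reference genes."
)

MethodRankings = dict[str, dict[str, StabilityRanking]]  # method -> mode -> ranking


@dataclass(frozen=True)
class StudyReport:
    genes: tuple[str, ...]
    rankings: MethodRankings
    comparisons: dict[str, RankComparison]  # corrected vs E2, per method
    bestkeeper_result: bestkeeper.BestKeeperResult | None
    comprehensive: deltact.ComprehensiveRanking | None
    vcurves: dict[str, genorm.PairwiseVariationCurve]  # per mode
    genorm_results: dict[str, genorm.GeNormResult] = field(default_factory=dict)
    normfinder_results: dict[str, normfinder.NormFinderResult] = field(default_factory=dict)
    deltact_result: deltact.DeltaCtResult | None = None
    parameters: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Genes x (method, mode) matrix of printed rank labels."""
        cols = {}
        for method, by_mode in self.rankings.items():
            for mode, ranking in by_mode.items():
                cols[f"{method}_{mode}"] = {
                    g: format_rank_label(ranking[g]) for g in self.genes
                }
        return pd.DataFrame(cols, index=pd.Index(self.genes, name="gene"))


def run_study(
    cq: CqMatrix,
    eff: EfficiencyTable | None = None,
    methods: tuple[str, ...] = ("genorm", "normfinder", "bestkeeper", "deltact"),
    efficiency_mode: str = "both",
    genorm_cutoff: float = genorm.DEFAULT_V_CUTOFF,
    bestkeeper_sd_threshold: float = bestkeeper.DEFAULT_SD_THRESHOLD,
    normfinder_mode: str = "auto",
) -> StudyReport:
    """Run the selected methods and the corrected-vs-E2 comparison."""
    if efficiency_mode not in {"corrected", "e2", "both"}:
        raise ValueError(f"unknown efficiency_mode {efficiency_mode!r}")
    modes = {
        "corrected": ("corrected",),
        "e2": ("E2",),
        "both": ("corrected", "E2"),
    }[efficiency_mode]
    if "corrected" in modes and eff is None:
        raise ValueError("corrected mode requires an efficiency table")

    logq = {
        mode: log_rq(compute_rq(cq, eff, mode))  # type: ignore[arg-type]
        for mode in modes
    }
    group_labels = cq.group_labels()

    rankings: MethodRankings = {}
    genorm_results: dict[str, genorm.GeNormResult] = {}
    nf_results: dict[str, normfinder.NormFinderResult] = {}
    vcurves: dict[str, genorm.PairwiseVariationCurve] = {}

    if "genorm" in methods:
        rankings["genorm"] = {}
        for mode in modes:
            res = genorm.rank_genes(logq[mode], list(cq.genes))
            res = genorm.GeNormResult(
                res.genes,
                StabilityRanking("genorm", res.ranking.labels, mode, res.m_final),
                res.m_final,
                res.exclusion_order,
                res.final_pair,
                res.final_pair_mean_m,
                res.m_trajectory,
            )
            genorm_results[mode] = res
            rankings["genorm"][mode] = res.ranking
            vcurves[mode] = genorm.pairwise_variation_curve(
                logq[mode], res, cutoff=genorm_cutoff
            )
    if "normfinder" in methods:
        rankings["normfinder"] = {}
        for mode in modes:
            res = normfinder.stability(
                logq[mode], cq.genes, groups=group_labels, mode=normfinder_mode
            )
            nf_results[mode] = res
            rankings["normfinder"][mode] = StabilityRanking(
                "normfinder", res.ranking.labels, mode, res.rho
            )

    bk_result = None
    if "bestkeeper" in methods:
        bk_result = bestkeeper.bestkeeper_index(cq, sd_threshold=bestkeeper_sd_threshold)
        rankings["bestkeeper_r"] = {"raw": bk_result.by_correlation}
        rankings["bestkeeper_sd"] = {"raw": bk_result.by_sd}

    dc_result = None
    if "deltact" in methods:
        dc_result = deltact.deltact_scores(cq)
        rankings["deltact"] = {"raw": dc_result.ranking}

    comprehensive = None
    if set(methods) >= {"genorm", "normfinder", "bestkeeper", "deltact"}:
        comprehensive = deltact.comprehensive_rank(cq)
        rankings["comprehensive"] = {"raw": comprehensive.final}

    comparisons = {}
    if len(modes) == 2:
        for method in ("genorm", "normfinder"):
            if method in rankings:
                comparisons[method] = compare(
                    rankings[method]["corrected"], rankings[method]["E2"]
                )

    parameters = {
        "schema_version": SCHEMA_VERSION,
        "methods": list(methods),
        "efficiency_mode": efficiency_mode,
        "genorm_cutoff": genorm_cutoff,
        "bestkeeper_sd_threshold": bestkeeper_sd_threshold,
        "normfinder_mode": normfinder_mode,
        "n_genes": cq.n_genes,
        "n_samples": cq.n_samples,
        "grouped": cq.groups is not None,
        "input_sha256": hashlib.sha256(cq.values.tobytes()).hexdigest(),
    }
    return StudyReport(
        genes=cq.genes,
        rankings=rankings,
        comparisons=comparisons,
        bestkeeper_result=bk_result,
        comprehensive=comprehensive,
        vcurves=vcurves,
        genorm_results=genorm_results,
        normfinder_results=nf_results,
        deltact_result=dc_result,
        parameters=parameters,
    )


def _report_dict(report: StudyReport) -> dict:
    out: dict = {"schema_version": SCHEMA_VERSION, "parameters": report.parameters}
    out["rankings"] = {
        method: {
            mode: {g: format_rank_label(r[g]) for g in report.genes}
            for mode, r in by_mode.items()
        }
        for method, by_mode in report.rankings.items()
    }
    out["comparisons"] = {
        method: {
            "n_changed": c.n_changed,
            "n_total": c.n_total,
            "pct_changed": round(c.pct_changed),
            "n_minor": c.n_minor,
            "n_major": c.n_major,
            "per_gene": c.to_frame().to_dict(orient="records"),
        }
        for method, c in report.comparisons.items()
    }
    out["pairwise_variation"] = {
        mode: {
            "n": list(v.n_values),
            "V": [round(x, 10) for x in v.v_values],
            "cutoff": v.cutoff,
            "optimal_n": v.optimal_n,
            "advisory": v.advisory,
            "caveat": GENORM_CAVEAT,
        }
        for mode, v in report.vcurves.items()
    }
    if report.comprehensive is not None:
        out["comprehensive_note"] = report.comprehensive.note
    return out


def render_report(report: StudyReport, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write report files; identical report -> identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6g")
        written.append(path)

    if fmt == "json":
        path = out / "report.json"
        path.write_text(json.dumps(_report_dict(report), indent=1, sort_keys=True))
        return [path]
    if fmt == "md":
        path = out / "report.md"
        path.write_text(_render_markdown(report))
        return [path]
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")

    save(report.table(), "rank_table.tsv")
    for mode, res in report.genorm_results.items():
        df = res.ranking.to_frame().set_index("gene")
        df["exclusion_step"] = [
            res.exclusion_order.index(g) + 1 if g in res.exclusion_order else 0
            for g in df.index
        ]
        save(df, f"genorm_m_{mode}.tsv")
    for mode, v in report.vcurves.items():
        save(
            pd.DataFrame({"n": v.n_values, "V": v.v_values}).set_index("n"),
            f"genorm_v_{mode}.tsv",
        )
    for mode, res in report.normfinder_results.items():
        save(res.to_frame().set_index("gene"), f"normfinder_{mode}.tsv")
    if report.bestkeeper_result is not None:
        save(report.bestkeeper_result.to_frame(), "bestkeeper.tsv")
    if report.deltact_result is not None:
        save(report.deltact_result.ranking.to_frame().set_index("gene"), "deltact.tsv")
    if report.comprehensive is not None:
        save(report.comprehensive.to_frame(), "comprehensive.tsv")
    for method, c in report.comparisons.items():
        save(c.to_frame().set_index("gene"), f"rank_changes_{method}.tsv")
    return written


def _render_markdown(report: StudyReport) -> str:
    lines = ["# Reference-gene stability report", ""]
    table = report.table()
    header = ["gene", *table.columns]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "|".join("---" for _ in header) + "|")
    for gene, row in table.iterrows():
        lines.append("| " + " | ".join([str(gene), *map(str, row)]) + " |")
    lines.append("")
    for method, c in report.comparisons.items():
        lines.append(
            f"- {method}: {c.n_changed}/{c.n_total} ranks changed "
            f"({round(c.pct_changed)}%), {c.n_minor} minor / {c.n_major} major"
        )
    for mode, v in report.vcurves.items():
        opt = v.optimal_n if v.optimal_n is not None else "undefined"
        lines.append(f"- optimal reference-gene number ({mode}): {opt}")
        if v.advisory:
            lines.append(f"  - {v.advisory}")
    lines += ["", f"> {GENORM_CAVEAT}"]
    if report.comprehensive is not None:
        lines.append(f"> {report.comprehensive.note}")
    lines.append("")
    return "\n".join(lines)
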