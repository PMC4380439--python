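"""Published multi-method ranking fixture and its discrepancy summary.

The shipped TSV transcribes the rank table of a 14-gene, two-dataset
reference-gene validation study: for geNorm and NormFinder the ranks
obtained with assay-specific efficiency correction, without correction,
and from the raw-Cq web aggregator; for BestKeeper the correlation-based
and SD-based ranks. Tie entries are printed ``1/2``.

Replaying the efficiency-corrected vs uncorrected comparison over both
datasets reproduces the study's headline discrepancy statistics:
20/28 changed (71%, 16 major) for geNorm and 14/28 changed (50%,
5 major) for NormFinder.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rank_compare import (
    PairSummary,
    RankComparison,
    StabilityRanking,
    compare,
    parse_rank_label,
    summarize_pairs,
)

__all__ = ["load_published_rankings", "published_ranking", "published_discrepancy"]

DATASETS = ("fs1", "cis")
RANK_COLUMNS = (
    "genorm_eff",
    "genorm_noeff",
    "genorm_reffinder",
    "normfinder_eff",
    "normfinder_noeff",
    "normfinder_reffinder",
    "bestkeeper_r",
    "bestkeeper_sd",
)


def load_published_rankings() -> pd.DataFrame:
    with resources.files("refstab.data").joinpath("published_rankings.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def published_ranking(dataset: str, column: str) -> StabilityRanking:
    """One rank column of the fixture as a StabilityRanking."""
    df = load_published_rankings()
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}")
    if column not in RANK_COLUMNS:
        raise ValueError(f"unknown rank column {column!r}")
    sub = df[df["dataset"] == dataset]
    labels = {g: parse_rank_label(r) for g, r in zip(sub["gene"], sub[column])}
    mode = "E2" if column.endswith(("noeff", "reffinder")) else "corrected"
    return StabilityRanking(column, labels, mode)


def published_discrepancy(method: str) -> tuple[PairSummary, dict[str, RankComparison]]:
    """Corrected-vs-uncorrected comparison pooled over both datasets.

    ``method`` is ``genorm`` or ``normfinder``. Returns the pooled
    summary and the per-dataset comparisons.
    """
    if method not in {"genorm", "normfinder"}:
        raise ValueError(f"unknown method {method!r}")
    per_dataset = {
        ds: compare(
            published_ranking(ds, f"{method}_eff"),
            published_ranking(ds, f"{method}_noeff"),
        )
        for ds in DATASETS
    }
    return summarize_pairs(per_dataset.values()), per_dataset
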