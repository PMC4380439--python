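"""BestKeeper descriptive statistics, index, and the two rankings.

Operates on raw Cq only — the output is by construction independent of
any amplification-efficiency table. Genes whose Cq dispersion exceeds a
threshold (default 1.5 cycles) are excluded from the index but still
receive a correlation and appear in both rankings:

* ``by_correlation`` — Pearson r of each gene's Cq vector against the
  index (per-sample geometric mean of retained genes' Cq), descending;
* ``by_sd`` — raw Cq standard deviation, ascending (the ranking a
  Cq-only aggregator falls back to).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_data import CqMatrix
from .rank_compare import StabilityRanking, ranking_from_scores

__all__ = ["BestKeeperResult", "descriptives", "bestkeeper_index"]

DEFAULT_SD_THRESHOLD = 1.5


def descriptives(cq: CqMatrix, dispersion: str = "sd") -> pd.DataFrame:
    """Per-gene n, geometric/arithmetic mean, min, max, dispersion, CV%.

    ``dispersion='sd'`` is the sample standard deviation (ddof=1);
    ``'mad'`` gives the mean absolute deviation from the arithmetic
    mean, the dispersion flavour of the original spreadsheet tool.
    """
    x = cq.values
    ar_mean = x.mean(axis=1)
    if dispersion == "sd":
        disp = x.std(axis=1, ddof=1)
    elif dispersion == "mad":
        disp = np.abs(x - ar_mean[:, None]).mean(axis=1)
    else:
        raise ValueError(f"unknown dispersion {dispersion!r}")
    return pd.DataFrame(
        {
            "n": x.shape[1],
            "geo_mean": stats.gmean(x, axis=1),
            "ar_mean": ar_mean,
            "min": x.min(axis=1),
            "max": x.max(axis=1),
            "sd": disp,
            "cv_pct": 100.0 * disp / ar_mean,
        },
        index=pd.Index(cq.genes, name="gene"),
    )


@dataclass(frozen=True)
class BestKeeperResult:
    stats: pd.DataFrame  # descriptives + excluded, r, p
    index: pd.Series  # per-sample geometric mean Cq of retained genes
    by_correlation: StabilityRanking
    by_sd: StabilityRanking
    sd_threshold: float

    @property
    def excluded(self) -> list[str]:
        return list(self.stats.index[self.stats["excluded"]])

    def to_frame(self) -> pd.DataFrame:
        df = self.stats.copy()
        corr = self.by_correlation.numeric()
        sd = self.by_sd.numeric()
        df["rank_by_r"] = [int(corr[g]) for g in df.index]
        df["rank_by_sd"] = [int(sd[g]) for g in df.index]
        return df


def bestkeeper_index(
    cq: CqMatrix,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    dispersion: str = "sd",
) -> BestKeeperResult:
    """Build the index over retained genes and rank all genes both ways."""
    df = descriptives(cq, dispersion=dispersion)
    df["excluded"] = df["sd"] > sd_threshold
    retained = [g for g in cq.genes if not df.loc[g, "excluded"]]
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 genes with dispersion <= {sd_threshold}; "
            "cannot build an index"
        )
    keep_idx = [cq.genes.index(g) for g in retained]
    index = pd.Series(
        stats.gmean(cq.values[keep_idx], axis=0), index=list(cq.samples), name="index"
    )

    r_vals, p_vals = {}, {}
    for i, gene in enumerate(cq.genes):
        r, p = stats.pearsonr(cq.values[i], index.to_numpy())
        r_vals[gene] = float(r)
        p_vals[gene] = float(p)
    df["r"] = [r_vals[g] for g in df.index]
    df["p"] = [p_vals[g] for g in df.index]

    # descending r == ascending (-r); SD ascending
    by_corr = ranking_from_scores(
        "bestkeeper_r", {g: -r_vals[g] for g in cq.genes}, order=cq.genes
    )
    by_corr = StabilityRanking("bestkeeper_r", by_corr.labels, "raw", r_vals)
    by_sd = ranking_from_scores(
        "bestkeeper_sd",
        {g: float(df.loc[g, "sd"]) for g in cq.genes},
        "raw",
        order=cq.genes,
    )
    return BestKeeperResult(df, index, by_corr, by_sd, sd_threshold)
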