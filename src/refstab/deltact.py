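"""Comparative dCt stability scoring and the comprehensive rank aggregate.

The comparative dCt score of gene i is the mean, over every partner
gene k, of the standard deviation across samples of the pairwise Cq
difference Cq_i - Cq_k. It is computed directly on raw Cq and is
algebraically identical to the geNorm M value evaluated on perfect-
doubling (E=2) log quantities over the full panel.

The comprehensive ranking emulates the popular raw-Cq web aggregator:
run geNorm and NormFinder on E=2 quantities, BestKeeper by Cq standard
deviation, and the comparative dCt method, then order genes by the
geometric mean of the four component ranks. This aggregation is an
emulation convention, not a validated statistic, and is labelled as
advisory in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bestkeeper, genorm, normfinder
from .qpcr_data import CqMatrix, compute_rq, log_rq
from .rank_compare import StabilityRanking, ranking_from_scores

__all__ = ["DeltaCtResult", "ComprehensiveRanking", "deltact_scores", "comprehensive_rank"]

ADVISORY_NOTE = (
    "The comprehensive rank is an arithmetic aggregation of four methods "
    "with different underlying models; treat it as a complementary, "
    "advisory summary, not a validated stability statistic."
)


@dataclass(frozen=True)
class DeltaCtResult:
    genes: tuple[str, ...]
    scores: dict[str, float]
    ranking: StabilityRanking


def deltact_scores(cq: CqMatrix) -> DeltaCtResult:
    """score_i = mean over k != i of SD_samples(Cq_i - Cq_k); ascending rank."""
    x = cq.values
    g = x.shape[0]
    if g < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    diff = x[:, None, :] - x[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    scores = {gene: float(v) for gene, v in zip(cq.genes, sd.sum(axis=1) / (g - 1))}
    ranking = ranking_from_scores("deltact", scores, "raw", order=cq.genes)
    return DeltaCtResult(cq.genes, scores, ranking)


@dataclass(frozen=True)
class ComprehensiveRanking:
    genes: tuple[str, ...]
    component_ranks: pd.DataFrame  # genes x {genorm, normfinder, bestkeeper_sd, deltact}
    geo_mean: dict[str, float]
    final: StabilityRanking
    note: str = ADVISORY_NOTE

    def to_frame(self) -> pd.DataFrame:
        df = self.component_ranks.copy()
        df["geo_mean"] = [self.geo_mean[g] for g in df.index]
        final = self.final.numeric()
        df["final_rank"] = [int(final[g]) for g in df.index]
        return df


def comprehensive_rank(cq: CqMatrix) -> ComprehensiveRanking:
    """Geometric-mean-of-ranks aggregation of the four methods on raw Cq.

    geNorm and NormFinder run on E=2 relative quantities (the raw-Cq
    path); geNorm's top tie contributes rank 1.5 to both tied genes.
    Final ties are broken by comparative dCt score, then input order.
    """
    if cq.n_genes < 3:
        raise ValueError("comprehensive ranking needs at least 3 genes")
    logq = log_rq(compute_rq(cq, efficiency_mode="E2"))
    gn = genorm.rank_genes(logq, list(cq.genes)).ranking.numeric()
    nf = normfinder.stability_ungrouped(logq, cq.genes).ranking.numeric()
    bk = bestkeeper.bestkeeper_index(cq).by_sd.numeric()
    dc = deltact_scores(cq)
    dct = dc.ranking.numeric()

    comp = pd.DataFrame(
        {
            "genorm": [gn[g] for g in cq.genes],
            "normfinder": [nf[g] for g in cq.genes],
            "bestkeeper_sd": [bk[g] for g in cq.genes],
            "deltact": [dct[g] for g in cq.genes],
        },
        index=pd.Index(cq.genes, name="gene"),
    )
    gm = {g: float(np.exp(np.log(comp.loc[g]).mean())) for g in cq.genes}
    pos = {g: i for i, g in enumerate(cq.genes)}
    ordered = sorted(cq.genes, key=lambda g: (gm[g], dc.scores[g], pos[g]))
    labels = {g: ordered.index(g) + 1 for g in cq.genes}
    final = StabilityRanking("comprehensive", labels, "raw", gm)
    return ComprehensiveRanking(cq.genes, comp, gm, final)
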