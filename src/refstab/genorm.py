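"""geNorm: M values, stepwise exclusion ranking and pairwise variation.

All computations run on a log2 relative-quantity matrix (genes x
samples). The gene-stability measure M_j is the mean, over all partner
genes k, of the standard deviation across samples of the pairwise log
ratio ``logq_j - logq_k``; low M means stable. Ranking proceeds by
repeatedly dropping the highest-M gene until two genes — which a purely
pairwise measure cannot separate — remain and share the top rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rank_compare import StabilityRanking

__all__ = [
    "GeNormResult",
    "PairwiseVariationCurve",
    "m_values",
    "rank_genes",
    "pairwise_variation_curve",
]

DEFAULT_V_CUTOFF = 0.15


def _check_logq(logq: np.ndarray) -> np.ndarray:
    logq = np.asarray(logq, dtype=float)
    if logq.ndim != 2 or logq.shape[0] < 2 or logq.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    return logq


def m_values(logq: np.ndarray) -> np.ndarray:
    """Per-gene M: mean over partners of SD (ddof=1) of pairwise log ratios."""
    logq = _check_logq(logq)
    g = logq.shape[0]
    # V[j,k] = SD_samples(logq_j - logq_k); symmetric, zero diagonal
    diff = logq[:, None, :] - logq[None, :, :]
    v = diff.std(axis=2, ddof=1)
    return (v.sum(axis=1)) / (g - 1)


@dataclass(frozen=True)
class PairwiseVariationCurve:
    """V(n, n+1) values for n = 2..G-1 and the implied optimal gene count."""

    n_values: tuple[int, ...]
    v_values: tuple[float, ...]
    cutoff: float
    optimal_n: int | None

    @property
    def advisory(self) -> str | None:
        if self.optimal_n is None:
            return (
                "no pairwise variation fell below the cutoff; inspect the "
                "trend of V(n, n+1) visually to choose the gene count"
            )
        return None


@dataclass(frozen=True)
class GeNormResult:
    """Stepwise geNorm output.

    ``m_final`` holds each gene's M at the step it was excluded (the
    remaining pair reports their common pair SD). ``m_trajectory`` has
    one row per exclusion step with the M of every gene still in play.
    """

    genes: tuple[str, ...]
    ranking: StabilityRanking
    m_final: dict[str, float]
    exclusion_order: tuple[str, ...]
    final_pair: tuple[str, str]
    final_pair_mean_m: dict[str, float]
    m_trajectory: tuple[dict[str, float], ...]


def rank_genes(logq: np.ndarray, genes: list[str] | tuple[str, ...] | None = None) -> GeNormResult:
    """Stepwise exclusion ranking; the last two genes tie for rank 1/2.

    At each step the gene with the highest M over the remaining panel is
    removed (ties broken by removing the gene later in input order) and
    assigned ranks G, G-1, ..., 3. The final two genes share the tie set
    {1, 2}; their reported M is the SD of their log ratio.
    """
    logq = _check_logq(logq)
    g = logq.shape[0]
    if g < 3:
        raise ValueError("stepwise ranking needs at least 3 genes")
    if genes is None:
        genes = [f"g{i+1}" for i in range(g)]
    genes = tuple(str(x) for x in genes)
    if len(genes) != g:
        raise ValueError("gene names do not match matrix rows")

    remaining = list(range(g))
    excluded: list[int] = []
    m_final: dict[str, float] = {}
    trajectory: list[dict[str, float]] = []
    while len(remaining) > 2:
        m = m_values(logq[remaining])
        trajectory.append({genes[i]: float(v) for i, v in zip(remaining, m)})
        # argmax with later-in-input-order tie-break
        worst_pos = max(range(len(remaining)), key=lambda p: (m[p], remaining[p]))
        worst = remaining[worst_pos]
        m_final[genes[worst]] = float(m[worst_pos])
        excluded.append(worst)
        remaining.pop(worst_pos)

    pair = (genes[remaining[0]], genes[remaining[1]])
    pair_v = float(np.std(logq[remaining[0]] - logq[remaining[1]], ddof=1))
    m_pair = m_values(logq[remaining])  # both equal pair_v for two genes
    trajectory.append({genes[i]: float(v) for i, v in zip(remaining, m_pair)})
    for i in remaining:
        m_final[genes[i]] = pair_v

    labels: dict[str, int | frozenset[int]] = {}
    tie = frozenset({1, 2})
    for name in pair:
        labels[name] = tie
    for step, idx in enumerate(excluded):
        labels[genes[idx]] = g - step
    labels = {name: labels[name] for name in genes}
    ranking = StabilityRanking("genorm", labels, values=dict(m_final))
    return GeNormResult(
        genes=genes,
        ranking=ranking,
        m_final=m_final,
        exclusion_order=tuple(genes[i] for i in excluded),
        final_pair=pair,
        final_pair_mean_m={name: float(v) for name, v in zip(pair, m_pair)},
        m_trajectory=tuple(trajectory),
    )


def stability_order(result: GeNormResult) -> list[str]:
    """Genes from most to least stable (tie pair first, input order)."""
    return list(result.final_pair) + list(reversed(result.exclusion_order))


def pairwise_variation_curve(
    logq: np.ndarray,
    result: GeNormResult,
    cutoff: float = DEFAULT_V_CUTOFF,
) -> PairwiseVariationCurve:
    """V(n, n+1) = SD over samples of log2(NF_n / NF_{n+1}).

    NF_n is the per-sample geometric mean of the relative quantities of
    the n most stable genes, so log2 NF_n is the mean of the top-n rows
    of ``logq``. The optimal gene count is the smallest n whose
    V(n, n+1) falls below the cutoff (0.15 rule of thumb); when no V
    does, it is undefined and a visual-trend advisory is attached.
    """
    logq = _check_logq(logq)
    g = logq.shape[0]
    if g < 3:
        raise ValueError("pairwise variation needs at least 3 genes")
    order = stability_order(result)
    idx = [result.genes.index(name) for name in order]
    ns, vs = [], []
    log_nf_prev = logq[idx[:2]].mean(axis=0)
    for n in range(2, g):
        log_nf_next = logq[idx[: n + 1]].mean(axis=0)
        v = float(np.std(log_nf_prev - log_nf_next, ddof=1))
        ns.append(n)
        vs.append(v)
        log_nf_prev = log_nf_next
    optimal_n: int | None = None
    for n, v in zip(ns, vs):
        if v < cutoff:
            optimal_n = n
            break
    return PairwiseVariationCurve(tuple(ns), tuple(vs), cutoff, optimal_n)
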