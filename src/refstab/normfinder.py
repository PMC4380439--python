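"""Model-based stability estimation (NormFinder-style).

Works on a log2 relative-quantity matrix. The model decomposes each
gene's log signal into a gene effect, a shared per-sample (loading)
effect, optional group-level expression shifts, and gene-specific
noise. The ungrouped estimator is a method-of-moments variance
estimate from two-way residuals with a contamination correction so
that every other gene's noise leaking into the per-sample mean is
removed in expectation. The grouped estimator additionally measures
each gene's systematic deviation between groups and shrinks it
towards zero in proportion to its sampling noise.

Absolute stability values are implementation-specific across the many
circulating NormFinder ports; rankings are the contract here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rank_compare import StabilityRanking, ranking_from_scores

__all__ = ["NormFinderResult", "stability_ungrouped", "stability_grouped", "stability"]


@dataclass(frozen=True)
class NormFinderResult:
    genes: tuple[str, ...]
    rho: dict[str, float]
    ranking: StabilityRanking
    grouped: bool
    # grouped mode only: per gene x group intragroup variance and
    # (shrunken) intergroup deviation
    sigma2: pd.DataFrame | None = None
    d_raw: pd.DataFrame | None = None
    d_shrunk: pd.DataFrame | None = None
    gamma2: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.ranking.to_frame().rename(columns={"stability": "rho"})
        if self.grouped and self.sigma2 is not None:
            for grp in self.sigma2.columns:
                df[f"sigma2_{grp}"] = self.sigma2[grp].reindex(df["gene"]).to_numpy()
                df[f"d_{grp}"] = self.d_shrunk[grp].reindex(df["gene"]).to_numpy()
        return df


def _check(logq: np.ndarray, min_genes: int, min_samples: int) -> np.ndarray:
    logq = np.asarray(logq, dtype=float)
    if logq.ndim != 2:
        raise ValueError("logq must be 2-D (genes x samples)")
    g, n = logq.shape
    if g < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {g}")
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    return logq


def _gene_names(genes: Sequence[str] | None, g: int) -> tuple[str, ...]:
    if genes is None:
        return tuple(f"g{i+1}" for i in range(g))
    if len(genes) != g:
        raise ValueError("gene names do not match matrix rows")
    return tuple(str(x) for x in genes)


def _twoway_s2(x: np.ndarray) -> np.ndarray:
    """Per-gene residual variance after removing gene and sample means."""
    n = x.shape[1]
    r = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    return (r**2).sum(axis=1) / (n - 1)


def _corrected_sigma2(s2: np.ndarray) -> np.ndarray:
    """Contamination-corrected variance estimates (signed).

    sigma2_i = (s2_i - sum(s2)/(G(G-1))) * G/(G-2); unbiased under the
    two-way model (the per-sample mean mixes in 1/G^2 of every other
    gene's variance). May come out slightly negative for very quiet
    genes; callers floor at zero before taking square roots, keeping
    the raw estimate unbiased.
    """
    g = s2.shape[0]
    if g < 3:
        raise ValueError("contamination correction undefined for fewer than 3 genes")
    return (s2 - s2.sum() / (g * (g - 1))) * g / (g - 2)


def stability_ungrouped(
    logq: np.ndarray, genes: Sequence[str] | None = None
) -> NormFinderResult:
    """Stability rho_i = sqrt(corrected per-gene variance); rank ascending."""
    logq = _check(logq, min_genes=3, min_samples=4)
    g = logq.shape[0]
    names = _gene_names(genes, g)
    sigma2 = np.maximum(_corrected_sigma2(_twoway_s2(logq)), 0.0)
    rho = {name: float(np.sqrt(v)) for name, v in zip(names, sigma2)}
    ranking = ranking_from_scores("normfinder", rho, order=names)
    return NormFinderResult(names, rho, ranking, grouped=False)


def stability_grouped(
    logq: np.ndarray,
    groups: Sequence[str],
    genes: Sequence[str] | None = None,
) -> NormFinderResult:
    """Grouped stability combining intragroup noise and intergroup shift.

    Per gene i and group g: sigma2_ig from within-group two-way
    residuals; raw deviation d_ig = within-group mean of the
    sample-centered signal, centered per gene with group-size weights.
    The intergroup variance gamma2 is estimated over all (i, g) cells,
    each d_ig is shrunk by gamma2 / (gamma2 + sigma2_ig / n_g), and

        rho_i = mean over groups of ( |d_shrunk_ig| + sigma_ig / sqrt(n_g) ).
    """
    logq = _check(logq, min_genes=3, min_samples=4)
    g, n = logq.shape
    names = _gene_names(genes, g)
    labels = np.asarray([str(x) for x in groups])
    if labels.shape[0] != n:
        raise ValueError("group labels do not match sample count")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("grouped mode needs at least 2 groups")
    sizes = {grp: int((labels == grp).sum()) for grp in uniq}
    too_small = [grp for grp, k in sizes.items() if k < 3]
    if too_small:
        raise ValueError(f"groups smaller than 3 samples: {too_small}")

    sigma2 = np.empty((g, len(uniq)))
    d_raw = np.empty((g, len(uniq)))
    centered = logq - logq.mean(axis=0, keepdims=True)  # remove sample effect
    for c, grp in enumerate(uniq):
        mask = labels == grp
        sigma2[:, c] = np.maximum(_corrected_sigma2(_twoway_s2(logq[:, mask])), 0.0)
        d_raw[:, c] = centered[:, mask].mean(axis=1)
    weights = np.array([sizes[grp] for grp in uniq], dtype=float)
    d_raw = d_raw - (d_raw * weights).sum(axis=1, keepdims=True) / weights.sum()

    ng = weights[None, :]
    gamma2 = max(float(np.mean(d_raw**2) - np.mean(sigma2 / ng)), 0.0)
    if gamma2 == 0.0:
        d_shrunk = np.zeros_like(d_raw)
    else:
        d_shrunk = d_raw * gamma2 / (gamma2 + sigma2 / ng)

    rho_vec = (np.abs(d_shrunk) + np.sqrt(sigma2) / np.sqrt(ng)).mean(axis=1)
    rho = {name: float(v) for name, v in zip(names, rho_vec)}
    ranking = ranking_from_scores("normfinder", rho, order=names)
    idx = pd.Index(names, name="gene")
    return NormFinderResult(
        names,
        rho,
        ranking,
        grouped=True,
        sigma2=pd.DataFrame(sigma2, index=idx, columns=uniq),
        d_raw=pd.DataFrame(d_raw, index=idx, columns=uniq),
        d_shrunk=pd.DataFrame(d_shrunk, index=idx, columns=uniq),
        gamma2=gamma2,
    )


def stability(
    logq: np.ndarray,
    genes: Sequence[str] | None = None,
    groups: Sequence[str] | Mapping[str, str] | None = None,
    mode: str = "auto",
) -> NormFinderResult:
    """Dispatch between grouped and ungrouped modes.

    ``auto`` uses the grouped path when at least two groups are given.
    """
    if mode not in {"auto", "grouped", "ungrouped"}:
        raise ValueError(f"unknown mode {mode!r}")
    labels: Sequence[str] | None = None
    if groups is not None:
        labels = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    wants_grouped = labels is not None and len(set(labels)) >= 2
    if mode == "grouped" or (mode == "auto" and wants_grouped):
        if labels is None:
            raise ValueError("grouped mode requires group labels")
        return stability_grouped(logq, labels, genes)
    return stability_ungrouped(logq, genes)
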