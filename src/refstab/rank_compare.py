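"""Stability rankings and the pairwise ranking-comparison procedure.

A rank label is either an integer position or a tie set (e.g. the
two top genes a pairwise-correlation method cannot separate, printed
as ``1/2``). Comparing two rankings yields a per-gene rank-change
magnitude and a class: unchanged, minor (one position up or down) or
major (more than one position). Tie sets are measured to their
nearest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RankLabel",
    "StabilityRanking",
    "GeneComparison",
    "RankComparison",
    "compare",
    "summarize_pairs",
    "parse_rank_label",
    "format_rank_label",
]

RankLabel = int | frozenset[int]


def parse_rank_label(text: str | int | float) -> RankLabel:
    """Parse a printed rank label: ``'7'`` -> 7, ``'1/2'`` -> {1, 2}."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return int(text)
    text = str(text).strip()
    if "/" in text:
        return frozenset(int(p) for p in text.split("/"))
    return int(text)


def format_rank_label(label: RankLabel) -> str:
    if isinstance(label, frozenset):
        return "/".join(str(r) for r in sorted(label))
    return str(label)


@dataclass(frozen=True)
class StabilityRanking:
    """Per-gene rank labels from one stability method on one dataset.

    ``labels`` maps gene -> integer rank or tie set; integer ranks and
    tie-set members together must tile 1..G exactly once.
    """

    method: str
    labels: Mapping[str, RankLabel]
    efficiency_mode: str = "corrected"
    values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        labels = {str(g): lab for g, lab in self.labels.items()}
        positions: list[int] = []
        tie_holders: dict[frozenset[int], int] = {}
        for lab in labels.values():
            if isinstance(lab, frozenset):
                tie_holders[lab] = tie_holders.get(lab, 0) + 1
            else:
                positions.append(int(lab))
        for tie, holders in tie_holders.items():
            if holders != len(tie):
                raise ValueError(
                    f"tie set {sorted(tie)} held by {holders} genes, "
                    f"expected {len(tie)}"
                )
            positions.extend(tie)
        if sorted(positions) != list(range(1, len(labels) + 1)):
            raise ValueError(
                f"rank labels must tile 1..{len(labels)} exactly once, "
                f"got {sorted(positions)}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.labels)

    def __getitem__(self, gene: str) -> RankLabel:
        return self.labels[gene]

    def numeric(self) -> dict[str, float]:
        """Tie-aware numeric ranks (a tie set contributes its mean)."""
        return {
            g: (sum(lab) / len(lab) if isinstance(lab, frozenset) else float(lab))
            for g, lab in self.labels.items()
        }

    def ordered_genes(self) -> list[str]:
        return sorted(self.labels, key=lambda g: self.numeric()[g])

    def to_frame(self) -> pd.DataFrame:
        rows = {g: format_rank_label(lab) for g, lab in self.labels.items()}
        df = pd.DataFrame({"gene": list(rows), "rank": list(rows.values())})
        if self.values is not None:
            df["stability"] = [self.values.get(g) for g in rows]
        return df


@dataclass(frozen=True)
class GeneComparison:
    gene: str
    label_a: RankLabel
    label_b: RankLabel
    delta: int
    cls: str  # unchanged | minor | major


@dataclass(frozen=True)
class RankComparison:
    """Result of comparing two rankings over the same gene set."""

    per_gene: tuple[GeneComparison, ...]

    @property
    def n_total(self) -> int:
        return len(self.per_gene)

    @property
    def n_changed(self) -> int:
        return sum(1 for g in self.per_gene if g.cls != "unchanged")

    @property
    def n_minor(self) -> int:
        return sum(1 for g in self.per_gene if g.cls == "minor")

    @property
    def n_major(self) -> int:
        return sum(1 for g in self.per_gene if g.cls == "major")

    @property
    def pct_changed(self) -> float:
        return 100.0 * self.n_changed / self.n_total if self.n_total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g.gene for g in self.per_gene],
                "rank_a": [format_rank_label(g.label_a) for g in self.per_gene],
                "rank_b": [format_rank_label(g.label_b) for g in self.per_gene],
                "delta": [g.delta for g in self.per_gene],
                "class": [g.cls for g in self.per_gene],
            }
        )


def _delta(a: RankLabel, b: RankLabel) -> int:
    set_a = a if isinstance(a, frozenset) else frozenset([a])
    set_b = b if isinstance(b, frozenset) else frozenset([b])
    return min(abs(x - y) for x in set_a for y in set_b)


def compare(a: StabilityRanking, b: StabilityRanking) -> RankComparison:
    """Per-gene rank change between two rankings of the same genes.

    A gene counts as changed iff its printed label differs (a move from
    rank 9 into the ``1/2`` tie set is a change of magnitude
    min(|9-1|, |9-2|) = 7). Changed genes with a change of at most one
    position are minor, larger moves are major. Symmetric in (a, b).
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("rankings cover different gene sets")
    rows = []
    for gene in a.labels:
        la, lb = a.labels[gene], b.labels[gene]
        delta = _delta(la, lb)
        if la == lb:
            cls = "unchanged"
        elif delta <= 1:
            cls = "minor"
        else:
            cls = "major"
        rows.append(GeneComparison(gene, la, lb, delta, cls))
    return RankComparison(tuple(rows))


@dataclass(frozen=True)
class PairSummary:
    n_changed: int
    n_total: int
    n_minor: int
    n_major: int

    @property
    def pct_changed(self) -> float:
        return 100.0 * self.n_changed / self.n_total if self.n_total else 0.0

    @property
    def pct_display(self) -> int:
        """Percentage rounded to nearest integer for report display."""
        return round(self.pct_changed)


def summarize_pairs(comparisons: Iterable[RankComparison]) -> PairSummary:
    """Pool one or more ranking comparisons into a single summary row."""
    comparisons = list(comparisons)
    return PairSummary(
        n_changed=sum(c.n_changed for c in comparisons),
        n_total=sum(c.n_total for c in comparisons),
        n_minor=sum(c.n_minor for c in comparisons),
        n_major=sum(c.n_major for c in comparisons),
    )


def ranking_from_scores(
    method: str,
    scores: Mapping[str, float],
    efficiency_mode: str = "corrected",
    order: Sequence[str] | None = None,
) -> StabilityRanking:
    """Integer ranking by ascending score; ties broken by input order."""
    genes = list(order) if order is not None else list(scores)
    idx = {g: i for i, g in enumerate(genes)}
    ordered = sorted(genes, key=lambda g: (scores[g], idx[g]))
    labels = {g: ordered.index(g) + 1 for g in genes}
    return StabilityRanking(method, labels, efficiency_mode, dict(scores))
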