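"""Cq data model, file I/O and the relative-quantity transform.

Cq tables come in two text layouts:

* wide  -- first column ``gene``, remaining columns are sample IDs,
  cells are Cq values (already replicate-aggregated);
* long  -- columns ``sample, gene[, replicate], cq``, one row per
  technical replicate.

All downstream stability methods operate either on the raw Cq matrix
(BestKeeper, comparative dCt) or on log2 relative quantities derived
from it (geNorm, NormFinder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "EfficiencyTable",
    "RQMatrix",
    "QpcrDataError",
    "read_cq",
    "write_cq",
    "read_efficiency",
    "read_groups",
    "compute_rq",
    "log_rq",
]

CQ_MIN, CQ_MAX = 0.0, 45.0
EFF_MIN, EFF_MAX = 1.5, 2.2
EFF_WARN_LO, EFF_WARN_HI = 1.8, 2.1

EfficiencyMode = Literal["corrected", "E2"]


class QpcrDataError(ValueError):
    """Raised for malformed or incomplete qPCR input data."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass(frozen=True)
class CqMatrix:
    """Complete genes x samples matrix of quantification-cycle values.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers (rows).
    samples
        Ordered, unique sample identifiers (columns).
    values
        Float array of shape ``(len(genes), len(samples))``; every cell
        must be finite and inside ``(0, 45)`` cycles. Incomplete
        matrices are rejected, never imputed.
    groups
        Optional mapping sample -> group label covering every sample.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        samples = tuple(str(s) for s in self.samples)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "samples", samples)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise QpcrDataError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise QpcrDataError("duplicate gene identifiers")
        if len(set(samples)) != len(samples):
            raise QpcrDataError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            raise QpcrDataError("incomplete matrix: non-finite or missing Cq values")
        if np.any(values <= CQ_MIN) or np.any(values >= CQ_MAX):
            raise QpcrDataError(f"Cq values must lie in ({CQ_MIN}, {CQ_MAX}) cycles")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if self.groups is not None:
            groups = {str(k): str(v) for k, v in self.groups.items()}
            missing = set(samples) - set(groups)
            if missing:
                raise QpcrDataError(f"samples without group label: {sorted(missing)}")
            groups = {s: groups[s] for s in samples}
            object.__setattr__(self, "groups", groups)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_labels(self) -> np.ndarray | None:
        """Per-sample group labels aligned with ``samples``, or None."""
        if self.groups is None:
            return None
        return np.array([self.groups[s] for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    def subset_genes(self, genes: Sequence[str]) -> "CqMatrix":
        idx = [self.genes.index(g) for g in genes]
        return CqMatrix(tuple(genes), self.samples, self.values[idx], self.groups)


@dataclass(frozen=True)
class EfficiencyTable:
    """Per-gene amplification base E; E = 2 means 100% efficiency."""

    efficiencies: Mapping[str, float]

    def __post_init__(self) -> None:
        eff = {str(g): float(e) for g, e in self.efficiencies.items()}
        for gene, e in eff.items():
            if not (EFF_MIN <= e <= EFF_MAX):
                raise QpcrDataError(
                    f"efficiency E={e} for {gene} outside plausible range "
                    f"[{EFF_MIN}, {EFF_MAX}]"
                )
            if not (EFF_WARN_LO <= e <= EFF_WARN_HI):
                warnings.warn(
                    f"efficiency E={e} for {gene} outside usual range "
                    f"[{EFF_WARN_LO}, {EFF_WARN_HI}]",
                    stacklevel=2,
                )
        object.__setattr__(self, "efficiencies", eff)

    def __getitem__(self, gene: str) -> float:
        return self.efficiencies[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.efficiencies

    @classmethod
    def uniform(cls, genes: Sequence[str], e: float = 2.0) -> "EfficiencyTable":
        return cls({g: e for g in genes})

    @classmethod
    def from_percent(cls, percents: Mapping[str, float]) -> "EfficiencyTable":
        """Build from percent efficiencies (100 -> E = 2)."""
        return cls({g: 1.0 + p / 100.0 for g, p in percents.items()})

    def vector(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self.efficiencies]
        if missing:
            raise QpcrDataError(f"genes absent from efficiency table: {missing}")
        return np.array([self.efficiencies[g] for g in genes], dtype=float)


@dataclass(frozen=True)
class RQMatrix:
    """Per-gene relative quantities; the min-Cq sample of each gene is 1."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    efficiency_mode: EfficiencyMode = "corrected"
    groups: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "samples", tuple(self.samples))
        values = np.asarray(self.values, dtype=float)
        if np.any(values <= 0):
            raise QpcrDataError("relative quantities must be strictly positive")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))


def read_cq(
    path: str | Path,
    layout: Literal["wide", "long"] = "wide",
    replicate_policy: Literal["mean", "median"] = "mean",
    max_spread: float | None = None,
    groups: Mapping[str, str] | None = None,
) -> CqMatrix:
    """Read a Cq table from CSV/TSV.

    ``replicate_policy`` controls how technical replicates in the long
    layout are aggregated (arithmetic mean by default). ``max_spread``,
    if given, emits a warning for any (gene, sample) whose replicate
    range exceeds that many cycles.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, dtype={0: str})
        df = df.rename(columns={df.columns[0]: "gene"})
        genes = df["gene"].tolist()
        samples = [str(c) for c in df.columns[1:]]
        body = df.iloc[:, 1:]
        numeric = body.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().to_numpy().any() and not body.isna().to_numpy().any():
            raise QpcrDataError("non-numeric Cq value in wide table")
        return CqMatrix(tuple(genes), tuple(samples), numeric.to_numpy(float), groups)

    if layout != "long":
        raise QpcrDataError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample", "gene", "cq"}
    if not required.issubset(df.columns):
        raise QpcrDataError(f"long layout needs columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    df["cq"] = pd.to_numeric(df["cq"], errors="raise")
    dup = df.duplicated(subset=["sample", "gene", "replicate"])
    if dup.any():
        bad = df.loc[dup, ["sample", "gene", "replicate"]].iloc[0].tolist()
        raise QpcrDataError(f"duplicate (sample, gene, replicate) triple: {bad}")
    df["sample"] = df["sample"].astype(str)
    df["gene"] = df["gene"].astype(str)
    genes = list(dict.fromkeys(df["gene"]))
    samples = list(dict.fromkeys(df["sample"]))
    agg = getattr(df.groupby(["gene", "sample"], sort=False)["cq"], replicate_policy)()
    if max_spread is not None:
        spread = df.groupby(["gene", "sample"], sort=False)["cq"].agg(lambda s: s.max() - s.min())
        for (g, s), rng in spread[spread > max_spread].items():
            warnings.warn(
                f"replicate spread {rng:.2f} cycles for ({g}, {s}) exceeds "
                f"{max_spread} cycles",
                stacklevel=2,
            )
    wide = agg.unstack("sample")
    missing = wide.isna()
    if missing.to_numpy().any():
        g = missing.index[missing.any(axis=1)][0]
        s = missing.columns[missing.loc[g]][0]
        raise QpcrDataError(f"incomplete matrix: missing Cq for ({g}, {s})")
    wide = wide.loc[genes, samples]
    return CqMatrix(tuple(genes), tuple(samples), wide.to_numpy(float), groups)


def write_cq(cq: CqMatrix, path: str | Path) -> None:
    """Write a CqMatrix in wide layout (round-trips with ``read_cq``)."""
    path = Path(path)
    df = cq.to_frame().reset_index(names="gene")
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.6f")


def read_efficiency(
    path: str | Path, unit: Literal["base", "percent"] = "base"
) -> EfficiencyTable:
    """Read a ``gene,efficiency`` table; values may be bases or percents."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "efficiency"}.issubset(df.columns):
        raise QpcrDataError("efficiency table needs columns gene, efficiency")
    values = {str(g): float(e) for g, e in zip(df["gene"], df["efficiency"])}
    if unit == "percent":
        return EfficiencyTable.from_percent(values)
    return EfficiencyTable(values)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a ``sample,group`` table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"sample", "group"}.issubset(df.columns):
        raise QpcrDataError("groups table needs columns sample, group")
    return {str(s): str(g) for s, g in zip(df["sample"], df["group"])}


def compute_rq(
    cq: CqMatrix,
    eff: EfficiencyTable | None = None,
    efficiency_mode: EfficiencyMode = "corrected",
) -> RQMatrix:
    """Relative quantities RQ(i,j) = E_i ** (minCq_i - Cq_ij).

    Each gene is referenced to its own lowest-Cq sample, which gets
    RQ = 1; all other samples fall in (0, 1]. In ``E2`` mode the
    efficiency table is ignored and every E_i is 2 (perfect doubling).
    """
    if efficiency_mode == "E2":
        e = np.full(cq.n_genes, 2.0)
    elif efficiency_mode == "corrected":
        if eff is None:
            raise QpcrDataError("corrected mode requires an efficiency table")
        e = eff.vector(cq.genes)
    else:
        raise QpcrDataError(f"unknown efficiency_mode {efficiency_mode!r}")
    min_cq = cq.values.min(axis=1, keepdims=True)
    rq = e[:, None] ** (min_cq - cq.values)
    return RQMatrix(cq.genes, cq.samples, rq, efficiency_mode, cq.groups)


def log_rq(rq: RQMatrix) -> np.ndarray:
    """Elementwise log2 of relative quantities.

    In E2 mode this equals ``minCq_i - Cq_ij`` exactly (base-2 identity).
    """
    return np.log2(rq.values)
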