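"""Synthetic Cq data with known ground-truth stability structure.

Latent model, on the log2 scale: sample j of group g has a shared
loading factor L_j ~ N(0, tau^2); gene i adds a designed group shift
delta_ig and noise eps_ij ~ N(0, sigma_i^2), giving latent abundance
q_ij = L_j + delta_ig + eps_ij. The observed quantification cycle is

    Cq_ij = b_i - q_ij * ln(2) / ln(E_i)

so that with a perfect-doubling assay (E_i = 2) one latent log2 unit
is exactly one cycle. Technical replicates add Gaussian cycle noise
around Cq_ij.

Two presets emulate a 14-gene validation study: ``fs1`` (three culture
conditions of sizes 4/4/3 with some genes shifted between conditions)
and ``cis`` (six ungrouped tissue samples). Both include four assays
whose efficiency deviates from 100% by well over ten percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .qpcr_data import CqMatrix, EfficiencyTable

__all__ = ["SimulationConfig", "SimulationResult", "simulate", "preset", "write_dataset"]

GENE_PANEL = (
    "ACTB", "B2M", "GAPDH", "HMBS", "HPRT1", "IGF1R", "RLP13",
    "RPS18", "SDHA", "SOX9", "TBP", "TOP2B", "UBC", "YWHAZ",
)
# assays with efficiency off by >10% from 100% (E outside [1.8, 2.2])
LOW_EFFICIENCY = {"RPS18": 1.65, "TBP": 1.70, "UBC": 1.75, "YWHAZ": 1.79}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic dataset."""

    genes: tuple[str, ...]
    baseline_cq: tuple[float, ...]  # b_i, cycles
    noise_sd: tuple[float, ...]  # sigma_i, log2 units
    loading_sd: float  # tau, log2 units
    group_sizes: tuple[int, ...]
    group_names: tuple[str, ...]
    group_shifts: tuple[tuple[float, ...], ...]  # delta[i][g], log2 units
    efficiencies: tuple[float, ...]
    n_replicates: int = 3
    replicate_sd: float = 0.1  # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.genes)
        k = len(self.group_sizes)
        if not (
            len(self.baseline_cq) == len(self.noise_sd)
            == len(self.efficiencies) == g
        ):
            raise ValueError("per-gene parameter lengths disagree")
        if len(self.group_names) != k or len(self.group_shifts) != g:
            raise ValueError("group parameter lengths disagree")
        if any(len(row) != k for row in self.group_shifts):
            raise ValueError("group_shifts must be genes x groups")
        if any(s < 0 for s in self.noise_sd) or self.loading_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("every group needs at least one sample")
        if any(not (1.5 <= e <= 2.2) for e in self.efficiencies):
            raise ValueError("efficiencies must lie in [1.5, 2.2]")
        if self.n_replicates < 1 or self.replicate_sd < 0:
            raise ValueError("invalid replicate settings")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)

    @property
    def grouped(self) -> bool:
        return len(self.group_sizes) > 1

    def scaled_groups(self, n_per_group: int) -> "SimulationConfig":
        """Same design with every group resized to ``n_per_group`` samples."""
        return SimulationConfig(
            genes=self.genes,
            baseline_cq=self.baseline_cq,
            noise_sd=self.noise_sd,
            loading_sd=self.loading_sd,
            group_sizes=tuple(n_per_group for _ in self.group_sizes),
            group_names=self.group_names,
            group_shifts=self.group_shifts,
            efficiencies=self.efficiencies,
            n_replicates=self.n_replicates,
            replicate_sd=self.replicate_sd,
            seed=self.seed,
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        cfg = asdict(self)
        cfg["seed"] = seed
        cfg["group_shifts"] = tuple(tuple(r) for r in self.group_shifts)
        return SimulationConfig(**cfg)

    def with_uniform_efficiency(self, e: float = 2.0) -> "SimulationConfig":
        cfg = asdict(self)
        cfg["efficiencies"] = tuple(e for _ in self.genes)
        cfg["group_shifts"] = tuple(tuple(r) for r in self.group_shifts)
        return SimulationConfig(**cfg)


@dataclass(frozen=True)
class SimulationResult:
    cq: CqMatrix  # replicate-aggregated matrix
    efficiency: EfficiencyTable
    groups: dict[str, str]
    config: SimulationConfig
    truth: dict = field(repr=False, default_factory=dict)
    replicates: np.ndarray | None = field(repr=False, default=None)  # gene x sample x rep


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw one dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_samples
    group_of = np.repeat(np.arange(len(config.group_sizes)), config.group_sizes)
    samples = tuple(
        f"{config.group_names[group_of[j]]}_{j + 1}" for j in range(n)
    )
    loading = rng.normal(0.0, config.loading_sd, size=n)
    noise = rng.normal(0.0, 1.0, size=(g, n)) * np.asarray(config.noise_sd)[:, None]
    shifts = np.asarray(config.group_shifts)[:, group_of]
    q = loading[None, :] + shifts + noise

    e = np.asarray(config.efficiencies)
    cycles_per_log2 = np.log(2.0) / np.log(e)
    cq_true = np.asarray(config.baseline_cq)[:, None] - q * cycles_per_log2[:, None]

    reps = cq_true[:, :, None] + rng.normal(
        0.0, config.replicate_sd, size=(g, n, config.n_replicates)
    )
    cq_mean = reps.mean(axis=2) if config.replicate_sd > 0 else cq_true

    groups = {s: config.group_names[group_of[j]] for j, s in enumerate(samples)}
    cq = CqMatrix(config.genes, samples, cq_mean, groups if config.grouped else None)
    eff = EfficiencyTable(dict(zip(config.genes, e)))
    truth = {
        "loading": loading.tolist(),
        "latent_log2": q.tolist(),
        "cq_true": cq_true.tolist(),
        "noise_sd": list(config.noise_sd),
        "group_shifts": [list(r) for r in config.group_shifts],
        "seed": config.seed,
    }
    return SimulationResult(cq, eff, groups, config, truth, reps)


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named study-like designs: ``fs1`` (grouped 4/4/3) or ``cis`` (6 samples)."""
    g = len(GENE_PANEL)
    # fixed per-preset stream so the design (not the data) is a constant
    rng = np.random.default_rng(sum(ord(c) for c in name) * 7919)
    baseline = tuple(float(x) for x in np.round(np.linspace(19.0, 30.0, g), 1))
    # designed stability structure: three clearly stable genes, a gap,
    # a mid-range gradient, and one clearly unstable gene
    noise = (0.08, 0.1, 0.12) + tuple(
        float(x) for x in np.round(np.linspace(0.5, 0.8, g - 4), 3)
    ) + (1.2,)
    eff = tuple(
        LOW_EFFICIENCY.get(gene, float(np.round(1.85 + 0.2 * rng.random(), 3)))
        for gene in GENE_PANEL
    )
    if name == "fs1":
        groups = ("mono", "tcam", "msc")
        sizes = (4, 4, 3)
        # condition-responsive ("unstable by design") genes: shifts are
        # balanced across the panel so the per-sample gene mean stays put
        designed_shifts = {
            g - 3: (0.0, 0.3, -0.3),
            g - 2: (0.0, -0.3, 0.3),
            g - 1: (0.0, 0.9, -0.9),
        }
        shifts = [
            designed_shifts.get(i, (0.0, 0.0, 0.0))
            for i in range(len(GENE_PANEL))
        ]
        return SimulationConfig(
            genes=GENE_PANEL,
            baseline_cq=baseline,
            noise_sd=noise,
            loading_sd=0.35,
            group_sizes=sizes,
            group_names=groups,
            group_shifts=tuple(shifts),
            efficiencies=eff,
            seed=seed,
        )
    if name == "cis":
        return SimulationConfig(
            genes=GENE_PANEL,
            baseline_cq=baseline,
            noise_sd=noise,
            loading_sd=0.5,
            group_sizes=(6,),
            group_names=("cis",),
            group_shifts=tuple((0.0,) for _ in GENE_PANEL),
            efficiencies=eff,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose 'fs1' or 'cis'")


def write_dataset(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write cq.csv (long, with replicates), efficiency.csv, groups.csv,
    truth.json and config.yaml into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cq_path = out / "cq.csv"
    with cq_path.open("w") as fh:
        fh.write("sample,gene,replicate,cq\n")
        reps = result.replicates
        for i, gene in enumerate(result.cq.genes):
            for j, sample in enumerate(result.cq.samples):
                if reps is None:
                    fh.write(f"{sample},{gene},1,{result.cq.values[i, j]:.6f}\n")
                else:
                    for r in range(reps.shape[2]):
                        fh.write(f"{sample},{gene},{r + 1},{reps[i, j, r]:.6f}\n")
    paths["cq"] = cq_path

    eff_path = out / "efficiency.csv"
    with eff_path.open("w") as fh:
        fh.write("gene,efficiency\n")
        for gene in result.cq.genes:
            fh.write(f"{gene},{result.efficiency[gene]:.4f}\n")
    paths["efficiency"] = eff_path

    if result.config.grouped:
        grp_path = out / "groups.csv"
        with grp_path.open("w") as fh:
            fh.write("sample,group\n")
            for sample in result.cq.samples:
                fh.write(f"{sample},{result.groups[sample]}\n")
        paths["groups"] = grp_path

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(result.truth, indent=1))
    paths["truth"] = truth_path

    cfg = asdict(result.config)
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths["config"] = cfg_path
    return paths
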