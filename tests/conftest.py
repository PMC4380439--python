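from __future__ import annotations

import numpy as np
import pytest

from refstab.qpcr_data import CqMatrix, EfficiencyTable


def random_cq(
    rng: np.random.Generator,
    n_genes: int = 5,
    n_samples: int = 6,
    groups: dict[str, str] | None = None,
) -> CqMatrix:
    """Random complete Cq matrix in a realistic cycle range."""
    base = rng.uniform(20.0, 30.0, size=(n_genes, 1))
    values = base + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    values = np.clip(values, 10.0, 40.0)
    genes = tuple(f"g{i+1}" for i in range(n_genes))
    samples = tuple(f"s{j+1}" for j in range(n_samples))
    return CqMatrix(genes, samples, values, groups)


def random_efficiency(rng: np.random.Generator, genes) -> EfficiencyTable:
    return EfficiencyTable({g: float(rng.uniform(1.8, 2.1)) for g in genes})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cq(rng) -> CqMatrix:
    return random_cq(rng, 4, 5)
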