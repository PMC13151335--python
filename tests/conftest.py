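"""Shared fixtures: tiny deterministic cohorts built in memory."""

import numpy as np
import pandas as pd
import pytest

from stratgen.datamodel import GeneAnnotation, GenotypeMatrix
from stratgen.synthetic import AncestralModel, simulate_genotypes


def make_genotypes(n=20, m=10, seed=0, maf_range=(0.1, 0.5), sex=None,
                   chrom="1", pos_start=1000, pos_step=1000):
    """Small dense genotype matrix with non-palindromic SNPs."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    variants = pd.DataFrame({
        "id": [f"rs{j}" for j in range(m)],
        "chrom": chrom,
        "pos": pos_start + pos_step * np.arange(m),
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    if sex is None:
        sex = np.where(rng.random(n) < 0.5, "female", "male")
    return GenotypeMatrix([f"I{i}" for i in range(n)], variants, dosages, sex=sex)


@pytest.fixture
def small_genotypes():
    return make_genotypes()


@pytest.fixture
def two_pops():
    """Balding-Nichols pair of 200-individual populations, F = 0.1."""
    model = AncestralModel.draw(1000, F=0.1, seed=11)
    g, _ = simulate_genotypes((200, 200), model, seed=12)
    lab = np.asarray(g.population_label)
    return (g.select_individuals(lab == "pop1"),
            g.select_individuals(lab == "pop2"))


@pytest.fixture
def gene_annotation():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["G1", "G2", "G3"],
        "chrom": ["1", "1", "2"],
        "start": [1_000_000, 4_000_000, 1_000_000],
        "end": [1_020_000, 4_050_000, 1_010_000],
        "length": [2_000, 5_000, 1_500],
    }))
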