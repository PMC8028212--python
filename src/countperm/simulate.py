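"""Synthetic genotype/phenotype generator under Hardy-Weinberg equilibrium.

SNP columns are drawn i.i.d. from the trinomial genotype distribution
implied by a minor allele frequency ``p`` under perfect Hardy-Weinberg
equilibrium, with category probabilities

    P(0) = p^2,   P(1) = 2 p (1 - p),   P(2) = (1 - p)^2,

and the binary phenotype is Bernoulli with P(0) = q. SNPs and phenotype
are mutually independent, so every generated tuple is null: there is no
genotype-phenotype association to detect. This is exactly the regime a
permutation null should reproduce, which makes the generator the
workhorse for validating the fast table transform.

All stochastic functions take an explicit ``numpy.random.Generator``;
there is no module-level RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import CountTable, GenotypeMatrix, build_count_table

__all__ = [
    "SimulationConfig",
    "generate_snp",
    "generate_phenotype",
    "generate_genotype_matrix",
    "generate_tuple_count_table",
]

#: Default minor allele frequency of the reference synthetic dataset.
DEFAULT_MAF = 0.45
#: Default probability of a phenotype label equal to 0.
DEFAULT_ZERO_PROB = 0.66


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly between 0 and 1, got {value}")
    return value


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the null synthetic dataset.

    Attributes
    ----------
    n_individuals : cohort size n.
    n_snps : number of independent SNP columns m.
    maf : minor allele frequency p in (0, 1).
    phenotype_zero_prob : probability q that a phenotype label is 0.
    seed : seed for the generator stream.
    """

    n_individuals: int = 10_000
    n_snps: int = 2
    maf: float = DEFAULT_MAF
    phenotype_zero_prob: float = DEFAULT_ZERO_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        _check_fraction(self.maf, "maf")
        _check_fraction(self.phenotype_zero_prob, "phenotype_zero_prob")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def genotype_probabilities(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype category probabilities (P0, P1, P2) for a MAF."""
    p = _check_fraction(maf, "maf")
    return np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])


def generate_snp(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one SNP column of ``n`` i.i.d. Hardy-Weinberg genotypes."""
    if n < 1:
        raise ValueError("n must be at least 1")
    probs = genotype_probabilities(maf)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def generate_phenotype(n: int, zero_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a binary phenotype vector with P(0) = ``zero_prob``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    q = _check_fraction(zero_prob, "zero_prob")
    return (rng.random(n) >= q).astype(np.int8)


def generate_genotype_matrix(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Generate an n x m matrix of mutually independent SNP columns."""
    cols = [
        generate_snp(config.n_individuals, config.maf, rng)
        for _ in range(config.n_snps)
    ]
    return GenotypeMatrix(np.column_stack(cols))


def generate_tuple_count_table(
    config: SimulationConfig, rng: np.random.Generator
) -> CountTable:
    """Generate one null SNP-SNP-phenotype tuple and tally it into a count table."""
    snp1 = generate_snp(config.n_individuals, config.maf, rng)
    snp2 = generate_snp(config.n_individuals, config.maf, rng)
    phenotype = generate_phenotype(
        config.n_individuals, config.phenotype_zero_prob, rng
    )
    return build_count_table(snp1, snp2, phenotype)
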