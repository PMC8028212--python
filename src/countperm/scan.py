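"""Empirical significance of SNP-pair interaction measures via transform nulls.

For each SNP pair the count table is built once from the data; the null
distribution of the chosen measure is then sampled by transforming that
table ``n_perm`` times, never touching the n x m genotype matrix again.
The empirical p-value uses the add-one convention

    p = (1 + #{null >= observed}) / (1 + n_perm),

one-sided in the upper tail (all shipped measures are non-negative
dependence scores), with ties counted as exceedances; it can never be 0
and never falls below 1 / (n_perm + 1).

Each pair gets its own RNG substream spawned from (seed, snp1 index,
snp2 index), so scan results are reproducible and independent of the
order in which pairs are processed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import MeasureValue, apply_measure
from .permute import sample_ensemble
from .tables import CountTable, GenotypeMatrix, build_count_table

__all__ = [
    "NullDistribution",
    "ScanRecord",
    "null_distribution",
    "empirical_pvalue",
    "scan_pairs",
]


@dataclass(frozen=True)
class NullDistribution:
    """Measure values evaluated on an ensemble of permuted count tables."""

    values: np.ndarray
    measure_name: str

    def __post_init__(self) -> None:
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if values.size == 0:
            raise ValueError("null distribution must be non-empty")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ScanRecord:
    """Result for one SNP pair: observed measure and its permutation p-value."""

    snp1_id: str
    snp2_id: str
    observed: MeasureValue
    n_perm: int
    p_empirical: float
    seed: int


def null_distribution(
    table: CountTable, measure: str, n_perm: int, rng: np.random.Generator
) -> NullDistribution:
    """Sample the permutation null of ``measure`` for one count table."""
    ensemble = sample_ensemble(table, n_perm, rng)
    values = apply_measure(ensemble.counts, measure).value
    return NullDistribution(values=values, measure_name=measure)


def empirical_pvalue(observed: MeasureValue | float, null: NullDistribution) -> float:
    """Add-one upper-tail permutation p-value; ties count as exceedances."""
    obs = observed.value if isinstance(observed, MeasureValue) else observed
    exceed = int(np.count_nonzero(null.values >= float(obs)))
    return (1 + exceed) / (1 + len(null))


def _pair_rng(seed: int, a: int, b: int) -> np.random.Generator:
    # substream keyed by the pair itself -> order-independent reproducibility
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(a, b)))


def scan_pairs(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray,
    pairs: list[tuple[int, int]],
    measure: str = "multi_information",
    n_perm: int = 999,
    seed: int = 0,
) -> list[ScanRecord]:
    """Scan a list of SNP index pairs and assign empirical p-values.

    The genotype matrix is consulted once per pair (to build the count
    table); the ``n_perm`` null samples are pure table transforms.
    """
    if isinstance(genotypes, GenotypeMatrix):
        values, snp_ids = genotypes.values, genotypes.snp_ids
    else:
        values = np.asarray(genotypes)
        snp_ids = [f"snp{i}" for i in range(values.shape[1])]
    m = values.shape[1]
    records: list[ScanRecord] = []
    for a, b in pairs:
        if not (0 <= a < m and 0 <= b < m):
            raise IndexError(f"pair ({a}, {b}) out of range for {m} SNPs")
        table = build_count_table(values[:, a], values[:, b], phenotype)
        rng = _pair_rng(seed, a, b)
        null = null_distribution(table, measure, n_perm, rng)
        observed = apply_measure(table, measure)
        records.append(
            ScanRecord(
                snp1_id=snp_ids[a],
                snp2_id=snp_ids[b],
                observed=observed,
                n_perm=n_perm,
                p_empirical=empirical_pvalue(observed, null),
                seed=seed,
            )
        )
    return records
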