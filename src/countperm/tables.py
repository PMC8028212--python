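"""Genotype-pair / phenotype count tables and their permutation-invariant margins.

The central data structure of the package is the 3x3x2 count table ``C``
with entries ``c[i, j, k]``: the number of individuals whose first SNP has
genotype ``i``, second SNP genotype ``j`` (0 = homozygous major,
1 = heterozygous, 2 = homozygous minor) and binary phenotype ``k``.
Dividing by the total gives the plug-in joint probability estimate from
which every entropy-based interaction measure is computed.

Under a permutation test only the phenotype labels are shuffled, so the
genotype cell counts ``n_ij = c_ij0 + c_ij1``, the phenotype-0 total
``n_0`` and the cohort size ``n`` are invariant; they are the sufficient
statistics that drive the fast table transform in :mod:`countperm.permute`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "CountTable",
    "GenotypeMargins",
    "GenotypeMatrix",
    "build_count_table",
    "compute_margins",
    "expand_table",
]

#: Internal missing-data code for genotype and phenotype arrays.
MISSING = -1

N_GENOTYPES = 3
N_PHENOTYPES = 2


@dataclass(frozen=True)
class CountTable:
    """A 3x3x2 integer array of individual counts, indexed (snp1, snp2, phenotype)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_GENOTYPES, N_GENOTYPES, N_PHENOTYPES):
            raise ValueError(
                f"count table must have shape (3, 3, 2), got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("count table entries must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        """Total number of individuals tallied (sum of all 18 cells)."""
        return int(self.counts.sum())

    @classmethod
    def from_layers(cls, layer0, layer1) -> "CountTable":
        """Build from two 3x3 layers (phenotype 0 and phenotype 1)."""
        return cls(np.stack([np.asarray(layer0), np.asarray(layer1)], axis=-1))

    def layer(self, k: int) -> np.ndarray:
        """The 3x3 slice of counts with phenotype value ``k``."""
        return self.counts[:, :, k]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))

    def __hash__(self):
        return hash(self.counts.tobytes())


@dataclass(frozen=True)
class GenotypeMargins:
    """The permutation-invariant margins of a count table.

    Attributes
    ----------
    n_ij : (3, 3) array of genotype cell counts, invariant under any
        shuffle of the phenotype labels.
    n0 : number of individuals with phenotype 0.
    n : total number of individuals.
    """

    n_ij: np.ndarray
    n0: int
    n: int

    def __post_init__(self) -> None:
        n_ij = np.asarray(self.n_ij, dtype=np.int64)
        if n_ij.shape != (N_GENOTYPES, N_GENOTYPES):
            raise ValueError("n_ij must be a 3x3 array")
        if (n_ij < 0).any():
            raise ValueError("genotype counts must be non-negative")
        if int(n_ij.sum()) != self.n:
            raise ValueError("sum of n_ij must equal n")
        if not 0 <= self.n0 <= self.n:
            raise ValueError("n0 must lie in [0, n]")
        n_ij.setflags(write=False)
        object.__setattr__(self, "n_ij", n_ij)


@dataclass
class GenotypeMatrix:
    """An n-individuals x m-SNPs additive-coded genotype matrix.

    Entries are 0/1/2 (copies of the minor allele mapped to homozygous
    major / heterozygous / homozygous minor) with :data:`MISSING` for
    missing calls.
    """

    values: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("genotype matrix must be two-dimensional")
        bad = ~np.isin(values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        self.values = values.astype(np.int8)
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(values.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(values.shape[0])]
        if len(self.snp_ids) != values.shape[1]:
            raise ValueError("snp_ids length must match number of columns")
        if len(self.sample_ids) != values.shape[0]:
            raise ValueError("sample_ids length must match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def _validated_column(values, name: str, n_levels: int) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    valid = set(range(n_levels)) | {MISSING}
    bad = ~np.isin(arr, sorted(valid))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{name}[{idx}] = {arr[idx]} is outside the allowed values "
            f"{sorted(range(n_levels))} (or {MISSING} for missing)"
        )
    return arr.astype(np.int64)


def build_count_table(snp1, snp2, phenotype) -> CountTable:
    """Tally two genotype columns and a binary phenotype into a 3x3x2 table.

    Individuals with a missing value in any of the three variables are
    dropped (complete-case per tuple), so the table total equals the number
    of complete individuals.
    """
    s1 = _validated_column(snp1, "snp1", N_GENOTYPES)
    s2 = _validated_column(snp2, "snp2", N_GENOTYPES)
    ph = _validated_column(phenotype, "phenotype", N_PHENOTYPES)
    if not (len(s1) == len(s2) == len(ph)):
        raise ValueError(
            f"length mismatch: snp1 has {len(s1)}, snp2 has {len(s2)}, "
            f"phenotype has {len(ph)} entries"
        )
    complete = (s1 != MISSING) & (s2 != MISSING) & (ph != MISSING)
    s1, s2, ph = s1[complete], s2[complete], ph[complete]
    flat = (s1 * N_GENOTYPES + s2) * N_PHENOTYPES + ph
    counts = np.bincount(flat, minlength=N_GENOTYPES * N_GENOTYPES * N_PHENOTYPES)
    return CountTable(counts.reshape(N_GENOTYPES, N_GENOTYPES, N_PHENOTYPES))


def compute_margins(table: CountTable) -> GenotypeMargins:
    """Extract the permutation-invariant margins (n_ij, n_0, n) of a table."""
    n_ij = table.counts.sum(axis=2)
    n0 = int(table.counts[:, :, 0].sum())
    return GenotypeMargins(n_ij=n_ij, n0=n0, n=int(n_ij.sum()))


def expand_table(table: CountTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruct per-individual columns (snp1, snp2, phenotype) from a table.

    The expansion lists each (i, j, k) combination ``c_ijk`` times, in a
    fixed deterministic order. Since every statistic in this package is a
    function of the count table alone, any dataset with these tallies is
    equivalent; the expansion lets label-permutation methods run when only
    the table is available.
    """
    idx = np.repeat(
        np.arange(N_GENOTYPES * N_GENOTYPES * N_PHENOTYPES), table.counts.ravel()
    )
    k = idx % N_PHENOTYPES
    ij = idx // N_PHENOTYPES
    return ij // N_GENOTYPES, ij % N_GENOTYPES, k
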