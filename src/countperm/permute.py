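"""Permutation of count tables: the fast hypergeometric transform and its oracle.

A permutation test shuffles phenotype labels while leaving genotypes
fixed. For any statistic that depends on the data only through the 3x3x2
count table, the shuffled table can be sampled directly: assigning the
``n_0`` zero-labels to genotype cells is drawing without replacement, so
the phenotype-0 count of the first cell in an arbitrary cell order is

    c*_000 ~ Hypergeometric(n, n_0, n_00),

and each later cell draws from the population and zero-labels left over
after the cells before it,

    c*_ij0 ~ Hypergeometric(n - sum n_i'j',  n_0 - sum c*_i'j'0,  n_ij),

with the phenotype-1 layer forced by c*_ij1 = n_ij - c*_ij0. One
transform therefore costs at most nine hypergeometric draws regardless of
the cohort size n, whereas naive label permutation re-tallies all n
individuals. The draws are *not* independent across cells — the running
depletion of zero-labels is what enforces the conservation law
``sum_ij c*_ij0 = n_0`` — so the iteration order matters for the
construction but not for the resulting distribution.

:func:`naive_permute` implements the label-shuffling reference method;
the two must agree in distribution, which the :mod:`countperm.equivalence`
module verifies statistically and the test suite verifies exactly on
small tables by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import (
    CountTable,
    GenotypeMargins,
    build_count_table,
    compute_margins,
)

__all__ = [
    "DEFAULT_CELL_ORDER",
    "PermutedEnsemble",
    "sample_hypergeometric",
    "transform_count_table",
    "naive_permute",
    "naive_ensemble",
    "sample_ensemble",
]

#: Default assignment order for the nine genotype cells: column-major,
#: (0,0) < (1,0) < (2,0) < (0,1) < ... < (2,2). Any order that visits each
#: cell once yields the same distribution of transformed tables.
DEFAULT_CELL_ORDER: tuple[tuple[int, int], ...] = tuple(
    (i, j) for j in range(3) for i in range(3)
)

CellOrder = tuple[tuple[int, int], ...]


def _validate_order(order: CellOrder) -> CellOrder:
    cells = [tuple(c) for c in order]
    if sorted(cells) != sorted((i, j) for i in range(3) for j in range(3)):
        raise ValueError(
            "cell order must contain each of the nine (i, j) pairs exactly once"
        )
    return tuple(cells)  # type: ignore[return-value]


@dataclass(frozen=True)
class PermutedEnsemble:
    """A batch of permuted count tables sharing one set of source margins.

    ``counts`` has shape (n_tables, 3, 3, 2); every member satisfies the
    conservation laws ``c*_ij0 + c*_ij1 = n_ij`` and ``sum c*_ij0 = n_0``
    of the source margins.
    """

    counts: np.ndarray
    source_margins: GenotypeMargins
    method_tag: str  # "transform" or "naive"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 4 or counts.shape[1:] != (3, 3, 2):
            raise ValueError("ensemble counts must have shape (n_tables, 3, 3, 2)")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __getitem__(self, index: int) -> CountTable:
        return CountTable(self.counts[index])

    def layer0(self) -> np.ndarray:
        """Phenotype-0 cell counts, shape (n_tables, 3, 3)."""
        return self.counts[:, :, :, 0]


def sample_hypergeometric(
    population: int, successes: int, draws: int, rng: np.random.Generator
) -> int:
    """Number of successes when ``draws`` items are taken without replacement
    from ``population`` items of which ``successes`` are successes.

    This wrapper pins the (population, successes, draws) parameterization
    so library argument-convention differences cannot leak into the
    transform algorithm. Preconditions are enforced, never clamped.
    """
    if not 0 <= successes <= population:
        raise ValueError(
            f"successes must lie in [0, population]; got {successes} of {population}"
        )
    if not 0 <= draws <= population:
        raise ValueError(
            f"draws must lie in [0, population]; got {draws} of {population}"
        )
    if draws == 0:
        return 0
    # numpy parameterization: (ngood, nbad, nsample)
    return int(rng.hypergeometric(successes, population - successes, draws))


def transform_count_table(
    table: CountTable,
    rng: np.random.Generator,
    order: CellOrder = DEFAULT_CELL_ORDER,
) -> CountTable:
    """Sample one permuted count table directly from the table's margins.

    Equivalent in distribution to shuffling phenotype labels and
    re-tallying, at a cost of at most nine hypergeometric draws.
    """
    order = _validate_order(order)
    margins = compute_margins(table)
    remaining_pop = margins.n
    remaining_zeros = margins.n0
    layer0 = np.zeros((3, 3), dtype=np.int64)
    for i, j in order:
        n_ij = int(margins.n_ij[i, j])
        drawn = sample_hypergeometric(remaining_pop, remaining_zeros, n_ij, rng)
        layer0[i, j] = drawn
        remaining_pop -= n_ij
        remaining_zeros -= drawn
    return CountTable.from_layers(layer0, margins.n_ij - layer0)


def naive_permute(
    snp1, snp2, phenotype, rng: np.random.Generator
) -> CountTable:
    """Reference method: shuffle the phenotype labels, then re-tally the table."""
    phenotype = np.asarray(phenotype)
    return build_count_table(snp1, snp2, rng.permutation(phenotype))


def naive_ensemble(
    snp1, snp2, phenotype, n_perm: int, rng: np.random.Generator
) -> PermutedEnsemble:
    """Batch of ``n_perm`` naive label-permutation tables from raw columns."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    base = build_count_table(snp1, snp2, phenotype)
    margins = compute_margins(base)
    s1 = np.asarray(snp1, dtype=np.int64)
    s2 = np.asarray(snp2, dtype=np.int64)
    ph = np.asarray(phenotype, dtype=np.int64).copy()
    flat = s1 * 3 + s2
    counts = np.empty((n_perm, 3, 3, 2), dtype=np.int64)
    for t in range(n_perm):
        rng.shuffle(ph)
        layer0 = np.bincount(flat[ph == 0], minlength=9).reshape(3, 3)
        counts[t, :, :, 0] = layer0
        counts[t, :, :, 1] = margins.n_ij - layer0
    return PermutedEnsemble(counts, margins, method_tag="naive")


def sample_ensemble(
    table: CountTable,
    n_perm: int,
    rng: np.random.Generator,
    order: CellOrder = DEFAULT_CELL_ORDER,
) -> PermutedEnsemble:
    """Sample ``n_perm`` independent transformed tables.

    Vectorized across the ensemble: the nine cells are visited once, each
    drawing a length-``n_perm`` batch of hypergeometric variates whose
    success counts are depleted by the draws of the cells before it. Cost
    is independent of the cohort size n.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    order = _validate_order(order)
    margins = compute_margins(table)
    remaining_pop = margins.n
    remaining_zeros = np.full(n_perm, margins.n0, dtype=np.int64)
    layer0 = np.zeros((n_perm, 3, 3), dtype=np.int64)
    for i, j in order:
        n_ij = int(margins.n_ij[i, j])
        if n_ij == 0:
            continue
        drawn = rng.hypergeometric(
            remaining_zeros, remaining_pop - remaining_zeros, n_ij
        )
        layer0[:, i, j] = drawn
        remaining_pop -= n_ij
        remaining_zeros -= drawn
    counts = np.stack([layer0, margins.n_ij[None, :, :] - layer0], axis=-1)
    return PermutedEnsemble(counts, margins, method_tag="transform")
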