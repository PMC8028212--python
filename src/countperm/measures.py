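"""Entropy profiles and information-theoretic interaction measures.

All measures here are functions of the Shannon entropies of the empirical
joint distribution obtained by normalizing a count table. Entropies are
in bits (log base 2); multiply by ``math.log(2)`` to convert to nats.
The built-in interaction score is the multi-information (total
correlation) of the three variables,

    Omega = H_1 + H_2 + H_3 - H_123,

which is zero iff the two SNPs and the phenotype are jointly independent
and grows with any form of mutual dependence, including purely epistatic
ones invisible to single-locus tests. Further measures (mutual
information, information gain variants, synergy, ...) can be registered
as named functions of the :class:`EntropyProfile`.

Every function accepts either a single :class:`~countperm.tables.CountTable`
or a stacked array of tables with shape (..., 3, 3, 2); entropy fields are
then arrays, so registered measures written with numpy arithmetic
vectorize over ensembles for free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.special import xlogy

from .tables import CountTable

__all__ = [
    "EntropyProfile",
    "MeasureValue",
    "to_probabilities",
    "entropy_profile",
    "multi_information",
    "apply_measure",
    "register_measure",
    "available_measures",
]

TableLike = Union[CountTable, np.ndarray]

_LN2 = np.log(2.0)


def _as_counts(table: TableLike) -> np.ndarray:
    counts = table.counts if isinstance(table, CountTable) else np.asarray(table)
    if counts.shape[-3:] != (3, 3, 2):
        raise ValueError("expected trailing table shape (3, 3, 2)")
    return counts


def to_probabilities(table: TableLike) -> np.ndarray:
    """Plug-in (maximum-likelihood) joint probability estimate, counts / n."""
    counts = _as_counts(table)
    totals = counts.sum(axis=(-3, -2, -1), keepdims=True)
    if (totals == 0).any():
        raise ValueError("cannot normalize an empty count table (total = 0)")
    return counts / totals


@dataclass(frozen=True)
class EntropyProfile:
    """Marginal, pairwise and joint Shannon entropies (bits) of one table.

    Variables are numbered 1 = first SNP, 2 = second SNP, 3 = phenotype.
    Fields are scalars for a single table, arrays for a stacked batch.
    """

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    h12: np.ndarray
    h13: np.ndarray
    h23: np.ndarray
    h123: np.ndarray


def entropy_profile(table: TableLike) -> EntropyProfile:
    """Compute all marginal/pairwise/joint entropies of a count table."""
    p = to_probabilities(table)
    nd = p.ndim
    ax1, ax2, ax3 = nd - 3, nd - 2, nd - 1  # snp1, snp2, phenotype axes
    joint = -xlogy(p, p).sum(axis=(ax1, ax2, ax3)) / _LN2
    return EntropyProfile(
        h1=_marginal_entropy(p, keep=(ax1,)),
        h2=_marginal_entropy(p, keep=(ax2,)),
        h3=_marginal_entropy(p, keep=(ax3,)),
        h12=_marginal_entropy(p, keep=(ax1, ax2)),
        h13=_marginal_entropy(p, keep=(ax1, ax3)),
        h23=_marginal_entropy(p, keep=(ax2, ax3)),
        h123=joint,
    )


def _marginal_entropy(p: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    """Entropy in bits of the marginal over the kept table axes.

    Zero cells contribute exactly 0 (masked via xlogy, no epsilon padding).
    """
    table_axes = (p.ndim - 3, p.ndim - 2, p.ndim - 1)
    drop = tuple(a for a in table_axes if a not in keep)
    marginal = p.sum(axis=drop)
    ent_axes = tuple(range(marginal.ndim - len(keep), marginal.ndim))
    return -xlogy(marginal, marginal).sum(axis=ent_axes) / _LN2


@dataclass(frozen=True)
class MeasureValue:
    """A named scalar interaction measure in bits (array-valued for batches)."""

    name: str
    value: np.ndarray


MeasureFn = Callable[[EntropyProfile], np.ndarray]

_REGISTRY: dict[str, MeasureFn] = {}


def register_measure(name: str, fn: MeasureFn) -> None:
    """Register a named measure as a function of an :class:`EntropyProfile`."""
    _REGISTRY[name] = fn


def available_measures() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


register_measure(
    "multi_information", lambda ep: ep.h1 + ep.h2 + ep.h3 - ep.h123
)


def apply_measure(table: TableLike, measure: str) -> MeasureValue:
    """Evaluate a registered measure on a count table (or stacked batch)."""
    try:
        fn = _REGISTRY[measure]
    except KeyError:
        raise KeyError(
            f"unknown measure {measure!r}; available: {available_measures()}"
        ) from None
    return MeasureValue(name=measure, value=fn(entropy_profile(table)))


def multi_information(table: TableLike) -> MeasureValue:
    """Multi-information Omega = H_1 + H_2 + H_3 - H_123, in bits."""
    return apply_measure(table, "multi_information")
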