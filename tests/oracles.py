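"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's hypergeometric reasoning: the
permutation null is computed by literally enumerating every distinct way
of assigning the phenotype-0 labels to individuals.
"""

from itertools import combinations
from math import comb

import numpy as np

from countperm import CountTable, compute_margins


def exact_permutation_pmf(table: CountTable) -> dict[tuple[int, ...], float]:
    """Exact joint PMF of the phenotype-0 layer under label permutation.

    Enumerates all C(n, n_0) placements of the zero labels over the n
    individuals (each equally likely under a uniform shuffle) and tallies
    the resulting flattened 9-cell phenotype-0 layer. Feasible for n <= ~12.
    """
    margins = compute_margins(table)
    cell_of_individual = np.repeat(np.arange(9), margins.n_ij.ravel())
    pmf: dict[tuple[int, ...], float] = {}
    total = comb(margins.n, margins.n0)
    for zeros in combinations(range(margins.n), margins.n0):
        layer0 = np.zeros(9, dtype=int)
        for ind in zeros:
            layer0[cell_of_individual[ind]] += 1
        key = tuple(layer0)
        pmf[key] = pmf.get(key, 0.0) + 1.0 / total
    return pmf


def direct_multi_information(table: CountTable) -> float:
    """Multi-information recomputed straight from the probability definitions.

    Independent code path: explicit loops and math.log2, no shared entropy
    helper with the package.
    """
    from math import log2

    counts = np.asarray(table.counts, dtype=float)
    n = counts.sum()
    p = counts / n

    def ent(dist):
        return -sum(x * log2(x) for x in np.asarray(dist).ravel() if x > 0)

    h1 = ent(p.sum(axis=(1, 2)))
    h2 = ent(p.sum(axis=(0, 2)))
    h3 = ent(p.sum(axis=(0, 1)))
    h123 = ent(p)
    return h1 + h2 + h3 - h123
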