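"""A reference count table for documentation, worked examples and tests.

``HWE_EXAMPLE_TABLE`` is a single realization of the null synthetic
generator for n = 10,000 individuals with both SNPs at minor allele
frequency 0.45 and phenotype zero-probability 0.66. Its margins
(n_0 = 6551, genotype cell counts summing to 10,000) make it a
convenient fixed input for moment checks of the hypergeometric
transform, since every permuted table shares those margins exactly.
"""

from __future__ import annotations

from .tables import CountTable

__all__ = ["HWE_EXAMPLE_TABLE"]

HWE_EXAMPLE_TABLE = CountTable.from_layers(
    [
        [619, 992, 439],
        [964, 1576, 614],
        [409, 674, 264],
    ],
    [
        [347, 527, 200],
        [496, 862, 332],
        [220, 328, 137],
    ],
)
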