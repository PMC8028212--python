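import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from countperm import (
    DEFAULT_CELL_ORDER,
    CountTable,
    build_count_table,
    compute_margins,
    expand_table,
    naive_ensemble,
    naive_permute,
    sample_ensemble,
    sample_hypergeometric,
    transform_count_table,
)
from oracles import exact_permutation_pmf


class CountingRng:
    """Proxy Generator that counts hypergeometric draws."""

    def __init__(self, rng):
        self._rng = rng
        self.hypergeometric_calls = 0

    def hypergeometric(self, *args, **kwargs):
        self.hypergeometric_calls += 1
        return self._rng.hypergeometric(*args, **kwargs)

    def __getattr__(self, name):
        return getattr(self._rng, name)


class TestSampleHypergeometric:
    def test_all_successes_forces_draws(self, rng):
        assert all(sample_hypergeometric(10, 10, 4, rng) == 4 for _ in range(20))

    def test_no_successes_forces_zero(self, rng):
        assert all(sample_hypergeometric(10, 0, 4, rng) == 0 for _ in range(20))

    def test_draws_equal_population(self, rng):
        assert sample_hypergeometric(5, 3, 5, rng) == 3

    def test_pmf_small_case(self, rng):
        # drawing 2 of 6 with 3 successes: P(0)=3/15, P(1)=9/15, P(2)=3/15
        draws = np.array(
            [sample_hypergeometric(6, 3, 2, rng) for _ in range(30_000)]
        )
        observed = np.bincount(draws, minlength=3)
        expected = np.array([3 / 15, 9 / 15, 3 / 15]) * draws.size
        assert stats.chisquare(observed, expected).pvalue > 0.001

    @pytest.mark.parametrize(
        "population,successes,draws",
        [(5, 6, 2), (5, -1, 2), (5, 3, 6), (5, 3, -1)],
    )
    def test_invalid_parameters_rejected(self, population, successes, draws, rng):
        with pytest.raises(ValueError):
            sample_hypergeometric(population, successes, draws, rng)


class TestTransform:
    def test_degenerate_all_zero_labels(self, rng, example_table):
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[:, :, 0] = example_table.counts.sum(axis=2)
        table = CountTable(counts)
        out = transform_count_table(table, rng)
        assert out == table  # n_0 = n: transform is deterministic

    def test_single_genotype_cell_forces_draw(self, rng):
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[0, 0, 0], counts[0, 0, 1] = 7, 3
        table = CountTable(counts)
        for _ in range(10):
            out = transform_count_table(table, rng)
            assert out.counts[0, 0, 0] == 7
            assert out.counts[0, 0, 1] == 3

    def test_margins_preserved(self, rng, example_table):
        margins = compute_margins(example_table)
        out = compute_margins(transform_count_table(example_table, rng))
        assert np.array_equal(out.n_ij, margins.n_ij)
        assert out.n0 == margins.n0

    def test_invalid_cell_order_rejected(self, rng, example_table):
        with pytest.raises(ValueError, match="nine"):
            transform_count_table(example_table, rng, order=((0, 0),) * 9)

    def test_matches_exact_enumeration(self, rng, tiny_table):
        # n=6: enumerate all C(6,4) zero-label placements as the oracle
        pmf = exact_permutation_pmf(tiny_table)
        n_draws = 40_000
        ensemble = sample_ensemble(tiny_table, n_draws, rng)
        keys = sorted(pmf)
        observed = {k: 0 for k in keys}
        for row in ensemble.layer0().reshape(n_draws, 9):
            observed[tuple(row)] += 1
        expected = np.array([pmf[k] * n_draws for k in keys])
        assert stats.chisquare([observed[k] for k in keys], expected).pvalue > 0.001

    def test_single_transform_matches_enumeration(self, rng, tiny_table):
        pmf = exact_permutation_pmf(tiny_table)
        n_draws = 20_000
        observed = {k: 0 for k in pmf}
        for _ in range(n_draws):
            out = transform_count_table(tiny_table, rng)
            observed[tuple(out.layer(0).ravel())] += 1
        keys = sorted(pmf)
        expected = np.array([pmf[k] * n_draws for k in keys])
        assert stats.chisquare([observed[k] for k in keys], expected).pvalue > 0.001

    def test_draw_count_independent_of_cohort_size(self):
        # the transform consumes one hypergeometric draw per populated cell,
        # regardless of n
        for scale in (1, 1000):
            counts = np.zeros((3, 3, 2), dtype=int)
            counts[0, 0, 0] = 3 * scale
            counts[1, 1, 0] = 2 * scale
            counts[1, 1, 1] = 4 * scale
            counts[2, 0, 1] = 1 * scale
            counting = CountingRng(np.random.default_rng(0))
            transform_count_table(CountTable(counts), counting)
            assert counting.hypergeometric_calls == 3  # populated (i,j) cells


class TestNaive:
    def test_constant_phenotype_is_identity(self, rng):
        s1 = rng.integers(0, 3, 40)
        s2 = rng.integers(0, 3, 40)
        ph = np.zeros(40, dtype=int)
        table = build_count_table(s1, s2, ph)
        assert naive_permute(s1, s2, ph, rng) == table

    def test_margins_preserved(self, rng):
        s1 = rng.integers(0, 3, 100)
        s2 = rng.integers(0, 3, 100)
        ph = rng.integers(0, 2, 100)
        reference = compute_margins(build_count_table(s1, s2, ph))
        out = compute_margins(naive_permute(s1, s2, ph, rng))
        assert np.array_equal(out.n_ij, reference.n_ij)
        assert out.n0 == reference.n0

    def test_matches_exact_enumeration(self, rng, tiny_table):
        pmf = exact_permutation_pmf(tiny_table)
        s1, s2, ph = expand_table(tiny_table)
        n_draws = 20_000
        observed = {k: 0 for k in pmf}
        for _ in range(n_draws):
            out = naive_permute(s1, s2, ph, rng)
            observed[tuple(out.layer(0).ravel())] += 1
        keys = sorted(pmf)
        expected = np.array([pmf[k] * n_draws for k in keys])
        assert stats.chisquare([observed[k] for k in keys], expected).pvalue > 0.001


class TestEnsembles:
    def test_size_one(self, rng, example_table):
        ensemble = sample_ensemble(example_table, 1, rng)
        assert len(ensemble) == 1
        margins = compute_margins(ensemble[0])
        assert margins.n0 == 6551

    def test_nperm_validation(self, rng, example_table):
        with pytest.raises(ValueError):
            sample_ensemble(example_table, 0, rng)
        with pytest.raises(ValueError):
            naive_ensemble([0], [0], [0], 0, rng)

    def test_marginal_law_every_cell(self, rng, example_table):
        # by exchangeability each cell is Hypergeometric(n, n0, n_ij)
        margins = compute_margins(example_table)
        n_perm = 20_000
        ensemble = sample_ensemble(example_table, n_perm, rng)
        for i in range(3):
            for j in range(3):
                n_ij = margins.n_ij[i, j]
                dist = stats.hypergeom(margins.n, margins.n0, n_ij)
                mean, var = dist.stats(moments="mv")
                sample = ensemble.layer0()[:, i, j]
                assert abs(sample.mean() - mean) < 3 * np.sqrt(var / n_perm)

    def test_order_invariance(self, example_table):
        reversed_order = tuple(reversed(DEFAULT_CELL_ORDER))
        a = sample_ensemble(
            example_table, 10_000, np.random.default_rng(11)
        )
        b = sample_ensemble(
            example_table, 10_000, np.random.default_rng(12), order=reversed_order
        )
        for i in range(3):
            for j in range(3):
                res = stats.epps_singleton_2samp(
                    a.layer0()[:, i, j], b.layer0()[:, i, j]
                )
                assert res.pvalue > 1e-4

    def test_transform_and_naive_moments_agree(self, rng, example_table):
        n_perm = 20_000
        transformed = sample_ensemble(example_table, n_perm, rng)
        naive = naive_ensemble(*expand_table(example_table), n_perm, rng)
        margins = compute_margins(example_table)
        for i in range(3):
            for j in range(3):
                var = stats.hypergeom(
                    margins.n, margins.n0, margins.n_ij[i, j]
                ).var()
                se = np.sqrt(2 * var / n_perm)
                assert (
                    abs(
                        transformed.layer0()[:, i, j].mean()
                        - naive.layer0()[:, i, j].mean()
                    )
                    < 3 * se
                )


@settings(deadline=None, max_examples=40)
@given(
    counts=st.lists(st.integers(0, 30), min_size=18, max_size=18).filter(
        lambda c: sum(c) > 0
    ),
    seed=st.integers(0, 2**31 - 1),
)
def test_conservation_laws_hold_exactly(counts, seed):
    """Every sampled table preserves n_ij per cell and the zero-label total."""
    table = CountTable(np.array(counts).reshape(3, 3, 2))
    margins = compute_margins(table)
    rng = np.random.default_rng(seed)
    single = transform_count_table(table, rng)
    assert np.array_equal(single.counts.sum(axis=2), margins.n_ij)
    assert single.counts[:, :, 0].sum() == margins.n0
    ensemble = sample_ensemble(table, 25, rng)
    assert np.all(ensemble.counts.sum(axis=3) == margins.n_ij)
    assert np.all(ensemble.layer0().sum(axis=(1, 2)) == margins.n0)
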