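"""Statistical equivalence of the fast transform and naive label permutation.

The transform is only useful if the tables it samples are drawn from the
same distribution as tables produced by genuinely shuffling phenotype
labels. This module operationalizes that check:

* a *trial* generates one null synthetic tuple, samples ``n_perm``
  permuted tables by both methods, and compares the two samples of each
  phenotype-0 cell count ``c*_ij0`` with a two-sample Epps-Singleton
  test (chosen because it is valid for discrete data, unlike the
  two-sample Kolmogorov-Smirnov test);
* a *suite* repeats this over trials with minor allele frequency and
  phenotype-zero probability drawn uniformly from (0.01, 0.99); under
  the hypothesis that the two methods agree, the pooled per-cell
  p-values are uniform on (0, 1), which is assessed by a QQ plot and a
  Kolmogorov-Smirnov uniformity test;
* a *negative control* replaces the transform with a deliberately wrong
  sampler (independent binomials per cell, which matches every cell's
  mean but breaks the without-replacement dependence between cells) to
  demonstrate the suite has power to detect a wrong null.

Cells whose count is constant in both samples (e.g. an empty genotype
cell) admit no distributional test; their p-value is reported as NaN and
excluded from pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .permute import PermutedEnsemble, naive_ensemble, sample_ensemble
from .simulate import generate_phenotype, generate_snp
from .tables import CountTable, build_count_table, compute_margins, expand_table

__all__ = [
    "EquivalenceTrialResult",
    "binomial_control_ensemble",
    "independent_normal_ensemble",
    "cell_pvalues",
    "run_equivalence_trial",
    "run_equivalence_suite",
    "pooled_pvalues",
    "uniformity_test",
    "overlay_distributions",
]


@dataclass(frozen=True)
class EquivalenceTrialResult:
    """Per-cell two-sample p-values for one synthetic tuple.

    ``p_values`` is a 3x3 array, one entry per genotype cell (i, j); NaN
    marks a cell that was constant in both ensembles and hence untestable.
    """

    maf: float
    zero_prob: float
    n: int
    p_values: np.ndarray

    def applicable(self) -> np.ndarray:
        """The finite (testable) p-values, flattened."""
        flat = self.p_values.ravel()
        return flat[np.isfinite(flat)]


def binomial_control_ensemble(
    table: CountTable, n_perm: int, rng: np.random.Generator
) -> PermutedEnsemble:
    """Deliberately WRONG sampler: independent Binomial(n_ij, n_0/n) per cell.

    Matches each cell's permutation-null mean but ignores the
    without-replacement coupling between cells, so the zero-label total
    is no longer conserved. Used as a negative control only.
    """
    margins = compute_margins(table)
    rate = margins.n0 / margins.n
    layer0 = rng.binomial(margins.n_ij[None, :, :], rate, size=(n_perm, 3, 3))
    counts = np.stack([layer0, margins.n_ij[None, :, :] - layer0], axis=-1)
    return PermutedEnsemble(counts, margins, method_tag="binomial-control")


def independent_normal_ensemble(
    table: CountTable, n_perm: int, rng: np.random.Generator
) -> PermutedEnsemble:
    """Deliberately WRONG sampler: independent per-cell normal approximation.

    Each cell is drawn from a rounded normal with the exact hypergeometric
    mean and variance of that cell, independently of the others. The
    marginals are nearly right, but without the cross-cell coupling the
    conservation law ``sum c*_ij0 = n_0`` fails almost surely; a
    regression test pins this failure to justify the iterative sampler.
    """
    m = compute_margins(table)
    f = m.n0 / m.n
    mean = m.n_ij * f
    var = m.n_ij * f * (1 - f) * (m.n - m.n_ij) / max(m.n - 1, 1)
    layer0 = np.rint(
        rng.normal(mean[None, :, :], np.sqrt(var)[None, :, :], size=(n_perm, 3, 3))
    ).astype(np.int64)
    layer0 = np.clip(layer0, 0, m.n_ij[None, :, :])
    counts = np.stack([layer0, m.n_ij[None, :, :] - layer0], axis=-1)
    return PermutedEnsemble(counts, m, method_tag="normal-control")


def cell_pvalues(a: PermutedEnsemble, b: PermutedEnsemble) -> np.ndarray:
    """Epps-Singleton p-value per genotype cell comparing two ensembles.

    Returns a 3x3 array; NaN where both samples are constant (no
    distribution to compare) or the test is numerically degenerate.
    """
    p = np.full((3, 3), np.nan)
    layer_a, layer_b = a.layer0(), b.layer0()
    for i in range(3):
        for j in range(3):
            xa, xb = layer_a[:, i, j], layer_b[:, i, j]
            if xa.min() == xa.max() and xb.min() == xb.max():
                continue
            try:
                with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                    # near-degenerate cells trigger a rank warning from the
                    # characteristic-function covariance; treated as untestable
                    # only if the test itself fails
                    warnings.simplefilter("ignore")
                    p[i, j] = stats.epps_singleton_2samp(xa, xb).pvalue
            except (np.linalg.LinAlgError, ValueError):
                continue
    return p


def run_equivalence_trial(
    n: int,
    maf: float,
    zero_prob: float,
    n_perm: int,
    rng: np.random.Generator,
) -> EquivalenceTrialResult:
    """One equivalence trial: generate a tuple, permute both ways, test cells."""
    if n_perm < 100:
        raise ValueError("n_perm below 100 gives the two-sample test too little power")
    snp1 = generate_snp(n, maf, rng)
    snp2 = generate_snp(n, maf, rng)
    phenotype = generate_phenotype(n, zero_prob, rng)
    table = build_count_table(snp1, snp2, phenotype)
    transformed = sample_ensemble(table, n_perm, rng)
    naive = naive_ensemble(snp1, snp2, phenotype, n_perm, rng)
    return EquivalenceTrialResult(
        maf=maf,
        zero_prob=zero_prob,
        n=n,
        p_values=cell_pvalues(transformed, naive),
    )


def run_equivalence_suite(
    n_trials: int,
    n: int,
    n_perm: int,
    rng: np.random.Generator,
    parameter_range: tuple[float, float] = (0.01, 0.99),
) -> list[EquivalenceTrialResult]:
    """Repeat equivalence trials with MAF and zero-probability ~ U(lo, hi)."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    lo, hi = parameter_range
    results = []
    for _ in range(n_trials):
        maf = float(rng.uniform(lo, hi))
        zero_prob = float(rng.uniform(lo, hi))
        results.append(run_equivalence_trial(n, maf, zero_prob, n_perm, rng))
    return results


def pooled_pvalues(results: list[EquivalenceTrialResult]) -> np.ndarray:
    """All applicable per-cell p-values across a suite, flattened."""
    if not results:
        return np.empty(0)
    return np.concatenate([r.applicable() for r in results])


def uniformity_test(pvalues: np.ndarray) -> tuple[float, float]:
    """KS test of pooled p-values against U(0, 1); returns (statistic, p-value)."""
    res = stats.kstest(pvalues, "uniform")
    return float(res.statistic), float(res.pvalue)


def overlay_distributions(
    table: CountTable,
    n_perm: int,
    rng: np.random.Generator,
    outdir=None,
    bins: int = 60,
):
    """Paired transform-vs-naive histograms per cell plus the measure overlay.

    Samples ``n_perm`` tables by each method (naive via expansion of the
    table into equivalent per-individual columns), bins each cell's
    phenotype-0 counts and the multi-information values, and optionally
    writes a 3x3 cell figure, a measure figure, and binned TSVs to
    ``outdir``. Returns a dict of pandas DataFrames keyed by
    ``"cells"`` and ``"multi_information"``.
    """
    import pandas as pd

    from .measures import apply_measure

    if n_perm < 1000:
        raise ValueError("overlay comparisons need n_perm >= 1000")
    transformed = sample_ensemble(table, n_perm, rng)
    naive = naive_ensemble(*expand_table(table), n_perm, rng)

    cell_rows = []
    for i in range(3):
        for j in range(3):
            xt = transformed.layer0()[:, i, j]
            xn = naive.layer0()[:, i, j]
            lo = int(min(xt.min(), xn.min()))
            hi = int(max(xt.max(), xn.max()))
            edges = np.histogram_bin_edges(
                np.concatenate([xt, xn]), bins=min(bins, hi - lo + 1)
            )
            ht, _ = np.histogram(xt, bins=edges)
            hn, _ = np.histogram(xn, bins=edges)
            for left, right, ct, cn in zip(edges[:-1], edges[1:], ht, hn):
                cell_rows.append((i, j, left, right, ct, cn))
    cells = pd.DataFrame(
        cell_rows,
        columns=["i", "j", "bin_left", "bin_right", "transform", "naive"],
    )

    omega_t = apply_measure(transformed.counts, "multi_information").value
    omega_n = apply_measure(naive.counts, "multi_information").value
    edges = np.histogram_bin_edges(np.concatenate([omega_t, omega_n]), bins=bins)
    ht, _ = np.histogram(omega_t, bins=edges)
    hn, _ = np.histogram(omega_n, bins=edges)
    omega = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "transform": ht,
            "naive": hn,
        }
    )

    if outdir is not None:
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(outdir / "cell_histograms.tsv", sep="\t", index=False)
        omega.to_csv(outdir / "multi_information_histograms.tsv", sep="\t", index=False)

        fig, axes = plt.subplots(3, 3, figsize=(11, 9), constrained_layout=True)
        for i in range(3):
            for j in range(3):
                ax = axes[i, j]
                ax.hist(transformed.layer0()[:, i, j], bins=40, alpha=0.5,
                        label="transform", color="tab:red", density=True)
                ax.hist(naive.layer0()[:, i, j], bins=40, alpha=0.5,
                        label="naive", color="tab:blue", density=True)
                ax.set_title(f"cell ({i}, {j})")
        axes[0, 0].legend()
        fig.suptitle("Permuted phenotype-0 cell counts: transform vs naive")
        fig.savefig(outdir / "cell_overlay.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
        ax.hist(omega_t, bins=50, alpha=0.5, label="transform",
                color="tab:red", density=True)
        ax.hist(omega_n, bins=50, alpha=0.5, label="naive",
                color="tab:blue", density=True)
        ax.set_xlabel("multi-information (bits)")
        ax.set_ylabel("density")
        ax.legend()
        fig.savefig(outdir / "multi_information_overlay.png", dpi=120)
        plt.close(fig)

    return {"cells": cells, "multi_information": omega}
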