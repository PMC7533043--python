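"""Among-strain heterogeneity in derived-allele accumulation.

The central test randomizes derived alleles among genomes while holding
each site's derived-allele count fixed, and compares the observed variance
of per-strain DA totals to the permutation null. Companion tests cover the
0-/4-fold DA ratio across strains, group contrasts (e.g. strains from a
high-radiation area vs. the rest), and correlations with per-strain
covariates such as latitude, including a per-chromosome one-tailed sign
test.

Monte-Carlo p-values use the add-one estimator p = (1 + #{null >= obs}) /
(1 + N) so a permutation p is never exactly zero, with ties counting toward
the null tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .degeneracy_filter import SiteTable
from .polarize import DerivedMatrix

__all__ = [
    "RandomizationResult",
    "variance_randomization_test",
    "ratio_randomization_test",
    "group_difference_test",
    "covariate_correlation",
    "sign_test_p",
]


@dataclass
class RandomizationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    statistic: str = ""
    excluded_strains: tuple = ()

    def __post_init__(self) -> None:
        assert len(self.null_distribution) == self.n_permutations
        assert 0.0 < self.p_value <= 1.0


def _mc_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + len(null))


def _permute_carriers(matrix: np.ndarray, n_permutations: int, rng) -> np.ndarray:
    """Null strain-total matrix (n_permutations x n_strains).

    For every site the derived-allele count k is kept fixed and the k
    carriers are redrawn uniformly without replacement, independently per
    permutation; implemented by ranking uniform draws per site.
    """
    n_strains, n_sites = matrix.shape
    k = matrix.sum(axis=0)  # carriers per site
    totals = np.empty((n_permutations, n_strains), dtype=np.int64)
    # batched to bound memory at ~n_sites*n_strains doubles per permutation
    for p in range(n_permutations):
        u = rng.random((n_sites, n_strains))
        ranks = np.argsort(np.argsort(u, axis=1), axis=1)
        carriers = ranks < k[:, None]
        totals[p] = carriers.sum(axis=0)
    return totals


def variance_randomization_test(
    derived: DerivedMatrix,
    population: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Test among-strain variance of total DA counts by randomization.

    Observed statistic: variance (ddof=1) across the population's strains
    of their total derived-allele counts. Null: per site, which k strains
    carry the derived allele is reassigned uniformly (k fixed per site).
    """
    rows = derived.rows_for_population(population)
    if len(rows) < 3:
        raise ValueError("need at least three strains")
    sub = derived.matrix[rows]
    carrier_counts = sub.sum(axis=0)
    if not (carrier_counts > 0).any():
        raise ValueError("no derived alleles in this population")
    observed = float(np.var(sub.sum(axis=1), ddof=1))
    rng = np.random.default_rng(seed)
    null_totals = _permute_carriers(sub, n_permutations, rng)
    null = np.var(null_totals, axis=1, ddof=1)
    return RandomizationResult(
        observed=observed,
        null_distribution=null,
        p_value=_mc_p(observed, null),
        n_permutations=n_permutations,
        seed=seed,
        statistic="variance of per-strain DA totals",
    )


def ratio_randomization_test(
    derived: DerivedMatrix,
    table: SiteTable,
    population: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Among-strain variance of the 0-/4-fold DA ratio, by randomization.

    Permutations reassign carriers within the 0-fold and 4-fold site sets
    separately. Strains with zero 4-fold DAs have an undefined ratio and
    are excluded with a warning.
    """
    rows = derived.rows_for_population(population)
    if len(rows) < 3:
        raise ValueError("need at least three strains")
    sub = derived.matrix[rows]
    mask0 = table.class_mask("0fold")[derived.site_coords]
    mask4 = table.class_mask("4fold")[derived.site_coords]
    sub0, sub4 = sub[:, mask0], sub[:, mask4]
    tot0, tot4 = sub0.sum(axis=1), sub4.sum(axis=1)
    keep = tot4 > 0
    excluded = tuple(
        derived.strain_ids[rows[i]] for i in np.flatnonzero(~keep)
    )
    if excluded:
        warnings.warn(
            f"strains with zero 4-fold DAs excluded from ratio test: {excluded}",
            stacklevel=2,
        )
    if keep.sum() < 3:
        raise ValueError("fewer than three strains with defined ratios")
    observed = float(np.var(tot0[keep] / tot4[keep], ddof=1))
    rng = np.random.default_rng(seed)
    null0 = _permute_carriers(sub0, n_permutations, rng)
    null4 = _permute_carriers(sub4, n_permutations, rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(null4 > 0, null0 / np.maximum(null4, 1), np.nan)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        row = ratios[p]
        ok = np.isfinite(row)
        null[p] = np.var(row[ok], ddof=1) if ok.sum() >= 2 else 0.0
    return RandomizationResult(
        observed=observed,
        null_distribution=null,
        p_value=_mc_p(observed, null),
        n_permutations=n_permutations,
        seed=seed,
        statistic="variance of per-strain 0/4-fold DA ratios",
        excluded_strains=excluded,
    )


def group_difference_test(
    totals,
    group_labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Two-group contrast of per-strain DA totals by label permutation.

    ``totals`` is a sequence of per-strain DA counts and ``group_labels``
    a parallel sequence with exactly two distinct labels (each group of
    size >= 2). Observed statistic: |difference in group means|; the null
    relabels strains uniformly; the absolute statistic makes the test
    two-sided.
    """
    totals = np.asarray(totals, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    g1 = labels == uniq[0]
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("each group needs at least two strains")
    observed = abs(totals[g1].mean() - totals[~g1].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    n1 = int(g1.sum())
    for p in range(n_permutations):
        perm = rng.permutation(len(totals))
        sel = np.zeros(len(totals), dtype=bool)
        sel[perm[:n1]] = True
        null[p] = abs(totals[sel].mean() - totals[~sel].mean())
    return RandomizationResult(
        observed=float(observed),
        null_distribution=null,
        p_value=_mc_p(observed, null),
        n_permutations=n_permutations,
        seed=seed,
        statistic="absolute difference of group mean DA totals",
    )


def sign_test_p(k: int, n: int) -> float:
    """One-tailed sign test: P[Binom(n, 1/2) >= k]."""
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    return float(stats.binom.sf(k - 1, n, 0.5))


def covariate_correlation(
    totals,
    covariate,
    per_chromosome_totals=None,
) -> dict:
    """Pearson correlation of per-strain DA totals with a covariate.

    ``per_chromosome_totals`` (optional) is a mapping
    ``chrom -> per-strain totals``; when given, each chromosome's
    correlation sign is compared with the genome-level sign and the number
    of concordant chromosomes is assessed with the exact one-tailed sign
    test P[Binom(n_chrom, 1/2) >= k].
    """
    totals = np.asarray(totals, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if totals.shape != cov.shape:
        raise ValueError("totals and covariate must be parallel")
    if len(totals) < 3:
        raise ValueError("need the covariate for at least three strains")
    if np.allclose(cov.std(), 0.0):
        raise ValueError("covariate is constant")
    r, p = stats.pearsonr(totals, cov)
    out = {"r": float(r), "p": float(p)}
    if per_chromosome_totals is not None:
        genome_sign = np.sign(r)
        signs = {}
        concordant = 0
        for chrom, t in per_chromosome_totals.items():
            rc, _ = stats.pearsonr(np.asarray(t, dtype=float), cov)
            signs[chrom] = float(np.sign(rc))
            concordant += int(np.sign(rc) == genome_sign)
        out["per_chromosome_sign"] = signs
        out["n_concordant"] = concordant
        out["sign_test_p"] = sign_test_p(concordant, len(signs))
    return out
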