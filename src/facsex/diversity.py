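"""Nucleotide diversity, Watterson's theta and Tajima's D.

All statistics are computed per chromosome and per population over the
complete sites of a chosen degeneracy class, then combined into genome
averages weighted by the number of analyzed sites per chromosome (so the
per-bp denominators stay consistent between chromosomes of unequal
filtered length).

pi is the average pairwise difference per site; theta_w is the number of
segregating sites scaled by the harmonic number a_n = sum_{i<n} 1/i and the
site count; D is the standardized difference between the two with the
classical constants.  D is undefined (NaN, excluded from averages) when no
site segregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .degeneracy_filter import SiteTable
from .io_formats import AlignedGenomes

__all__ = [
    "DiversitySummary",
    "site_pair_diversity",
    "tajimas_d_constants",
    "diversity_from_matrix",
    "diversity_stats",
    "paired_chromosome_test",
]


def tajimas_d_constants(n: int) -> dict:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n."""
    if n < 2:
        raise ValueError("need at least two sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_pair_diversity(block: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference for an n x L character block."""
    n, L = block.shape
    n_pairs = n * (n - 1) / 2.0
    same_pairs = np.zeros(L)
    for base in np.unique(block):
        c = (block == base).sum(axis=0)
        same_pairs += c * (c - 1) / 2.0
    return 1.0 - same_pairs / n_pairs


@dataclass
class ChromStats:
    chrom: str
    n_sites: int
    n_segregating: int
    pi: float
    theta_w: float
    tajimas_d: float  # NaN when undefined


@dataclass
class DiversitySummary:
    population: str
    site_class: str
    n_strains: int
    per_chromosome: pd.DataFrame  # chrom, n_sites, n_segregating, pi, theta_w, tajimas_d
    pi: float  # genome weighted mean per bp
    theta_w: float
    tajimas_d: float  # site-weighted over chromosomes where defined

    def to_tsv(self, path) -> None:
        self.per_chromosome.to_csv(path, sep="\t", index=False)


def diversity_from_matrix(block: np.ndarray) -> tuple:
    """(pi, theta_w, D, n_segregating) per bp for an n x L block of bases.

    The block must contain proper bases only (complete sites).
    """
    n, L = block.shape
    if n < 2:
        raise ValueError("population must have at least two strains")
    if L == 0:
        return 0.0, 0.0, float("nan"), 0
    per_site = site_pair_diversity(block)
    pi_total = float(per_site.sum())
    seg = int((per_site > 0).sum())
    const = tajimas_d_constants(n)
    theta_total = seg / const["a1"]
    if seg == 0:
        d = float("nan")
    else:
        var = const["e1"] * seg + const["e2"] * seg * (seg - 1)
        d = (pi_total - theta_total) / np.sqrt(var)
    return pi_total / L, theta_total / L, d, seg


def diversity_stats(
    genomes: AlignedGenomes,
    table: SiteTable,
    population: str,
    site_class: str = "4fold",
) -> DiversitySummary:
    """Per-chromosome and genome-wide diversity for one population.

    Only complete sites of ``site_class`` enter; genome means are weighted
    by the per-chromosome analyzed-site counts.  Tajima's D genome value is
    the site-count-weighted mean over chromosomes where it is defined.
    """
    rows = genomes.rows_for_population(population)
    if len(rows) < 2:
        raise ValueError(f"population {population!r} has fewer than two strains")
    mask = table.class_mask(site_class) & table.complete
    records = []
    for chrom, start, end in genomes.chrom_map:
        cols = np.flatnonzero(mask[start:end]) + start
        block = genomes.matrix[np.ix_(rows, cols)]
        if cols.size == 0:
            records.append(ChromStats(chrom, 0, 0, 0.0, 0.0, float("nan")))
            continue
        pi, tw, d, seg = diversity_from_matrix(block)
        records.append(ChromStats(chrom, int(cols.size), seg, pi, tw, d))
    df = pd.DataFrame([r.__dict__ for r in records])
    w = df["n_sites"].to_numpy(float)
    if w.sum() == 0:
        raise ValueError(f"no complete {site_class} sites for population {population!r}")
    pi_g = float(np.average(df["pi"], weights=w))
    tw_g = float(np.average(df["theta_w"], weights=w))
    defined = df["tajimas_d"].notna().to_numpy()
    if defined.any():
        d_g = float(np.average(df.loc[defined, "tajimas_d"], weights=w[defined]))
    else:
        d_g = float("nan")
    return DiversitySummary(
        population=population,
        site_class=site_class,
        n_strains=len(rows),
        per_chromosome=df,
        pi=pi_g,
        theta_w=tw_g,
        tajimas_d=d_g,
    )


def paired_chromosome_test(values_a, values_b, weights=None) -> tuple:
    """Two-sided paired t-test across chromosomes plus a fold ratio.

    Returns ``(t, p, fold)`` where fold is the ratio of (weighted) means
    of ``values_a`` over ``values_b``.  Exactly-constant differences are
    handled explicitly: all-zero differences give ``t=0, p=1``; a nonzero
    constant difference gives ``p=0`` with an infinite t of the proper
    sign.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least two chromosomes")
    if weights is None:
        weights = np.ones_like(a)
    fold = float(np.average(a, weights=weights) / np.average(b, weights=weights))
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0, fold
        return float(np.sign(diff.mean()) * np.inf), 0.0, fold
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), fold
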