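"""Recombinational diversity and the frequency of sex.

In a facultatively sexual, partially selfing organism the population-scaled
mutation and recombination parameters are

    theta = 4 Ne u / (1 + F)        rho = 4 Ne r S (1 - F)

where u is the mutation rate per bp per cell division, r the recombination
rate in Morgans/bp per meiosis, F the inbreeding coefficient and S the
frequency of sex (sexual generations per mitotic generation).  Dividing the
two identities gives the estimator implemented here:

    S = (rho / theta) * (u / r) / [(1 + F)(1 - F)]

rho per bp comes either from imported LDhat-style per-chromosome 4*Ne*r
estimates (the fidelity path) or from a built-in linkage-disequilibrium
decay estimator that fits the sample-size-adjusted Ohta–Kimura expectation
E[r^2] ~ (10 + C)/(22 + 13 C + C^2) + 1/n with C = rho_pbp * distance —
an explicit approximation, not a reimplementation of composite-likelihood
methods.  Genome rho is the summed 4*Ne*r over chromosomes divided by the
full reference length in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .degeneracy_filter import SiteTable
from .io_formats import AlignedGenomes, RhoImport

__all__ = [
    "RhoSexEstimate",
    "RhoEstimateUnavailable",
    "average_rho_runs",
    "normalize_rho",
    "ohta_kimura_r2",
    "estimate_rho_builtin",
    "sex_frequency",
    "estimate_sex",
]


class RhoEstimateUnavailable(RuntimeError):
    """Raised when the LD-decay fit is infeasible or ill-conditioned."""


def average_rho_runs(imports) -> dict:
    """Average 4*Ne*r across runs for each chromosome.

    Returns ``{chrom: mean 4Ner}``; multiple runs of the same chromosome
    are averaged unweighted. A chromosome with zero runs simply does not
    appear; requesting one downstream raises there.
    """
    imports = list(imports)
    if not imports:
        raise ValueError("no rho imports given")
    by_chrom: dict = {}
    for imp in imports:
        by_chrom.setdefault(imp.chrom, []).append(imp.rho_4ner)
    return {c: float(np.mean(v)) for c, v in by_chrom.items()}


def normalize_rho(total_4ner: float, reference_length_bp: int) -> float:
    """rho per bp (Morgans/bp): genome 4*Ne*r over the reference length."""
    if reference_length_bp <= 0:
        raise ValueError("reference length must be positive")
    if total_4ner < 0:
        raise ValueError("4Ner must be >= 0")
    return total_4ner / reference_length_bp


def ohta_kimura_r2(C: np.ndarray, n: int) -> np.ndarray:
    """Expected r^2 between site pairs at scaled distance C = rho * d.

    The drift approximation (10 + C)/(22 + 13 C + C^2) plus the 1/n
    sample-size inflation.
    """
    C = np.asarray(C, dtype=float)
    return (10.0 + C) / (22.0 + 13.0 * C + C**2) + 1.0 / n


def _pairwise_r2(geno: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs of a 0/1 genotype matrix."""
    g = geno.astype(float)
    g -= g.mean(axis=0)
    cov = g.T @ g
    var = np.diag(cov).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    return r**2


def estimate_rho_builtin(
    genomes: AlignedGenomes,
    table: SiteTable | None,
    chromosome: str,
    population: str,
    maf_min: float = 0.1,
    n_bins: int = 20,
    max_pairs: int = 2_000_000,
    seed: int | None = None,
) -> tuple:
    """LD-decay estimate of the chromosome's total 4*Ne*r.

    Uses biallelic complete sites with minor-allele frequency >= maf_min in
    the population, computes r^2 for all (or a random subsample of) site
    pairs, bins mean r^2 by physical distance and fits rho per bp by
    weighted least squares against the Ohta–Kimura expectation.

    Returns ``(rho_4ner_total, diagnostics_dict)``; raises
    :class:`RhoEstimateUnavailable` for degenerate inputs (too few sites or
    all pairs at one distance).
    """
    rows = genomes.rows_for_population(population)
    n = len(rows)
    if n < 4:
        raise RhoEstimateUnavailable("need at least four strains")
    start, end = genomes.chrom_span(chromosome)
    if table is not None:
        complete = table.complete[start:end]
    else:
        sub = genomes.matrix[:, start:end]
        complete = ~((sub == "-") | (sub == "N")).any(axis=0)
    m = genomes.matrix[np.ix_(rows, np.arange(start, end))]

    # biallelic + MAF filter
    pos_list = []
    geno_cols = []
    cand = np.flatnonzero(complete)
    for c in cand:
        col = m[:, c]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            continue
        maf = counts.min() / n
        if maf < maf_min:
            continue
        pos_list.append(c)
        geno_cols.append((col == alleles[1]).astype(np.uint8))
    if len(pos_list) < 2:
        raise RhoEstimateUnavailable("fewer than two qualifying polymorphic sites")
    pos = np.asarray(pos_list)
    geno = np.column_stack(geno_cols)

    r2 = _pairwise_r2(geno)
    iu, ju = np.triu_indices(len(pos), k=1)
    if len(iu) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju = iu[keep], ju[keep]
    d = np.abs(pos[ju] - pos[iu]).astype(float)
    r2v = r2[iu, ju]
    ok = np.isfinite(r2v)
    d, r2v = d[ok], r2v[ok]
    if d.size == 0 or np.unique(d).size < 2:
        raise RhoEstimateUnavailable("all site pairs at a single distance; fit ill-conditioned")

    edges = np.linspace(0, d.max() + 1, n_bins + 1)
    which = np.digitize(d, edges) - 1
    bin_d, bin_r2, bin_n = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        bin_d.append(d[sel].mean())
        bin_r2.append(r2v[sel].mean())
        bin_n.append(sel.sum())
    if len(bin_d) < 2:
        raise RhoEstimateUnavailable("fewer than two populated distance bins")
    bin_d = np.asarray(bin_d)
    bin_r2 = np.asarray(bin_r2)
    wts = np.sqrt(np.asarray(bin_n, dtype=float))

    def resid(log_rho):
        rho = np.exp(log_rho[0])
        return (ohta_kimura_r2(rho * bin_d, n) - bin_r2) * wts

    best = None
    for start_rho in (1e-6, 1e-4, 1e-2):
        fit = least_squares(resid, x0=[np.log(start_rho)], method="lm", max_nfev=200)
        if best is None or fit.cost < best.cost:
            best = fit
    rho_pbp = float(np.exp(best.x[0]))
    chrom_length = end - start
    diagnostics = {
        "rho_pbp": rho_pbp,
        "n_sites": len(pos),
        "n_pairs": int(d.size),
        "n_bins": len(bin_d),
        "cost": float(best.cost),
    }
    return rho_pbp * chrom_length, diagnostics


def sex_frequency(theta_pbp: float, rho_pbp: float, u: float, r: float, F: float = 0.98) -> tuple:
    """Frequency of sex S and mitotic generations between sexual ones.

    ``S = (rho/theta) (u/r) / [(1+F)(1-F)]``; returns ``(S, 1/S)`` with
    ``1/S`` infinite when rho is zero.
    """
    if theta_pbp <= 0:
        raise ValueError("theta must be positive")
    if r <= 0 or u <= 0:
        raise ValueError("u and r must be positive")
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    if rho_pbp < 0:
        raise ValueError("rho must be >= 0")
    S = (rho_pbp / theta_pbp) * (u / r) / ((1.0 + F) * (1.0 - F))
    gens = float("inf") if S == 0 else 1.0 / S
    return S, gens


@dataclass
class RhoSexEstimate:
    """Bundle of rho and frequency-of-sex results for one population."""

    population: str
    per_chromosome: pd.DataFrame  # chrom, rho_4ner (run-averaged)
    total_4ner: float
    reference_length_bp: int
    rho_pbp: float
    theta_pbp: float
    u: float
    r: float
    F: float
    S: float
    generations_between_sex: float
    inputs: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.per_chromosome.to_csv(path, sep="\t", index=False)


def estimate_sex(
    imports,
    theta_pbp: float,
    reference_length_bp: int,
    u: float,
    r: float,
    F: float = 0.98,
    population: str = "",
) -> RhoSexEstimate:
    """End-to-end: run-average rho imports, normalise, estimate S."""
    per_chrom = average_rho_runs(imports)
    total = float(sum(per_chrom.values()))
    rho_pbp = normalize_rho(total, reference_length_bp)
    S, gens = sex_frequency(theta_pbp, rho_pbp, u, r, F)
    df = pd.DataFrame(
        {"chrom": list(per_chrom), "rho_4ner": list(per_chrom.values())}
    )
    return RhoSexEstimate(
        population=population,
        per_chromosome=df,
        total_4ner=total,
        reference_length_bp=reference_length_bp,
        rho_pbp=rho_pbp,
        theta_pbp=theta_pbp,
        u=u,
        r=r,
        F=F,
        S=S,
        generations_between_sex=gens,
        inputs={"u": u, "r": r, "F": F, "theta_pbp": theta_pbp},
    )
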