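"""Distribution of fitness effects from paired site-frequency spectra.

The model follows the classical two-stage construction for estimating a
gamma distribution of deleterious fitness effects: a putatively neutral
site class (4-fold degenerate sites) is first used to fit a step-change
demographic model (ancestral size N1, present size N2 = ratio * N1 since
``t2`` x N2 generations ago); with the demography fixed, the selected
class (0-fold sites) is fit with gamma-distributed deleterious effects.

Allele-frequency dynamics are computed on a discrete Wright-Fisher grid of
``K1`` haploid copies (default 100). New mutations enter at count 1 at a
constant per-generation influx; the standing frequency distribution is the
solution of the linear balance equations at the ancestral size, propagated
through the size change, and binomially down-sampled to the sample size n.
Selection against a derived allele with population-scaled effect
``gamma = 4*Ne*Sd`` acts deterministically each generation with per-copy
coefficient ``s = gamma / (2K)`` (capped below 1; effects too strong for
the grid contribute essentially no polymorphism, which is also their
biological behaviour). The gamma distribution over effects is integrated
by mass-binning on a fixed log-spaced grid of precomputed spectra.

The likelihood is Poisson per frequency class (independent-sites
approximation): classes 1..n have mean ``theta_scale * E_i`` and class 0
absorbs the remaining sites. Fixations are only accumulated over the
modelled post-change epoch, so absolute class-n masses are dominated by
sampling all-derived at segregating sites; divergence-calibrated fixation
counts are outside this model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .degeneracy_filter import CODON_TO_AA, SiteTable
from .io_formats import GeneModels
from .polarize import DerivedMatrix

__all__ = [
    "StepDemography",
    "SFSPair",
    "DFEFit",
    "build_sfs",
    "expected_sfs",
    "fit_dfe",
    "fit_demography",
    "likelihood_ratio_test",
    "positive_selection_test",
    "classify_conservation",
]

_BASES = ("A", "C", "G", "T")

#: severity bin edges for population-scaled deleterious effects
SEVERITY_EDGES = (1.0, 10.0, 100.0)

#: log-spaced grid of population-scaled effects for gamma integration
_GAMMA_GRID = np.geomspace(1e-2, 2e4, 36)

_S_MAX = 0.95  # per-copy selection cap on the grid


@dataclass(frozen=True)
class StepDemography:
    """One step change: N2 = ratio * N1, ``t2`` x N2 generations ago.

    ``ratio=1`` (or ``t2=0``) is the constant-size model.
    """

    ratio: float = 1.0
    t2: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.t2 < 0:
            raise ValueError("ratio must be > 0 and t2 >= 0")

    @property
    def is_constant(self) -> bool:
        return self.ratio == 1.0 or self.t2 == 0.0


@dataclass
class SFSPair:
    """Unfolded spectra for a neutral and a selected site class.

    ``neutral`` and ``selected`` have length n+1: class i counts sites
    whose derived allele is carried by exactly i of the n sampled strains
    (class 0 = monomorphic ancestral, class n = fixed derived).
    """

    n: int
    neutral: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.neutral = np.asarray(self.neutral, dtype=float)
        self.selected = np.asarray(self.selected, dtype=float)
        if len(self.neutral) != self.n + 1 or len(self.selected) != self.n + 1:
            raise ValueError("spectra must have n+1 frequency classes")
        if (self.neutral < 0).any() or (self.selected < 0).any():
            raise ValueError("spectra counts must be non-negative")

    @property
    def neutral_total(self) -> float:
        return float(self.neutral.sum())

    @property
    def selected_total(self) -> float:
        return float(self.selected.sum())


@dataclass
class DFEFit:
    demography: StepDemography
    shape: float  # gamma shape b
    mean_4NeSd: float  # mean population-scaled deleterious effect
    theta_neutral: float
    theta_selected: float
    severity_proportions: dict
    loglik_neutral: float
    loglik_selected: float
    n_params: int
    extras: dict = field(default_factory=dict)

    @property
    def scale(self) -> float:
        """Gamma scale parameter (mean / shape)."""
        return self.mean_4NeSd / self.shape

    @property
    def loglik(self) -> float:
        return self.loglik_neutral + self.loglik_selected


# ---------------------------------------------------------------------------
# observed spectra
# ---------------------------------------------------------------------------

def build_sfs(
    derived: DerivedMatrix,
    table: SiteTable,
    population: str,
    neutral_class: str = "4fold",
    selected_class: str = "0fold",
    polarized=None,
    selected_mask: np.ndarray | None = None,
) -> SFSPair:
    """Unfolded SFS pair over complete sites for one population.

    Monomorphic complete sites of a class fall in frequency class 0; when
    the ``polarized`` site list is supplied, missing-status sites are
    excluded from the class-0 count instead of being counted as
    monomorphic ancestral.  ``selected_mask`` optionally restricts the
    selected class to a per-site boolean mask over the concatenated
    coordinates (e.g. a conservation class).
    """
    rows = derived.rows_for_population(population)
    n = len(rows)
    missing_coords = (
        {s.coord for s in polarized if s.status == "missing"} if polarized else set()
    )
    spectra = {}
    for key, cls in (("neutral", neutral_class), ("selected", selected_class)):
        mask = table.class_mask(cls) & table.complete
        if key == "selected" and selected_mask is not None:
            mask = mask & selected_mask
        total = int(mask.sum())
        if missing_coords:
            total -= sum(1 for c in missing_coords if mask[c])
        cols = mask[derived.site_coords]
        counts = derived.matrix[np.ix_(rows, np.flatnonzero(cols))].sum(axis=0)
        sfs = np.bincount(counts[counts > 0], minlength=n + 1).astype(float)
        # class 0: complete class sites with no derived carrier in this
        # population (monomorphic-ancestral here, possibly derived elsewhere)
        sfs[0] = total - (counts > 0).sum()
        spectra[key] = sfs
    return SFSPair(n=n, neutral=spectra["neutral"], selected=spectra["selected"])


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _transition(K: int, gamma: float) -> np.ndarray:
    """WF transition matrix for K haploid copies, scaled effect gamma.

    ``gamma > 0`` is deleterious for the derived allele, ``gamma < 0``
    advantageous. Row j: current count; columns: binomial offspring counts
    after deterministic selection.
    """
    q = np.arange(K + 1) / K
    s = np.clip(gamma / (2.0 * K), -_S_MAX, _S_MAX)
    q_star = q * (1.0 - s) / (1.0 - q * s)
    j = np.arange(K + 1)
    return stats.binom.pmf(j[None, :], K, q_star[:, None])


def _equilibrium_segregating(P: np.ndarray) -> np.ndarray:
    """Standing counts f_1..f_{K-1} under unit influx at count 1.

    Solves f = f P_seg + e1 for the expected number of sites at each
    segregating count per unit of per-generation mutation influx.
    """
    K = P.shape[0] - 1
    Pseg = P[1:K, 1:K]
    e1 = np.zeros(K - 1)
    e1[0] = 1.0
    return np.linalg.solve(np.eye(K - 1) - Pseg.T, e1)


def _resample_counts(f: np.ndarray, K_old: int, K_new: int) -> tuple:
    """Map standing counts onto a new grid size by binomial resampling."""
    j_old = np.arange(1, K_old)
    q = j_old / K_old
    j_new = np.arange(K_new + 1)
    R = stats.binom.pmf(j_new[None, :], K_new, q[:, None])
    out = f @ R
    return out[1:K_new], float(out[K_new])  # segregating, newly fixed


def _standing_distribution(dem: StepDemography, gamma: float, k1: int) -> tuple:
    """(segregating counts on present grid, fixed mass, K_present)."""
    P1 = _transition(k1, gamma)
    f1 = _equilibrium_segregating(P1)
    if dem.is_constant:
        return f1, 0.0, k1
    k2 = int(np.clip(round(dem.ratio * k1), 10, 400))
    f2, fixed = _resample_counts(f1, k1, k2)
    P2 = _transition(k2, gamma)
    Pseg = P2[1:k2, 1:k2]
    p_fix = P2[1:k2, k2]
    e1 = np.zeros(k2 - 1)
    e1[0] = 1.0
    T = max(1, int(round(dem.t2 * k2)))
    for _ in range(T):
        fixed += float(f2 @ p_fix)
        f2 = f2 @ Pseg + e1
    return f2, fixed, k2


def _sample_sfs(f_seg: np.ndarray, fixed: float, K: int, n: int) -> np.ndarray:
    """Down-sample standing counts to sample classes 0..n (unit influx)."""
    j = np.arange(1, K)
    q = j / K
    i = np.arange(n + 1)
    B = stats.binom.pmf(i[None, :], n, q[:, None])
    e = f_seg @ B
    e[n] += fixed
    return e


class _SpectrumCache:
    """Per-(demography, n, k1) cache of expected sample spectra."""

    def __init__(self) -> None:
        self._store: dict = {}

    def unit_sfs(self, dem: StepDemography, n: int, gamma: float, k1: int) -> np.ndarray:
        key = (dem, n, k1, float(gamma))
        if key not in self._store:
            f, fixed, K = _standing_distribution(dem, gamma, k1)
            self._store[key] = _sample_sfs(f, fixed, K, n)
        return self._store[key]

    def grid(self, dem: StepDemography, n: int, k1: int, gammas=_GAMMA_GRID) -> np.ndarray:
        key = (dem, n, k1, "grid", tuple(gammas))
        if key not in self._store:
            self._store[key] = np.vstack(
                [self.unit_sfs(dem, n, g, k1) for g in gammas]
            )
        return self._store[key]


_CACHE = _SpectrumCache()


def _gamma_weights(shape: float, mean: float, grid=_GAMMA_GRID) -> np.ndarray:
    """Probability mass of Gamma(shape, scale=mean/shape) per grid point.

    Mass below the grid is assigned to the smallest point (effectively
    neutral), mass above to the largest (effectively lethal).
    """
    dist = stats.gamma(a=shape, scale=mean / shape)
    edges = np.sqrt(grid[:-1] * grid[1:])
    cdf = dist.cdf(edges)
    w = np.empty(len(grid))
    w[0] = cdf[0]
    w[1:-1] = np.diff(cdf)
    w[-1] = 1.0 - cdf[-1]
    return w


def expected_sfs(
    demography: StepDemography,
    n: int,
    selection: tuple | None = None,
    theta_site: float = 0.01,
    k1: int = 100,
) -> np.ndarray:
    """Expected proportions of frequency classes 0..n per site.

    ``selection=None`` gives the neutral expectation; ``selection=(shape,
    mean)`` integrates over a gamma distribution of deleterious
    population-scaled effects. ``theta_site`` sets the per-site mutation
    input (mutation influx per generation = theta_site / 2, which yields
    the classical neutral E[xi_i] ~ theta/i at constant size).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if selection is None:
        e = _CACHE.unit_sfs(demography, n, 0.0, k1)
    else:
        shape, mean = selection
        if shape <= 0 or mean < 0:
            raise ValueError("gamma shape must be > 0 and mean >= 0")
        if mean == 0:
            e = _CACHE.unit_sfs(demography, n, 0.0, k1)
        else:
            grid_sfs = _CACHE.grid(demography, n, k1)
            e = _gamma_weights(shape, mean) @ grid_sfs
    if not np.all(np.isfinite(e)):
        raise RuntimeError("expected SFS computation did not converge")
    counts = e * (theta_site / 2.0)
    seg = counts[1:].sum()
    if seg >= 1.0:
        raise RuntimeError("theta_site too large for a per-site proportion model")
    p = counts.copy()
    p[0] = 1.0 - seg
    return p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _poisson_loglik(obs: np.ndarray, unit: np.ndarray, log_theta: float) -> float:
    """Poisson log-likelihood over classes 0..n.

    ``unit`` is the unit-influx expected spectrum for classes 0..n (class
    0 entry ignored); class-0 mean is total minus the scaled segregating
    mass.
    """
    theta = np.exp(log_theta)
    total = obs.sum()
    m = unit[1:] * theta
    m0 = total - m.sum()
    if m0 <= 0:
        return -np.inf
    means = np.concatenate([[m0], np.maximum(m, 1e-300)])
    return float(np.sum(obs * np.log(means) - means))


def fit_demography(
    sfs_counts: np.ndarray,
    n: int,
    k1: int = 100,
    include_constant: bool = True,
) -> tuple:
    """Stage 1: ML step-change demography for a neutral spectrum.

    Returns ``(StepDemography, theta, loglik)`` of the best model over
    multiple optimizer starts (the constant-size model is included as a
    candidate when ``include_constant``).
    """
    obs = np.asarray(sfs_counts, dtype=float)

    def neg(params):
        log_ratio, log_t2, log_theta = params
        ratio = float(np.exp(log_ratio))
        t2 = float(np.exp(log_t2))
        if not (0.1 <= ratio <= 8.0 and 0.01 <= t2 <= 2.0):
            return 1e12
        dem = StepDemography(ratio=ratio, t2=t2)
        unit = _CACHE.unit_sfs(dem, n, 0.0, k1)
        ll = _poisson_loglik(obs, unit, log_theta)
        return -ll if np.isfinite(ll) else 1e12

    # analytic-ish theta start: match singletons to unit spectrum
    unit0 = _CACHE.unit_sfs(StepDemography(), n, 0.0, k1)
    theta0 = max(obs[1] / max(unit0[1], 1e-12), 1e-6)
    starts = [
        (np.log(2.0), np.log(0.5), np.log(theta0)),
        (np.log(1.2), np.log(0.2), np.log(theta0)),
        (np.log(4.0), np.log(1.0), np.log(theta0)),
        (np.log(0.5), np.log(0.5), np.log(theta0)),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(neg, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("demography optimization failed for all starts")
    log_ratio, log_t2, log_theta = best.x
    dem = StepDemography(ratio=float(np.exp(log_ratio)), t2=float(np.exp(log_t2)))
    ll_step = -float(best.fun)
    if include_constant:
        dem_c = StepDemography()
        unit_c = _CACHE.unit_sfs(dem_c, n, 0.0, k1)
        res_c = optimize.minimize_scalar(
            lambda lt: -_poisson_loglik(obs, unit_c, lt),
            bounds=(np.log(theta0) - 8, np.log(theta0) + 8),
            method="bounded",
        )
        if -res_c.fun > ll_step:
            return dem_c, float(np.exp(res_c.x)), float(-res_c.fun)
    return dem, float(np.exp(log_theta)), ll_step


def fit_constant_demography(sfs_counts: np.ndarray, n: int, k1: int = 100) -> tuple:
    """Constant-size null fit: returns (StepDemography(), theta, loglik)."""
    obs = np.asarray(sfs_counts, dtype=float)
    dem = StepDemography()
    unit = _CACHE.unit_sfs(dem, n, 0.0, k1)
    theta0 = max(obs[1] / max(unit[1], 1e-12), 1e-6)
    res = optimize.minimize_scalar(
        lambda lt: -_poisson_loglik(obs, unit, lt),
        bounds=(np.log(theta0) - 8, np.log(theta0) + 8),
        method="bounded",
    )
    return dem, float(np.exp(res.x)), float(-res.fun)


def severity_proportions(shape: float, mean: float) -> dict:
    """Gamma mass in the four severity bins of 4*Ne*Sd."""
    dist = stats.gamma(a=shape, scale=mean / shape)
    e = SEVERITY_EDGES
    p = dist.cdf(e)
    return {
        "0-1": float(p[0]),
        "1-10": float(p[1] - p[0]),
        "10-100": float(p[2] - p[1]),
        ">100": float(1.0 - p[2]),
    }


def fit_dfe(
    sfs: SFSPair,
    k1: int = 100,
    demography: StepDemography | None = None,
    n_starts: int = 4,
) -> DFEFit:
    """Two-stage ML fit of demography plus a gamma DFE.

    Stage 1 fits the step-change demography (and neutral mutation input)
    to the neutral spectrum; stage 2 fixes the demography and fits the
    gamma shape and mean population-scaled deleterious effect (plus the
    selected-class mutation input) to the selected spectrum. Multi-start
    Nelder-Mead; the best log-likelihood is reported.
    """
    n = sfs.n
    if demography is None:
        demography, theta_n, ll_n = fit_demography(sfs.neutral, n, k1=k1)
    else:
        theta_n, ll_n = _fit_theta_only(sfs.neutral, demography, n, k1)

    grid_sfs = _CACHE.grid(demography, n, k1)
    obs = sfs.selected

    def neg(params):
        log_b, log_mean, log_theta = params
        b = float(np.exp(log_b))
        mean = float(np.exp(log_mean))
        if not (0.02 <= b <= 5.0 and 1e-3 <= mean <= 5e4):
            return 1e12
        unit = _gamma_weights(b, mean) @ grid_sfs
        ll = _poisson_loglik(obs, unit, log_theta)
        return -ll if np.isfinite(ll) else 1e12

    unit_neu = grid_sfs[0]
    theta0 = max(obs[1] / max(unit_neu[1], 1e-12), 1e-6)

    def profiled(log_b, log_mean):
        """theta profiled out by 1-D search at fixed DFE parameters."""
        res = optimize.minimize_scalar(
            lambda lt: neg((log_b, log_mean, lt)),
            bounds=(np.log(theta0) - 6, np.log(theta0) + 6),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return res.fun, res.x

    # coarse landscape scan to seed the simplex away from local optima
    scan = []
    for b0 in (0.1, 0.2, 0.4, 0.8, 1.5):
        for m0 in (0.5, 5.0, 30.0, 150.0, 600.0, 3000.0):
            f, lt = profiled(np.log(b0), np.log(m0))
            scan.append((f, (np.log(b0), np.log(m0), lt)))
    scan.sort(key=lambda t: t[0])
    start_grid = [x0 for _, x0 in scan[: max(2, n_starts)]]
    best = None
    for x0 in start_grid:
        res = optimize.minimize(neg, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 1500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError("DFE optimization failed for all starts")
    log_b, log_mean, log_theta = best.x
    b = float(np.exp(log_b))
    mean = float(np.exp(log_mean))
    return DFEFit(
        demography=demography,
        shape=b,
        mean_4NeSd=mean,
        theta_neutral=theta_n,
        theta_selected=float(np.exp(log_theta)),
        severity_proportions=severity_proportions(b, mean),
        loglik_neutral=ll_n,
        loglik_selected=-float(best.fun),
        n_params=2,
    )


def _fit_theta_only(obs, dem, n, k1):
    unit = _CACHE.unit_sfs(dem, n, 0.0, k1)
    theta0 = max(obs[1] / max(unit[1], 1e-12), 1e-6)
    res = optimize.minimize_scalar(
        lambda lt: -_poisson_loglik(np.asarray(obs, float), unit, lt),
        bounds=(np.log(theta0) - 8, np.log(theta0) + 8),
        method="bounded",
    )
    return float(np.exp(res.x)), float(-res.fun)


def likelihood_ratio_test(loglik_null: float, loglik_alt: float, df: int,
                          tolerance: float = 1e-6) -> tuple:
    """LRT statistic 2*(lA - l0) and its chi-square p-value.

    ``loglik_alt`` may fall below ``loglik_null`` only within ``tolerance``
    (then the statistic is clamped to 0); a larger shortfall indicates an
    optimization failure and raises.
    """
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -tolerance * max(1.0, abs(loglik_null)):
        raise RuntimeError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}: "
            "optimization failure"
        )
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df))


def positive_selection_test(
    sfs: SFSPair,
    k1: int = 100,
    demography: StepDemography | None = None,
) -> dict:
    """LRT for a class of advantageous mutations in the selected spectrum.

    The alternative adds a proportion ``p_a`` of new mutations with a
    single advantageous scaled effect ``gamma_a``; the null fixes
    ``p_a = 0`` (the plain gamma-DFE fit). Two extra parameters, df = 2.
    """
    null_fit = fit_dfe(sfs, k1=k1, demography=demography)
    dem = null_fit.demography
    n = sfs.n
    grid_sfs = _CACHE.grid(dem, n, k1)
    benef_grid = np.geomspace(1.0, 500.0, 8)
    benef_sfs = np.vstack([_CACHE.unit_sfs(dem, n, -g, k1) for g in benef_grid])
    obs = sfs.selected

    def neg(params):
        log_b, log_mean, log_theta, logit_pa, log_ga = params
        b = float(np.exp(log_b))
        mean = float(np.exp(log_mean))
        pa = 1.0 / (1.0 + np.exp(-logit_pa))
        ga = float(np.exp(log_ga))
        if not (0.02 <= b <= 5.0 and 1e-3 <= mean <= 5e4 and benef_grid[0] <= ga <= benef_grid[-1]):
            return 1e12
        unit_del = _gamma_weights(b, mean) @ grid_sfs
        # log-interpolate the beneficial spectrum at gamma_a
        k = np.searchsorted(benef_grid, ga)
        k = np.clip(k, 1, len(benef_grid) - 1)
        w = (np.log(ga) - np.log(benef_grid[k - 1])) / (
            np.log(benef_grid[k]) - np.log(benef_grid[k - 1])
        )
        unit_ben = (1 - w) * benef_sfs[k - 1] + w * benef_sfs[k]
        unit = (1 - pa) * unit_del + pa * unit_ben
        ll = _poisson_loglik(obs, unit, log_theta)
        return -ll if np.isfinite(ll) else 1e12

    x0_base = (
        np.log(null_fit.shape),
        np.log(null_fit.mean_4NeSd),
        np.log(null_fit.theta_selected),
    )
    best = None
    for pa0, ga0 in ((0.02, 10.0), (0.1, 100.0)):
        x0 = (*x0_base, np.log(pa0 / (1 - pa0)), np.log(ga0))
        res = optimize.minimize(neg, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    ll_alt = -float(best.fun)
    # the alternative nests the null; numerical shortfalls clamp to the null
    ll_alt = max(ll_alt, null_fit.loglik_selected)
    stat, p = likelihood_ratio_test(null_fit.loglik_selected, ll_alt, df=2)
    pa_hat = 1.0 / (1.0 + np.exp(-best.x[3]))
    return {
        "statistic": stat,
        "p": p,
        "df": 2,
        "p_a": float(pa_hat),
        "gamma_a": float(np.exp(best.x[4])),
        "null_fit": null_fit,
        "loglik_alt": ll_alt,
    }


# ---------------------------------------------------------------------------
# conservation classes
# ---------------------------------------------------------------------------

def classify_conservation(
    models: GeneModels,
    outgroup1_seq: str,
    outgroup2_seq: str,
    table: SiteTable,
) -> np.ndarray:
    """Per-site CON/NCON labels for 0-fold sites from two outgroups.

    A 0-fold site is CON when the codon containing it translates to the
    same amino acid in both outgroup sequences, NCON when the amino acids
    differ, and None (unclassified) when either outgroup codon contains
    missing data. Returns an object array over all concatenated sites
    (None outside classified 0-fold sites).
    """
    out = np.full(table.n_sites, None, dtype=object)
    analyzed = {g.gene_id: g for g in models.analyzed()}
    for gid in table.gene_ids:
        if gid not in analyzed:
            continue
        gene = analyzed[gid]
        coords = gene.cds_site_coords()
        cds1 = gene.cds_sequence(outgroup1_seq)
        cds2 = gene.cds_sequence(outgroup2_seq)
        for c0 in range(0, len(coords) - 2, 3):
            codon1 = cds1[c0 : c0 + 3]
            codon2 = cds2[c0 : c0 + 3]
            zero_fold = [
                coords[c0 + p]
                for p in range(3)
                if table.degeneracy[coords[c0 + p]] == 0
            ]
            if not zero_fold:
                continue
            if any(b not in _BASES for b in codon1 + codon2):
                continue
            aa1, aa2 = CODON_TO_AA[codon1], CODON_TO_AA[codon2]
            if aa1 == "*" or aa2 == "*":
                continue
            label = "CON" if aa1 == aa2 else "NCON"
            for c in zero_fold:
                out[c] = label
    return out
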