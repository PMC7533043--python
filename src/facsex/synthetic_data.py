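"""Synthetic datasets with recorded ground truth.

Three generators cover the pipeline's inputs:

- :func:`simulate_population`: a coalescent (msprime) sample from one
  population with given per-bp scaled mutation and recombination rates,
  used to validate the diversity and LD-decay estimators. Partial selfing
  and facultative sex enter through the effective-rate identities
  ``theta = 4 N u / (1 + F)`` and ``rho = 4 N r S (1 - F)``
  (:func:`effective_rates`), so feeding the recorded truth back through
  the frequency-of-sex estimator must recover S.
- :func:`simulate_two_lineages`: two long-diverged in-group populations
  plus two outgroups over an annotated coding genome. Lineage stems carry
  Poisson numbers of fixed differences with per-lineage rate multipliers
  (emulating generation-time differences), strains carry
  latitude-dependent extra terminal-branch mutations, within-population
  polymorphism comes from per-population coalescent samples, and
  mutations at 0-fold sites are thinned by acceptance sampling against a
  gamma distribution of deleterious effects (fixation-probability weights
  for stem mutations, milder sojourn weights for polymorphisms, so
  purifying selection bites harder on fixed than on polymorphic
  differences). Infinite sites: every mutation gets its own site.
- :func:`simulate_sfs`: Poisson sampling of site-frequency spectra from
  the DFE model's own expected spectra, for parameter-recovery tests.

A small forward Wright-Fisher simulator (:func:`forward_wright_fisher`,
N <= 500) cross-validates the coalescent scaling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import msprime
import numpy as np

from .degeneracy_filter import CODON_TO_AA, annotate_degeneracy, build_site_table
from .dfe import SFSPair, StepDemography, expected_sfs
from .io_formats import AlignedGenomes, Gene, GeneModels

__all__ = [
    "SimulationTruth",
    "effective_rates",
    "simulate_population",
    "simulate_two_lineages",
    "simulate_sfs",
    "forward_wright_fisher",
]

_BASES = np.array(["A", "C", "G", "T"])
_NONSTOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


@dataclass
class SimulationTruth:
    """Exact generating parameters and per-strain truth of a simulation."""

    seed: int
    theta_pbp: float = 0.0
    rho_eff_pbp: float = 0.0
    S: float = 0.0
    F: float = 0.0
    u: float = 0.0
    r: float = 0.0
    rate_multipliers: dict = field(default_factory=dict)
    strain_da_intensity: dict = field(default_factory=dict)
    strain_mutation_counts: dict = field(default_factory=dict)
    ancestral_sequence: str = ""
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def effective_rates(u: float, r: float, N: float, F: float, S: float) -> tuple:
    """(theta_pbp, rho_eff_pbp) for a partially selfing facultative sexual.

    theta = 4 N u / (1 + F); rho = 4 N r S (1 - F).
    """
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    if S < 0:
        raise ValueError("S must be >= 0")
    return 4.0 * N * u / (1.0 + F), 4.0 * N * r * S * (1.0 - F)


@dataclass
class PopulationSample:
    """Haplotypes of one coalescent population sample."""

    matrix: np.ndarray  # '<U1' (n, L) character haplotypes
    genotypes: np.ndarray  # uint8 (n, n_variants) derived indicators
    positions: np.ndarray  # int site of each variant
    truth: SimulationTruth
    tree_sequence: object = None


def simulate_population(
    n: int,
    L: int,
    theta_pbp: float,
    rho_eff_pbp: float = 0.0,
    seed: int = 1,
    finite_sites: bool = False,
) -> PopulationSample:
    """Coalescent sample of n haploid genomes over L bp.

    Infinite-sites by default (continuous mutation positions mapped to
    distinct integer sites); ``finite_sites=True`` uses a discrete genome
    where recurrent hits may collide.
    """
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 and L >= 1")
    if theta_pbp < 0 or rho_eff_pbp < 0:
        raise ValueError("rates must be >= 0")
    N = 10_000.0
    mu = theta_pbp / (2.0 * N)
    rr = rho_eff_pbp / (2.0 * N)
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=N,
        sequence_length=L,
        recombination_rate=rr,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=seed + 1,
        discrete_genome=finite_sites,
        model=msprime.BinaryMutationModel(),
    )
    geno = ts.genotype_matrix().T.astype(np.uint8)  # (n, n_variants)
    geno = (geno > 0).astype(np.uint8)
    raw_pos = np.array([s.position for s in ts.sites()])
    if finite_sites:
        pos = raw_pos.astype(int)
    else:
        pos = np.floor(raw_pos).astype(int)
        # infinite sites on an integer grid: push collisions to free sites
        used = set()
        out = []
        for p in pos:
            q = int(p)
            while q in used and q < L - 1:
                q += 1
            while q in used and q > 0:
                q -= 1
            used.add(q)
            out.append(q)
        order = np.argsort(out)
        pos = np.array(out)[order]
        geno = geno[:, order]
    matrix = np.full((n, L), "A", dtype="<U1")
    for j, p in enumerate(pos):
        matrix[geno[:, j] == 1, p] = "G"
    truth = SimulationTruth(
        seed=seed,
        theta_pbp=theta_pbp,
        rho_eff_pbp=rho_eff_pbp,
        extra={"n": n, "L": L, "finite_sites": finite_sites},
    )
    return PopulationSample(
        matrix=matrix, genotypes=geno, positions=pos, truth=truth, tree_sequence=ts
    )


# ---------------------------------------------------------------------------
# two-lineage genome simulator
# ---------------------------------------------------------------------------

def _random_gene_seq(rng, n_codons: int) -> str:
    codons = ["ATG"] + [
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
    ] + ["TAA"]
    return "".join(codons)


def _fixation_weight(gamma: np.ndarray) -> np.ndarray:
    """Relative fixation probability of a deleterious scaled effect."""
    g = np.asarray(gamma, dtype=float)
    with np.errstate(over="ignore"):
        w = np.where(g < 1e-8, 1.0, g / np.expm1(np.minimum(g, 500.0)))
    return w


def _sojourn_weight(gamma: np.ndarray) -> np.ndarray:
    """Relative chance a deleterious mutation is seen segregating.

    Milder than the fixation weight for every gamma, so selection removes
    proportionally more fixed than polymorphic differences.
    """
    g = np.asarray(gamma, dtype=float)
    return np.where(g < 1e-8, 1.0, 2.0 * (-np.expm1(-g / 2.0)) / g)


def _mutate_base(rng, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


@dataclass
class TwoLineageDataset:
    genomes: AlignedGenomes
    models: GeneModels
    truth: SimulationTruth
    site_table: object  # ground-truth SiteTable from the true ancestor


def simulate_two_lineages(
    n_a: int = 23,
    n_b: int = 8,
    seed: int = 1,
    n_chromosomes: int = 3,
    genes_per_chromosome: int = 12,
    codons_per_gene: int = 200,
    intergenic_length: int = 60,
    stem_divergence: float = 0.012,
    rate_multiplier_a: float = 1.19,
    rate_multiplier_b: float = 1.0,
    outgroup_divergence: float = 0.05,
    outgroup2_divergence: float = 0.10,
    theta_a: float = 0.002,
    theta_b: float = 0.001,
    latitude_effect: float = 0.0,
    latitudes_a: np.ndarray | None = None,
    dfe_shape: float = 0.23,
    dfe_mean: float = 300.0,
    pop_a: str = "EU",
    pop_b: str = "FE",
) -> TwoLineageDataset:
    """Two diverged lineages + two outgroups over an annotated genome.

    ``stem_divergence`` is the expected per-neutral-bp fixed divergence of
    each lineage stem before the per-lineage rate multipliers;
    ``latitude_effect`` adds ``latitude_effect * (lat_ref - lat_i)``
    expected extra private mutations per neutral bp on strain i's terminal
    branch (lat_ref = max latitude), producing more derived alleles in
    southern strains. Defaults follow the study conditions the pipeline is
    built for: 23 vs. 8 strains, ~1.2x faster stem in lineage A, ~2x
    higher polymorphism in lineage A, and a leptokurtic gamma DFE at
    0-fold sites. Infinite sites throughout (disjoint site draws), so the
    true ancestor is recoverable wherever polarization can resolve it.
    """
    rng = np.random.default_rng(seed)

    # ancestral annotated genome
    chrom_map = []
    genes = []
    anc_parts = []
    pos = 0
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        chrom_start = pos
        for gi in range(genes_per_chromosome):
            spacer = "".join(_BASES[rng.integers(0, 4, intergenic_length)])
            anc_parts.append(spacer)
            pos += intergenic_length
            gene_seq = _random_gene_seq(rng, codons_per_gene)
            genes.append(
                Gene(
                    gene_id=f"{chrom}_g{gi + 1}",
                    chrom=chrom,
                    strand="+",
                    spans=[(pos, pos + len(gene_seq))],
                )
            )
            anc_parts.append(gene_seq)
            pos += len(gene_seq)
        tail = "".join(_BASES[rng.integers(0, 4, intergenic_length)])
        anc_parts.append(tail)
        pos += intergenic_length
        chrom_map.append((chrom, chrom_start, pos))
    ancestral = "".join(anc_parts)
    L = len(ancestral)
    models = GeneModels(genes=genes)

    # ground-truth site classes from the true ancestor
    strain_ids_a = [f"{pop_a}_{i + 1:02d}" for i in range(n_a)]
    strain_ids_b = [f"{pop_b}_{i + 1:02d}" for i in range(n_b)]
    all_ids = strain_ids_a + strain_ids_b + ["NA_OUT", "SC_OUT"]
    population = {s: pop_a for s in strain_ids_a}
    population.update({s: pop_b for s in strain_ids_b})
    population["NA_OUT"] = "OUTGROUP_NA"
    population["SC_OUT"] = "OUTGROUP_SC"

    probe = AlignedGenomes(
        matrix=np.tile(np.frombuffer(ancestral.encode(), "S1").astype("<U1"), (len(all_ids), 1)),
        strain_ids=all_ids,
        population=population,
        chrom_map=chrom_map,
    )
    table = build_site_table(probe, models)
    table = annotate_degeneracy(ancestral, models, table)
    is_zero_fold = table.degeneracy == 0
    neutral_like = ~is_zero_fold  # 2/4-fold and noncoding mutate unthinned

    available = np.ones(L, dtype=bool)

    def draw_sites(rate: float, thin: str | None) -> np.ndarray:
        """Bernoulli site draws at `rate`, DFE-thinned at 0-fold sites."""
        p = np.where(available, rate, 0.0)
        hit = rng.random(L) < p
        idx = np.flatnonzero(hit)
        if thin is not None and idx.size:
            zf = is_zero_fold[idx]
            if zf.any():
                gammas = rng.gamma(dfe_shape, dfe_mean / dfe_shape, size=int(zf.sum()))
                w = _fixation_weight(gammas) if thin == "fixed" else _sojourn_weight(gammas)
                keep_zf = rng.random(int(zf.sum())) < w
                keep = np.ones(idx.size, dtype=bool)
                keep[zf] = keep_zf
                idx = idx[keep]
        available[idx] = False
        return idx

    anc_arr = np.frombuffer(ancestral.encode(), "S1").astype("<U1")

    def mutated_copy(base_arr, sites):
        arr = base_arr.copy()
        for s in sites:
            arr[s] = _mutate_base(rng, arr[s])
        return arr

    # outgroups: divergence from the ancestor (no polarity role for SC)
    out1_sites = draw_sites(outgroup_divergence, "fixed")
    out2_sites = draw_sites(outgroup2_divergence, "fixed")
    out1 = mutated_copy(anc_arr, out1_sites)
    out2 = mutated_copy(anc_arr, out2_sites)

    # lineage stems: fixed differences, per-lineage rate multipliers
    stem_a_sites = draw_sites(stem_divergence * rate_multiplier_a, "fixed")
    stem_b_sites = draw_sites(stem_divergence * rate_multiplier_b, "fixed")
    founder_a = mutated_copy(anc_arr, stem_a_sites)
    founder_b = mutated_copy(anc_arr, stem_b_sites)

    # within-population polymorphism via per-population coalescent samples
    def population_polymorphism(n_strains, theta, pop_seed):
        ts = msprime.sim_ancestry(
            samples=n_strains, ploidy=1, population_size=10_000.0,
            sequence_length=L, random_seed=pop_seed,
        )
        ts = msprime.sim_mutations(
            ts, rate=theta / (2.0 * 10_000.0), random_seed=pop_seed + 1,
            discrete_genome=False, model=msprime.BinaryMutationModel(),
        )
        geno = (ts.genotype_matrix().T > 0).astype(np.uint8)
        placed = []
        for j in range(geno.shape[1]):
            free = np.flatnonzero(available)
            if free.size == 0:
                break
            site = int(free[rng.integers(0, free.size)])
            if is_zero_fold[site]:
                g = rng.gamma(dfe_shape, dfe_mean / dfe_shape)
                if rng.random() >= _sojourn_weight(np.array([g]))[0]:
                    continue
            available[site] = False
            placed.append((site, geno[:, j]))
        return placed

    # msprime requires 0 < seed < 2^32; derive child seeds via the rng
    seed_a = int(rng.integers(1, 2**31 - 2))
    seed_b = int(rng.integers(1, 2**31 - 2))
    poly_a = population_polymorphism(n_a, theta_a, seed_a)
    poly_b = population_polymorphism(n_b, theta_b, seed_b)

    # latitude-dependent terminal-branch extras (population A only)
    if latitudes_a is None:
        latitudes_a = np.linspace(36.0, 55.0, n_a)
    latitudes_a = np.asarray(latitudes_a, dtype=float)
    lat_ref = float(latitudes_a.max())
    extra_counts = rng.poisson(
        latitude_effect * (lat_ref - latitudes_a) * L
    )
    extra_sites = {i: draw_sites_count(rng, available, int(c)) for i, c in enumerate(extra_counts)}

    # assemble strain sequences and truth counts
    rows = []
    strain_counts = {}
    for i, sid in enumerate(strain_ids_a):
        arr = founder_a.copy()
        cnt = len(stem_a_sites)
        cnt += sum(1 for _, carriers in poly_a if carriers[i])
        for site in extra_sites[i]:
            arr[site] = _mutate_base(rng, arr[site])
            cnt += 1
        rows.append(arr)
        strain_counts[sid] = cnt
    for i, sid in enumerate(strain_ids_b):
        rows.append(founder_b.copy())
        strain_counts[sid] = len(stem_b_sites) + sum(
            1 for _, carriers in poly_b if carriers[i]
        )
    rows.append(out1)
    rows.append(out2)
    matrix = np.vstack(rows)

    # derived alleles must be consistent within a site: carriers share one base
    for site, carriers in poly_a:
        d = _mutate_base(rng, anc_arr[site])
        for i in np.flatnonzero(carriers):
            matrix[i, site] = d
    for site, carriers in poly_b:
        d = _mutate_base(rng, anc_arr[site])
        for i in np.flatnonzero(carriers):
            matrix[n_a + i, site] = d

    subgroup = {s: None for s in all_ids}
    for s in strain_ids_a[: max(2, n_a // 4)]:
        subgroup[s] = "Chernobyl"
    latitude = {s: None for s in all_ids}
    for i, s in enumerate(strain_ids_a):
        latitude[s] = float(latitudes_a[i])

    genomes = AlignedGenomes(
        matrix=matrix,
        strain_ids=all_ids,
        population=population,
        subgroup=subgroup,
        latitude=latitude,
        chrom_map=chrom_map,
    )
    truth = SimulationTruth(
        seed=seed,
        theta_pbp=theta_a,
        rate_multipliers={pop_a: rate_multiplier_a, pop_b: rate_multiplier_b},
        strain_da_intensity={
            s: float(latitude_effect * (lat_ref - latitudes_a[i]))
            for i, s in enumerate(strain_ids_a)
        },
        strain_mutation_counts={k: int(v) for k, v in strain_counts.items()},
        ancestral_sequence=ancestral,
        extra={
            "n_a": n_a,
            "n_b": n_b,
            "stem_divergence": stem_divergence,
            "dfe_shape": dfe_shape,
            "dfe_mean": dfe_mean,
            "theta_b": theta_b,
            "latitude_effect": latitude_effect,
            "n_stem_a": int(len(stem_a_sites)),
            "n_stem_b": int(len(stem_b_sites)),
        },
    )
    return TwoLineageDataset(genomes=genomes, models=models, truth=truth, site_table=table)


def draw_sites_count(rng, available: np.ndarray, count: int) -> np.ndarray:
    """Claim `count` previously unused sites uniformly at random."""
    free = np.flatnonzero(available)
    count = min(count, free.size)
    idx = rng.choice(free, size=count, replace=False) if count else np.empty(0, int)
    available[idx] = False
    return idx


def simulate_sfs(
    demography: StepDemography,
    n: int,
    site_totals: tuple,
    dfe: tuple | None = None,
    seed: int = 1,
    theta_site: float = 0.01,
    k1: int = 100,
) -> tuple:
    """Poisson-sampled SFS pair from the model's expected spectra.

    ``site_totals`` is (neutral_sites, selected_sites); ``dfe`` is None or
    (shape, mean 4*Ne*Sd) applied to the selected class only.
    """
    rng = np.random.default_rng(seed)
    n_neutral, n_selected = site_totals

    def draw(total, selection):
        if total == 0:
            return np.zeros(n + 1)
        p = expected_sfs(demography, n, selection=selection, theta_site=theta_site, k1=k1)
        counts = rng.poisson(p[1:] * total)
        return np.concatenate([[total - counts.sum()], counts]).astype(float)

    neutral = draw(n_neutral, None)
    selected = draw(n_selected, dfe)
    truth = SimulationTruth(
        seed=seed,
        theta_pbp=theta_site,
        extra={
            "demography_ratio": demography.ratio,
            "demography_t2": demography.t2,
            "dfe": list(dfe) if dfe else None,
            "site_totals": [int(n_neutral), int(n_selected)],
            "n": n,
        },
    )
    return SFSPair(n=n, neutral=neutral, selected=selected), truth


def forward_wright_fisher(
    N: int,
    L: int,
    u: float,
    generations: int | None = None,
    n_sample: int = 20,
    selfing: float = 0.0,
    seed: int = 1,
) -> np.ndarray:
    """Small forward haploid Wright-Fisher simulation (cross-validation).

    Returns an (n_sample, L) 0/1 matrix after ``generations`` (default
    8N) of neutral evolution with per-site mutation probability u per
    generation (0 <-> 1 flips). ``selfing`` is accepted for signature
    symmetry but has no effect in a haploid model.
    """
    if N > 500:
        raise ValueError("forward mode is for N <= 500")
    rng = np.random.default_rng(seed)
    gens = generations or 8 * N
    popm = np.zeros((N, L), dtype=np.uint8)
    for _ in range(gens):
        parents = rng.integers(0, N, size=N)
        popm = popm[parents]
        n_mut = rng.poisson(N * L * u)
        if n_mut:
            ri = rng.integers(0, N, size=n_mut)
            rj = rng.integers(0, L, size=n_mut)
            popm[ri, rj] ^= 1
    sample = popm[rng.choice(N, size=min(n_sample, N), replace=False)]
    return sample
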