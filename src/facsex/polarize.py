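"""Ancestral vs. derived allele assignment with a two-tier outgroup rule.

For each complete site, alleles are polarized as follows:

1. one population polymorphic, the other monomorphic: the monomorphic
   population serves as outgroup; its allele is ancestral if it is present
   among the polymorphic population's alleles, otherwise the site is
   ``missing``;
2. both populations monomorphic but different (a fixed difference): the
   designated distant outgroup (e.g. the North American lineage) decides —
   its allele is ancestral if it matches one of the two, else ``missing``;
3. both monomorphic and identical: monomorphic, no derived allele;
4. both polymorphic (a shared polymorphism, which phylogenetically
   independent sister lineages should not show) or more than two alleles:
   the distant outgroup is consulted; if its allele segregates in *both*
   populations it is taken as ancestral, otherwise the site is ``missing``.

Derived-allele (DA) carriers are the strains not carrying the ancestral
allele; a fixed difference makes every strain of the derived population a
carrier. The collection of polarized sites yields the inferred common
ancestral sequence and the strains x sites binary derived-allele matrix
used by every downstream divergence analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degeneracy_filter import SiteTable
from .io_formats import AlignedGenomes

__all__ = [
    "PolarizedSite",
    "DerivedMatrix",
    "polarize_site",
    "polarize_all",
    "build_ancestral_sequence",
    "build_derived_matrix",
]

STATUS_MONO = "monomorphic"
STATUS_POLY_A = "polymorphic_popA"
STATUS_POLY_B = "polymorphic_popB"
STATUS_POLY_BOTH = "polymorphic_both"
STATUS_FIXED = "fixed_difference"
STATUS_MISSING = "missing"


@dataclass
class PolarizedSite:
    coord: int
    status: str
    ancestral: str | None
    derived: tuple = ()
    carriers_a: tuple = ()  # strain indices within popA sample order
    carriers_b: tuple = ()

    def __post_init__(self) -> None:
        if self.status == STATUS_MISSING and (self.carriers_a or self.carriers_b):
            raise ValueError("missing-status site cannot record carriers")


def polarize_site(
    popA_alleles,
    popB_alleles,
    na_allele: str,
    coord: int = -1,
) -> PolarizedSite:
    """Polarize one complete site given the sampled alleles of each population.

    ``popA_alleles`` / ``popB_alleles`` are sequences of bases (one per
    strain, sample order preserved for carrier indices); ``na_allele`` is
    the distant outgroup base.
    """
    a = list(popA_alleles)
    b = list(popB_alleles)
    if not a or not b:
        raise ValueError("allele multisets must be non-empty")
    set_a, set_b = set(a), set(b)
    poly_a, poly_b = len(set_a) > 1, len(set_b) > 1

    def carriers(alleles, ancestral):
        return tuple(i for i, al in enumerate(alleles) if al != ancestral)

    def resolved(status, ancestral):
        derived = tuple(sorted((set_a | set_b) - {ancestral}))
        return PolarizedSite(
            coord=coord,
            status=status,
            ancestral=ancestral,
            derived=derived,
            carriers_a=carriers(a, ancestral),
            carriers_b=carriers(b, ancestral),
        )

    missing = PolarizedSite(coord=coord, status=STATUS_MISSING, ancestral=None)

    if len(set_a | set_b) > 2 or (poly_a and poly_b):
        # shared polymorphism or >2 alleles: outgroup tie-break before discarding
        if na_allele in set_a and na_allele in set_b:
            return resolved(STATUS_POLY_BOTH, na_allele)
        return missing
    if poly_a and not poly_b:
        anc = next(iter(set_b))
        if anc in set_a:
            return resolved(STATUS_POLY_A, anc)
        return missing
    if poly_b and not poly_a:
        anc = next(iter(set_a))
        if anc in set_b:
            return resolved(STATUS_POLY_B, anc)
        return missing
    # both monomorphic
    al_a, al_b = next(iter(set_a)), next(iter(set_b))
    if al_a == al_b:
        return PolarizedSite(coord=coord, status=STATUS_MONO, ancestral=al_a)
    if na_allele == al_a or na_allele == al_b:
        return resolved(STATUS_FIXED, na_allele)
    return missing


def polarize_all(
    genomes: AlignedGenomes,
    table: SiteTable,
    pop_a: str,
    pop_b: str,
    na_population: str = "OUTGROUP_NA",
) -> list:
    """Polarize every complete site of the alignment.

    Returns a list of :class:`PolarizedSite` (one per complete site, in
    coordinate order). Carrier indices refer to the sample order of each
    population's rows as returned by ``rows_for_population``.
    """
    rows_a = genomes.rows_for_population(pop_a)
    rows_b = genomes.rows_for_population(pop_b)
    rows_na = genomes.rows_for_population(na_population)
    if len(rows_na) != 1:
        raise ValueError(f"expected exactly one {na_population} sequence")
    na_row = rows_na[0]

    out = []
    coords = np.flatnonzero(table.complete)
    m = genomes.matrix
    for c in coords:
        out.append(
            polarize_site(m[rows_a, c], m[rows_b, c], m[na_row, c], coord=int(c))
        )
    return out


def build_ancestral_sequence(polarized, genomes: AlignedGenomes) -> str:
    """Common ancestral sequence of the two populations.

    Resolved sites carry the inferred ancestral base, monomorphic sites the
    shared allele, and missing-status or incomplete sites 'N'.
    """
    seq = np.full(genomes.n_sites, "N", dtype="<U1")
    for site in polarized:
        if site.ancestral is not None:
            seq[site.coord] = site.ancestral
    return "".join(seq)


@dataclass
class DerivedMatrix:
    """Binary strains x sites derived-allele matrix over resolved sites.

    Rows follow ``strain_ids`` (popA strains then popB strains); columns
    are the complete sites whose polarization did not end ``missing``,
    identified by ``site_coords`` on the concatenated axis.
    """

    matrix: np.ndarray  # uint8 (n_strains, n_resolved_sites)
    strain_ids: list
    population: dict  # strain -> pop label
    site_coords: np.ndarray  # int64
    status: np.ndarray = field(default=None)  # object, per column

    def rows_for_population(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.strain_ids) if self.population[s] == population]
        if not idx:
            raise KeyError(f"no strains in population {population!r}")
        return np.asarray(idx, dtype=int)

    def strain_totals(self, population: str | None = None) -> pd.Series:
        rows = (
            np.arange(len(self.strain_ids))
            if population is None
            else self.rows_for_population(population)
        )
        return pd.Series(
            self.matrix[rows].sum(axis=1),
            index=[self.strain_ids[i] for i in rows],
            name="derived_alleles",
        )

    def derived_counts(self, population: str) -> np.ndarray:
        """Per-site derived carrier count within a population."""
        return self.matrix[self.rows_for_population(population)].sum(axis=0)


def build_derived_matrix(
    polarized,
    genomes: AlignedGenomes,
    pop_a: str,
    pop_b: str,
) -> DerivedMatrix:
    """Assemble the derived-allele matrix from polarized sites.

    Columns exist only for resolved (non-missing, non-monomorphic-only)
    polarization outcomes; monomorphic sites are included as all-zero
    columns only if they are resolved (they are, trivially, with zero
    carriers) — they are skipped to keep the matrix sparse in sites.
    """
    rows_a = genomes.rows_for_population(pop_a)
    rows_b = genomes.rows_for_population(pop_b)
    strain_ids = [genomes.strain_ids[i] for i in rows_a] + [
        genomes.strain_ids[i] for i in rows_b
    ]
    n_a = len(rows_a)
    keep = [
        s for s in polarized if s.status not in (STATUS_MISSING, STATUS_MONO)
    ]
    mat = np.zeros((len(strain_ids), len(keep)), dtype=np.uint8)
    coords = np.empty(len(keep), dtype=np.int64)
    status = np.empty(len(keep), dtype=object)
    for j, site in enumerate(keep):
        coords[j] = site.coord
        status[j] = site.status
        for i in site.carriers_a:
            mat[i, j] = 1
        for i in site.carriers_b:
            mat[n_a + i, j] = 1
    population = {s: genomes.population[s] for s in strain_ids}
    return DerivedMatrix(
        matrix=mat,
        strain_ids=strain_ids,
        population=population,
        site_coords=coords,
        status=status,
    )


def polarized_to_frame(polarized) -> pd.DataFrame:
    """TSV-ready table of polarization outcomes."""
    return pd.DataFrame(
        {
            "coordinate": [s.coord for s in polarized],
            "status": [s.status for s in polarized],
            "ancestral": [s.ancestral or "N" for s in polarized],
            "derived": ["/".join(s.derived) for s in polarized],
            "n_carriers_popA": [len(s.carriers_a) for s in polarized],
            "n_carriers_popB": [len(s.carriers_b) for s in polarized],
        }
    )
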