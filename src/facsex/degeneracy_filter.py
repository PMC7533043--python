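"""Gene and site filters, codon-position and degeneracy annotation.

The analysis uses only unambiguous genes: paralogous gene pairs are removed
by a deterministic pairwise similarity screen (k-mer prefilter plus global
alignment identity), and only "core" (non-subtelomeric) genes are kept.
Sites enter the statistics only when complete, i.e. no strain in either
in-group population and neither outgroup has a gap or N.

Degeneracy (0-, 2- or 4-fold) is assigned from the inferred common
ancestral sequence of the two in-group populations: for each coding
position, the other two codon positions are held at their ancestral state
and the number of bases encoding the same amino acid under the standard
genetic code is counted (1 -> 0-fold, 2 or 3 -> 2-fold, 4 -> 4-fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import AlignedGenomes, Gene, GeneModels

__all__ = [
    "SiteTable",
    "CODON_TO_AA",
    "dedupe_genes",
    "build_site_table",
    "annotate_degeneracy",
    "filter_complete_sites",
    "codon_degeneracy",
]

_BASES = ("A", "C", "G", "T")

# codon -> amino acid (stop = '*') under the standard code
_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

# degeneracy codes in SiteTable.degeneracy
DEG_NONCODING = -1
DEG_UNCLASSIFIED = -2


def codon_degeneracy(codon: str, position: int) -> int:
    """Fold class (0, 2 or 4) of ``position`` (0-based) within ``codon``.

    Counts how many of the four bases at that position leave the amino acid
    unchanged with the other two positions fixed; 1 synonymous base is
    0-fold, 2 or 3 are grouped as 2-fold, 4 is 4-fold.
    """
    codon = codon.upper()
    if any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous codon {codon!r}")
    aa = CODON_TO_AA[codon]
    n_same = 0
    for b in _BASES:
        alt = codon[:position] + b + codon[position + 1 :]
        if CODON_TO_AA[alt] == aa:
            n_same += 1
    return {1: 0, 2: 2, 3: 2, 4: 4}[n_same]


@dataclass
class SiteTable:
    """Per-site annotation over the concatenated alignment.

    Arrays all have length ``n_sites``:

    - ``gene_index``: index into ``gene_ids`` or -1 (not in a retained gene)
    - ``codon_position``: 1..3 within the codon in translation order, 0 outside CDS
    - ``degeneracy``: 0/2/4 fold, -1 noncoding, -2 unclassified
    - ``complete``: no missing data in any in-group strain or outgroup
    - ``ancestral``: inferred ancestral base, 'N' where unresolved
    """

    chrom: np.ndarray  # object, per-site chromosome id
    gene_index: np.ndarray  # int32
    codon_position: np.ndarray  # int8
    degeneracy: np.ndarray  # int8
    complete: np.ndarray  # bool
    ancestral: np.ndarray  # '<U1'
    gene_ids: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.gene_index)

    def class_mask(self, site_class: str) -> np.ndarray:
        """Boolean mask of sites in a degeneracy class.

        ``site_class`` is one of ``'0fold'``, ``'2fold'``, ``'4fold'``,
        ``'all-coding'`` (any classified coding site) or ``'all'``.
        """
        d = self.degeneracy
        if site_class == "0fold":
            return d == 0
        if site_class == "2fold":
            return d == 2
        if site_class == "4fold":
            return d == 4
        if site_class == "all-coding":
            return d >= 0
        if site_class == "all":
            return np.ones(self.n_sites, dtype=bool)
        raise ValueError(f"unknown site class {site_class!r}")

    def to_frame(self) -> pd.DataFrame:
        gene = np.array(
            [self.gene_ids[i] if i >= 0 else "" for i in self.gene_index], dtype=object
        )
        deg = np.array(
            [
                {0: "0fold", 2: "2fold", 4: "4fold", DEG_NONCODING: "noncoding",
                 DEG_UNCLASSIFIED: "unclassified"}[int(v)]
                for v in self.degeneracy
            ],
            dtype=object,
        )
        return pd.DataFrame(
            {
                "coordinate": np.arange(self.n_sites),
                "chromosome": self.chrom,
                "gene_id": gene,
                "codon_position": self.codon_position,
                "degeneracy": deg,
                "complete": self.complete,
                "ancestral": self.ancestral,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene dedupe
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dedupe_genes(
    models: GeneModels,
    reference_sequence: str,
    identity_threshold: float = 0.8,
    min_hit_length: int = 100,
    prefilter_k: int = 11,
) -> GeneModels:
    """Flag genes with a significant match to another gene as not retained.

    A pair of genes is a significant match when both coding sequences are at
    least ``min_hit_length`` bp and their global alignment identity
    (1 - edit_distance / longer_length, via edlib) is at least
    ``identity_threshold``. A shared-k-mer prefilter skips obviously
    unrelated pairs. Both members of a matching pair are dropped, mirroring
    an all-against-all screen where duplicates hit each other.
    """
    import edlib

    genes = list(models.genes)
    seqs = [g.cds_sequence(reference_sequence) for g in genes]
    kmer_sets = [_kmers(s, prefilter_k) for s in seqs]
    matched = [False] * len(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if min(len(seqs[i]), len(seqs[j])) < min_hit_length:
                continue
            if not (kmer_sets[i] & kmer_sets[j]):
                continue
            res = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")
            identity = 1.0 - res["editDistance"] / max(len(seqs[i]), len(seqs[j]))
            if identity >= identity_threshold:
                matched[i] = matched[j] = True
    retained = 0
    out = []
    for g, hit in zip(genes, matched):
        g2 = Gene(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            spans=list(g.spans),
            core_flag=g.core_flag,
            retained_flag=not hit,
            valid=g.valid,
        )
        retained += g2.retained_flag
        out.append(g2)
    if retained == 0:
        warnings.warn("similarity screen retained zero genes", stacklevel=2)
    return GeneModels(genes=out)


# ---------------------------------------------------------------------------
# site table construction
# ---------------------------------------------------------------------------

def build_site_table(genomes: AlignedGenomes, models: GeneModels) -> SiteTable:
    """Structural annotation: gene membership and codon position.

    Only analyzed genes (valid + core + retained) claim sites; a site may
    belong to at most one such gene (overlapping claims raise).  Degeneracy
    is left unclassified until :func:`annotate_degeneracy` is called with
    the ancestral sequence, and completeness until
    :func:`filter_complete_sites`.
    """
    n = genomes.n_sites
    gene_index = np.full(n, -1, dtype=np.int32)
    codon_position = np.zeros(n, dtype=np.int8)
    analyzed = models.analyzed()
    gene_ids = [g.gene_id for g in analyzed]
    for gi, gene in enumerate(analyzed):
        coords = gene.cds_site_coords()
        if (gene_index[coords] != -1).any():
            raise ValueError(f"gene {gene.gene_id} overlaps another retained gene")
        gene_index[coords] = gi
        codon_position[coords] = (np.arange(len(coords)) % 3) + 1
    return SiteTable(
        chrom=genomes.site_chromosome(),
        gene_index=gene_index,
        codon_position=codon_position,
        degeneracy=np.full(n, DEG_NONCODING, dtype=np.int8),
        complete=np.zeros(n, dtype=bool),
        ancestral=np.full(n, "N", dtype="<U1"),
        gene_ids=gene_ids,
    )


def annotate_degeneracy(
    ancestral_sequence,
    models: GeneModels,
    table: SiteTable,
) -> SiteTable:
    """Fill codon degeneracy from the ancestral sequence.

    For each analyzed gene the ancestral CDS is read in translation order;
    every position gets the fold class of its ancestral codon. Codons with
    missing ancestral bases are unclassified; a gene whose ancestral frame
    contains an internal stop codon is logged and dropped from the table.
    """
    anc = "".join(ancestral_sequence) if not isinstance(ancestral_sequence, str) else ancestral_sequence
    if len(anc) != table.n_sites:
        raise ValueError("ancestral sequence length does not match site table")
    table.ancestral = np.frombuffer(anc.upper().encode("ascii"), dtype="S1").astype("<U1")
    deg = table.degeneracy
    deg[:] = DEG_NONCODING

    analyzed = models.analyzed()
    id_to_gene = {g.gene_id: g for g in analyzed}
    for gi, gid in enumerate(table.gene_ids):
        gene = id_to_gene[gid]
        coords = gene.cds_site_coords()
        cds = gene.cds_sequence(anc)
        drop = False
        for c0 in range(0, len(cds) - 2, 3):
            codon = cds[c0 : c0 + 3]
            if any(b not in _BASES for b in codon):
                deg[coords[c0 : c0 + 3]] = DEG_UNCLASSIFIED
                continue
            if CODON_TO_AA[codon] == "*" and c0 < len(cds) - 3:
                drop = True
                break
        if drop:
            warnings.warn(
                f"gene {gid}: internal stop codon in ancestral frame; excluded",
                stacklevel=2,
            )
            deg[coords] = DEG_NONCODING
            table.gene_index[coords] = -1
            table.codon_position[coords] = 0
            continue
        for c0 in range(0, len(cds) - 2, 3):
            codon = cds[c0 : c0 + 3]
            if any(b not in _BASES for b in codon):
                continue
            if CODON_TO_AA[codon] == "*":  # terminal stop: positions unclassified
                deg[coords[c0 : c0 + 3]] = DEG_UNCLASSIFIED
                continue
            for p in range(3):
                deg[coords[c0 + p]] = codon_degeneracy(codon, p)
    return table


def filter_complete_sites(table: SiteTable, genomes: AlignedGenomes) -> SiteTable:
    """Mark sites with no missing data in any strain or outgroup row.

    Gap ('-') and 'N' both count as missing. All rows of the alignment
    (in-group strains of both populations and the outgroups) must carry a
    proper base for the site to be complete.
    """
    m = genomes.matrix
    table.complete = ~((m == "-") | (m == "N")).any(axis=0)
    return table


def complete_site_counts(table: SiteTable, classes=("0fold", "4fold")) -> dict:
    """Number of complete sites per degeneracy class (reporting helper)."""
    return {c: int((table.class_mask(c) & table.complete).sum()) for c in classes}
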