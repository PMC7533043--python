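"""Reading and writing the external formats of the pipeline.

A dataset is a per-chromosome set of multiple-alignment FASTA files (every
file contains the same strains, including outgroup rows), a strain metadata
TSV (``strain_id  population  subgroup  latitude``), a GFF3 gene annotation
on the in-group reference coordinates, and optionally per-chromosome
population recombination-rate (4*Ne*r) summaries from LDhat runs.

Internally all coordinates are 0-based half-open over the *concatenated*
genome; GFF3's 1-based inclusive convention is converted at the boundary.
Chromosome structure is kept in an ordered ``chrom_map`` of half-open spans
that tile the concatenated coordinate axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignedGenomes",
    "Gene",
    "GeneModels",
    "RhoImport",
    "AlignmentError",
    "MetadataError",
    "LdhatFormatError",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "read_gene_models",
    "import_ldhat",
]

#: population labels treated as outgroup rows
OUTGROUP_PREFIX = "OUTGROUP"

_VALID = set("ACGT-N")


class AlignmentError(ValueError):
    """Raised when alignment files are internally inconsistent."""


class MetadataError(ValueError):
    """Raised when the metadata TSV does not cover the alignment."""


class LdhatFormatError(ValueError):
    """Raised when an LDhat summary file cannot be parsed."""


@dataclass
class AlignedGenomes:
    """Strains x sites character matrix with chromosome coordinate map.

    ``matrix`` holds single characters from {A, C, G, T, -, N}; gap and N are
    both treated as missing data downstream but preserved distinctly here.
    Outgroup rows are ordinary rows whose population label starts with
    ``OUTGROUP`` (e.g. ``OUTGROUP_NA``, ``OUTGROUP_SC``).
    """

    matrix: np.ndarray  # dtype '<U1', shape (n_strains, n_sites)
    strain_ids: list
    population: dict
    subgroup: dict = field(default_factory=dict)
    latitude: dict = field(default_factory=dict)
    chrom_map: list = field(default_factory=list)  # [(chrom_id, start, end)]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.strain_ids) != self.matrix.shape[0]:
            raise AlignmentError("strain_ids length does not match matrix rows")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise AlignmentError("duplicate strain ids")
        missing = [s for s in self.strain_ids if s not in self.population]
        if missing:
            raise MetadataError(f"strains without population label: {missing}")
        total = sum(end - start for _, start, end in self.chrom_map)
        if self.chrom_map and total != self.n_sites:
            raise AlignmentError(
                f"chrom_map covers {total} sites but matrix has {self.n_sites}"
            )
        pos = 0
        for chrom, start, end in self.chrom_map:
            if start != pos or end <= start:
                raise AlignmentError("chrom_map spans must be ordered, disjoint and tiling")
            pos = end

    # -- basic queries ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def ingroup_ids(self) -> list:
        return [s for s in self.strain_ids if not self.population[s].startswith(OUTGROUP_PREFIX)]

    @property
    def outgroup_ids(self) -> list:
        return [s for s in self.strain_ids if self.population[s].startswith(OUTGROUP_PREFIX)]

    def row_index(self, strain_id: str) -> int:
        return self.strain_ids.index(strain_id)

    def rows_for_population(self, population: str) -> np.ndarray:
        """Row indices of all strains with this population label."""
        idx = [i for i, s in enumerate(self.strain_ids) if self.population[s] == population]
        if not idx:
            raise KeyError(f"no strains with population label {population!r}")
        return np.asarray(idx, dtype=int)

    def sequence(self, strain_id: str) -> str:
        return "".join(self.matrix[self.row_index(strain_id)])

    def chrom_span(self, chrom_id: str) -> tuple:
        for chrom, start, end in self.chrom_map:
            if chrom == chrom_id:
                return start, end
        raise KeyError(f"unknown chromosome {chrom_id!r}")

    def chromosomes(self) -> list:
        return [c for c, _, _ in self.chrom_map]

    def site_chromosome(self) -> np.ndarray:
        """Chromosome id per concatenated site (object array)."""
        out = np.empty(self.n_sites, dtype=object)
        for chrom, start, end in self.chrom_map:
            out[start:end] = chrom
        return out


@dataclass
class Gene:
    """A protein-coding gene model on concatenated coordinates.

    ``spans`` are 0-based half-open (start, end) CDS intervals stored in
    genomic order; for minus-strand genes the coding sequence is the
    reverse complement of the concatenated spans read right to left.
    """

    gene_id: str
    chrom: str
    strand: str
    spans: list  # [(start, end)] concatenated coords, genomic order
    core_flag: bool = True
    retained_flag: bool = True
    valid: bool = True

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.spans)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    def cds_sequence(self, concatenated: str) -> str:
        """Extract the coding sequence in translation order."""
        parts = [concatenated[s:e] for s, e in self.spans]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_site_coords(self) -> np.ndarray:
        """Concatenated coordinates of CDS sites in translation order."""
        coords = np.concatenate([np.arange(s, e) for s, e in self.spans])
        if self.strand == "-":
            coords = coords[::-1]
        return coords


@dataclass
class GeneModels:
    genes: list

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def analyzed(self) -> list:
        """Genes that pass every filter: valid, core, retained."""
        return [g for g in self.genes if g.valid and g.core_flag and g.retained_flag]

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class RhoImport:
    """One LDhat-style genome-wide 4*Ne*r estimate for one chromosome run."""

    chrom: str
    rho_4ner: float
    run_id: int = 0
    n_sites: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho_4ner) or self.rho_4ner < 0:
            raise LdhatFormatError(
                f"4Ner must be finite and >= 0, got {self.rho_4ner} for {self.chrom}"
            )


# ---------------------------------------------------------------------------
# alignment FASTA
# ---------------------------------------------------------------------------

def _normalise(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1").astype("<U1")
    bad = ~np.isin(arr, list(_VALID))
    if bad.any():
        arr = arr.copy()
        arr[bad] = "N"
    return arr


def read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"strain_id": str})
    required = {"strain_id", "population"}
    if not required.issubset(meta.columns):
        raise MetadataError(f"metadata must have columns {sorted(required)}")
    if "subgroup" not in meta.columns:
        meta["subgroup"] = None
    if "latitude" not in meta.columns:
        meta["latitude"] = np.nan
    return meta


def write_metadata(genomes: AlignedGenomes, path) -> None:
    rows = []
    for s in genomes.strain_ids:
        rows.append(
            {
                "strain_id": s,
                "population": genomes.population[s],
                "subgroup": genomes.subgroup.get(s),
                "latitude": genomes.latitude.get(s),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment(fasta_paths, metadata_path) -> AlignedGenomes:
    """Read per-chromosome alignment FASTAs and strain metadata.

    Parameters
    ----------
    fasta_paths
        Either a mapping ``chrom_id -> path`` or a sequence of paths, in
        which case the file stem is used as the chromosome id.  Order
        defines the concatenation order.
    metadata_path
        TSV with columns strain_id, population, subgroup, latitude.
    """
    if isinstance(fasta_paths, Mapping):
        items = list(fasta_paths.items())
    else:
        items = [(Path(p).stem, p) for p in fasta_paths]
    if not items:
        raise AlignmentError("no alignment files given")

    meta = read_metadata(metadata_path)
    meta_strains = set(meta["strain_id"])

    per_chrom = []
    strain_ids = None
    for chrom, path in items:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise AlignmentError(f"{path}: no FASTA records")
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{path}: sequences have unequal lengths {sorted(lengths)}; "
                "alignment is corrupt"
            )
        if strain_ids is None:
            strain_ids = list(records)
        elif set(records) != set(strain_ids):
            raise AlignmentError(
                f"{path}: strain set differs from first chromosome"
            )
        unknown = set(records) - meta_strains
        if unknown:
            raise MetadataError(
                f"strains present in {path} but absent from metadata: {sorted(unknown)}"
            )
        per_chrom.append((chrom, records))

    blocks = []
    chrom_map = []
    pos = 0
    for chrom, records in per_chrom:
        block = np.vstack([_normalise(records[s]) for s in strain_ids])
        blocks.append(block)
        chrom_map.append((chrom, pos, pos + block.shape[1]))
        pos += block.shape[1]
    matrix = np.hstack(blocks)

    meta_idx = meta.set_index("strain_id")
    population = {s: str(meta_idx.loc[s, "population"]) for s in strain_ids}
    subgroup = {
        s: (None if pd.isna(meta_idx.loc[s, "subgroup"]) else str(meta_idx.loc[s, "subgroup"]))
        for s in strain_ids
    }
    latitude = {
        s: (None if pd.isna(meta_idx.loc[s, "latitude"]) else float(meta_idx.loc[s, "latitude"]))
        for s in strain_ids
    }
    return AlignedGenomes(
        matrix=matrix,
        strain_ids=list(strain_ids),
        population=population,
        subgroup=subgroup,
        latitude=latitude,
        chrom_map=chrom_map,
    )


def write_alignment(genomes: AlignedGenomes, out_dir) -> dict:
    """Write one FASTA per chromosome; returns ``chrom_id -> path``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for chrom, start, end in genomes.chrom_map:
        records = [
            SeqRecord(Seq("".join(genomes.matrix[i, start:end])), id=s, description="")
            for i, s in enumerate(genomes.strain_ids)
        ]
        path = out_dir / f"{chrom}.fasta"
        SeqIO.write(records, str(path), "fasta")
        paths[chrom] = path
    return paths


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _overlaps(a_start, a_end, spans) -> bool:
    return any(a_start < e and s < a_end for s, e in spans)


def read_gene_models(
    gff_path,
    subtelomere_spans: Mapping | None = None,
    chrom_offsets: Mapping | None = None,
) -> GeneModels:
    """Read CDS gene models from GFF3.

    Parameters
    ----------
    gff_path
        GFF3 file with CDS features carrying a Parent (or gene_id/ID)
        attribute. Coordinates are 1-based inclusive per the GFF standard
        and are converted to 0-based half-open.
    subtelomere_spans
        Mapping ``chrom -> [(start, end), ...]`` of 0-based half-open
        subtelomeric intervals *in chromosome coordinates*. Genes
        overlapping any such interval get ``core_flag=False``.  The spans
        are a required user input for core-gene analyses because
        subtelomere definitions are reference-specific.
    chrom_offsets
        Optional ``chrom -> concatenated start`` offsets; when given, gene
        spans are shifted onto the concatenated coordinate axis.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    subtelomere_spans = subtelomere_spans or {}
    chrom_offsets = chrom_offsets or {}

    by_gene: dict = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [None])[0]
        gid = parent or cds.attributes.get("ID", [cds.id])[0]
        rec = by_gene.setdefault(gid, {"chrom": cds.seqid, "strand": cds.strand, "spans": []})
        if rec["chrom"] != cds.seqid or rec["strand"] != cds.strand:
            raise ValueError(f"gene {gid}: CDS features disagree on chromosome/strand")
        rec["spans"].append((cds.start - 1, cds.end))  # GFF 1-based incl -> 0-based half-open

    genes = []
    for gid, rec in by_gene.items():
        spans = sorted(rec["spans"])
        length = sum(e - s for s, e in spans)
        valid = length % 3 == 0
        if not valid:
            import warnings

            warnings.warn(
                f"gene {gid}: CDS length {length} not divisible by 3; excluded",
                stacklevel=2,
            )
        g_start = spans[0][0]
        g_end = spans[-1][1]
        core = not _overlaps(g_start, g_end, subtelomere_spans.get(rec["chrom"], []))
        offset = chrom_offsets.get(rec["chrom"], 0)
        genes.append(
            Gene(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                spans=[(s + offset, e + offset) for s, e in spans],
                core_flag=core,
                valid=valid,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GeneModels(genes=genes)


# ---------------------------------------------------------------------------
# LDhat import
# ---------------------------------------------------------------------------

_TWO_COL = re.compile(r"^(\S+)\s+([0-9.eE+\-]+)\s*$")
_RAW_4NER = re.compile(r"4N\s*e?\s*r[^=]*=\s*([0-9.eE+\-]+)", re.IGNORECASE)


def import_ldhat(outfile_paths: Iterable, chrom_ids: Sequence | None = None) -> list:
    """Parse per-chromosome 4*Ne*r summaries.

    Two dialects are accepted:

    * a simple two-column table ``chromosome  4Ner`` with one line per run
      (repeated chromosomes are repeated runs, kept separate here);
    * a raw LDhat-style text file containing a line with ``4Ner ... = X``,
      in which case the chromosome id is taken from ``chrom_ids`` (parallel
      to ``outfile_paths``) or the file stem.

    Negative, non-numeric or absent values raise :class:`LdhatFormatError`
    naming the file and line.
    """
    outfile_paths = list(outfile_paths)
    imports: list = []
    run_counter: dict = {}
    for i, path in enumerate(outfile_paths):
        text = Path(path).read_text().strip()
        if not text:
            raise LdhatFormatError(f"{path}: empty file")
        lines = text.splitlines()
        parsed_any = False
        two_col_rows = []
        for ln, line in enumerate(lines, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _TWO_COL.match(line)
            if m:
                try:
                    value = float(m.group(2))
                except ValueError as exc:
                    raise LdhatFormatError(f"{path}:{ln}: bad value {m.group(2)!r}") from exc
                two_col_rows.append((ln, m.group(1), value))
            else:
                two_col_rows = []
                break
        if two_col_rows:
            for ln, chrom, value in two_col_rows:
                run = run_counter.get(chrom, 0)
                run_counter[chrom] = run + 1
                try:
                    imports.append(RhoImport(chrom=chrom, rho_4ner=value, run_id=run))
                except LdhatFormatError as exc:
                    raise LdhatFormatError(f"{path}:{ln}: {exc}") from exc
            parsed_any = True
        else:
            chrom = chrom_ids[i] if chrom_ids is not None else Path(path).stem
            for ln, line in enumerate(lines, start=1):
                m = _RAW_4NER.search(line)
                if m:
                    run = run_counter.get(chrom, 0)
                    run_counter[chrom] = run + 1
                    try:
                        imports.append(
                            RhoImport(chrom=chrom, rho_4ner=float(m.group(1)), run_id=run)
                        )
                    except (ValueError, LdhatFormatError) as exc:
                        raise LdhatFormatError(f"{path}:{ln}: {exc}") from exc
                    parsed_any = True
        if not parsed_any:
            raise LdhatFormatError(f"{path}: no 4Ner estimate found")
    return imports
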