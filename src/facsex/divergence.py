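"""Derived-allele divergence from the inferred common ancestor.

Each strain's divergence is the number of derived alleles (DAs) it carries
— fixed differences count for every strain of the population, polymorphic
derived alleles only for their carriers — expressed per bp of complete
sites of a degeneracy class.  The ratio of 0-fold to 4-fold per-strain
divergence measures the efficacy of purifying selection (lower ratio =
stronger selection); partitioning sites into fixed vs. polymorphic
separates cumulative from recent selection.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .degeneracy_filter import SiteTable
from .diversity import paired_chromosome_test
from .polarize import DerivedMatrix

__all__ = ["StrainDAProfile", "da_profile", "zero_four_ratios"]

CLASSES = ("0fold", "4fold")
PARTITIONS = ("all", "fixed", "polymorphic")


@dataclass
class StrainDAProfile:
    """Per-strain derived-allele counts by chromosome, class and partition.

    ``counts`` is a DataFrame indexed by (chrom, site_class, partition)
    with one column per strain; ``denominators`` maps (chrom, site_class)
    to the complete-site count used for per-bp rates.
    """

    population: str
    strains: list
    counts: pd.DataFrame
    denominators: dict

    def strain_total(self, strain: str, site_class: str, partition: str = "all") -> int:
        sel = self.counts.xs((site_class, partition), level=("site_class", "partition"))
        return int(sel[strain].sum())

    def totals(self, site_class: str, partition: str = "all") -> pd.Series:
        sel = self.counts.xs((site_class, partition), level=("site_class", "partition"))
        return sel.sum(axis=0)

    def per_bp(self, site_class: str, partition: str = "all") -> pd.Series:
        denom = sum(
            v for (c, cls), v in self.denominators.items() if cls == site_class
        )
        return self.totals(site_class, partition) / denom

    def mean_per_strain_pbp(self, site_class: str, partition: str = "all") -> float:
        return float(self.per_bp(site_class, partition).mean())

    def chrom_mean_pbp(self, site_class: str, partition: str = "all") -> pd.Series:
        """Per-chromosome mean-over-strains DAs per bp."""
        out = {}
        for (chrom, cls), denom in self.denominators.items():
            if cls != site_class or denom == 0:
                continue
            row = self.counts.loc[(chrom, cls, partition)]
            out[chrom] = float(row.mean()) / denom
        return pd.Series(out).sort_index()

    def to_frame(self) -> pd.DataFrame:
        return self.counts.reset_index()


def da_profile(
    derived: DerivedMatrix,
    table: SiteTable,
    population: str,
    classes=CLASSES,
) -> StrainDAProfile:
    """Count DAs per strain, chromosome, degeneracy class and partition.

    A site is *fixed* in the population when every sampled strain carries
    the derived allele, *polymorphic* when a proper non-empty subset does;
    the split is evaluated within this population regardless of the other.
    """
    rows = derived.rows_for_population(population)
    strains = [derived.strain_ids[i] for i in rows]
    sub = derived.matrix[rows]
    carrier_counts = sub.sum(axis=0)
    fixed_cols = carrier_counts == len(rows)
    poly_cols = (carrier_counts > 0) & ~fixed_cols

    site_chrom = table.chrom[derived.site_coords]
    chroms = pd.unique(table.chrom)
    records = []
    index = []
    for chrom in chroms:
        in_chrom = site_chrom == chrom
        for cls in classes:
            cls_sites = table.class_mask(cls)[derived.site_coords] & in_chrom
            for partition, pmask in (
                ("all", np.ones_like(cls_sites)),
                ("fixed", fixed_cols),
                ("polymorphic", poly_cols),
            ):
                cols = cls_sites & pmask
                records.append(sub[:, cols].sum(axis=1))
                index.append((chrom, cls, partition))
    counts = pd.DataFrame(
        records,
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "site_class", "partition"]),
        columns=strains,
    )
    chrom_per_site = table.chrom
    denominators = {}
    for chrom in chroms:
        chrom_mask = chrom_per_site == chrom
        for cls in classes:
            denominators[(chrom, cls)] = int(
                (table.class_mask(cls) & table.complete & chrom_mask).sum()
            )
    return StrainDAProfile(
        population=population, strains=strains, counts=counts, denominators=denominators
    )


def zero_four_ratios(
    profile_a: StrainDAProfile,
    profile_b: StrainDAProfile,
    partition: str = "all",
    mode: str = "weighted",
) -> dict:
    """0-/4-fold divergence ratios for two populations and their contrast.

    For each population, per-chromosome ratios of mean-per-strain per-bp
    DAs (0-fold over 4-fold) are combined either as a weighted mean with
    the 4-fold complete-site counts as weights (``mode='weighted'``, the
    default, matching per-chromosome ratio averaging) or as the ratio of
    genome-pooled per-bp divergences (``mode='pooled'``). Chromosomes with
    zero 4-fold divergence are flagged and excluded from the paired test
    with a warning.

    Returns a dict with per-population ratios, the A/B fold difference and
    the across-chromosome paired t-test on the ratios.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"partition must be one of {PARTITIONS}")
    out = {"partition": partition, "mode": mode}
    per_chrom = {}
    for label, prof in (("A", profile_a), ("B", profile_b)):
        d0 = prof.chrom_mean_pbp("0fold", partition)
        d4 = prof.chrom_mean_pbp("4fold", partition)
        chroms = d0.index.intersection(d4.index)
        d0, d4 = d0[chroms], d4[chroms]
        usable = d4 > 0
        if not usable.all():
            warnings.warn(
                f"population {prof.population}: chromosomes with zero 4-fold "
                f"divergence excluded from ratio: {list(chroms[~usable])}",
                stacklevel=2,
            )
        ratios = (d0[usable] / d4[usable]).rename("ratio_0_4")
        weights = np.array(
            [prof.denominators[(c, "4fold")] for c in ratios.index], dtype=float
        )
        if mode == "weighted":
            ratio = float(np.average(ratios, weights=weights))
        elif mode == "pooled":
            ratio = prof.mean_per_strain_pbp("0fold", partition) / prof.mean_per_strain_pbp(
                "4fold", partition
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        per_chrom[label] = ratios
        out[f"ratio_{label}"] = ratio
    out["fold_A_over_B"] = out["ratio_A"] / out["ratio_B"]
    common = per_chrom["A"].index.intersection(per_chrom["B"].index)
    if len(common) >= 2:
        t, p, _ = paired_chromosome_test(
            per_chrom["A"][common].to_numpy(), per_chrom["B"][common].to_numpy()
        )
        out["t"], out["p"] = t, p
    else:
        out["t"], out["p"] = float("nan"), float("nan")
    out["per_chromosome_A"] = per_chrom["A"]
    out["per_chromosome_B"] = per_chrom["B"]
    return out
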