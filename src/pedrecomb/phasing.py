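"""Phase-informative sites and grandparent-of-origin assignment.

A site is informative for one transmission side (paternal or maternal)
when the F1 parent of that side is heterozygous and the genotypes of its
own two parents differ in a way that attributes each F1 allele to
exactly one grandparent (one grandparent homozygous for one allele and
the other either homozygous for the other allele or heterozygous).
The transmitted F1 allele is then traceable in an offspring unless the
F1's partner and the offspring are both heterozygous.

Origin labels are small integer codes: 0 = grandfather of the side,
1 = grandmother, -1 = untraceable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import PATERNAL, Pedigree, SIDES
from .sites import GenotypeTable, SiteGenotypes

GRANDFATHER = 0
GRANDMOTHER = 1
UNTRACEABLE = -1

LABEL_LEGEND = {GRANDFATHER: "grandfather", GRANDMOTHER: "grandmother",
                UNTRACEABLE: "untraceable"}


class MendelianError(ValueError):
    """Genotype configuration impossible under Mendelian transmission."""


def classify_informative(site: SiteGenotypes, side: str,
                         pedigree: Pedigree) -> dict[int, int] | None:
    """Return the allele -> grandparent-label mapping, or None.

    The mapping exists when the side's F1 parent is heterozygous and
    exactly one perfect matching assigns each F1 allele to a distinct
    grandparent.  Raises :class:`MendelianError` when no matching exists
    (such sites should have been removed by the Mendelian filter).
    """
    roles = pedigree.side_roles(side)
    f1 = site.alleles(roles.f1)
    gf = set(site.alleles(roles.grandfather))
    gm = set(site.alleles(roles.grandmother))
    if len(f1) != 2 or f1[0] == f1[1] or not gf or not gm:
        return None
    a, b = f1
    m1 = a in gf and b in gm  # a from grandfather, b from grandmother
    m2 = b in gf and a in gm
    if not m1 and not m2:
        raise MendelianError(
            f"{site.chrom}:{site.pos} {side}: F1 alleles {f1} not attributable "
            f"to grandparents {sorted(gf)}/{sorted(gm)}")
    if m1 and m2:
        return None
    if m1:
        return {a: GRANDFATHER, b: GRANDMOTHER}
    return {b: GRANDFATHER, a: GRANDMOTHER}


def assign_origin(site: SiteGenotypes, side: str, offspring: str,
                  pedigree: Pedigree, mapping: dict[int, int]) -> int:
    """Grandparent-of-origin label of the allele the offspring received
    from the focal side's F1 parent, or ``UNTRACEABLE``.

    Resolution: a haploid offspring call (female on non-PAR Z) is the
    paternal allele outright; a homozygous offspring fixes the focal
    allele; otherwise the partner must be homozygous so the partner's
    contribution can be subtracted.  Partner and offspring both
    heterozygous is the untraceable case.
    """
    roles = pedigree.side_roles(side)
    off = site.alleles(offspring)
    partner = site.alleles(roles.partner)
    f1 = set(site.alleles(roles.f1))
    if not off:
        return UNTRACEABLE
    if len(off) == 1:
        # haploid: only the paternally transmitted Z allele exists
        if side != PATERNAL:
            return UNTRACEABLE
        if off[0] not in f1:
            raise MendelianError(
                f"{site.chrom}:{site.pos}: offspring {offspring} haploid "
                f"allele {off[0]} absent from the father")
        focal = off[0]
    else:
        if not partner:
            return UNTRACEABLE
        pset = set(partner)
        x, y = off
        # one allele from the focal F1, the other from the partner
        valid_focal = {a for a, b in ((x, y), (y, x))
                       if a in f1 and b in pset}
        if not valid_focal:
            raise MendelianError(
                f"{site.chrom}:{site.pos}: offspring {offspring} genotype "
                f"{off} impossible from parents {sorted(f1)}/{sorted(pset)}")
        if len(valid_focal) > 1:
            return UNTRACEABLE  # partner and offspring both heterozygous
        focal = valid_focal.pop()
    if focal not in mapping:
        return UNTRACEABLE
    return mapping[focal]


@dataclass
class PhasedSites:
    """Origin-label sequences per (offspring, side, chromosome)."""

    frame: pd.DataFrame  # columns: chrom, pos, offspring, side, label
    n_untraceable: int
    n_informative_sites: int  # (site, side) pairs that were phasable

    def labels(self, offspring: str, side: str, chrom: str
               ) -> tuple[np.ndarray, np.ndarray]:
        """(positions, labels) sorted by position, untraceables excluded."""
        f = self.frame
        sel = f[(f.offspring == offspring) & (f.side == side)
                & (f.chrom == chrom) & (f.label != UNTRACEABLE)]
        return sel["pos"].to_numpy(), sel["label"].to_numpy()

    def groups(self):
        for (offspring, side, chrom), grp in self.frame[
                self.frame.label != UNTRACEABLE].groupby(
                ["offspring", "side", "chrom"], sort=True):
            yield (offspring, side, chrom), grp["pos"].to_numpy(), grp["label"].to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhasedSites":
        frame = pd.read_csv(path, sep="\t")
        unt = int((frame.label == UNTRACEABLE).sum())
        n_inf = len(frame)
        return cls(frame=frame, n_untraceable=unt, n_informative_sites=n_inf)


def phase_offspring(table: GenotypeTable, pedigree: Pedigree) -> PhasedSites:
    """Assign origin labels for every offspring on both sides.

    Sites informative for both sides are emitted once per side.  Sites
    with an untraceable transmission are kept in the output frame with
    label -1 (excluded from :meth:`PhasedSites.labels`) so they are
    countable.  Input must be position-sorted within chromosomes.
    """
    if not table.is_sorted_within_chrom():
        raise ValueError("sites must be sorted by position within chromosomes")
    records = []
    n_untraceable = 0
    n_informative = 0
    for site in table.sites():
        for side in SIDES:
            try:
                mapping = classify_informative(site, side, pedigree)
            except MendelianError:
                raise
            if mapping is None:
                continue
            n_informative += 1
            for child in pedigree.offspring:
                label = assign_origin(site, side, child, pedigree, mapping)
                if label == UNTRACEABLE:
                    n_untraceable += 1
                records.append({"chrom": site.chrom, "pos": site.pos,
                                "offspring": child, "side": side,
                                "label": label})
    frame = pd.DataFrame(records, columns=["chrom", "pos", "offspring",
                                           "side", "label"])
    return PhasedSites(frame=frame, n_untraceable=n_untraceable,
                       n_informative_sites=n_informative)
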