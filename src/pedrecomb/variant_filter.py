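"""Site-level quality filters applied to a called multi-sample VCF.

The filter cascade mirrors the stringent pre-phasing filtering used for
pedigree recombination mapping: repeat/gap masking, biallelic-only,
per-individual depth bounds (>= 15 reads and <= 2x the mean autosomal
coverage), genotype quality >= 30, and Mendelian consistency across all
trios.  Filters are applied in a fixed order so the per-filter removal
counts are comparable between runs.

Z-chromosome semantics: female genotypes outside the pseudoautosomal
region are haploid; a female diploid heterozygote there is treated as a
miscalled site and removed.  The female maximum-depth bound on the
non-PAR Z is 1x (not 2x) the mean autosomal coverage, since females
carry a single Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .intervals import IntervalSet, points_in_regions
from .pedigree import Pedigree
from .sites import HAPLOID, MISSING, GenotypeTable

FILTER_ORDER = ("mask", "biallelic", "coverage", "genotype_quality", "mendelian")

DP_MIN = 15
DP_MAX_FACTOR = 2.0
GQ_MIN = 30


@dataclass
class FilterReport:
    """Per-filter removed-site counts, in application order."""

    removed: dict[str, int] = field(default_factory=dict)
    surviving: int = 0
    input_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "surviving", "removed": self.surviving})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def check_sums(self) -> bool:
        return self.input_sites == self.surviving + sum(self.removed.values())


def _zygosity_masks(table: GenotypeTable):
    gt = table.gt
    diploid = gt[:, :, 1] >= 0
    haploid = gt[:, :, 1] == HAPLOID
    called = diploid | haploid
    het = diploid & (gt[:, :, 0] != gt[:, :, 1])
    return diploid, haploid, called, het


def _female_nonpar_z(table: GenotypeTable, pedigree: Pedigree,
                     layout: GenomeLayout) -> tuple[np.ndarray, np.ndarray]:
    """(site on non-PAR Z, sample is female) boolean masks."""
    nonpar_z = np.zeros(len(table), dtype=bool)
    for c in layout:
        if not c.is_z:
            continue
        sel = table.chrom == c.name
        p0 = table.pos - 1
        in_par = np.zeros(len(table), dtype=bool)
        if c.par is not None:
            in_par = (p0 >= c.par[0]) & (p0 < c.par[1])
        nonpar_z |= sel & ~in_par
    female = np.array([pedigree.is_female(s) for s in table.samples])
    return nonpar_z, female


def apply_z_semantics(table: GenotypeTable, pedigree: Pedigree,
                      layout: GenomeLayout) -> tuple[GenotypeTable, int]:
    """Coerce female non-PAR-Z genotypes to haploid; drop het females there.

    A female diploid heterozygote on the non-PAR Z cannot be a real
    genotype (females carry one Z) and, absent a haploid re-call, the
    whole site is removed.  Homozygous female diploid calls are coerced
    to haploid.  Returns the adjusted table and the removed-site count.
    """
    for s in pedigree.samples:
        table.sample_index(s)
    nonpar_z, female = _female_nonpar_z(table, pedigree, layout)
    if not nonpar_z.any():
        return table, 0
    gt = table.gt.copy()
    diploid = gt[:, :, 1] >= 0
    het = diploid & (gt[:, :, 0] != gt[:, :, 1])
    zone = nonpar_z[:, None] & female[None, :]
    bad_site = (zone & het).any(axis=1)
    coerce = zone & diploid & ~het
    gt[coerce, 1] = HAPLOID
    out = GenotypeTable(table.samples, table.chrom, table.pos, table.ref,
                        table.alt, gt, table.dp, table.gq, table.ad,
                        table.ad_other, flags=table.flags, meta=table.meta)
    return out.subset(~bad_site), int(bad_site.sum())


def mendelian_consistent(table: GenotypeTable, pedigree: Pedigree) -> np.ndarray:
    """Per-site Mendelian consistency across every trio in the pedigree.

    A diploid child must be explainable as one allele from each parent; a
    haploid child (female on non-PAR Z) inherits its single Z allele from
    its father.  Missing calls in a trio make that trio uninformative
    rather than inconsistent.
    """
    n = len(table)
    ok = np.ones(n, dtype=bool)
    gt = table.gt

    def carries(j: int, allele: np.ndarray) -> np.ndarray:
        return (gt[:, j, 0] == allele) | ((gt[:, j, 1] >= 0) & (gt[:, j, 1] == allele))

    for child, father, mother in pedigree.trios():
        jc = table.sample_index(child)
        jf = table.sample_index(father)
        jm = table.sample_index(mother)
        child_called = gt[:, jc, 0] >= 0
        f_called = gt[:, jf, 0] >= 0
        m_called = gt[:, jm, 0] >= 0
        child_dip = gt[:, jc, 1] >= 0
        a1 = gt[:, jc, 0]
        a2 = gt[:, jc, 1]
        # diploid child: one allele per parent, in either assignment
        cons_dip = ((carries(jf, a1) & carries(jm, a2))
                    | (carries(jf, a2) & carries(jm, a1)))
        # haploid child: single (Z) allele comes from the father
        cons_hap = carries(jf, a1)
        cons = np.where(child_dip, cons_dip, cons_hap)
        evaluable = child_called & f_called & m_called
        ok &= np.where(evaluable, cons, True)
    return ok


def filter_sites(table: GenotypeTable, mean_autosomal_coverage: float,
                 pedigree: Pedigree, layout: GenomeLayout | None = None,
                 repeats: IntervalSet | None = None,
                 gaps: IntervalSet | None = None,
                 dp_min: int = DP_MIN, dp_max_factor: float = DP_MAX_FACTOR,
                 gq_min: int = GQ_MIN) -> tuple[GenotypeTable, FilterReport]:
    """Apply the site-level filter cascade in fixed order.

    Order: mask -> biallelic -> coverage -> genotype quality -> Mendelian.
    A site survives only if every individual in the pedigree has a called
    genotype with DP in [15, 2 x mean autosomal coverage] (1x for females
    on the non-PAR Z) and GQ >= 30, the site is an unmasked biallelic
    SNP, and all trios are Mendelian-consistent.
    """
    if mean_autosomal_coverage <= 0:
        raise ValueError("mean_autosomal_coverage must be positive")
    for s in pedigree.samples:
        table.sample_index(s)

    report = FilterReport(input_sites=len(table))
    alive = np.ones(len(table), dtype=bool)

    masked = table.flags["in_repeat"] | table.flags["in_gap"]
    if repeats or gaps:
        regions: IntervalSet = {}
        for src in (repeats, gaps):
            for c, ivs in (src or {}).items():
                regions.setdefault(c, []).extend(ivs)
        masked = masked | points_in_regions(table.chrom, table.pos - 1, regions)
    report.removed["mask"] = int((alive & masked).sum())
    alive &= ~masked

    non_biallelic = ~table.flags["biallelic"]
    report.removed["biallelic"] = int((alive & non_biallelic).sum())
    alive &= ~non_biallelic

    _, _, called, _ = _zygosity_masks(table)
    dp_hi = np.full((len(table), table.n_samples),
                    dp_max_factor * mean_autosomal_coverage)
    if layout is not None:
        nonpar_z, female = _female_nonpar_z(table, pedigree, layout)
        zone = nonpar_z[:, None] & female[None, :]
        dp_hi[zone] = mean_autosomal_coverage
    dp_ok = (table.dp >= dp_min) & (table.dp <= dp_hi)
    # a no-call carries no usable evidence: fails the coverage criterion
    cov_fail = (~called | ~dp_ok).any(axis=1)
    report.removed["coverage"] = int((alive & cov_fail).sum())
    alive &= ~cov_fail

    gq_fail = (called & (table.gq < gq_min)).any(axis=1)
    report.removed["genotype_quality"] = int((alive & gq_fail).sum())
    alive &= ~gq_fail

    mend_fail = ~mendelian_consistent(table, pedigree)
    report.removed["mendelian"] = int((alive & mend_fail).sum())
    alive &= ~mend_fail

    report.surviving = int(alive.sum())
    return table.subset(alive), report
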