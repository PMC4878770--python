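"""Synthetic three-generation pedigree simulator with known recombination truth.

The simulator produces founder haplotypes at a configurable SNP density,
passes gametes through a meiosis model (sex-specific crossover rates,
gamma-renewal interference, optional obligate crossover, non-crossover
gene-conversion tracts with a tunable strong-allele transmission bias),
and emits multi-sample genotype records with configurable call errors.
Ground-truth crossover breakpoints, conversion tracts and
grandparent-of-origin labels are retained so every downstream stage of
the pipeline can be checked against known events.

Z-chromosome semantics: males are ZZ and recombine along the whole
chromosome; females are ZW and recombine only in the pseudoautosomal
region (PAR), so a female gamete carries either the Z or the W outside
the PAR.  The W is modelled as a Z homologue whose non-PAR sequence is
absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Chromosome, GenomeLayout
from .pedigree import FEMALE, MALE, MATERNAL, PATERNAL, Pedigree, default_pedigree
from .sites import HAPLOID, MISSING, GenotypeTable

BASES = ("A", "C", "G", "T")
WEAK = frozenset("AT")
STRONG = frozenset("GC")


def is_ws_pair(b1: str, b2: str) -> bool:
    """One weak (A/T) and one strong (G/C) allele."""
    return (b1 in WEAK) != (b2 in WEAK)


@dataclass
class MeiosisModel:
    """Per-meiosis recombination model.

    Crossover positions follow a stationary gamma-renewal process with
    shape ``interference_shape`` (shape 1 is the Poisson / no-interference
    limit) and mean spacing set by the sex-specific rate in cM/Mb.
    ``gbgc_c`` is the transmission distortion at weak:strong heteroduplex
    mismatches inside conversion tracts: the strong allele is transmitted
    with probability (1 + c) / 2.
    """

    rate_female_cM_per_Mb: float = 2.28
    rate_male_cM_per_Mb: float = 3.56
    obligate_co: bool = True
    interference_shape: float = 5.0
    nco_rate_per_Mb: float = 0.1
    tract_length_mean: float = 500.0
    gbgc_c: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_female_cM_per_Mb < 0 or self.rate_male_cM_per_Mb < 0:
            raise ValueError("crossover rates must be non-negative")
        if self.interference_shape < 1:
            raise ValueError("interference_shape must be >= 1")
        if self.nco_rate_per_Mb < 0:
            raise ValueError("nco_rate_per_Mb must be non-negative")
        if self.tract_length_mean < 1:
            raise ValueError("tract_length_mean must be >= 1 bp")
        if not -1.0 <= self.gbgc_c <= 1.0:
            raise ValueError("gbgc_c must lie in [-1, 1]")

    def rate_for(self, sex: str) -> float:
        if sex == FEMALE:
            return self.rate_female_cM_per_Mb
        if sex == MALE:
            return self.rate_male_cM_per_Mb
        raise ValueError(f"unknown sex label {sex!r}")


@dataclass
class ErrorModel:
    """Genotype-call artifact model.

    ``w_contamination_rate`` injects the female-specific artifact seen
    when reads from W-linked sequence map to autosomal loci of a
    male-derived assembly: every female called heterozygous, every male
    homozygous reference.
    """

    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    depth_mean: float = 42.0
    gq_floor_fraction: float = 0.0
    w_contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "missing_rate",
                     "gq_floor_fraction", "w_contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    @property
    def is_null(self) -> bool:
        return (self.genotype_error_rate == 0 and self.missing_rate == 0
                and self.gq_floor_fraction == 0
                and self.w_contamination_rate == 0)


@dataclass(frozen=True)
class CoBreakpoint:
    offspring: str
    side: str
    chrom: str
    pos: int  # breakpoint in bp; sites at position > pos switch origin


@dataclass(frozen=True)
class Conversion:
    pos: int  # 1-based site position
    from_base: str  # allele on the background haplotype
    to_base: str  # allele actually transmitted


@dataclass(frozen=True)
class NcoTract:
    offspring: str
    side: str
    chrom: str
    start: int  # 0-based half-open tract
    end: int
    conversions: tuple[Conversion, ...]


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated genotypes."""

    co_breakpoints: list[CoBreakpoint] = field(default_factory=list)
    nco_tracts: list[NcoTract] = field(default_factory=list)
    # (offspring, side) -> chrom -> grandparent index per site (0 = GF, 1 = GM)
    origins: dict[tuple[str, str], dict[str, np.ndarray]] = field(default_factory=dict)

    def conversions(self) -> list[tuple[NcoTract, Conversion]]:
        return [(t, c) for t in self.nco_tracts for c in t.conversions]


@dataclass
class SiteCatalog:
    """Simulated segregating-site positions and alleles, per chromosome."""

    pos: dict[str, np.ndarray]  # 1-based positions
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]

    def n_sites(self, chrom: str) -> int:
        return len(self.pos[chrom])


# haplotype set: chrom -> int8 array (2, n_sites); -1 = sequence absent
HaplotypeSet = dict[str, np.ndarray]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_founders(layout: GenomeLayout, seed) -> tuple[SiteCatalog, list[HaplotypeSet]]:
    """Draw segregating sites and four founder diploids.

    Returns the site catalog and haplotypes for (paternal grandfather,
    paternal grandmother, maternal grandfather, maternal grandmother).
    Site counts per chromosome are Poisson at ``snp_density`` per bp; at
    each site the eight founder haplotype alleles are drawn independently
    and monomorphic draws are rejected, so every site segregates.
    """
    rng = _as_rng(seed)
    if layout.snp_density <= 0:
        raise ValueError("snp_density must be positive to simulate founders")
    for c in layout:
        if layout.snp_density * c.length < 1:
            raise ValueError(
                f"expected site count below 1 on chromosome {c.name!r}; "
                "increase snp_density or chromosome length")
    pos: dict[str, np.ndarray] = {}
    ref: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    founder_alleles: dict[str, np.ndarray] = {}
    for c in layout:
        n = rng.poisson(layout.snp_density * c.length)
        n = max(int(n), 1)
        p = np.sort(rng.choice(c.length, size=min(n, c.length), replace=False)) + 1
        pos[c.name] = p.astype(np.int64)
        n = len(p)
        ri = rng.integers(0, 4, size=n)
        # alt offset 1..3 guarantees a distinct base; yields both W:S and
        # W:W / S:S site types
        ai = (ri + rng.integers(1, 4, size=n)) % 4
        base_arr = np.array(BASES, dtype=object)
        ref[c.name] = base_arr[ri]
        alt[c.name] = base_arr[ai]
        alleles = rng.integers(0, 2, size=(n, 8)).astype(np.int8)
        mono = (alleles.sum(axis=1) % 8) == 0
        while mono.any():
            alleles[mono] = rng.integers(0, 2, size=(int(mono.sum()), 8))
            mono = (alleles.sum(axis=1) % 8) == 0
        founder_alleles[c.name] = alleles
    catalog = SiteCatalog(pos=pos, ref=ref, alt=alt)
    founders: list[HaplotypeSet] = []
    for f in range(4):
        is_female = f in (1, 3)
        haps: HaplotypeSet = {}
        for c in layout:
            h = founder_alleles[c.name][:, 2 * f:2 * f + 2].T.copy()
            if c.is_z and is_female:
                # hap1 is the W: only PAR sequence is shared with the Z
                p0 = pos[c.name] - 1
                in_par = np.zeros(len(p0), dtype=bool)
                if c.par is not None:
                    in_par = (p0 >= c.par[0]) & (p0 < c.par[1])
                h[1, ~in_par] = -1
            haps[c.name] = h
        founders.append(haps)
    return catalog, founders


def _stationary_gamma_renewal(lo: float, hi: float, mean_spacing: float,
                              shape: float, rng: np.random.Generator) -> list[float]:
    """Points of a stationary gamma-renewal process on [lo, hi)."""
    theta = mean_spacing / shape
    # warm-up from far left so the first event in-window is at equilibrium
    x = lo - 25.0 * mean_spacing
    pts: list[float] = []
    while True:
        x += rng.gamma(shape, theta)
        if x >= hi:
            break
        if x >= lo:
            pts.append(x)
    return pts


def _draw_crossovers(chrom: Chromosome, sex: str, model: MeiosisModel,
                     rng: np.random.Generator) -> list[int]:
    """Crossover breakpoints (bp) for one gamete on one chromosome."""
    if chrom.is_z and sex == FEMALE:
        if chrom.par is None:
            return []
        lo, hi = chrom.par
        rate = model.rate_for(sex)
        if rate <= 0:
            return []
        mean_bp = 100.0 / rate * 1e6
        # no obligate conditioning inside the PAR: forcing >= 1 CO in such
        # a short interval would grossly inflate the configured rate
        pts = _stationary_gamma_renewal(lo, hi, mean_bp, model.interference_shape, rng)
        return sorted(int(p) for p in pts)
    rate = model.rate_for(sex)
    if rate <= 0:
        return []
    mean_bp = 100.0 / rate * 1e6
    for _ in range(100_000):
        pts = _stationary_gamma_renewal(0.0, float(chrom.length), mean_bp,
                                        model.interference_shape, rng)
        if pts or not model.obligate_co:
            return sorted(int(p) for p in pts)
    raise RuntimeError(
        f"could not draw an obligate crossover on {chrom.name} at rate {rate}")


def simulate_meiosis(parent_haps: HaplotypeSet, sex: str, model: MeiosisModel,
                     catalog: SiteCatalog, layout: GenomeLayout, seed,
                     transmit_z: str | None = None,
                     ) -> tuple[HaplotypeSet, list[tuple[str, int]],
                                list[tuple[str, int, int, tuple[Conversion, ...]]],
                                dict[str, np.ndarray]]:
    """One gamete from one parent.

    Returns ``(gamete, co_breakpoints, nco_tracts, origins)`` where
    ``origins[chrom][i]`` is the parental haplotype index (0 = the
    parent's paternal haplotype) transmitted at site ``i``, and the
    breakpoint/tract lists carry ``(chrom, ...)`` tuples.  ``transmit_z``
    forces which sex chromosome a female transmits (``"Z"`` sires sons,
    ``"W"`` daughters); outside the PAR the W carries no sites.
    """
    if sex not in (MALE, FEMALE):
        raise ValueError(f"unknown sex label {sex!r}")
    rng = _as_rng(seed)
    gamete: HaplotypeSet = {}
    cos: list[tuple[str, int]] = []
    tracts: list[tuple[str, int, int, tuple[Conversion, ...]]] = []
    origins: dict[str, np.ndarray] = {}
    for chrom in layout:
        if chrom.name not in parent_haps:
            raise ValueError(f"parent haplotypes missing chromosome {chrom.name!r}")
        haps = parent_haps[chrom.name]
        pos = catalog.pos[chrom.name]
        n = len(pos)
        breaks = _draw_crossovers(chrom, sex, model, rng)
        # strand path: start strand, switching at each breakpoint
        if chrom.is_z and sex == FEMALE and transmit_z in ("Z", "W"):
            final = 0 if transmit_z == "Z" else 1
            start = final if len(breaks) % 2 == 0 else 1 - final
        else:
            start = int(rng.integers(0, 2))
        strand = np.full(n, start, dtype=np.int8)
        for b in breaks:
            strand[pos > b] ^= 1
        g = haps[strand, np.arange(n)].copy()
        cos.extend((chrom.name, b) for b in breaks)
        origins[chrom.name] = strand
        # non-crossover gene-conversion tracts
        if chrom.is_z and sex == FEMALE:
            region = chrom.par
        else:
            region = (0, chrom.length)
        if region is not None and model.nco_rate_per_Mb > 0:
            lo, hi = region
            span_mb = (hi - lo) / 1e6
            k = rng.poisson(model.nco_rate_per_Mb * span_mb)
            p_geom = min(1.0, 1.0 / model.tract_length_mean)
            for _ in range(k):
                tract = None
                for _try in range(100):
                    s = int(rng.integers(lo, hi))
                    ln = int(rng.geometric(p_geom))
                    e = min(s + ln, hi)
                    if not any(s - 1 <= b <= e for b in breaks):
                        tract = (s, e)
                        break
                if tract is None:
                    continue
                s, e = tract
                idx = np.nonzero((pos - 1 >= s) & (pos - 1 < e))[0]
                convs: list[Conversion] = []
                ref = catalog.ref[chrom.name]
                alt = catalog.alt[chrom.name]
                for i in idx:
                    a0, a1 = int(haps[0, i]), int(haps[1, i])
                    if a0 < 0 or a1 < 0 or a0 == a1:
                        continue
                    b0 = ref[i] if a0 == 0 else alt[i]
                    b1 = ref[i] if a1 == 0 else alt[i]
                    if is_ws_pair(b0, b1):
                        p_strong = (1.0 + model.gbgc_c) / 2.0
                        strong_allele = a0 if b0 in STRONG else a1
                        weak_allele = a1 if strong_allele == a0 else a0
                        t = strong_allele if rng.random() < p_strong else weak_allele
                    else:
                        t = a0 if rng.random() < 0.5 else a1
                    bg = int(g[i])
                    if t != bg:
                        g[i] = t
                        fb = ref[i] if bg == 0 else alt[i]
                        tb = ref[i] if t == 0 else alt[i]
                        convs.append(Conversion(int(pos[i]), str(fb), str(tb)))
                tracts.append((chrom.name, s, e, tuple(convs)))
        gamete[chrom.name] = g
    return gamete, cos, tracts, origins


@dataclass
class PedigreeSim:
    """A complete simulated pedigree: haplotypes for all 11 individuals."""

    layout: GenomeLayout
    pedigree: Pedigree
    catalog: SiteCatalog
    haplotypes: dict[str, HaplotypeSet]  # sample -> chrom -> (2, n) alleles
    truth: SimTruth
    meiosis_model: MeiosisModel

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.pedigree.offspring)


def simulate_pedigree(layout: GenomeLayout, model: MeiosisModel, seed,
                      pedigree: Pedigree | None = None) -> PedigreeSim:
    """Simulate founders, F1 and F2 haplotypes with full recombination truth.

    Truth is recorded for the ten F1 -> F2 meioses only; recombination in
    the founder -> F1 gametes shapes the F1 haplotypes but is not part of
    the observable truth (the pipeline detects events in F1 gametes).
    """
    rng = _as_rng(seed)
    ped = pedigree or default_pedigree()
    catalog, founders = simulate_founders(layout, rng)
    fmap = dict(zip(ped.founders, founders))

    def child_haps(father: str, mother: str, child_sex: str) -> HaplotypeSet:
        pat, _, _, _ = simulate_meiosis(hapset[father], MALE, model, catalog,
                                        layout, rng)
        mat, _, _, _ = simulate_meiosis(hapset[mother], FEMALE, model, catalog,
                                        layout, rng,
                                        transmit_z="W" if child_sex == FEMALE else "Z")
        return {c.name: np.vstack([pat[c.name], mat[c.name]]) for c in layout}

    hapset: dict[str, HaplotypeSet] = dict(fmap)
    hapset[ped.father] = child_haps(ped.paternal_grandfather,
                                    ped.paternal_grandmother, MALE)
    hapset[ped.mother] = child_haps(ped.maternal_grandfather,
                                    ped.maternal_grandmother, FEMALE)

    truth = SimTruth()
    for child in ped.offspring:
        child_sex = ped.sex[child]
        pat, cos_p, nco_p, ori_p = simulate_meiosis(
            hapset[ped.father], MALE, model, catalog, layout, rng)
        mat, cos_m, nco_m, ori_m = simulate_meiosis(
            hapset[ped.mother], FEMALE, model, catalog, layout, rng,
            transmit_z="W" if child_sex == FEMALE else "Z")
        hapset[child] = {c.name: np.vstack([pat[c.name], mat[c.name]])
                         for c in layout}
        for side, cos, ncos, ori in ((PATERNAL, cos_p, nco_p, ori_p),
                                     (MATERNAL, cos_m, nco_m, ori_m)):
            truth.co_breakpoints.extend(
                CoBreakpoint(child, side, ch, p) for ch, p in cos)
            truth.nco_tracts.extend(
                NcoTract(child, side, ch, s, e, cv) for ch, s, e, cv in ncos)
            truth.origins[(child, side)] = ori
    return PedigreeSim(layout=layout, pedigree=ped, catalog=catalog,
                       haplotypes=hapset, truth=truth, meiosis_model=model)


def genotype_table(sim: PedigreeSim, error_model: ErrorModel | None = None,
                   seed=0) -> GenotypeTable:
    """Render the simulated haplotypes as multi-sample genotype records.

    A null error model emits idealised records: constant depth at
    ``depth_mean``, balanced allele depths at heterozygous calls, GQ 99.
    Any active error channel switches depth and allele depths to
    Poisson/binomial sampling.
    """
    em = error_model or ErrorModel()
    rng = _as_rng(seed)
    ped = sim.pedigree
    samples = ped.samples
    s = len(samples)
    chrom_arrs, pos_arrs, ref_arrs, alt_arrs, gt_arrs = [], [], [], [], []
    w_artifacts: list[tuple[str, int]] = []
    for chrom in sim.layout:
        pos = sim.catalog.pos[chrom.name]
        n = len(pos)
        gt = np.full((n, s, 2), MISSING, dtype=np.int8)
        for j, name in enumerate(samples):
            h = sim.haplotypes[name][chrom.name]
            a, b = h[0].copy(), h[1].copy()
            both = (a >= 0) & (b >= 0)
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            gt[both, j, 0] = lo[both]
            gt[both, j, 1] = hi[both]
            only_a = (a >= 0) & (b < 0)
            gt[only_a, j, 0] = a[only_a]
            gt[only_a, j, 1] = HAPLOID
            only_b = (b >= 0) & (a < 0)
            gt[only_b, j, 0] = b[only_b]
            gt[only_b, j, 1] = HAPLOID
        if em.w_contamination_rate > 0 and not chrom.is_z:
            hit = rng.random(n) < em.w_contamination_rate
            fem = np.array([ped.is_female(x) for x in samples])
            for i in np.nonzero(hit)[0]:
                gt[i, fem, 0] = 0
                gt[i, fem, 1] = 1
                gt[i, ~fem, 0] = 0
                gt[i, ~fem, 1] = 0
                w_artifacts.append((chrom.name, int(pos[i])))
        chrom_arrs.append(np.full(n, chrom.name, dtype=object))
        pos_arrs.append(pos)
        ref_arrs.append(sim.catalog.ref[chrom.name])
        alt_arrs.append(sim.catalog.alt[chrom.name])
        gt_arrs.append(gt)
    chroms = np.concatenate(chrom_arrs)
    pos = np.concatenate(pos_arrs)
    gt = np.concatenate(gt_arrs, axis=0)
    n = len(pos)

    if em.genotype_error_rate > 0:
        hit = rng.random((n, s)) < em.genotype_error_rate
        for i, j in zip(*np.nonzero(hit)):
            old = tuple(gt[i, j])
            if old[0] == MISSING:
                continue
            if old[1] == HAPLOID:
                gt[i, j, 0] = 1 - old[0]
            else:
                choices = [(0, 0), (0, 1), (1, 1)]
                choices = [c for c in choices if c != tuple(old)]
                gt[i, j, :] = choices[int(rng.integers(0, len(choices)))]
    if em.missing_rate > 0:
        miss = rng.random((n, s)) < em.missing_rate
        gt[miss] = (MISSING, MISSING)

    diploid = gt[:, :, 1] >= 0
    haploid = gt[:, :, 1] == HAPLOID
    called = diploid | haploid
    het = diploid & (gt[:, :, 0] != gt[:, :, 1])
    # genotypes are stored sorted, so gt[..., 0] == 1 means the call is
    # all-ALT (hom alt or haploid alt)
    all_alt = called & (gt[:, :, 0] == 1)
    if em.is_null:
        dp = np.full((n, s), int(round(em.depth_mean)), dtype=np.int32)
        alt_reads = np.where(het, dp // 2, np.where(all_alt, dp, 0))
        gq = np.full((n, s), 99, dtype=np.int32)
    else:
        dp = rng.poisson(em.depth_mean, size=(n, s)).astype(np.int32)
        dp = np.maximum(dp, 1)
        alt_frac = np.where(all_alt, 1.0, np.where(het, 0.5, 0.0))
        alt_reads = rng.binomial(dp, alt_frac)
        gq = np.full((n, s), 99, dtype=np.int32)
        if em.gq_floor_fraction > 0:
            low = rng.random((n, s)) < em.gq_floor_fraction
            gq[low] = rng.integers(5, 30, size=int(low.sum()))
    dp = np.where(called, dp, 0)
    gq = np.where(called, gq, 0)
    alt_reads = np.where(called, alt_reads, 0)
    ad = np.stack([dp - alt_reads, alt_reads], axis=-1)
    ad[~called] = 0

    table = GenotypeTable(samples, chroms, pos, np.concatenate(ref_arrs),
                          np.concatenate(alt_arrs), gt, dp, gq, ad,
                          meta={"w_artifact_sites": w_artifacts,
                                "mean_autosomal_coverage": float(em.depth_mean)})
    return table
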