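"""Downstream recombination statistics.

Covers the genetic-map arithmetic (cM distances and cM/Mb rates from
event counts over meioses), agreement with an external linkage map,
chromosome-end profiles with a sex comparison, crossover interference as
the coefficient of coincidence (CoC) in 1 Mb windows, a permutation test
for event clustering (hot-spots), proportional-overlap assignment of
events to gene-anatomy categories with Fisher tests, region-overlap
odds ratios, per-chromosome paired GC comparison, and the GC-biased
gene-conversion transmission-distortion test (exact binomial on W>S
versus S>W conversion counts, c = 2p - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .co_detect import CrossoverEvent
from .intervals import (IntervalSet, merge_intervals, merge_regions,
                        overlap_length, total_bp)
from .nco_detect import NCOEvent, S_TO_W, W_TO_S
from .pedigree import MATERNAL, PATERNAL

# ---------------------------------------------------------------------------
# map arithmetic


def map_distance(n_events: int, n_meioses: int) -> float:
    """Genetic distance in cM implied by event counts: 100 * events / meioses."""
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return 100.0 * n_events / n_meioses


def rate_cm_per_mb(distance_cM: float, length_Mb: float) -> float:
    if length_Mb <= 0:
        raise ValueError("chromosome length must be positive")
    return distance_cM / length_Mb


@dataclass
class MapTable:
    """Per-chromosome genetic map built from observed events.

    Sex-average per-chromosome distances divide the total event count by
    all meioses; the Z chromosome divides the paternal count by all
    meioses (a male map length, since the non-PAR Z recombines only in
    males).  Sex-specific genome totals divide same-sex autosomal counts
    by the same-sex meioses only.
    """

    frame: pd.DataFrame  # chrom, n_total, n_maternal, n_paternal,
    #                      distance_cM, length_Mb, rate_cM_per_Mb, linkage_cM
    n_meioses: int
    n_meioses_per_sex: int

    @property
    def autosomal(self) -> pd.DataFrame:
        return self.frame[~self.frame["is_z"]]

    def total_autosomal_cM(self) -> float:
        return float(self.autosomal["distance_cM"].sum())

    def sex_map_cM(self, side: str) -> float:
        col = "n_maternal" if side == MATERNAL else "n_paternal"
        return map_distance(int(self.autosomal[col].sum()), self.n_meioses_per_sex)


def build_map_table(events: list[CrossoverEvent], chrom_lengths: dict[str, int],
                    n_meioses: int, n_meioses_per_sex: int,
                    z_chroms: set[str] | None = None,
                    linkage_cM: dict[str, float] | None = None) -> MapTable:
    z_chroms = z_chroms or set()
    rows = []
    df = pd.DataFrame([{"chrom": e.chrom, "side": e.side} for e in events])
    for chrom, length in chrom_lengths.items():
        sub = df[df.chrom == chrom] if len(df) else df
        n_mat = int((sub.side == MATERNAL).sum()) if len(sub) else 0
        n_pat = int((sub.side == PATERNAL).sum()) if len(sub) else 0
        is_z = chrom in z_chroms
        n_for_distance = n_pat if is_z else n_mat + n_pat
        dist = map_distance(n_for_distance, n_meioses)
        rows.append({
            "chrom": chrom, "n_total": n_mat + n_pat, "n_maternal": n_mat,
            "n_paternal": n_pat, "is_z": is_z, "distance_cM": dist,
            "length_Mb": length / 1e6,
            "rate_cM_per_Mb": rate_cm_per_mb(dist, length / 1e6),
            "linkage_cM": (linkage_cM or {}).get(chrom, np.nan),
        })
    return MapTable(frame=pd.DataFrame(rows), n_meioses=n_meioses,
                    n_meioses_per_sex=n_meioses_per_sex)


def correlate_with_linkage(observed_cM, linkage_cM) -> float:
    """Pearson correlation between observed and linkage map columns.

    Invariant to positive rescaling of either column, so event counts
    and count-proportional distances give the same r.
    """
    x = np.asarray(observed_cM, dtype=float)
    y = np.asarray(linkage_cM, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a map column")
    r, _ = stats.pearsonr(x, y)
    return float(r)


# ---------------------------------------------------------------------------
# chromosome-end profile


@dataclass
class EndProfile:
    histograms: dict[str, pd.DataFrame]  # per window size: sex x bin counts
    mwu_u: float
    mwu_z: float
    mwu_p_one_sided: float
    n_male: int
    n_female: int


def _sex_of_side(side: str) -> str:
    return "male" if side == PATERNAL else "female"


def end_distance_profile(events: list[CrossoverEvent],
                         chrom_lengths: dict[str, int],
                         window_sizes=(10_000_000, 1_000_000),
                         terminal_bp: int = 10_000_000) -> EndProfile:
    """Distance-to-nearest-chromosome-end histograms per sex.

    The rank test compares male versus female per-event terminal
    distances (events within ``terminal_bp`` of an end), one-sided for
    male events lying closer to the ends.
    """
    rows = []
    for e in events:
        length = chrom_lengths[e.chrom]
        mid = e.midpoint
        if not 0 <= mid <= length:
            raise ValueError(f"event midpoint {mid} outside {e.chrom} (len {length})")
        rows.append({"sex": _sex_of_side(e.side),
                     "dist": min(mid, length - mid),
                     "size_class": (">100Mb" if length > 100e6
                                    else "50-100Mb" if length >= 50e6
                                    else "<50Mb")})
    df = pd.DataFrame(rows, columns=["sex", "dist", "size_class"])
    histograms = {}
    for w in window_sizes:
        span = terminal_bp if w < 10_000_000 else None
        sub = df if span is None else df[df.dist < span]
        if len(sub):
            binned = (sub.assign(bin=(sub.dist // w).astype(int))
                      .groupby(["sex", "bin"]).size().unstack(fill_value=0))
        else:
            binned = pd.DataFrame()
        histograms[f"{w}"] = binned
    term = df[df.dist < terminal_bp]
    male = term[term.sex == "male"]["dist"].to_numpy()
    female = term[term.sex == "female"]["dist"].to_numpy()
    if len(male) and len(female):
        res = stats.mannwhitneyu(male, female, alternative="less")
        u = float(res.statistic)
        n1, n2 = len(male), len(female)
        mu = n1 * n2 / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (mu - u) / sigma if sigma > 0 else np.nan
        p = float(res.pvalue)
    else:
        u, z, p = np.nan, np.nan, np.nan
    return EndProfile(histograms=histograms, mwu_u=u, mwu_z=z,
                      mwu_p_one_sided=p, n_male=len(male), n_female=len(female))


# ---------------------------------------------------------------------------
# crossover interference


@dataclass
class CoCProfile:
    """Observed/expected double-crossover counts by window separation."""

    distance_Mb: np.ndarray
    observed: np.ndarray
    expected: np.ndarray

    @property
    def coc(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.observed / self.expected
        out[self.expected <= 0] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_Mb": self.distance_Mb,
                             "observed": self.observed,
                             "expected": self.expected,
                             "coc": self.coc})


def coincidence_coefficient(events: list[CrossoverEvent],
                            chrom_lengths: dict[str, int],
                            meioses: list[tuple[str, str]],
                            window_bp: int = 1_000_000,
                            max_distance_bp: int | None = None) -> CoCProfile:
    """Coefficient of coincidence from 1 Mb window co-occupancy.

    For every within-chromosome window pair at separation d, a meiosis
    contributes an observed double crossover when it has at least one
    event in both windows; the expectation multiplies the windows'
    marginal occupancy probabilities.  Counts are pooled over window
    pairs and chromosomes into per-separation bins; CoC(d) =
    observed / expected, undefined (NaN) where the expectation is zero.
    """
    if not meioses:
        raise ValueError("need at least one meiosis identity")
    m_index = {m: i for i, m in enumerate(meioses)}
    n_m = len(meioses)
    max_w = max(int(np.ceil(l / window_bp)) for l in chrom_lengths.values())
    if max_distance_bp is not None:
        max_w = min(max_w, int(max_distance_bp // window_bp) + 1)
    obs = np.zeros(max_w, dtype=float)
    exp = np.zeros(max_w, dtype=float)
    for chrom, length in chrom_lengths.items():
        n_w = int(np.ceil(length / window_bp))
        occ = np.zeros((n_m, n_w), dtype=bool)
        for e in events:
            if e.chrom != chrom:
                continue
            key = (e.offspring, e.side)
            if key not in m_index:
                raise ValueError(f"event meiosis {key} not in meioses list")
            w = min(int(e.midpoint // window_bp), n_w - 1)
            occ[m_index[key], w] = True
        marg = occ.mean(axis=0)
        for i in range(n_w):
            for j in range(i + 1, n_w):
                d = j - i
                if d >= max_w:
                    break
                obs[d] += int((occ[:, i] & occ[:, j]).sum())
                exp[d] += marg[i] * marg[j] * n_m
    dist = (np.arange(max_w) * window_bp) / 1e6
    return CoCProfile(distance_Mb=dist[1:], observed=obs[1:], expected=exp[1:])


# ---------------------------------------------------------------------------
# hot-spot permutation test


@dataclass
class HotspotResult:
    observed_pairs: int
    p_value: float
    n_perm: int
    null_counts: np.ndarray = field(repr=False, default=None)


def _sorted_close_pairs(mids: np.ndarray, pair_distance: float) -> int:
    """Pairs (i < j) with mids[j] - mids[i] < pair_distance; mids sorted."""
    hi = np.searchsorted(mids, mids + pair_distance, side="left")
    return int((hi - np.arange(len(mids)) - 1).sum())


def _close_pair_count(chroms, mids, meiosis_ids, pair_distance) -> int:
    """Close pairs from *different* meioses on the same chromosome."""
    chroms = np.asarray(chroms, dtype=object)
    mids = np.asarray(mids, dtype=float)
    ids = pd.Series(meiosis_ids)
    count = 0
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        m = np.sort(mids[sel])
        count += _sorted_close_pairs(m, pair_distance)
        for _, grp in ids[sel].groupby(ids[sel]):
            m_same = np.sort(mids[grp.index.to_numpy()])
            count -= _sorted_close_pairs(m_same, pair_distance)
    return count


def hotspot_randomization(events: list[CrossoverEvent],
                          chrom_lengths: dict[str, int],
                          pair_distance: int = 100_000,
                          n_perm: int = 1000, seed=0,
                          exclude_gap_events: bool = False) -> HotspotResult:
    """Permutation test for co-localised events from independent meioses.

    The statistic is the number of event pairs from different meioses on
    the same chromosome closer than ``pair_distance``.  Each permutation
    redraws every event's midpoint uniformly on its own chromosome,
    preserving per-chromosome and per-meiosis event counts; only
    positions are randomised.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    use = [e for e in events if not (exclude_gap_events and e.overlaps_gap)]
    if not use:
        return HotspotResult(observed_pairs=0, p_value=1.0, n_perm=n_perm,
                             null_counts=np.zeros(n_perm))
    chroms = [e.chrom for e in use]
    mids = [e.midpoint for e in use]
    ids = [(e.offspring, e.side) for e in use]
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    observed = _close_pair_count(chroms, mids, ids, pair_distance)
    # index groups are fixed across permutations: only positions move
    chrom_groups: dict[str, list[int]] = {}
    id_groups: dict[tuple, list[int]] = {}
    for i, (c, m) in enumerate(zip(chroms, ids)):
        chrom_groups.setdefault(c, []).append(i)
        id_groups.setdefault((c, m), []).append(i)
    c_idx = [np.asarray(v) for v in chrom_groups.values()]
    i_idx = [np.asarray(v) for v in id_groups.values() if len(v) > 1]

    def count_pairs(pos: np.ndarray) -> int:
        total = sum(_sorted_close_pairs(np.sort(pos[ix]), pair_distance)
                    for ix in c_idx)
        same = sum(_sorted_close_pairs(np.sort(pos[ix]), pair_distance)
                   for ix in i_idx)
        return total - same

    null = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        null[k] = count_pairs(rng.random(len(use)) * lengths)
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return HotspotResult(observed_pairs=observed, p_value=p, n_perm=n_perm,
                         null_counts=null)


# ---------------------------------------------------------------------------
# gene-anatomy feature assignment


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int  # 0-based half-open
    tx_end: int
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, coordinate order


FEATURE_CATEGORIES = ("promoter", "first_exon", "first_intron",
                      "other_exons", "other_introns", "intergenic")


def read_bed12(path) -> list[GeneModel]:
    genes = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for r in df.itertuples(index=False):
        start, end = int(r[1]), int(r[2])
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        exons = tuple((start + s, start + s + l) for s, l in zip(starts, sizes))
        genes.append(GeneModel(name=str(r[3]), chrom=str(r[0]),
                               strand=str(r[5]), tx_start=start, tx_end=end,
                               exons=exons))
    return genes


def _subtract(ivs: list[tuple[int, int]],
              minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in merge_intervals(ivs):
        cur = s
        for ms, me in merge_intervals(minus):
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def feature_regions(genes: list[GeneModel], chrom_lengths: dict[str, int],
                    promoter_bp: int = 2000) -> dict[str, IntervalSet]:
    """Partition the genome into the six gene-anatomy categories.

    Overlaps between categories are resolved by precedence (promoter >
    first exon > first intron > other exons > other introns); intergenic
    is the remainder of the genome.  Promoters and first exons/introns
    are strand-aware.
    """
    raw: dict[str, IntervalSet] = {c: {} for c in FEATURE_CATEGORIES}

    def add(cat, chrom, s, e):
        if e > s:
            raw[cat].setdefault(chrom, []).append((s, e))

    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.name!r} lacks strand; cannot place promoter")
        L = chrom_lengths.get(g.chrom, None)
        if g.strand == "+":
            add("promoter", g.chrom, max(0, g.tx_start - promoter_bp), g.tx_start)
            exons = list(g.exons)
        else:
            hi = g.tx_end + promoter_bp
            if L is not None:
                hi = min(L, hi)
            add("promoter", g.chrom, g.tx_end, hi)
            exons = list(g.exons)[::-1]  # transcription order
        introns = []
        coord_exons = sorted(g.exons)
        for (s1, e1), (s2, e2) in zip(coord_exons, coord_exons[1:]):
            introns.append((e1, s2))
        if g.strand == "-":
            introns = introns[::-1]
        if exons:
            add("first_exon", g.chrom, *exons[0])
            for ex in exons[1:]:
                add("other_exons", g.chrom, *ex)
        if introns:
            add("first_intron", g.chrom, *introns[0])
            for iv in introns[1:]:
                add("other_introns", g.chrom, *iv)

    out: dict[str, IntervalSet] = {}
    claimed: IntervalSet = {}
    for cat in FEATURE_CATEGORIES[:-1]:
        regions = merge_regions(raw[cat])
        resolved: IntervalSet = {}
        for chrom, ivs in regions.items():
            resolved[chrom] = _subtract(ivs, claimed.get(chrom, []))
            claimed.setdefault(chrom, []).extend(resolved[chrom])
            claimed[chrom] = merge_intervals(claimed[chrom])
        out[cat] = resolved
    inter: IntervalSet = {}
    for chrom, L in chrom_lengths.items():
        inter[chrom] = _subtract([(0, L)], claimed.get(chrom, []))
    out["intergenic"] = inter
    return out


@dataclass
class FeatureAssignment:
    weights: pd.DataFrame  # one row per event, one column per category
    category_bp: dict[str, int]
    density: dict[str, float]  # summed weights / category bp
    fisher: pd.DataFrame  # category vs intergenic odds ratio + p


def feature_assignment(intervals: list[tuple[str, int, int]],
                       genes: list[GeneModel],
                       chrom_lengths: dict[str, int],
                       promoter_bp: int = 2000) -> FeatureAssignment:
    """Assign events to gene-anatomy categories by proportional overlap.

    ``intervals`` are 0-based half-open event regions (a point event is
    a width-1 interval).  Each event distributes weight
    ``overlap / interval_length`` across categories; density is summed
    weight per category bp; each category is tested against intergenic
    with Fisher's exact test on (rounded event counts, kb margins).
    """
    regions = feature_regions(genes, chrom_lengths, promoter_bp)
    category_bp = {cat: total_bp(regions[cat]) for cat in FEATURE_CATEGORIES}
    rows = []
    for chrom, s, e in intervals:
        if e <= s:
            raise ValueError(f"empty event interval {chrom}:{s}-{e}")
        w = {}
        for cat in FEATURE_CATEGORIES:
            w[cat] = overlap_length(s, e, regions[cat].get(chrom, [])) / (e - s)
        rows.append(w)
    weights = pd.DataFrame(rows, columns=list(FEATURE_CATEGORIES))
    density = {}
    for cat in FEATURE_CATEGORIES:
        bp = category_bp[cat]
        density[cat] = float(weights[cat].sum()) / bp if bp > 0 else np.nan
    fisher_rows = []
    n_int = float(weights["intergenic"].sum()) if len(weights) else 0.0
    kb_int = max(1, round(category_bp["intergenic"] / 1000))
    for cat in FEATURE_CATEGORIES[:-1]:
        if category_bp[cat] == 0:
            fisher_rows.append({"category": cat, "odds_ratio": np.nan,
                                "p_value": np.nan})
            continue
        n_cat = float(weights[cat].sum()) if len(weights) else 0.0
        kb_cat = max(1, round(category_bp[cat] / 1000))
        tab = [[round(n_cat), kb_cat], [round(n_int), kb_int]]
        orat, p = stats.fisher_exact(tab)
        fisher_rows.append({"category": cat, "odds_ratio": float(orat),
                            "p_value": float(p)})
    return FeatureAssignment(weights=weights, category_bp=category_bp,
                             density=density,
                             fisher=pd.DataFrame(fisher_rows))


# ---------------------------------------------------------------------------
# region overlap test


@dataclass
class RegionOverlapResult:
    n_in: int
    n_out: int
    region_bp: int
    genome_bp: int
    odds_ratio: float
    p_value: float

    @property
    def overlap_fraction(self) -> float:
        n = self.n_in + self.n_out
        return self.n_in / n if n else np.nan


def region_overlap_test(points: list[tuple[str, float]], regions: IntervalSet,
                        genome_bp: int) -> RegionOverlapResult:
    """Do events fall inside a region set more or less often than by area?

    ``points`` are (chrom, position) event locations (midpoints for
    interval events).  Odds ratio = (in/out) / (region/non-region area);
    the p-value is Fisher's exact test on the events-vs-kb 2x2 table.
    """
    regions = merge_regions(regions)
    region_bp = total_bp(regions)
    if region_bp <= 0 or region_bp >= genome_bp:
        raise ValueError("regions must cover more than 0% and less than 100% "
                         "of the genome")
    n_in = 0
    for chrom, p in points:
        for s, e in regions.get(chrom, ()):
            if s <= p < e:
                n_in += 1
                break
    n_out = len(points) - n_in
    non_bp = genome_bp - region_bp
    if n_out == 0:
        orat = np.inf if n_in else np.nan
    else:
        orat = (n_in / n_out) / (region_bp / non_bp)
    tab = [[n_in, n_out],
           [max(1, round(region_bp / 1000)), max(1, round(non_bp / 1000))]]
    _, p = stats.fisher_exact(tab)
    return RegionOverlapResult(n_in=n_in, n_out=n_out, region_bp=region_bp,
                               genome_bp=genome_bp, odds_ratio=float(orat),
                               p_value=float(p))


# ---------------------------------------------------------------------------
# GC comparison


@dataclass
class GcComparison:
    pairs: pd.DataFrame  # chrom, event_gc, background_gc
    t_statistic: float
    p_value: float
    n_dropped: int  # chromosomes with no events


def gc_content_comparison(event_gc: dict[str, float],
                          background_gc: dict[str, float]) -> GcComparison:
    """Paired t-test of event-region GC against chromosome background GC.

    ``event_gc`` maps chromosome -> mean GC of event regions on it
    (chromosomes with no events are absent and counted as dropped);
    ``background_gc`` maps chromosome -> background GC fraction.
    Identical pairs throughout give t = 0 treated as p = 1.
    """
    chroms = [c for c in background_gc if c in event_gc
              and np.isfinite(event_gc[c])]
    dropped = len(background_gc) - len(chroms)
    pairs = pd.DataFrame({"chrom": chroms,
                          "event_gc": [event_gc[c] for c in chroms],
                          "background_gc": [background_gc[c] for c in chroms]})
    if len(pairs) < 2:
        return GcComparison(pairs, np.nan, np.nan, dropped)
    diffs = pairs["event_gc"] - pairs["background_gc"]
    if np.allclose(diffs, 0):
        return GcComparison(pairs, 0.0, 1.0, dropped)
    t, p = stats.ttest_rel(pairs["event_gc"], pairs["background_gc"])
    return GcComparison(pairs, float(t), float(p), dropped)


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return np.nan
    return (seq.count("G") + seq.count("C")) / acgt


# ---------------------------------------------------------------------------
# gBGC transmission distortion


@dataclass
class TransmissionBias:
    n_WS: int
    n_SW: int
    p_hat: float
    ci_low: float
    ci_high: float
    c: float
    p_value: float

    @property
    def n(self) -> int:
        return self.n_WS + self.n_SW


def transmission_bias_from_counts(n_WS: int, n_SW: int) -> TransmissionBias:
    """Exact binomial test of W>S vs S>W conversion counts against 0.5.

    p_hat is the strong-allele transmission proportion with a
    Clopper-Pearson 95% CI; the distortion is c = 2 * p_hat - 1.
    """
    n = n_WS + n_SW
    if n == 0:
        raise ValueError("no weak:strong conversion events")
    test = stats.binomtest(n_WS, n, 0.5, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    p_hat = n_WS / n
    return TransmissionBias(n_WS=n_WS, n_SW=n_SW, p_hat=p_hat,
                            ci_low=float(ci.low), ci_high=float(ci.high),
                            c=2.0 * p_hat - 1.0, p_value=float(test.pvalue))


def transmission_bias(nco_events: list[NCOEvent]) -> TransmissionBias:
    """Transmission distortion from direction-classified NCO events."""
    n_ws = sum(1 for e in nco_events if e.direction == W_TO_S)
    n_sw = sum(1 for e in nco_events if e.direction == S_TO_W)
    return transmission_bias_from_counts(n_ws, n_sw)
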