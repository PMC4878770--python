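"""Map arithmetic, linkage correlation, end profiles, interference,
hot-spot permutation, feature assignment, region overlap, GC comparison
and the transmission-distortion test — each against closed forms or
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from pedrecomb import datasets
from pedrecomb.co_detect import CrossoverEvent
from pedrecomb.nco_detect import NCOEvent, S_TO_W, W_TO_S
from pedrecomb.recomb_stats import (GeneModel, coincidence_coefficient,
                                    correlate_with_linkage,
                                    end_distance_profile, feature_assignment,
                                    feature_regions, gc_content_comparison,
                                    hotspot_randomization, map_distance,
                                    rate_cm_per_mb, region_overlap_test,
                                    transmission_bias,
                                    transmission_bias_from_counts)


def ev(chrom="chr1", left=1_000_000, right=1_000_001, offspring="o1",
       side="paternal", gap=False):
    return CrossoverEvent(offspring, side, chrom, left, right, gap)


class TestMapArithmetic:
    def test_sex_specific_autosomal_maps(self):
        assert map_distance(datasets.N_MATERNAL_AUTOSOMAL_CO,
                            datasets.N_MEIOSES_PER_SEX) == 2380.0
        assert map_distance(datasets.N_PATERNAL_AUTOSOMAL_CO,
                            datasets.N_MEIOSES_PER_SEX) == 3720.0

    def test_zero_events_zero_distance(self):
        assert map_distance(0, 5) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            map_distance(-1, 5)
        with pytest.raises(ValueError):
            map_distance(10, 0)
        with pytest.raises(ValueError):
            rate_cm_per_mb(10, 0)

    def test_par_rate_rounds_to_67(self):
        d = map_distance(datasets.N_Z_MATERNAL_PAR_CO,
                         datasets.N_MEIOSES_PER_SEX)
        assert round(rate_cm_per_mb(d, datasets.PAR_LENGTH_MB)) == 67

    def test_male_excess_rounds_to_56_percent(self):
        excess = (datasets.RATE_MALE_CM_PER_MB
                  / datasets.RATE_FEMALE_CM_PER_MB - 1) * 100
        assert round(excess) == 56


class TestLinkageCorrelation:
    def test_reference_table_correlation_rounds_to_095(self):
        t = datasets.flycatcher_map_table()
        r = correlate_with_linkage(t["distance_cM"], t["linkage_cM"])
        assert round(r, 2) == 0.95

    def test_proportional_columns_give_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate_with_linkage(x, [10 * v for v in x]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = datasets.flycatcher_map_table()
        r1 = correlate_with_linkage(t["distance_cM"], t["linkage_cM"])
        r2 = correlate_with_linkage(t["distance_cM"] * 10, t["linkage_cM"])
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_linkage([1, 1, 1], [1, 2, 3])


class TestEndProfile:
    def test_terminal_bin_assignment(self):
        profile = end_distance_profile(
            [ev(left=400_000, right=400_001, side="paternal")],
            {"chr1": 100_000_000})
        hist = profile.histograms["1000000"]
        assert hist.loc["male", 0] == 1

    def test_event_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            end_distance_profile([ev(left=2_000_000, right=2_000_001)],
                                 {"chr1": 1_000_000})

    def test_symmetric_events_give_symmetric_histogram(self):
        length = 40_000_000
        events = []
        for p in (5_000_000, 15_000_000):
            for q in (p, length - p):
                events.append(ev(left=q, right=q + 1, side="paternal",
                                 offspring=f"o{q}"))
        profile = end_distance_profile(events, {"chr1": length},
                                       window_sizes=(10_000_000,))
        hist = profile.histograms["10000000"]
        assert hist.loc["male", 0] == 2 and hist.loc["male", 1] == 2

    def test_rank_test_detects_male_end_bias(self):
        rng = np.random.default_rng(0)
        length = 50_000_000
        events = []
        for i in range(120):
            p = rng.uniform(0, 2e6) if i % 2 else rng.uniform(0, 9e6)
            side = "paternal" if i % 2 else "maternal"
            events.append(ev(left=int(p) + 1, right=int(p) + 2, side=side,
                             offspring=f"o{i}"))
        profile = end_distance_profile(events, {"chr1": length})
        assert profile.mwu_p_one_sided < 0.05
        assert profile.mwu_z > 0


def brute_force_coc(events, chrom_lengths, meioses, window=1_000_000):
    """Direct enumeration of window pairs for the CoC oracle."""
    obs = {}
    exp = {}
    for chrom, L in chrom_lengths.items():
        n_w = int(np.ceil(L / window))
        hits = {m: set() for m in meioses}
        for e in events:
            if e.chrom == chrom:
                hits[(e.offspring, e.side)].add(
                    min(int(e.midpoint // window), n_w - 1))
        for i in range(n_w):
            pi = sum(i in hits[m] for m in meioses) / len(meioses)
            for j in range(i + 1, n_w):
                pj = sum(j in hits[m] for m in meioses) / len(meioses)
                d = j - i
                o = sum(i in hits[m] and j in hits[m] for m in meioses)
                obs[d] = obs.get(d, 0) + o
                exp[d] = exp.get(d, 0.0) + pi * pj * len(meioses)
    return obs, exp


class TestCoC:
    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n_m = rng.integers(2, 5)
            meioses = [(f"o{i}", "paternal") for i in range(n_m)]
            L = int(rng.integers(3, 11)) * 1_000_000
            events = []
            for m in meioses:
                for _ in range(rng.integers(0, 4)):
                    p = int(rng.integers(0, L))
                    events.append(CrossoverEvent(m[0], m[1], "c", p, p + 1))
            prof = coincidence_coefficient(events, {"c": L}, meioses)
            obs, exp = brute_force_coc(events, {"c": L}, meioses)
            for k, d in enumerate(prof.distance_Mb):
                di = int(round(d))
                assert prof.observed[k] == obs.get(di, 0)
                assert prof.expected[k] == pytest.approx(exp.get(di, 0.0))

    def test_hand_computed_toy(self):
        # two meioses on a 3 Mb chromosome; events in windows 0 and 2 for
        # m1, window 0 for m2
        meioses = [("a", "paternal"), ("b", "paternal")]
        events = [CrossoverEvent("a", "paternal", "c", 100_000, 100_001),
                  CrossoverEvent("a", "paternal", "c", 2_500_000, 2_500_001),
                  CrossoverEvent("b", "paternal", "c", 200_000, 200_001)]
        prof = coincidence_coefficient(events, {"c": 3_000_000}, meioses)
        # d=2 Mb: observed double in m1 = 1; expected = 1.0 * 0.5 * 2 = 1
        k = list(np.round(prof.distance_Mb).astype(int)).index(2)
        assert prof.observed[k] == 1 and prof.expected[k] == pytest.approx(1.0)
        assert prof.coc[k] == pytest.approx(1.0)

    def test_never_cooccurring_short_range_zero(self):
        meioses = [(f"o{i}", "m") for i in range(4)]
        events = [CrossoverEvent(f"o{i}", "m", "c", 1 + 10_000_000 * 0, 2)
                  for i in range(4)]
        prof = coincidence_coefficient(events, {"c": 10_000_000}, meioses)
        near = prof.coc[np.isfinite(prof.coc) & (prof.distance_Mb < 5)]
        assert (near == 0).all() or len(near) == 0

    def test_empty_expectation_is_nan_not_zero(self):
        meioses = [("a", "m")]
        prof = coincidence_coefficient([], {"c": 5_000_000}, meioses)
        assert np.isnan(prof.coc).all()


class TestHotspot:
    def test_zero_events(self):
        res = hotspot_randomization([], {"chr1": 1_000_000}, n_perm=10)
        assert res.observed_pairs == 0 and res.p_value == 1.0

    def test_three_meioses_ten_kb_apart_count_three_pairs(self):
        events = [CrossoverEvent(f"o{i}", "paternal", "chr1",
                                 1_000_000 + i * 10_000,
                                 1_000_001 + i * 10_000)
                  for i in range(3)]
        res = hotspot_randomization(events, {"chr1": 100_000_000},
                                    n_perm=50, seed=1)
        assert res.observed_pairs == 3

    def test_same_meiosis_pairs_not_counted(self):
        events = [CrossoverEvent("o1", "paternal", "chr1", p, p + 1)
                  for p in (1_000_000, 1_010_000)]
        res = hotspot_randomization(events, {"chr1": 100_000_000}, n_perm=10)
        assert res.observed_pairs == 0

    def test_clustered_events_yield_small_p(self):
        rng = np.random.default_rng(3)
        events = [CrossoverEvent(f"o{i}", "paternal", "chr1",
                                 int(5_000_000 + rng.uniform(0, 50_000)),
                                 int(5_000_000 + rng.uniform(50_000, 90_000)))
                  for i in range(10)]
        res = hotspot_randomization(events, {"chr1": 200_000_000},
                                    n_perm=1000, seed=4)
        assert res.p_value < 0.01

    def test_deterministic_under_seed(self):
        events = [CrossoverEvent(f"o{i}", "paternal", "chr1",
                                 int(1e6 * (i + 1)), int(1e6 * (i + 1)) + 1)
                  for i in range(6)]
        r1 = hotspot_randomization(events, {"chr1": 50_000_000}, seed=9)
        r2 = hotspot_randomization(events, {"chr1": 50_000_000}, seed=9)
        assert r1.p_value == r2.p_value


TOY_GENES = [
    GeneModel("g1", "chr1", "+", 10_000, 20_000,
              exons=((10_000, 11_000), (12_000, 13_000), (19_000, 20_000))),
    GeneModel("g2", "chr1", "-", 40_000, 50_000,
              exons=((40_000, 42_000), (48_000, 50_000))),
]
TOY_LENGTHS = {"chr1": 100_000}


class TestFeatureAssignment:
    def test_promoter_intergenic_split(self):
        # 1,000 bp interval: 400 bp in the promoter [8,000, 10,000), rest
        # intergenic
        fa = feature_assignment([("chr1", 9_600, 10_600)], TOY_GENES,
                                TOY_LENGTHS)
        w = fa.weights.iloc[0]
        assert w["promoter"] == pytest.approx(0.4)
        assert w["first_exon"] == pytest.approx(0.6)  # [10000,11000) is exon 1

    def test_interval_inside_first_intron(self):
        fa = feature_assignment([("chr1", 11_200, 11_800)], TOY_GENES,
                                TOY_LENGTHS)
        assert fa.weights.iloc[0]["first_intron"] == pytest.approx(1.0)

    def test_minus_strand_promoter_upstream_of_tx_end(self):
        regions = feature_regions(TOY_GENES, TOY_LENGTHS)
        assert (50_000, 52_000) in regions["promoter"]["chr1"]

    def test_minus_strand_first_exon_is_rightmost(self):
        regions = feature_regions(TOY_GENES, TOY_LENGTHS)
        assert (48_000, 50_000) in regions["first_exon"]["chr1"]

    def test_strandless_gene_rejected(self):
        g = GeneModel("g", "chr1", ".", 0, 100, exons=((0, 100),))
        with pytest.raises(ValueError, match="strand"):
            feature_regions([g], TOY_LENGTHS)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        ivs = []
        for _ in range(50):
            s = int(rng.integers(0, 95_000))
            ivs.append(("chr1", s, s + int(rng.integers(100, 5_000))))
        fa = feature_assignment(ivs, TOY_GENES, TOY_LENGTHS)
        assert np.allclose(fa.weights.sum(axis=1), 1.0)

    def test_category_bp_partitions_genome(self):
        fa = feature_assignment([("chr1", 0, 10)], TOY_GENES, TOY_LENGTHS)
        assert sum(fa.category_bp.values()) == TOY_LENGTHS["chr1"]

    def test_matches_brute_force_per_bp_oracle(self):
        """Per-base-pair category lookup reproduces the interval math."""
        regions = feature_regions(TOY_GENES, TOY_LENGTHS)

        def category_of(p):
            for cat, regs in regions.items():
                for s, e in regs.get("chr1", []):
                    if s <= p < e:
                        return cat
            return "intergenic"

        rng = np.random.default_rng(7)
        for _ in range(30):
            s = int(rng.integers(0, 99_000))
            e = s + int(rng.integers(1, 1_000))
            fa = feature_assignment([("chr1", s, e)], TOY_GENES, TOY_LENGTHS)
            counts = {}
            for p in range(s, e):
                c = category_of(p)
                counts[c] = counts.get(c, 0) + 1
            for cat in fa.weights.columns:
                assert fa.weights.iloc[0][cat] == pytest.approx(
                    counts.get(cat, 0) / (e - s))


class TestRegionOverlap:
    def test_odds_ratio_closed_form(self):
        regions = {"chr1": [(0, 7_000)]}
        pts = [("chr1", p) for p in
               [1_000, 2_000, 50_000, 60_000, 70_000, 80_000]]
        res = region_overlap_test(pts, regions, genome_bp=100_000)
        assert res.n_in == 2 and res.n_out == 4
        expected_or = (2 / 4) / (7_000 / 93_000)
        assert res.odds_ratio == pytest.approx(expected_or)

    def test_zero_overlap_gives_zero_or(self):
        res = region_overlap_test([("chr1", 50_000)], {"chr1": [(0, 1_000)]},
                                  genome_bp=100_000)
        assert res.odds_ratio == 0.0

    def test_degenerate_regions_rejected(self):
        with pytest.raises(ValueError):
            region_overlap_test([], {}, genome_bp=1_000)
        with pytest.raises(ValueError):
            region_overlap_test([], {"chr1": [(0, 1_000)]}, genome_bp=1_000)


class TestGcComparison:
    def test_identical_pairs_handled(self):
        res = gc_content_comparison({"c1": 0.4, "c2": 0.5},
                                    {"c1": 0.4, "c2": 0.5})
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_three_pair_closed_form(self):
        ev_gc = {"c1": 0.45, "c2": 0.50, "c3": 0.42}
        bg_gc = {"c1": 0.41, "c2": 0.43, "c3": 0.40}
        res = gc_content_comparison(ev_gc, bg_gc)
        d = np.array([0.04, 0.07, 0.02])
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.t_statistic == pytest.approx(t_expected)

    def test_chromosomes_without_events_dropped_and_counted(self):
        res = gc_content_comparison({"c1": 0.45, "c2": 0.5},
                                    {"c1": 0.4, "c2": 0.45, "c3": 0.4})
        assert res.n_dropped == 1 and len(res.pairs) == 2


class TestTransmissionBias:
    def test_reference_counts_give_c_018(self):
        tb = transmission_bias_from_counts(datasets.N_WS_CONVERSIONS,
                                           datasets.N_SW_CONVERSIONS)
        assert round(tb.p_hat, 2) == 0.59
        assert round(tb.c, 2) == 0.18
        assert (round(tb.ci_low, 2), round(tb.ci_high, 2)) == (0.52, 0.65)
        assert tb.p_value < 0.05

    def test_symmetric_counts(self):
        tb = transmission_bias_from_counts(50, 50)
        assert tb.p_hat == 0.5 and tb.c == 0.0 and tb.p_value == 1.0

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            transmission_bias_from_counts(0, 0)

    def test_counts_from_events(self):
        events = [NCOEvent("o", "paternal", "c", i, "A", "G", W_TO_S)
                  for i in range(3)]
        events.append(NCOEvent("o", "paternal", "c", 99, "G", "A", S_TO_W))
        tb = transmission_bias(events)
        assert tb.n_WS == 3 and tb.n_SW == 1

    def test_ci_contains_point_estimate(self):
        tb = transmission_bias_from_counts(30, 10)
        assert tb.ci_low <= tb.p_hat <= tb.ci_high
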