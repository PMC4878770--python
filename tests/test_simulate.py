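"""Simulator behaviour: site density, renewal-process calibration,
Z/PAR restriction, obligate crossover, determinism, error channels."""

import numpy as np
import pytest

from pedrecomb.genome import Chromosome, GenomeLayout
from pedrecomb.io import truth_co_frame, truth_nco_frame
from pedrecomb.pedigree import FEMALE, MALE, default_pedigree
from pedrecomb.simulate import (ErrorModel, MeiosisModel, genotype_table,
                                is_ws_pair, simulate_founders,
                                simulate_meiosis, simulate_pedigree)
from pedrecomb.variant_filter import mendelian_consistent


@pytest.fixture(scope="module")
def one_chrom():
    return GenomeLayout([Chromosome("c1", 10_000_000)], snp_density=1e-4)


class TestFounders:
    def test_site_count_matches_density(self, one_chrom):
        cat, _ = simulate_founders(one_chrom, 1)
        n = cat.n_sites("c1")
        mean = 1e-4 * 10_000_000
        assert abs(n - mean) < 4 * np.sqrt(mean)  # Poisson, 4 SD

    def test_zero_density_rejected(self):
        layout = GenomeLayout([Chromosome("c1", 1000)], snp_density=0.0)
        with pytest.raises(ValueError):
            simulate_founders(layout, 1)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            Chromosome("c1", 0)

    def test_deterministic_under_seed(self, one_chrom):
        cat1, f1 = simulate_founders(one_chrom, 7)
        cat2, f2 = simulate_founders(one_chrom, 7)
        assert np.array_equal(cat1.pos["c1"], cat2.pos["c1"])
        assert np.array_equal(cat1.ref["c1"], cat2.ref["c1"])
        for a, b in zip(f1, f2):
            assert np.array_equal(a["c1"], b["c1"])

    def test_sites_segregate_and_mix_ws_types(self, one_chrom):
        cat, founders = simulate_founders(one_chrom, 3)
        alleles = np.stack([f["c1"] for f in founders])  # (4, 2, n)
        flat = alleles.reshape(8, -1)
        assert (flat.min(axis=0) == 0).all() and (flat.max(axis=0) == 1).all()
        ws = [is_ws_pair(r, a) for r, a in zip(cat.ref["c1"], cat.alt["c1"])]
        assert 0 < sum(ws) < len(ws)


class TestMeiosis:
    def test_poisson_crossover_count_at_shape_one(self, one_chrom):
        """Stationary renewal with shape 1 gives Poisson counts with
        mean rate * L / 100."""
        rng = np.random.default_rng(0)
        cat, founders = simulate_founders(one_chrom, rng)
        m = MeiosisModel(rate_male_cM_per_Mb=20.0, obligate_co=False,
                         interference_shape=1.0, nco_rate_per_Mb=0)
        counts = [len(simulate_meiosis(founders[0], MALE, m, cat, one_chrom,
                                       rng)[1])
                  for _ in range(2000)]
        counts = np.asarray(counts)
        expected = 20.0 * 10 / 100
        se = np.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_interference_reduces_count_variance(self, one_chrom):
        rng = np.random.default_rng(1)
        cat, founders = simulate_founders(one_chrom, rng)
        var = {}
        for nu in (1.0, 10.0):
            m = MeiosisModel(rate_male_cM_per_Mb=30.0, obligate_co=False,
                             interference_shape=nu, nco_rate_per_Mb=0)
            counts = [len(simulate_meiosis(founders[0], MALE, m, cat,
                                           one_chrom, rng)[1])
                      for _ in range(800)]
            var[nu] = np.var(counts)
        assert var[10.0] < 0.6 * var[1.0]

    def test_unknown_sex_rejected(self, one_chrom):
        cat, founders = simulate_founders(one_chrom, 1)
        with pytest.raises(ValueError, match="sex"):
            simulate_meiosis(founders[0], "hermaphrodite", MeiosisModel(),
                             cat, one_chrom, 1)

    def test_obligate_co_forces_event_per_chromosome(self, one_chrom):
        rng = np.random.default_rng(2)
        cat, founders = simulate_founders(one_chrom, rng)
        m = MeiosisModel(rate_male_cM_per_Mb=1.0, obligate_co=True,
                         nco_rate_per_Mb=0)
        for _ in range(50):
            _, cos, _, _ = simulate_meiosis(founders[0], MALE, m, cat,
                                            one_chrom, rng)
            assert len(cos) >= 1

    def test_female_z_crossovers_confined_to_par(self, layout):
        rng = np.random.default_rng(3)
        m = MeiosisModel(rate_female_cM_per_Mb=50.0, obligate_co=False,
                         nco_rate_per_Mb=0.5)
        par = layout.get("chrZ").par
        found = 0
        cat, founders = simulate_founders(layout, rng)
        for rep in range(200):
            _, cos, tracts, _ = simulate_meiosis(founders[1], FEMALE, m, cat,
                                                 layout, rng)
            for ch, p in cos:
                if ch == "chrZ":
                    found += 1
                    assert par[0] <= p < par[1]
            for ch, s, e, _ in tracts:
                if ch == "chrZ":
                    assert par[0] <= s and e <= par[1]
            if found > 5:
                break
        assert found > 0

    def test_neutral_conversion_transmission_is_symmetric(self):
        """With c = 0 the strong allele is transmitted in about half of
        the weak:strong conversions."""
        layout = GenomeLayout([Chromosome("c1", 10_000_000)], snp_density=5e-4)
        m = MeiosisModel(obligate_co=False, nco_rate_per_Mb=10.0,
                         tract_length_mean=2000, gbgc_c=0.0)
        rng = np.random.default_rng(4)
        cat, founders = simulate_founders(layout, rng)
        n_ws = n_total = 0
        for _ in range(200):
            _, _, tracts, _ = simulate_meiosis(founders[0], MALE, m, cat,
                                               layout, rng)
            for _, _, _, convs in tracts:
                for c in convs:
                    if is_ws_pair(c.from_base, c.to_base):
                        n_total += 1
                        if c.to_base in "GC":
                            n_ws += 1
        assert n_total > 300
        frac = n_ws / n_total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_total)


class TestPedigreeSim:
    def test_map_length_consistency(self):
        """Mean simulated crossover count x 100 / meioses matches the
        configured map length within 3 SE."""
        layout = GenomeLayout([Chromosome("c1", 20_000_000)], snp_density=2e-5)
        rate = 5.0
        m = MeiosisModel(rate_female_cM_per_Mb=rate, rate_male_cM_per_Mb=rate,
                         obligate_co=False, nco_rate_per_Mb=0)
        counts = []
        for rep in range(30):
            sim = simulate_pedigree(layout, m, 9000 + rep)
            counts.append(len(sim.truth.co_breakpoints))
        counts = np.asarray(counts, dtype=float)
        n_meioses = 10
        expected_cM = rate * 20.0  # per meiosis
        observed_cM = 100.0 * counts.mean() / n_meioses
        se_cM = 100.0 * counts.std(ddof=1) / np.sqrt(len(counts)) / n_meioses
        assert abs(observed_cM - expected_cM) < 3 * se_cM

    def test_truth_tables_byte_identical_under_seed(self, layout):
        frames = []
        for _ in range(2):
            sim = simulate_pedigree(layout, MeiosisModel(), seed=11)
            frames.append((truth_co_frame(sim.truth).to_csv(),
                           truth_nco_frame(sim.truth).to_csv()))
        assert frames[0] == frames[1]

    def test_female_offspring_hemizygous_on_nonpar_z(self, clean_sim):
        ped = clean_sim.pedigree
        female_f2 = [o for o in ped.offspring if ped.is_female(o)][0]
        haps = clean_sim.haplotypes[female_f2]["chrZ"]
        par = clean_sim.layout.get("chrZ").par
        pos0 = clean_sim.catalog.pos["chrZ"] - 1
        outside = (pos0 < par[0]) | (pos0 >= par[1])
        assert (haps[1, outside] == -1).all()  # no maternal Z outside PAR
        assert (haps[0] >= 0).all()  # paternal Z everywhere


class TestErrorModel:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            ErrorModel(genotype_error_rate=1.5)

    def test_all_missing_removes_every_genotype(self, clean_sim):
        t = genotype_table(clean_sim, ErrorModel(missing_rate=1.0), seed=0)
        assert (t.gt[:, :, 0] == -1).all()

    def test_genotype_errors_create_mendelian_violations(self, clean_sim):
        t = genotype_table(clean_sim, ErrorModel(genotype_error_rate=0.01),
                           seed=1)
        ok = mendelian_consistent(t, clean_sim.pedigree)
        assert (~ok).sum() >= 1

    def test_w_contamination_sites_tagged_and_patterned(self, clean_sim):
        t = genotype_table(clean_sim,
                           ErrorModel(w_contamination_rate=0.01), seed=2)
        tagged = t.meta["w_artifact_sites"]
        assert len(tagged) > 0
        ped = clean_sim.pedigree
        idx = {(c, p): i for i, (c, p) in enumerate(zip(t.chrom, t.pos))}
        for chrom, pos in tagged:
            site = t.site(idx[(chrom, pos)])
            assert all(site.is_het(s) for s in ped.females)
            assert all(site.alleles(s) == (0, 0) for s in ped.males)
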