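"""Shared fixtures: a desk-scale layout, the default pedigree, and
helpers to build hand-crafted genotype tables site by site."""

from __future__ import annotations

import numpy as np
import pytest

from pedrecomb.genome import Chromosome, GenomeLayout, default_layout
from pedrecomb.pedigree import default_pedigree
from pedrecomb.simulate import ErrorModel, MeiosisModel, simulate_pedigree
from pedrecomb.sites import HAPLOID, MISSING, GenotypeTable, SiteGenotypes


@pytest.fixture(scope="session")
def pedigree():
    return default_pedigree()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout([Chromosome("chr1", 10_000_000)], snp_density=1e-4)


@pytest.fixture(scope="session")
def clean_sim(layout):
    """One clean simulated pedigree shared across read-only tests."""
    return simulate_pedigree(layout, MeiosisModel(), seed=42)


def parse_gt(s: str) -> tuple[int, int]:
    if s in ("./.", "."):
        return (MISSING, MISSING)
    if "/" in s:
        a, b = sorted(int(x) for x in s.split("/"))
        return (a, b)
    return (int(s), HAPLOID)


def make_site(pedigree, genotypes: dict[str, str], chrom="chr1", pos=1000,
              ref="A", alt="G", dp=42, gq=99, dp_over=None, gq_over=None,
              ad_over=None, **flags) -> SiteGenotypes:
    """Build a single site; per-sample overrides via *_over dicts."""
    gt, dpd, gqd, add = {}, {}, {}, {}
    for s in pedigree.samples:
        g = parse_gt(genotypes.get(s, "0/0"))
        gt[s] = g
        d = (dp_over or {}).get(s, dp)
        dpd[s] = d
        gqd[s] = (gq_over or {}).get(s, gq)
        if ad_over and s in ad_over:
            add[s] = ad_over[s]
        elif g[1] == HAPLOID:
            add[s] = (d, 0) if g[0] == 0 else (0, d)
        elif g == (0, 1):
            add[s] = (d // 2, d - d // 2)
        elif g == (1, 1):
            add[s] = (0, d)
        else:
            add[s] = (d, 0)
    return SiteGenotypes(chrom=chrom, pos=pos, ref=ref, alt=alt, gt=gt,
                         dp=dpd, gq=gqd, ad=add, **flags)


def make_table(pedigree, sites: list[SiteGenotypes]) -> GenotypeTable:
    return GenotypeTable.from_sites(pedigree.samples, sites)
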