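"""In-memory container for multi-sample genotype data.

A :class:`GenotypeTable` holds one array per FORMAT field across all
sites and samples, which keeps the site-level quality filters vectorised.
A single site can be viewed as a :class:`SiteGenotypes` for the per-site
phasing logic and for tests.

Genotype encoding (``gt`` array, shape ``(n_sites, n_samples, 2)``):

* allele indexes ``0`` (REF) / ``1`` (ALT)
* ``MISSING = -1`` — no call
* second slot ``HAPLOID = -2`` — haploid call (single allele in slot 0),
  used for female genotypes on the non-PAR Z chromosome
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
HAPLOID = -2


@dataclass
class SiteGenotypes:
    """One variant site with per-individual genotype evidence."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt: dict[str, tuple[int, ...]]
    dp: dict[str, int]
    gq: dict[str, int]
    ad: dict[str, tuple[int, int]]
    ad_other: dict[str, int] = field(default_factory=dict)
    in_repeat: bool = False
    in_gap: bool = False
    tranche_pass90: bool = True
    tranche_pass999: bool = True
    biallelic: bool = True

    def alleles(self, sample: str) -> tuple[int, ...]:
        """Called alleles for a sample: 2 (diploid), 1 (haploid) or 0 (missing)."""
        g = self.gt[sample]
        if len(g) == 2 and g[1] == HAPLOID:
            g = (g[0],)
        return tuple(a for a in g if a >= 0)

    def is_het(self, sample: str) -> bool:
        a = self.alleles(sample)
        return len(a) == 2 and a[0] != a[1]

    def base(self, allele: int) -> str:
        return self.ref if allele == 0 else self.alt


class GenotypeTable:
    """Column-wise store of biallelic SNP genotypes for a fixed sample set."""

    FLAG_NAMES = ("in_repeat", "in_gap", "tranche_pass90", "tranche_pass999",
                  "biallelic")

    def __init__(self, samples, chrom, pos, ref, alt, gt, dp, gq, ad,
                 ad_other=None, flags=None, meta=None):
        n = len(pos)
        s = len(samples)
        self.samples = list(samples)
        self._sample_index = {name: i for i, name in enumerate(self.samples)}
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.gt = np.asarray(gt, dtype=np.int8).reshape(n, s, 2)
        self.dp = np.asarray(dp, dtype=np.int32).reshape(n, s)
        self.gq = np.asarray(gq, dtype=np.int32).reshape(n, s)
        self.ad = np.asarray(ad, dtype=np.int32).reshape(n, s, 2)
        self.ad_other = (np.zeros((n, s), dtype=np.int32) if ad_other is None
                         else np.asarray(ad_other, dtype=np.int32).reshape(n, s))
        self.flags = {}
        flags = flags or {}
        for name in self.FLAG_NAMES:
            default = name.startswith("tranche") or name == "biallelic"
            arr = flags.get(name)
            if arr is None:
                arr = np.full(n, default, dtype=bool)
            self.flags[name] = np.asarray(arr, dtype=bool)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self._sample_index[name]
        except KeyError:
            raise KeyError(f"sample {name!r} not in table") from None

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.samples, self.chrom[mask], self.pos[mask], self.ref[mask],
            self.alt[mask], self.gt[mask], self.dp[mask], self.gq[mask],
            self.ad[mask], self.ad_other[mask],
            flags={k: v[mask] for k, v in self.flags.items()},
            meta=self.meta,
        )

    def site(self, i: int) -> SiteGenotypes:
        return SiteGenotypes(
            chrom=str(self.chrom[i]), pos=int(self.pos[i]),
            ref=str(self.ref[i]), alt=str(self.alt[i]),
            gt={s: tuple(int(a) for a in self.gt[i, j])
                for j, s in enumerate(self.samples)},
            dp={s: int(self.dp[i, j]) for j, s in enumerate(self.samples)},
            gq={s: int(self.gq[i, j]) for j, s in enumerate(self.samples)},
            ad={s: (int(self.ad[i, j, 0]), int(self.ad[i, j, 1]))
                for j, s in enumerate(self.samples)},
            ad_other={s: int(self.ad_other[i, j])
                      for j, s in enumerate(self.samples)},
            in_repeat=bool(self.flags["in_repeat"][i]),
            in_gap=bool(self.flags["in_gap"][i]),
            tranche_pass90=bool(self.flags["tranche_pass90"][i]),
            tranche_pass999=bool(self.flags["tranche_pass999"][i]),
            biallelic=bool(self.flags["biallelic"][i]),
        )

    def sites(self):
        for i in range(len(self)):
            yield self.site(i)

    def sorted(self) -> "GenotypeTable":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.subset(order)

    def is_sorted_within_chrom(self) -> bool:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                return False
        return True

    @staticmethod
    def from_sites(samples, sites: list[SiteGenotypes]) -> "GenotypeTable":
        n = len(sites)
        gt = np.full((n, len(samples), 2), MISSING, dtype=np.int8)
        dp = np.zeros((n, len(samples)), dtype=np.int32)
        gq = np.zeros((n, len(samples)), dtype=np.int32)
        ad = np.zeros((n, len(samples), 2), dtype=np.int32)
        ado = np.zeros((n, len(samples)), dtype=np.int32)
        flags = {name: np.zeros(n, dtype=bool) for name in GenotypeTable.FLAG_NAMES}
        for i, s in enumerate(sites):
            for j, name in enumerate(samples):
                g = s.gt.get(name, (MISSING, MISSING))
                gt[i, j] = (g + (MISSING,))[:2] if len(g) < 2 else g[:2]
                dp[i, j] = s.dp.get(name, 0)
                gq[i, j] = s.gq.get(name, 0)
                ad[i, j] = s.ad.get(name, (0, 0))
                ado[i, j] = s.ad_other.get(name, 0)
            for name in GenotypeTable.FLAG_NAMES:
                flags[name][i] = getattr(s, name)
        return GenotypeTable(
            samples, [s.chrom for s in sites], [s.pos for s in sites],
            [s.ref for s in sites], [s.alt for s in sites],
            gt, dp, gq, ad, ado, flags=flags,
        )
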