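"""Non-crossover gene-conversion detection and its filter cascade.

A non-crossover (NCO) candidate is a single informative site whose
grandparent-of-origin label disagrees with the surrounding haploblock.
Because a single miscalled genotype produces exactly the same signal,
candidates pass a stringent conjunction of filters before being accepted
as gene-conversion events: the stricter 90% recalibration tranche,
distance from indels, SNP-cluster and deviating-site density limits,
no third-allele reads, allele-balance >= 25% in every heterozygote, and
exclusion of the all-females-heterozygous / all-males-homozygous-
reference pattern that arises when W-linked reads map to a male-derived
assembly.

Events at weak:strong sites are classified by conversion direction:
``W>S`` when a weak (A/T) background allele was replaced by a strong
(G/C) transmitted allele, ``S>W`` for the reverse, ``neither`` for
W:W or S:S pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .co_detect import NcoCandidate, PruneResult
from .intervals import IntervalSet
from .pedigree import Pedigree
from .phasing import classify_informative
from .sites import GenotypeTable
from .simulate import STRONG, WEAK

W_TO_S = "W>S"
S_TO_W = "S>W"
NEITHER = "neither"

FILTER_TRACE_ORDER = ("has_ad", "tranche90", "indel_10bp", "snp_cluster_30bp",
                      "deviating_5kb", "third_allele", "allele_balance",
                      "w_pattern")

INDEL_PROXIMITY_BP = 10
CLUSTER_WINDOW_BP = 30
CLUSTER_MAX_SNPS = 3
DEVIATING_WINDOW_BP = 5_000
DEVIATING_MAX_SITES = 2
MIN_ALLELE_FRACTION = 0.25


def classify_direction(untransmitted: str, transmitted: str) -> str:
    """Conversion direction for a (background, transmitted) base pair."""
    for b in (untransmitted, transmitted):
        if b not in WEAK and b not in STRONG:
            raise ValueError(f"non-ACGT allele {b!r}")
    if untransmitted in WEAK and transmitted in STRONG:
        return W_TO_S
    if untransmitted in STRONG and transmitted in WEAK:
        return S_TO_W
    return NEITHER


@dataclass(frozen=True)
class NCOEvent:
    offspring: str
    side: str
    chrom: str
    pos: int
    from_base: str  # allele on the surrounding (background) haplotype
    to_base: str  # allele actually transmitted
    direction: str
    filter_trace: tuple[tuple[str, bool], ...] = ()

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.filter_trace)


def collect_candidates(prune_results: dict[tuple, PruneResult]
                       ) -> list[NcoCandidate]:
    """Gather single-site phase mismatches from block pruning."""
    out: list[NcoCandidate] = []
    for res in prune_results.values():
        out.extend(res.nco_candidates)
    return sorted(out, key=lambda c: (c.chrom, c.pos, c.offspring, c.side))


def _near_indel(chrom: str, pos: int, indels: IntervalSet) -> bool:
    for s, e in indels.get(chrom, ()):
        # candidate overlaps, or lies within 10 bp of, the indel span
        if s - INDEL_PROXIMITY_BP <= pos - 1 < e + INDEL_PROXIMITY_BP:
            return True
    return False


def _in_snp_cluster(chrom: str, pos: int, context: GenotypeTable) -> bool:
    """More than 3 called SNPs in some 30 bp window containing the site."""
    q = context.pos[context.chrom == chrom]
    near = np.sort(q[(q >= pos - CLUSTER_WINDOW_BP) & (q <= pos + CLUSTER_WINDOW_BP)])
    for start in near:
        if start > pos:
            break
        in_win = near[(near >= start) & (near <= start + CLUSTER_WINDOW_BP)]
        if pos in in_win and len(in_win) > CLUSTER_MAX_SNPS:
            return True
    return False


def _deviating_fail_positions(candidates: list[NcoCandidate]) -> set[tuple]:
    """Candidates violating 'no more than two deviating sites in 5 kb'.

    Evaluated per offspring/side label sequence: whenever three or more
    candidates fall inside one 5 kb window, all of them fail.
    """
    fail: set[tuple] = set()
    bykey: dict[tuple, list[NcoCandidate]] = {}
    for c in candidates:
        bykey.setdefault((c.offspring, c.side, c.chrom), []).append(c)
    for key, group in bykey.items():
        group = sorted(group, key=lambda c: c.pos)
        pos = [c.pos for c in group]
        for i in range(len(pos)):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[i] <= DEVIATING_WINDOW_BP:
                j += 1
            if j - i + 1 > DEVIATING_MAX_SITES:
                for k in range(i, j + 1):
                    fail.add((group[k].offspring, group[k].side,
                              group[k].chrom, group[k].pos))
    return fail


def filter_nco(candidates: list[NcoCandidate], table: GenotypeTable,
               pedigree: Pedigree, context: GenotypeTable | None = None,
               indels: IntervalSet | None = None
               ) -> tuple[list[NCOEvent], list[NCOEvent]]:
    """Apply the NCO filter cascade; return (accepted, all evaluated).

    ``table`` is the filtered site set the candidates were phased from;
    ``context`` is the larger all-individual call set used for the
    SNP-cluster density test (defaults to ``table``).  The cascade is a
    pure conjunction — every filter is evaluated and recorded in
    ``filter_trace`` — so accept/reject does not depend on order.
    """
    context = context if context is not None else table
    indels = indels or {}
    site_index = {(str(c), int(p)): i
                  for i, (c, p) in enumerate(zip(table.chrom, table.pos))}
    deviating_fail = _deviating_fail_positions(candidates)
    females = [s for s in pedigree.samples if pedigree.is_female(s)]
    males = [s for s in pedigree.samples if not pedigree.is_female(s)]
    events: list[NCOEvent] = []
    for cand in candidates:
        i = site_index.get((cand.chrom, cand.pos))
        if i is None:
            raise KeyError(f"candidate site {cand.chrom}:{cand.pos} not in table")
        site = table.site(i)
        mapping = classify_informative(site, cand.side, pedigree)
        if mapping is None:
            raise ValueError(
                f"candidate {cand.chrom}:{cand.pos} not informative for "
                f"side {cand.side}")
        inv = {v: k for k, v in mapping.items()}
        to_allele = inv[cand.label]
        from_allele = inv[cand.surrounding_label]
        from_base = site.base(from_allele)
        to_base = site.base(to_allele)
        direction = classify_direction(from_base, to_base)

        trace: list[tuple[str, bool]] = []
        het_samples = [s for s in pedigree.samples if site.is_het(s)]
        has_ad = all(sum(site.ad[s]) > 0 for s in het_samples)
        trace.append(("has_ad", has_ad))
        trace.append(("tranche90", site.tranche_pass90))
        trace.append(("indel_10bp", not _near_indel(cand.chrom, cand.pos, indels)))
        trace.append(("snp_cluster_30bp",
                      not _in_snp_cluster(cand.chrom, cand.pos, context)))
        key = (cand.offspring, cand.side, cand.chrom, cand.pos)
        trace.append(("deviating_5kb", key not in deviating_fail))
        third = any(site.ad_other.get(s, 0) > 0 for s in pedigree.samples)
        trace.append(("third_allele", not third))
        balance_ok = True
        for s in het_samples:
            tot = sum(site.ad[s])
            if tot > 0 and min(site.ad[s]) / tot < MIN_ALLELE_FRACTION:
                balance_ok = False
        trace.append(("allele_balance", balance_ok))
        w_pattern = (len(females) > 0 and len(males) > 0
                     and all(site.is_het(s) for s in females)
                     and all(site.alleles(s) in ((0, 0), (0,))
                             for s in males))
        trace.append(("w_pattern", not w_pattern))

        event = NCOEvent(cand.offspring, cand.side, cand.chrom, cand.pos,
                         from_base, to_base, direction,
                         filter_trace=tuple(trace))
        events.append(event)
    return [e for e in events if e.passed], events


def events_to_frame(events: list[NCOEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "offspring": e.offspring, "side": e.side, "chrom": e.chrom,
        "pos": e.pos, "from_base": e.from_base, "to_base": e.to_base,
        "direction": e.direction,
        "filter_trace": ";".join(f"{k}={'P' if ok else 'F'}"
                                 for k, ok in e.filter_trace),
    } for e in events], columns=["offspring", "side", "chrom", "pos",
                                 "from_base", "to_base", "direction",
                                 "filter_trace"])


def events_from_frame(df: pd.DataFrame) -> list[NCOEvent]:
    out = []
    for r in df.itertuples():
        out.append(NCOEvent(str(r.offspring), str(r.side), str(r.chrom),
                            int(r.pos), str(r.from_base), str(r.to_base),
                            str(r.direction)))
    return out
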