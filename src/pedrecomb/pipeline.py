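"""End-to-end orchestration: simulate -> filter -> phase -> detect -> stats.

The stage functions operate on in-memory objects so the pipeline can be
run without touching disk (as the tests and recovery experiments do);
the CLI wraps them with file I/O at each stage boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import co_detect, nco_detect, recomb_stats
from .config import RunConfig
from .genome import GenomeLayout
from .pedigree import MATERNAL, PATERNAL, Pedigree
from .phasing import PhasedSites, phase_offspring
from .simulate import (ErrorModel, MeiosisModel, PedigreeSim, SimTruth,
                       genotype_table, simulate_pedigree)
from .sites import GenotypeTable
from .variant_filter import FilterReport, apply_z_semantics, filter_sites


@dataclass
class PipelineResult:
    sim: PedigreeSim
    table: GenotypeTable
    filter_report: FilterReport
    n_z_removed: int
    phased: PhasedSites
    co_events: list
    co_summary: co_detect.ResolutionSummary
    nco_events: list
    nco_evaluated: list
    prune_results: dict
    report: dict = field(default_factory=dict)


def run_simulated_pipeline(config: RunConfig | None = None, seed: int = 1,
                           layout: GenomeLayout | None = None,
                           meiosis: MeiosisModel | None = None,
                           errors: ErrorModel | None = None,
                           pedigree: Pedigree | None = None,
                           compute_stats: bool = True) -> PipelineResult:
    """Simulate a pedigree and run every detection stage on it."""
    cfg = config or RunConfig()
    layout = layout or cfg.layout
    meiosis = meiosis or cfg.meiosis
    errors = errors or cfg.errors
    th = cfg.thresholds

    sim = simulate_pedigree(layout, meiosis, seed, pedigree=pedigree)
    table = genotype_table(sim, errors, seed=np.random.default_rng(seed + 10_000))
    table, n_z_removed = apply_z_semantics(table, sim.pedigree, layout)
    filtered, report = filter_sites(
        table, mean_autosomal_coverage=errors.depth_mean,
        pedigree=sim.pedigree, layout=layout,
        dp_min=th.dp_min, dp_max_factor=th.dp_max_factor, gq_min=th.gq_min)
    phased = phase_offspring(filtered, sim.pedigree)
    events, summary, prunes = co_detect.detect_crossovers(
        phased, min_sites=th.min_sites, max_window=th.max_event_window_bp)
    candidates = nco_detect.collect_candidates(prunes)
    accepted, evaluated = nco_detect.filter_nco(
        candidates, filtered, sim.pedigree, context=filtered)
    result = PipelineResult(
        sim=sim, table=filtered, filter_report=report, n_z_removed=n_z_removed,
        phased=phased, co_events=events, co_summary=summary,
        nco_events=accepted, nco_evaluated=evaluated, prune_results=prunes)
    if compute_stats:
        result.report = compute_report(result, cfg)
    return result


def compute_report(result: PipelineResult, cfg: RunConfig) -> dict:
    """Aggregate counts and the downstream statistics into one report."""
    layout = result.sim.layout
    ped = result.sim.pedigree
    chrom_lengths = {c.name: c.length for c in layout}
    z_names = {c.name for c in layout if c.is_z}
    n_off = len(ped.offspring)
    table = recomb_stats.build_map_table(
        result.co_events, chrom_lengths, n_meioses=2 * n_off,
        n_meioses_per_sex=n_off, z_chroms=z_names)
    meioses = [(o, s) for o in ped.offspring for s in (PATERNAL, MATERNAL)]
    report = {
        "counts": {
            "sites_in": result.filter_report.input_sites,
            "sites_surviving": result.filter_report.surviving,
            "z_het_females_removed": result.n_z_removed,
            "informative_site_sides": result.phased.n_informative_sites,
            "untraceable": result.phased.n_untraceable,
            "co_events": len(result.co_events),
            "nco_events": len(result.nco_events),
            "nco_candidates": len(result.nco_evaluated),
            "truth_co": len(result.sim.truth.co_breakpoints),
            "truth_nco_conversions": len(result.sim.truth.conversions()),
        },
        "filter_report": dict(result.filter_report.removed),
        "resolution": result.co_summary.to_dict(),
        "map": {
            "total_autosomal_cM": table.total_autosomal_cM(),
            "female_autosomal_cM": table.sex_map_cM(MATERNAL),
            "male_autosomal_cM": table.sex_map_cM(PATERNAL),
        },
    }
    if result.co_events:
        hot = recomb_stats.hotspot_randomization(
            result.co_events, chrom_lengths,
            pair_distance=cfg.thresholds.hotspot_pair_bp,
            n_perm=1000, seed=cfg.seed)
        report["hotspot"] = {"observed_pairs": hot.observed_pairs,
                             "p_value": hot.p_value}
        coc = recomb_stats.coincidence_coefficient(
            result.co_events, chrom_lengths, meioses,
            window_bp=cfg.thresholds.coc_window_bp)
        valid = np.isfinite(coc.coc)
        report["coc"] = {
            "n_bins": int(valid.sum()),
            "mean_coc": float(np.nanmean(coc.coc)) if valid.any() else None,
        }
    ws = [e for e in result.nco_events
          if e.direction in (nco_detect.W_TO_S, nco_detect.S_TO_W)]
    if ws:
        tb = recomb_stats.transmission_bias(ws)
        report["gbgc"] = {"n_WS": tb.n_WS, "n_SW": tb.n_SW,
                          "p_hat": tb.p_hat, "c": tb.c,
                          "ci": [tb.ci_low, tb.ci_high],
                          "p_value": tb.p_value}
    return report


# ---------------------------------------------------------------------------
# truth-recovery scoring (used by the recovery experiments and tests)


@dataclass
class RecoveryScore:
    n_truth: int  # detectable truth events (see below)
    n_called: int
    n_matched_truth: int  # truth events contained in a called interval
    n_true_positive_calls: int

    @property
    def recall(self) -> float:
        return self.n_matched_truth / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (self.n_true_positive_calls / self.n_called
                if self.n_called else float("nan"))


def score_co_recovery(truth: SimTruth, events: list, phased: PhasedSites,
                      ) -> RecoveryScore:
    """Compare called crossover intervals with true breakpoints.

    A truth breakpoint is *detectable* when at least one informative site
    flanks it on each side in the same (offspring, side, chromosome)
    label sequence; breakpoints sharing one inter-marker interval are
    collapsed into a single expected event (an even number of
    co-occurring breakpoints is invisible, an odd number looks like
    one).  A called event is a true positive when its interval contains
    a truth breakpoint of its own meiosis.
    """
    expected: dict[tuple, list[tuple[int, int]]] = {}
    n_truth = 0
    bykey: dict[tuple, list[int]] = {}
    for b in truth.co_breakpoints:
        bykey.setdefault((b.offspring, b.side, b.chrom), []).append(b.pos)
    for key, positions in bykey.items():
        pos_sites, _ = phased.labels(*key)
        if len(pos_sites) < 2:
            continue
        intervals: dict[int, int] = {}
        for p in positions:
            # the origin switch falls between the last site at pos <= p
            # and the first site at pos > p
            idx = int(np.searchsorted(pos_sites, p, side="right"))
            if idx == 0 or idx == len(pos_sites):
                continue  # outside the informative span: undetectable
            intervals[idx] = intervals.get(idx, 0) + 1
        ivs = [(int(pos_sites[i - 1]), int(pos_sites[i]))
               for i, cnt in intervals.items() if cnt % 2 == 1]
        if ivs:
            expected[key] = ivs
            n_truth += len(ivs)
    n_matched = 0
    n_tp = 0
    for e in events:
        key = (e.offspring, e.side, e.chrom)
        hit = False
        for lo, hi in expected.get(key, []):
            if e.left <= lo and hi <= e.right:
                hit = True
        if hit:
            n_tp += 1
    for key, ivs in expected.items():
        for lo, hi in ivs:
            for e in events:
                if ((e.offspring, e.side, e.chrom) == key
                        and e.left <= lo and hi <= e.right):
                    n_matched += 1
                    break
    return RecoveryScore(n_truth=n_truth, n_called=len(events),
                         n_matched_truth=n_matched,
                         n_true_positive_calls=n_tp)
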