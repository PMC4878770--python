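"""Haploblock construction, error-block pruning and crossover calling.

Consecutive informative sites with the same grandparent-of-origin label
form a haploblock; a crossover is called in the interval between the
outermost sites of two adjacent blocks with different labels.  Short
interior blocks whose two label switches fall within 1 Mb are treated
as phasing/genotyping error (at most one real recombination event is
expected per Mb): single-site blocks become non-crossover candidates,
multi-site short blocks are logged as suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, interval_overlaps

MIN_SITES_DEFAULT = 3
MAX_EVENT_WINDOW_BP = 1_000_000
RESOLUTION_FINE = 5_000
RESOLUTION_COARSE = 10_000


@dataclass(frozen=True)
class Haploblock:
    offspring: str
    side: str
    chrom: str
    start: int  # first informative-site position (1-based)
    end: int  # last informative-site position (1-based)
    label: int
    n_sites: int


@dataclass(frozen=True)
class CrossoverEvent:
    """A crossover localised to the half-open bp interval (left, right]."""

    offspring: str
    side: str
    chrom: str
    left: int  # last site of the left block
    right: int  # first site of the right block
    overlaps_gap: bool = False

    @property
    def interval_length(self) -> int:
        return self.right - self.left

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left + self.right)

    @property
    def resolution_class(self) -> str:
        if self.interval_length < RESOLUTION_FINE:
            return "<5kb"
        if self.interval_length < RESOLUTION_COARSE:
            return "<10kb"
        return ">=10kb"


@dataclass(frozen=True)
class NcoCandidate:
    """A single-site phase mismatch inside a haploblock."""

    offspring: str
    side: str
    chrom: str
    pos: int
    label: int  # the mismatching label at this site
    surrounding_label: int


def build_haploblocks(positions: np.ndarray, labels: np.ndarray,
                      offspring: str = "", side: str = "",
                      chrom: str = "") -> list[Haploblock]:
    """Group a sorted origin-label sequence into maximal same-label runs."""
    positions = np.asarray(positions)
    labels = np.asarray(labels)
    if len(positions) != len(labels):
        raise ValueError("positions and labels must have equal length")
    if len(positions) == 0:
        return []
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    blocks: list[Haploblock] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            blocks.append(Haploblock(
                offspring=offspring, side=side, chrom=chrom,
                start=int(positions[run_start]), end=int(positions[i - 1]),
                label=int(labels[run_start]), n_sites=i - run_start))
            run_start = i
    return blocks


@dataclass
class PruneResult:
    blocks: list[Haploblock]
    nco_candidates: list[NcoCandidate] = field(default_factory=list)
    suspects: list[Haploblock] = field(default_factory=list)


def _merge(a: Haploblock, b: Haploblock) -> Haploblock:
    return Haploblock(a.offspring, a.side, a.chrom, a.start, b.end, a.label,
                      a.n_sites + b.n_sites)


def prune_blocks(blocks: list[Haploblock], min_sites: int = MIN_SITES_DEFAULT,
                 max_window: int = MAX_EVENT_WINDOW_BP) -> PruneResult:
    """Remove error-like short blocks until a fixed point.

    An interior block with fewer than ``min_sites`` sites whose two
    flanking label switches lie within ``max_window`` bp (measured from
    the last site of the left neighbour to the first site of the right
    neighbour) is removed; its equal-label neighbours merge.  Removed
    single-site blocks are emitted as non-crossover candidates, removed
    multi-site blocks logged as suspect.  The scan restarts leftmost
    after every removal, which makes the fixed point deterministic.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    out = list(blocks)
    result = PruneResult(blocks=out)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(out) - 1):
            blk = out[i]
            prev, nxt = out[i - 1], out[i + 1]
            if blk.n_sites < min_sites and nxt.start - prev.end <= max_window:
                if blk.n_sites == 1 and prev.label == nxt.label:
                    result.nco_candidates.append(NcoCandidate(
                        blk.offspring, blk.side, blk.chrom, blk.start,
                        blk.label, prev.label))
                else:
                    result.suspects.append(blk)
                if prev.label == nxt.label:
                    out[i - 1:i + 2] = [_merge(prev, nxt)]
                else:
                    del out[i]
                changed = True
                break
    result.blocks = out
    return result


@dataclass
class ResolutionSummary:
    n_events: int
    median_bp: float
    median_bp_no_gap: float
    frac_lt_5kb: float
    frac_lt_10kb: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def call_crossovers(blocks: list[Haploblock],
                    gaps: IntervalSet | None = None,
                    ) -> tuple[list[CrossoverEvent], ResolutionSummary]:
    """Call one crossover per adjacent block pair with differing labels.

    ``blocks`` must belong to a single (offspring, side, chromosome) and
    be pruned; use :func:`call_all_crossovers` for a whole phased set.
    """
    events: list[CrossoverEvent] = []
    for left, right in zip(blocks, blocks[1:]):
        if left.label == right.label:
            continue
        overlaps = bool(gaps) and interval_overlaps(
            left.chrom, left.end, right.start, gaps or {})
        events.append(CrossoverEvent(
            offspring=left.offspring, side=left.side, chrom=left.chrom,
            left=left.end, right=right.start, overlaps_gap=overlaps))
    return events, summarize_resolution(events)


def summarize_resolution(events: list[CrossoverEvent]) -> ResolutionSummary:
    lengths = np.array([e.interval_length for e in events], dtype=float)
    no_gap = np.array([e.interval_length for e in events if not e.overlaps_gap],
                      dtype=float)
    n = len(lengths)
    return ResolutionSummary(
        n_events=n,
        median_bp=float(np.median(lengths)) if n else float("nan"),
        median_bp_no_gap=float(np.median(no_gap)) if len(no_gap) else float("nan"),
        frac_lt_5kb=float((lengths < RESOLUTION_FINE).mean()) if n else float("nan"),
        frac_lt_10kb=float((lengths < RESOLUTION_COARSE).mean()) if n else float("nan"),
    )


def detect_crossovers(phased, min_sites: int = MIN_SITES_DEFAULT,
                      max_window: int = MAX_EVENT_WINDOW_BP,
                      gaps: IntervalSet | None = None):
    """Run block building, pruning and crossover calling on a phased set.

    Returns ``(events, summary, prune_results)`` where ``prune_results``
    maps (offspring, side, chrom) to the :class:`PruneResult`, from
    which non-crossover candidates are collected downstream.
    """
    all_events: list[CrossoverEvent] = []
    prune_results: dict[tuple[str, str, str], PruneResult] = {}
    for (offspring, side, chrom), pos, labels in phased.groups():
        blocks = build_haploblocks(pos, labels, offspring, side, chrom)
        pruned = prune_blocks(blocks, min_sites=min_sites, max_window=max_window)
        prune_results[(offspring, side, chrom)] = pruned
        events, _ = call_crossovers(pruned.blocks, gaps=gaps)
        all_events.extend(events)
    return all_events, summarize_resolution(all_events), prune_results


def events_to_frame(events: list[CrossoverEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "offspring": e.offspring, "side": e.side, "chrom": e.chrom,
        "left": e.left, "right": e.right, "length": e.interval_length,
        "overlaps_gap": e.overlaps_gap, "resolution_class": e.resolution_class,
    } for e in events], columns=["offspring", "side", "chrom", "left", "right",
                                 "length", "overlaps_gap", "resolution_class"])


def events_from_frame(df: pd.DataFrame) -> list[CrossoverEvent]:
    return [CrossoverEvent(str(r.offspring), str(r.side), str(r.chrom),
                           int(r.left), int(r.right), bool(r.overlaps_gap))
            for r in df.itertuples()]
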