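"""Small helpers for BED-style interval sets (0-based half-open)."""

from __future__ import annotations

import numpy as np
import pandas as pd

IntervalSet = dict[str, list[tuple[int, int]]]


def read_bed(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    out: IntervalSet = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        out[str(chrom)] = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
    return out


def write_bed(regions: IntervalSet, path) -> None:
    rows = [(c, s, e) for c, ivs in regions.items() for s, e in sorted(ivs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_regions(regions: IntervalSet) -> IntervalSet:
    return {c: merge_intervals(ivs) for c, ivs in regions.items()}


def total_bp(regions: IntervalSet) -> int:
    return sum(e - s for ivs in merge_regions(regions).values() for s, e in ivs)


def points_in_regions(chroms: np.ndarray, pos0: np.ndarray,
                      regions: IntervalSet) -> np.ndarray:
    """Membership of 0-based points in an interval set, vectorised per chromosome."""
    out = np.zeros(len(pos0), dtype=bool)
    for chrom, ivs in regions.items():
        sel = chroms == chrom
        if not sel.any() or not ivs:
            continue
        ivs = merge_intervals(ivs)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        p = pos0[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        out[sel] = ok
    return out


def interval_overlaps(chrom: str, start0: int, end0: int,
                      regions: IntervalSet) -> bool:
    """Whether [start0, end0) overlaps any region on ``chrom``."""
    for s, e in regions.get(chrom, ()):
        if s < end0 and start0 < e:
            return True
    return False


def overlap_length(start0: int, end0: int, ivs: list[tuple[int, int]]) -> int:
    return sum(max(0, min(end0, e) - max(start0, s)) for s, e in ivs)
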