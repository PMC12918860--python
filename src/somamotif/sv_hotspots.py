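"""Cross-donor rearrangement hotspots and common-fragile-site association.

An SV is in a hotspot iff any of its breakpoints lies within the window
(inclusive, same chromosome) of a breakpoint of an SV from a *different*
donor; identical coordinates across donors are the distance-0 case.
Intrachromosomal SVs overlap a CFS iff their [pos1, pos2] span intersects the
interval; translocations iff either breakpoint falls inside one.
"""
from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .catalogue_io import StructuralVariant

DEFAULT_HOTSPOT_WINDOW = 1_000_000


def _breakpoints(svs: Sequence[StructuralVariant]):
    """(chrom, pos, donor, sv index) for both ends of every SV."""
    points = []
    for i, s in enumerate(svs):
        points.append((s.chrom1, s.pos1, s.donor_id, i))
        points.append((s.chrom2, s.pos2, s.donor_id, i))
    return points


def call_hotspots(svs: Sequence[StructuralVariant],
                  window: int = DEFAULT_HOTSPOT_WINDOW) -> List[StructuralVariant]:
    """Set ``in_hotspot`` on every SV (mutates and returns the list)."""
    by_chrom: Dict[str, List[Tuple[int, str, int]]] = {}
    for chrom, pos, donor, idx in _breakpoints(svs):
        by_chrom.setdefault(chrom, []).append((pos, donor, idx))
    flagged = np.zeros(len(svs), dtype=bool)
    for points in by_chrom.values():
        points.sort()
        positions = np.array([p for p, _, _ in points])
        donors = [d for _, d, _ in points]
        for pos, donor, idx in points:
            lo = int(np.searchsorted(positions, pos - window, side="left"))
            hi = int(np.searchsorted(positions, pos + window, side="right"))
            if any(donors[j] != donor for j in range(lo, hi)):
                flagged[idx] = True
    for i, s in enumerate(svs):
        s.in_hotspot = bool(flagged[i])
    return list(svs)


def annotate_cfs(svs: Sequence[StructuralVariant],
                 cfs: Sequence[Tuple[str, int, int]]) -> List[StructuralVariant]:
    """Set ``overlaps_cfs`` from BED (0-based half-open) CFS intervals."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in cfs:
        by_chrom.setdefault(chrom, []).append((start, end))

    def span_hits(chrom: str, lo1: int, hi1: int) -> bool:
        # 1-based inclusive span [lo1, hi1] vs 0-based half-open [start, end)
        return any(start + 1 <= hi1 and lo1 <= end
                   for start, end in by_chrom.get(chrom, ()))

    def point_hits(chrom: str, pos1: int) -> bool:
        return any(start < pos1 <= end for start, end in by_chrom.get(chrom, ()))

    for s in svs:
        if s.sv_type == "TRA":
            s.overlaps_cfs = point_hits(s.chrom1, s.pos1) or point_hits(s.chrom2, s.pos2)
        else:
            s.overlaps_cfs = span_hits(s.chrom1, s.pos1, s.pos2)
    return list(svs)


def hotspot_cfs_association(svs: Sequence[StructuralVariant]):
    """2x2 table of in_hotspot x overlaps_cfs and its two-sided Fisher p.

    Returns (table, p); p is NaN with fewer than two SVs and 1.0 for
    degenerate margins.
    """
    table = np.zeros((2, 2), dtype=int)
    for s in svs:
        table[0 if s.in_hotspot else 1, 0 if s.overlaps_cfs else 1] += 1
    if len(svs) < 2:
        return table, math.nan
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p
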