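"""CpG-island proximity of promoters.

A promoter is CpG-associated when its TSS lies inside, or within 200 bp
of, a predicted CpG island.  Island intervals are 0-based half-open
(BED convention); the gap from a TSS at or past an island end is
``tss - end`` and the 200 bp bound is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["IntervalSet", "read_bed_intervals", "classify_cpg", "set_proportions"]

DEFAULT_MAX_DIST = 200


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged half-open intervals."""

    chroms: dict[str, np.ndarray]  # chrom -> (n, 2) array of (start, end)

    @classmethod
    def from_intervals(cls, intervals: list[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if s >= e:
                raise DataError(f"invalid interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.array(out, dtype=np.int64)
        return cls(merged)


def read_bed_intervals(path: str | Path) -> IntervalSet:
    """Read BED (first three columns used) into a merged interval set."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            intervals.append((f[0], int(f[1]), int(f[2])))
    return IntervalSet.from_intervals(intervals)


def classify_cpg(
    chrom: str, tss: int, islands: IntervalSet, max_dist: int = DEFAULT_MAX_DIST
) -> tuple[bool, float]:
    """(associated, distance) for one TSS.

    Distance is 0 inside an island, otherwise the gap to the nearest
    island edge on the same chromosome; a missing chromosome yields
    (False, inf).  Association is boundary-inclusive at `max_dist`.
    """
    ivs = islands.chroms.get(chrom)
    if ivs is None or len(ivs) == 0:
        return False, math.inf
    starts, ends = ivs[:, 0], ivs[:, 1]
    i = int(np.searchsorted(starts, tss, side="right")) - 1
    dist = math.inf
    if i >= 0:
        if tss < ends[i]:
            return True, 0.0
        dist = float(tss - ends[i])
    if i + 1 < len(starts):
        dist = min(dist, float(starts[i + 1] - tss))
    return dist <= max_dist, dist


def set_proportions(
    gene_sets: dict[str, list[str]],
    calls: dict[str, bool],
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Fraction of CpG-associated promoters per gene set, plus pairwise
    2x2 contingency tables (associated/not x setA/setB) for testing.

    Genes without a call raise; empty sets are skipped.
    """
    rows = []
    assoc_counts: dict[str, tuple[int, int]] = {}
    for label, gene_list in gene_sets.items():
        if not gene_list:
            continue
        missing = [g for g in gene_list if g not in calls]
        if missing:
            raise DataError(f"set {label!r}: {len(missing)} genes lack a CpG call")
        n_assoc = sum(1 for g in gene_list if calls[g])
        n = len(gene_list)
        assoc_counts[label] = (n_assoc, n - n_assoc)
        rows.append(
            {"gene_set": label, "n": n, "n_associated": n_assoc, "fraction": n_assoc / n}
        )
    table = pd.DataFrame(rows)
    contingency = {}
    labels = sorted(assoc_counts)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            contingency[(a, b)] = np.array([assoc_counts[a], assoc_counts[b]])
    return table, contingency
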