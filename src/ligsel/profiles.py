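"""TSS-anchored metagene profiles and windowed region scores.

Coverage around transcription start sites is summarized two ways, both
strand-aware (minus-strand vectors are reversed so positive offsets
always point downstream of the TSS, 5'->3'):

* :func:`metagene_profile` — per-offset mean RPM over a set of anchors,
  the histogram view (Pol II / H3K4me3 over +/-2 kb, H3K27me3 over
  +/-4 kb by default).
* :func:`region_scores` — per-gene summed RPM over a fixed window
  (+/-1 kb by default), the boxplot view, compared across conditions
  with the Wilcoxon rank-sum test.

Two anchoring modes are supported: every transcript TSS (``all_tss``,
profiles averaged across anchors) or the single TSS per gene with the
highest Pol II occupancy (``max_polII_tss``).  Anchors whose window
overruns a chromosome edge are dropped and counted, not zero-padded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .genes import GeneModel
from .tracks import CoverageTrack

__all__ = [
    "MetageneProfile",
    "RegionScoreSet",
    "select_dominant_tss",
    "metagene_profile",
    "region_scores",
    "rank_sum_test",
]

ANCHOR_MODES = ("all_tss", "max_polII_tss")

#: promoter half-width used to rank TSSs by Pol II occupancy; matches the
#: traveling-ratio promoter window for internal consistency.
DOMINANT_TSS_HALFWIDTH = 300


@dataclass
class MetageneProfile:
    offsets: np.ndarray  # bp relative to TSS, inclusive at both ends
    mean_rpm: np.ndarray
    n_anchors: int
    n_skipped: int
    anchor_mode: str
    gene_set: str = ""


@dataclass
class RegionScoreSet:
    scores: dict[str, float]  # gene id -> summed RPM
    window: tuple[int, int]
    anchor_mode: str
    gene_set: str = ""
    n_skipped: int = 0

    def values(self) -> np.ndarray:
        return np.array(list(self.scores.values()), dtype=float)


def _check_window(window: tuple[int, int]) -> tuple[int, int]:
    w0, w1 = int(window[0]), int(window[1])
    if w0 > w1:
        raise ConfigError(f"invalid window {window}: start offset exceeds end offset")
    return w0, w1


def _oriented_slice(
    rpm: np.ndarray, tss: int, strand: str, w0: int, w1: int
) -> np.ndarray | None:
    """Per-bp RPM oriented 5'->3' over offsets w0..w1 inclusive, or None
    if the window leaves the chromosome."""
    if strand == "+":
        lo, hi = tss + w0, tss + w1 + 1
        if lo < 0 or hi > len(rpm):
            return None
        return rpm[lo:hi]
    lo, hi = tss - w1, tss - w0 + 1
    if lo < 0 or hi > len(rpm):
        return None
    return rpm[lo:hi][::-1]


def select_dominant_tss(
    pol2_track: CoverageTrack,
    genes: list[GeneModel],
    halfwidth: int = DOMINANT_TSS_HALFWIDTH,
) -> dict[str, int]:
    """Per gene, the TSS with the highest promoter-proximal Pol II RPM.

    Occupancy is the summed RPM in +/- `halfwidth` bp around each
    transcript TSS; ties go to the first transcript.  Genes whose every
    TSS window leaves the chromosome are omitted.
    """
    out: dict[str, int] = {}
    rpm_cache: dict[str, np.ndarray] = {}
    for g in genes:
        if g.chrom not in rpm_cache:
            rpm_cache[g.chrom] = pol2_track.rpm(g.chrom)
        rpm = rpm_cache[g.chrom]
        best: tuple[float, int] | None = None
        for tss in g.tss_list:
            vec = _oriented_slice(rpm, tss, g.strand, -halfwidth, halfwidth)
            if vec is None:
                continue
            score = float(vec.sum())
            if best is None or score > best[0]:
                best = (score, tss)
        if best is not None:
            out[g.gene_id] = best[1]
    return out


def _anchors(
    genes: list[GeneModel],
    anchor_mode: str,
    pol2_track: CoverageTrack | None,
    track: CoverageTrack,
) -> list[tuple[str, str, int, str]]:
    """(gene_id, chrom, tss, strand) anchor list for the requested mode."""
    if anchor_mode not in ANCHOR_MODES:
        raise ConfigError(f"anchor_mode must be one of {ANCHOR_MODES}")
    if anchor_mode == "all_tss":
        return [(g.gene_id, g.chrom, tss, g.strand) for g in genes for tss in g.tss_list]
    dominant = select_dominant_tss(pol2_track if pol2_track is not None else track, genes)
    return [
        (g.gene_id, g.chrom, dominant[g.gene_id], g.strand)
        for g in genes
        if g.gene_id in dominant
    ]


def metagene_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    window: tuple[int, int] = (-2000, 2000),
    anchor_mode: str = "all_tss",
    pol2_track: CoverageTrack | None = None,
    gene_set: str = "",
) -> MetageneProfile:
    """Mean RPM per offset over all anchors of a gene set."""
    if not genes:
        raise DataError("metagene_profile: empty gene set")
    w0, w1 = _check_window(window)
    anchors = _anchors(genes, anchor_mode, pol2_track, track)
    rpm_cache: dict[str, np.ndarray] = {}
    total = np.zeros(w1 - w0 + 1, dtype=float)
    n_used = n_skipped = 0
    for _, chrom, tss, strand in anchors:
        if chrom not in rpm_cache:
            rpm_cache[chrom] = track.rpm(chrom)
        vec = _oriented_slice(rpm_cache[chrom], tss, strand, w0, w1)
        if vec is None:
            n_skipped += 1
            continue
        total += vec
        n_used += 1
    if n_used == 0:
        raise DataError("metagene_profile: every anchor window left the chromosome")
    return MetageneProfile(
        offsets=np.arange(w0, w1 + 1),
        mean_rpm=total / n_used,
        n_anchors=n_used,
        n_skipped=n_skipped,
        anchor_mode=anchor_mode,
        gene_set=gene_set,
    )


def region_scores(
    track: CoverageTrack,
    genes: list[GeneModel],
    window: tuple[int, int] = (-1000, 1000),
    anchor_mode: str = "all_tss",
    pol2_track: CoverageTrack | None = None,
    gene_set: str = "",
) -> RegionScoreSet:
    """Per-gene summed oriented RPM over [w0, w1] inclusive around the TSS.

    In ``all_tss`` mode a gene's score is the mean of its transcripts'
    window sums; in ``max_polII_tss`` mode the dominant TSS's sum.
    """
    if not genes:
        raise DataError("region_scores: empty gene set")
    w0, w1 = _check_window(window)
    anchors = _anchors(genes, anchor_mode, pol2_track, track)
    rpm_cache: dict[str, np.ndarray] = {}
    sums: dict[str, list[float]] = {}
    n_skipped = 0
    for gid, chrom, tss, strand in anchors:
        if chrom not in rpm_cache:
            rpm_cache[chrom] = track.rpm(chrom)
        vec = _oriented_slice(rpm_cache[chrom], tss, strand, w0, w1)
        if vec is None:
            n_skipped += 1
            continue
        sums.setdefault(gid, []).append(float(vec.sum()))
    scores = {gid: float(np.mean(v)) for gid, v in sums.items()}
    return RegionScoreSet(
        scores=scores,
        window=(w0, w1),
        anchor_mode=anchor_mode,
        gene_set=gene_set,
        n_skipped=n_skipped,
    )


def rank_sum_test(
    x, y, alternative: str = "two-sided", exact_max_n: int = 12
) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank-sum test.

    Returns (U statistic of `x`, p-value).  The null distribution is
    exact (full enumeration) when the pooled sample has at most
    `exact_max_n` observations and no ties; otherwise the normal
    approximation with midranks, tie correction and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("rank_sum_test: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_rank_sum(
    score_sets: dict[str, RegionScoreSet], alternative: str = "two-sided"
) -> dict[tuple[str, str], float]:
    """Two-sided rank-sum p for every condition pair of region scores."""
    out = {}
    for a, b in itertools.combinations(sorted(score_sets), 2):
        _, p = rank_sum_test(
            score_sets[a].values(), score_sets[b].values(), alternative=alternative
        )
        out[(a, b)] = p
    return out
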