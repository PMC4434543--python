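"""RNA Pol II traveling ratio (TR).

TR contrasts promoter-proximal polymerase with polymerase that has
transited into the gene body:

    TR = mean body RPM / mean promoter RPM

where the promoter window spans -300..+300 bp around the TSS (601 bp)
and the body window +301..+2250 bp (1950 bp), so the two windows
partition cleanly at +300.  A low TR indicates promoter-paused Pol II;
a high TR indicates efficient transition to elongation.  Per-condition
TRs are reported both raw and normalized to the resting state
(TR_activation / TR_rest), the form in which BCR stimulation shows
promoter accumulation (normalized TR < 1) and LPS stimulation shows
enhanced elongation (normalized TR > 1).

Both means are set-level: per gene the transcript window sums are
averaged, then averaged over the gene set, and the ratio is taken of
the two set means — not a mean of per-gene ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .genes import GeneModel
from .profiles import _anchors, _check_window, _oriented_slice
from .tracks import CoverageTrack

__all__ = [
    "PROMOTER_WINDOW",
    "BODY_WINDOW",
    "TravelingRatioResult",
    "traveling_ratio",
    "normalize_tr",
]

PROMOTER_WINDOW = (-300, 300)
BODY_WINDOW = (301, 2250)


@dataclass
class TravelingRatioResult:
    gene_set: str
    condition: str
    promoter_mean: float  # mean over genes of summed promoter RPM
    body_mean: float
    tr: float
    n_genes: int
    n_truncated: int  # genes whose body window hit the annotated gene end
    tr_normalized: float | None = None


def _window_sums(
    track: CoverageTrack,
    genes: list[GeneModel],
    window: tuple[int, int],
    anchor_mode: str,
    pol2_track: CoverageTrack | None,
    truncate_at_gene_end: bool,
) -> tuple[dict[str, float], int]:
    """Per-gene mean-over-transcripts window sum; also counts genes whose
    window was truncated at the annotated gene end."""
    w0, w1 = _check_window(window)
    gene_by_id = {g.gene_id: g for g in genes}
    anchors = _anchors(genes, anchor_mode, pol2_track, track)
    rpm_cache: dict[str, np.ndarray] = {}
    sums: dict[str, list[float]] = {}
    truncated: set[str] = set()
    for gid, chrom, tss, strand in anchors:
        if chrom not in rpm_cache:
            rpm_cache[chrom] = track.rpm(chrom)
        hi = w1
        if truncate_at_gene_end:
            end_offset = gene_by_id[gid].tss_to_end_offset(tss)
            if end_offset < hi:
                hi = end_offset
                truncated.add(gid)
        if hi < w0:
            sums.setdefault(gid, []).append(0.0)
            continue
        vec = _oriented_slice(rpm_cache[chrom], tss, strand, w0, hi)
        if vec is None:
            continue
        sums.setdefault(gid, []).append(float(vec.sum()))
    per_gene = {gid: float(np.mean(v)) for gid, v in sums.items()}
    return per_gene, len(truncated)


def traveling_ratio(
    track: CoverageTrack,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    body_window: tuple[int, int] = BODY_WINDOW,
    anchor_mode: str = "all_tss",
    pol2_track: CoverageTrack | None = None,
    truncate_at_gene_end: bool = True,
    gene_set: str = "",
    condition: str = "",
) -> TravelingRatioResult:
    """Set-level traveling ratio for one track and gene set.

    The body window of a gene shorter than `body_window[1]` is truncated
    at the annotated gene end (and the gene counted), so short genes
    contribute what body they have rather than flanking signal.
    TR is invariant to library size and to scaling of the raw counts.
    """
    if not genes:
        raise DataError("traveling_ratio: empty gene set")
    p_sums, _ = _window_sums(
        track, genes, promoter_window, anchor_mode, pol2_track, truncate_at_gene_end=False
    )
    b_sums, n_trunc = _window_sums(
        track, genes, body_window, anchor_mode, pol2_track, truncate_at_gene_end
    )
    common = sorted(set(p_sums) & set(b_sums))
    if not common:
        raise DataError("traveling_ratio: no gene with both windows in bounds")
    p = float(np.mean([p_sums[g] for g in common]))
    b = float(np.mean([b_sums[g] for g in common]))
    if p == 0:
        raise DataError(
            "traveling_ratio: promoter mean is zero; TR undefined for this set"
        )
    return TravelingRatioResult(
        gene_set=gene_set,
        condition=condition,
        promoter_mean=p,
        body_mean=b,
        tr=b / p,
        n_genes=len(common),
        n_truncated=n_trunc,
    )


def normalize_tr(tr_condition: float, tr_rest: float) -> float:
    """Rest-normalized traveling ratio, TR_activation / TR_rest."""
    if tr_rest <= 0:
        raise ConfigError("resting TR must be > 0 for normalization")
    return tr_condition / tr_rest
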