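"""Promoter motif scanning and enrichment.

A self-contained stand-in for an external motif-enrichment tool: PWMs
are scanned over -1000/+1000 promoter sequences with a log-odds score
against a uniform background, a promoter counts as hit when any window
on either strand reaches a fixed fraction of the motif's maximum
attainable score, and enrichment of a foreground gene set against the
unchanged-gene background is an upper-tail hypergeometric probability
with ZOOPS counting (zero or one occurrence per sequence).  Per gene
set the motifs with the 30 lowest p-values are intersected pairwise to
quantify how ligand-selective the promoter grammar is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from scipy import stats

from .errors import ConfigError, DataError
from .genes import GeneModel

__all__ = [
    "PWM",
    "load_pwms",
    "write_pwms",
    "extract_promoters",
    "scan_promoter",
    "enrichment_test",
    "enrich_gene_sets",
    "top_k_overlap",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: probability floor applied before taking logs, avoiding -inf scores
PROB_FLOOR = 1e-3


@dataclass
class PWM:
    """Position weight matrix as per-position base probabilities."""

    id: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ConfigError(f"PWM {self.id}: matrix must be length x 4")
        if self.matrix.shape[0] < 4:
            raise ConfigError(f"PWM {self.id}: length must be >= 4")
        if np.any(self.matrix <= 0):
            raise ConfigError(f"PWM {self.id}: probabilities must be > 0 (apply floor)")
        rowsums = self.matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ConfigError(f"PWM {self.id}: rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return np.log2(self.matrix / bg)

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, name: str = "",
                    floor: float = PROB_FLOOR) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        probs = np.clip(probs, floor, None)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(motif_id, probs, name=name)


def load_pwms(path: str | Path, floor: float = PROB_FLOOR) -> list[PWM]:
    """Read a JASPAR-style PWM text file (">ID NAME" then A/C/G/T rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES]).T  # length x 4
        out.append(PWM.from_counts(m.matrix_id or m.name, counts, name=m.name or "",
                                   floor=floor))
    return out


def write_pwms(pwms: list[PWM], path: str | Path, scale: int = 1000) -> None:
    """Write PWMs as JASPAR-style integer count matrices."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.name or p.id}\n")
            counts = np.rint(p.matrix * scale).astype(int)
            for bi, base in enumerate(_BASES):
                row = " ".join(f"{c:6d}" for c in counts[:, bi])
                fh.write(f"{base} [{row} ]\n")


def extract_promoters(
    genes: list[GeneModel],
    genome,
    window: tuple[int, int] = (-1000, 1000),
    chrom_seqs: dict[str, str] | None = None,
) -> dict[str, str]:
    """Strand-oriented promoter sequences, one per gene.

    Anchored at the gene's representative (first) TSS; minus-strand
    promoters are reverse-complemented so the motif scan always reads
    5'->3'.  `genome` is a pyfaidx.Fasta (or any mapping chrom->sequence
    supporting slicing); genes whose window leaves the chromosome are
    skipped.
    """
    w0, w1 = int(window[0]), int(window[1])
    if w0 > w1:
        raise ConfigError(f"invalid promoter window {window}")
    seqs: dict[str, str] = {}
    for g in genes:
        tss = g.primary_tss
        if g.strand == "+":
            lo, hi = tss + w0, tss + w1 + 1
        else:
            lo, hi = tss - w1, tss - w0 + 1
        try:
            chrom_seq = genome[g.chrom]
        except KeyError:
            continue
        if lo < 0 or hi > len(chrom_seq):
            continue
        s = str(chrom_seq[lo:hi]).upper()
        if g.strand == "-":
            s = str(Seq(s).reverse_complement())
        seqs[g.gene_id] = s
    return seqs


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def _strand_scores(idx: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Log-odds score at every start offset; NaN where the window has a
    non-ACGT base or runs off the end."""
    L = lo_matrix.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (wins >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        v = wins[valid]
        scores[valid] = lo_matrix[np.arange(L), v].sum(axis=1)
    return scores


def scan_promoter(
    seq: str,
    pwm: PWM,
    score_fraction: float = 0.8,
    background: np.ndarray | None = None,
) -> list[tuple[int, str, float]]:
    """Scan both strands; return (offset, strand, score) hits.

    A hit is any window whose log-odds score reaches `score_fraction` of
    the motif's maximum attainable score.  Offsets index the forward
    sequence; a '-' hit at offset o means the reverse complement of the
    motif matches the forward sequence starting at o.
    """
    if not 0 < score_fraction <= 1:
        raise ConfigError("score_fraction must be in (0, 1]")
    idx = _encode(seq)
    lo = pwm.log_odds(background)
    max_score = float(lo.max(axis=1).sum())
    threshold = score_fraction * max_score
    hits: list[tuple[int, str, float]] = []
    rc_lo = lo[::-1, ::-1]  # reverse complement: flip positions and bases
    for strand, mat in (("+", lo), ("-", rc_lo)):
        scores = _strand_scores(idx, mat)
        for off in np.flatnonzero(~np.isnan(scores) & (scores >= threshold)):
            hits.append((int(off), strand, float(scores[off])))
    hits.sort()
    return hits


def _has_hit(idx: np.ndarray, lo: np.ndarray, rc_lo: np.ndarray,
             threshold: float) -> bool:
    for mat in (lo, rc_lo):
        scores = _strand_scores(idx, mat)
        valid = scores[~np.isnan(scores)]
        if valid.size and valid.max() >= threshold:
            return True
    return False


def _hit_promoters(
    encoded: dict[str, np.ndarray], pwm: PWM, score_fraction: float,
    background: np.ndarray | None = None,
) -> int:
    """ZOOPS count: number of promoters with at least one hit."""
    lo = pwm.log_odds(background)
    rc_lo = lo[::-1, ::-1]
    threshold = score_fraction * float(lo.max(axis=1).sum())
    return sum(1 for idx in encoded.values() if _has_hit(idx, lo, rc_lo, threshold))


def enrichment_test(fg_hits: int, fg_total: int, bg_hits: int, bg_total: int) -> float:
    """Upper-tail hypergeometric p-value, P(X >= fg_hits).

    Drawing `fg_total` promoters from the pooled fg+bg collection of
    which `fg_hits + bg_hits` carry the motif.
    """
    if fg_total <= 0:
        raise DataError("enrichment_test: foreground must be non-empty")
    if not (0 <= fg_hits <= fg_total and 0 <= bg_hits <= bg_total):
        raise DataError("enrichment_test: inconsistent counts")
    M = fg_total + bg_total
    K = fg_hits + bg_hits
    p = float(stats.hypergeom.sf(fg_hits - 1, M, K, fg_total))
    return min(p, 1.0)


def enrich_gene_sets(
    foreground_promoters: dict[str, dict[str, str]],
    background_promoters: dict[str, str],
    pwms: list[PWM],
    score_fraction: float = 0.8,
) -> dict[str, pd.DataFrame]:
    """Per gene set, a table of motif enrichment against the background.

    `foreground_promoters` maps set label -> {gene: promoter sequence};
    the background is the unchanged-gene promoter collection.  Returns
    one DataFrame per set with columns motif, fg_hits, fg_total,
    bg_hits, bg_total, p_value, neg_log10_p.
    """
    if not background_promoters:
        raise DataError("background promoter set is empty")
    bg_encoded = {k: _encode(s) for k, s in background_promoters.items()}
    bg_counts = {
        p.id: _hit_promoters(bg_encoded, p, score_fraction) for p in pwms
    }
    bg_total = len(background_promoters)
    results: dict[str, pd.DataFrame] = {}
    for label, proms in foreground_promoters.items():
        rows = []
        fg_total = len(proms)
        fg_encoded = {k: _encode(s) for k, s in proms.items()}
        for p in pwms:
            fg_hits = _hit_promoters(fg_encoded, p, score_fraction)
            pv = enrichment_test(fg_hits, fg_total, bg_counts[p.id], bg_total)
            rows.append(
                {
                    "motif": p.id,
                    "fg_hits": fg_hits,
                    "fg_total": fg_total,
                    "bg_hits": bg_counts[p.id],
                    "bg_total": bg_total,
                    "p_value": pv,
                    "neg_log10_p": -np.log10(pv),
                }
            )
        results[label] = pd.DataFrame(rows)
    return results


def top_k_overlap(
    results_by_set: dict[str, pd.DataFrame], k: int = 30
) -> tuple[dict[str, list[str]], dict[tuple[str, str], int], pd.DataFrame]:
    """Lowest-k-p motifs per set, pairwise intersection sizes, and the
    full -log10 p matrix (motif x set) for scatter comparisons.

    Ties on p are broken by larger foreground hit count, then motif id.
    """
    top: dict[str, list[str]] = {}
    for label, df in results_by_set.items():
        if len(df) < k:
            raise ConfigError(
                f"set {label!r}: only {len(df)} motifs tested, need k={k}"
            )
        ranked = df.sort_values(
            ["p_value", "fg_hits", "motif"], ascending=[True, False, True]
        )
        top[label] = ranked["motif"].head(k).tolist()
    overlaps = {
        (a, b): len(set(top[a]) & set(top[b]))
        for a, b in itertools.combinations(sorted(results_by_set), 2)
    }
    matrix = pd.DataFrame(
        {
            label: df.set_index("motif")["neg_log10_p"]
            for label, df in results_by_set.items()
        }
    )
    return top, overlaps, matrix
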