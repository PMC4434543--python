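"""Fold-change classification of early-response genes.

Resting B cells stimulated through the B cell receptor (BCR) or through
TLR4 (LPS) induce a largely shared transcriptional program plus smaller
ligand-preferential sets.  Genes are classified from a normalized
expression table by a twofold rule:

* A gene is differentially expressed (DE) in a response when its linear
  fold change versus rest is >= 2 (up) or <= 1/2 (down); boundaries are
  inclusive ("minimal twofold").
* A gene DE in exactly one response is *preferential* to that response.
* A gene DE in both responses is still preferential when the
  non-preferred response changed it only two- to fourfold and the
  preferred fold is at least twice the non-preferred fold; otherwise the
  change is *shared*.
* Genes DE in neither response are *unchanged* if expressed above a
  minimum in the resting state, else *low_expressed*.

Fold changes are computed on a pseudocount-stabilized linear scale; the
twofold criterion is identical to |log2 fold| >= 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = [
    "LABELS",
    "fold_change",
    "call_de",
    "classify_gene",
    "classify_table",
    "build_gene_sets",
]

LABELS = (
    "shared_up",
    "shared_down",
    "bcr_pref_up",
    "bcr_pref_down",
    "lps_pref_up",
    "lps_pref_down",
    "unchanged",
    "low_expressed",
)


def fold_change(rest: float, stim: float, pseudocount: float = 1.0):
    """Linear fold change (stim + pc) / (rest + pc); strictly positive.

    Accepts scalars or arrays.  The pseudocount keeps zero-abundance
    genes finite and shrinks folds of barely expressed genes toward 1.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    rest = np.asarray(rest, dtype=float)
    stim = np.asarray(stim, dtype=float)
    if np.any(rest < 0) or np.any(stim < 0):
        raise ValueError("abundances must be non-negative")
    out = (stim + pseudocount) / (rest + pseudocount)
    return out.item() if out.ndim == 0 else out


def call_de(fold: float, threshold: float = 2.0) -> str:
    """Direction call: 'up' iff fold >= threshold, 'down' iff fold <= 1/threshold."""
    if threshold <= 1:
        raise ConfigError("DE threshold must be > 1")
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if fold >= threshold:
        return "up"
    if fold <= 1.0 / threshold:
        return "down"
    return "none"


def _resolve_preferential(
    fold_pref: float, fold_other: float, threshold: float
) -> bool:
    """Both responses DE in the same direction, folds on the up scale:
    preferential iff the other response's fold is within [t, t^2] and the
    preferred fold is at least t times it."""
    return (threshold <= fold_other <= threshold**2) and (
        fold_pref >= threshold * fold_other
    )


def classify_gene(
    fold_bcr: float,
    fold_lps: float,
    rest_abundance: float,
    min_expr: float = 1.0,
    threshold: float = 2.0,
) -> str:
    """Assign one of :data:`LABELS` from the two fold changes.

    The induced and reduced sides use symmetric logic; the reduced side
    operates on reciprocal folds.  In the rare case of opposing calls
    (up in one response, down in the other) the stronger response, by
    |log2 fold|, names the gene.
    """
    de_b = call_de(fold_bcr, threshold)
    de_l = call_de(fold_lps, threshold)

    if de_b == "none" and de_l == "none":
        return "unchanged" if rest_abundance >= min_expr else "low_expressed"

    if {de_b, de_l} == {"up", "down"}:
        # opposing directions: keep the stronger change's side; on an
        # exact tie keep the induced side (swap-symmetric tie-break)
        mb, ml = abs(math.log2(fold_bcr)), abs(math.log2(fold_lps))
        if mb > ml or (mb == ml and de_b == "up"):
            de_l = "none"
        else:
            de_b = "none"

    if de_b != "none" and de_l == "none":
        return f"bcr_pref_{de_b}"
    if de_l != "none" and de_b == "none":
        return f"lps_pref_{de_l}"

    # DE in both, same direction
    direction = de_b
    fb, fl = (fold_bcr, fold_lps) if direction == "up" else (1.0 / fold_bcr, 1.0 / fold_lps)
    if fb >= fl and _resolve_preferential(fb, fl, threshold):
        return f"bcr_pref_{direction}"
    if fl > fb and _resolve_preferential(fl, fb, threshold):
        return f"lps_pref_{direction}"
    return f"shared_{direction}"


def classify_table(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    threshold: float = 2.0,
    min_expr: float = 1.0,
    rest_col: str = "rest",
    bcr_col: str = "BCR120",
    lps_col: str = "LPS120",
) -> pd.DataFrame:
    """Classify every gene of an expression table.

    `table` is indexed by gene id with one column per condition; the
    resting and 120-min stimulated columns are required (classification
    uses 120 min only; earlier time points ride along for reporting).
    Returns a copy with ``fold_bcr``, ``fold_lps``, ``de_bcr``,
    ``de_lps`` and ``label`` columns appended.
    """
    missing = [c for c in (rest_col, bcr_col, lps_col) if c not in table.columns]
    if missing:
        raise SchemaError(f"expression table missing required columns: {missing}")
    if not table.index.is_unique:
        raise SchemaError("gene ids must be unique")
    if (table[[rest_col, bcr_col, lps_col]] < 0).any().any():
        raise SchemaError("expression values must be non-negative")

    out = table.copy()
    rest = out[rest_col].to_numpy(dtype=float)
    out["fold_bcr"] = fold_change(rest, out[bcr_col].to_numpy(dtype=float), pseudocount)
    out["fold_lps"] = fold_change(rest, out[lps_col].to_numpy(dtype=float), pseudocount)
    out["de_bcr"] = [call_de(f, threshold) for f in out["fold_bcr"]]
    out["de_lps"] = [call_de(f, threshold) for f in out["fold_lps"]]
    out["label"] = [
        classify_gene(fb, fl, r, min_expr=min_expr, threshold=threshold)
        for fb, fl, r in zip(out["fold_bcr"], out["fold_lps"], rest)
    ]
    return out


def build_gene_sets(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    threshold: float = 2.0,
    min_expr: float = 1.0,
    **cols,
) -> dict[str, list[str]]:
    """Disjoint gene sets (label -> gene id list) covering every gene.

    These sets are the inputs to all profiling modules: metagene
    profiles, traveling ratios, motif enrichment and CpG proportions
    are each computed per set.
    """
    classified = classify_table(
        table, pseudocount=pseudocount, threshold=threshold, min_expr=min_expr, **cols
    )
    sets: dict[str, list[str]] = {label: [] for label in LABELS}
    for gene, label in classified["label"].items():
        sets[label].append(str(gene))
    return sets
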