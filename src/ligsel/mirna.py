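"""miRNA differential categorization.

The twofold rule applied to normalized miRNA reads versus the resting
state, per stimulation.  Unlike the mRNA classification there is no
two-to-fourfold preferential refinement — each condition is simply
called up / down / none and the direction pair names the category,
including the opposing-direction sets (e.g. decreased by BCR but
increased by LPS) highlighted in the study.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError
from .expression import call_de, fold_change

__all__ = ["MIRNA_CATEGORIES", "categorize_mirna", "category_counts", "opposing_counts"]

MIRNA_CATEGORIES = (
    "up_both",
    "down_both",
    "up_bcr_only",
    "up_lps_only",
    "down_bcr_only",
    "down_lps_only",
    "up_bcr_down_lps",
    "down_bcr_up_lps",
    "unchanged",
)

_CATEGORY_BY_DIRECTIONS = {
    ("up", "up"): "up_both",
    ("down", "down"): "down_both",
    ("up", "none"): "up_bcr_only",
    ("none", "up"): "up_lps_only",
    ("down", "none"): "down_bcr_only",
    ("none", "down"): "down_lps_only",
    ("up", "down"): "up_bcr_down_lps",
    ("down", "up"): "down_bcr_up_lps",
    ("none", "none"): "unchanged",
}


def categorize_mirna(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    threshold: float = 2.0,
    min_expr: float = 0.0,
    rest_col: str = "rest",
    bcr_col: str = "BCR",
    lps_col: str = "LPS",
) -> pd.DataFrame:
    """Categorize each miRNA from its BCR and LPS fold changes vs rest.

    Shares the pseudocount-stabilized fold-change and boundary-inclusive
    twofold call with the mRNA classification.  `min_expr` optionally
    forces miRNAs below that resting abundance to ``unchanged`` (default
    no filter).  Returns the table with fold_bcr, fold_lps, de_bcr,
    de_lps and category columns appended.
    """
    missing = [c for c in (rest_col, bcr_col, lps_col) if c not in table.columns]
    if missing:
        raise SchemaError(f"miRNA table missing required columns: {missing}")
    if not table.index.is_unique:
        raise SchemaError("miRNA ids must be unique")
    if (table[[rest_col, bcr_col, lps_col]] < 0).any().any():
        raise SchemaError("miRNA reads must be non-negative")

    out = table.copy()
    rest = out[rest_col].to_numpy(dtype=float)
    out["fold_bcr"] = fold_change(rest, out[bcr_col].to_numpy(dtype=float), pseudocount)
    out["fold_lps"] = fold_change(rest, out[lps_col].to_numpy(dtype=float), pseudocount)
    out["de_bcr"] = [call_de(f, threshold) for f in out["fold_bcr"]]
    out["de_lps"] = [call_de(f, threshold) for f in out["fold_lps"]]
    cats = []
    for (db, dl), r in zip(zip(out["de_bcr"], out["de_lps"]), rest):
        expressed = max(r, 0.0) >= min_expr
        cats.append(_CATEGORY_BY_DIRECTIONS[(db, dl)] if expressed else "unchanged")
    out["category"] = cats
    return out


def category_counts(categorized: pd.DataFrame) -> dict[str, int]:
    counts = categorized["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in MIRNA_CATEGORIES}


def opposing_counts(categorized: pd.DataFrame) -> dict[str, int]:
    """Sizes of the opposing-reaction intersections (the Venn overlaps of
    increased-in-one / decreased-in-the-other)."""
    c = category_counts(categorized)
    return {
        "up_bcr_down_lps": c["up_bcr_down_lps"],
        "down_bcr_up_lps": c["down_bcr_up_lps"],
    }
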