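"""End-to-end pipeline: simulate (or load) -> classify -> profile -> TR
-> motifs -> miRNA -> CpG, with a combined JSON summary.

The configuration is a single YAML/dict with either a ``simulate``
section (a :class:`~ligsel.simulate.SimConfig`) or an ``inputs`` section
of file paths, plus a ``params`` section exposing every analysis
parameter with its standard default (twofold threshold, two-to-fourfold
preferential band, -300/+300 and +301/+2250 TR windows, +/-1 kb sum
windows, +/-2 kb and +/-4 kb profile windows, -1000/+1000 promoters,
200 bp CpG distance, top-30 motif lists).  All randomness flows from
the single seed; two runs with the same config produce byte-identical
summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cpg as cpg_mod
from . import expression, mirna, motifs, profiles, traveling
from .errors import ConfigError, DataError
from .genes import read_gtf
from .simulate import CONDITIONS, SIGNALS, SimConfig, generate_dataset, write_standard_files
from .tracks import read_bedgraph

__all__ = ["DEFAULT_PARAMS", "load_config", "run_pipeline"]

log = logging.getLogger("ligsel")

DEFAULT_PARAMS: dict = {
    "pseudocount": 1.0,
    "de_threshold": 2.0,
    "min_expr": 1.0,
    "anchor_mode": "all_tss",
    "profile_window": [-2000, 2000],
    "h3k27_profile_window": [-4000, 4000],
    "score_window": [-1000, 1000],
    "promoter_window": [-300, 300],
    "body_window": [301, 2250],
    "promoter_seq_window": [-1000, 1000],
    "score_fraction": 0.8,
    "top_k": 30,
    "cpg_max_dist": 200,
    "profile_sets": ["shared_up", "bcr_pref_up", "lps_pref_up", "unchanged"],
    "motif_foreground_sets": ["shared_up", "bcr_pref_up", "lps_pref_up"],
    "motif_background_set": "unchanged",
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def _merge_params(config: dict) -> dict:
    params = dict(DEFAULT_PARAMS)
    user = config.get("params", {})
    unknown = set(user) - set(params)
    if unknown:
        raise ConfigError(f"unknown pipeline parameters: {sorted(unknown)}")
    params.update(user)
    for key in params:
        if key.endswith("_window"):
            params[key] = [int(v) for v in params[key]]
    return params


class _GenomeFromString:
    """Minimal chrom->sequence mapping over an in-memory genome."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]


def _load_inputs(config: dict, out: Path, seed: int) -> dict:
    """Resolve the data layer: simulate in-memory, or read files."""
    if "simulate" in config:
        sim_cfg = SimConfig.from_dict({"seed": seed, **(config["simulate"] or {})})
        dataset = generate_dataset(sim_cfg)
        data_dir = out / "data"
        write_standard_files(dataset, data_dir)
        return {
            "genes": dataset.genes,
            "tracks": dataset.tracks,
            "expression": dataset.expression,
            "genome": _GenomeFromString({sim_cfg.chrom_name: dataset.genome}),
            "pwms": dataset.pwms,
            "mirna": dataset.mirna,
            "islands": cpg_mod.IntervalSet.from_intervals(dataset.cpg_islands),
            "truth": dataset.truth,
        }
    if "inputs" not in config:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")
    inp = config["inputs"]
    for key in ("annotation_gtf", "expression", "tracks"):
        if key not in inp:
            raise ConfigError(f"inputs section missing {key!r}")
    paths = {k: v for k, v in inp.items() if k != "tracks"}
    for key, p in list(paths.items()) + list(inp["tracks"].items()):
        if not Path(p).exists():
            raise DataError(f"input file for {key!r} not found: {p}")
    tracks = {key: read_bedgraph(p) for key, p in inp["tracks"].items()}
    data = {
        "genes": read_gtf(inp["annotation_gtf"]),
        "tracks": tracks,
        "expression": pd.read_csv(inp["expression"], sep="\t", index_col=0),
        "genome": None,
        "pwms": None,
        "mirna": None,
        "islands": None,
        "truth": None,
    }
    if "genome_fasta" in inp:
        import pyfaidx

        data["genome"] = pyfaidx.Fasta(inp["genome_fasta"])
    if "pwms" in inp:
        data["pwms"] = motifs.load_pwms(inp["pwms"])
    if "mirna" in inp:
        data["mirna"] = pd.read_csv(inp["mirna"], sep="\t", index_col=0)
    if "cpg_bed" in inp:
        data["islands"] = cpg_mod.read_bed_intervals(inp["cpg_bed"])
    return data


def _profile_table(track, sets_genes, window, anchor_mode, pol2_track):
    cols = {}
    for label, genes in sets_genes.items():
        if not genes:
            continue
        prof = profiles.metagene_profile(
            track, genes, window=tuple(window), anchor_mode=anchor_mode,
            pol2_track=pol2_track, gene_set=label,
        )
        cols[label] = prof.mean_rpm
        offsets = prof.offsets
    df = pd.DataFrame(cols)
    df.insert(0, "offset", offsets)
    return df


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write per-module tables plus summary.json.

    Returns the summary dict: recovered set sizes, traveling ratios,
    rank-sum p-values, motif top-k overlaps, miRNA category counts, CpG
    fractions, and the full parameter echo for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = _merge_params(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    data = _load_inputs(config, out, seed)
    genes = data["genes"]
    gene_by_id = {g.gene_id: g for g in genes}
    anchor_mode = params["anchor_mode"]

    summary: dict = {"seed": seed, "params": params, "warnings": []}

    # ---- classification ------------------------------------------------
    classified = expression.classify_table(
        data["expression"],
        pseudocount=params["pseudocount"],
        threshold=params["de_threshold"],
        min_expr=params["min_expr"],
    )
    classified.to_csv(out / "classes.tsv", sep="\t")
    gene_sets = {label: [] for label in expression.LABELS}
    for gid, label in classified["label"].items():
        gene_sets[label].append(str(gid))
    summary["set_sizes"] = {k: len(v) for k, v in gene_sets.items()}

    sets_models = {
        label: [gene_by_id[g] for g in gene_sets[label] if g in gene_by_id]
        for label in params["profile_sets"]
    }
    sets_models = {k: v for k, v in sets_models.items() if v}
    if not sets_models:
        raise DataError("no profiled gene set has annotated members")

    pol2_by_cond = {c: data["tracks"].get(f"polII_{c}") for c in CONDITIONS}

    # ---- metagene profiles and region scores ---------------------------
    summary["rank_sum_p"] = {}
    for signal in SIGNALS:
        avail = {c: data["tracks"].get(f"{signal}_{c}") for c in CONDITIONS}
        if any(t is None for t in avail.values()):
            summary["warnings"].append(f"signal {signal}: tracks missing, skipped")
            continue
        window = (
            params["h3k27_profile_window"] if signal == "h3k27me3"
            else params["profile_window"]
        )
        for cond, track in avail.items():
            df = _profile_table(track, sets_models, window, anchor_mode,
                                pol2_by_cond[cond])
            df.to_csv(out / f"profile_{signal}_{cond}.tsv", sep="\t", index=False)
        # +/-1 kb sums per condition, rank-sum vs rest and BCR vs LPS
        for label, models in sets_models.items():
            scores = {
                cond: profiles.region_scores(
                    track, models, window=tuple(params["score_window"]),
                    anchor_mode=anchor_mode, pol2_track=pol2_by_cond[cond],
                    gene_set=label,
                )
                for cond, track in avail.items()
            }
            pd.DataFrame(
                {c: pd.Series(s.scores) for c, s in scores.items()}
            ).to_csv(out / f"scores_{signal}_{label}.tsv", sep="\t")
            pvals = {
                f"{a}_vs_{b}": profiles.rank_sum_test(
                    scores[a].values(), scores[b].values()
                )[1]
                for a, b in (("BCR", "rest"), ("LPS", "rest"), ("BCR", "LPS"))
            }
            summary["rank_sum_p"].setdefault(signal, {})[label] = pvals

    # ---- traveling ratios ----------------------------------------------
    if all(pol2_by_cond.get(c) is not None for c in CONDITIONS):
        tr_rows = []
        summary["traveling_ratio"] = {}
        for label, models in sets_models.items():
            results = {
                cond: traveling.traveling_ratio(
                    pol2_by_cond[cond], models,
                    promoter_window=tuple(params["promoter_window"]),
                    body_window=tuple(params["body_window"]),
                    anchor_mode=anchor_mode, pol2_track=pol2_by_cond[cond],
                    gene_set=label, condition=cond,
                )
                for cond in CONDITIONS
            }
            for cond, r in results.items():
                r.tr_normalized = traveling.normalize_tr(r.tr, results["rest"].tr)
                tr_rows.append(dataclasses.asdict(r))
            summary["traveling_ratio"][label] = {
                cond: {"tr": results[cond].tr,
                       "tr_normalized": results[cond].tr_normalized}
                for cond in CONDITIONS
            }
        pd.DataFrame(tr_rows).to_csv(out / "traveling_ratio.tsv", sep="\t", index=False)

    # ---- motif enrichment ----------------------------------------------
    if data["genome"] is not None and data["pwms"]:
        bg_label = params["motif_background_set"]
        bg_models = [gene_by_id[g] for g in gene_sets.get(bg_label, []) if g in gene_by_id]
        if not bg_models:
            raise DataError(f"motif background set {bg_label!r} is empty")
        window = tuple(params["promoter_seq_window"])
        bg_proms = motifs.extract_promoters(bg_models, data["genome"], window=window)
        fg_proms = {}
        for label in params["motif_foreground_sets"]:
            models = [gene_by_id[g] for g in gene_sets.get(label, []) if g in gene_by_id]
            if models:
                fg_proms[label] = motifs.extract_promoters(
                    models, data["genome"], window=window
                )
        results = motifs.enrich_gene_sets(
            fg_proms, bg_proms, data["pwms"], score_fraction=params["score_fraction"]
        )
        for label, df in results.items():
            df.to_csv(out / f"motif_enrichment_{label}.tsv", sep="\t", index=False)
        top, overlaps, matrix = motifs.top_k_overlap(results, k=params["top_k"])
        matrix.to_csv(out / "motif_neglogp_matrix.tsv", sep="\t")
        summary["motif_top_k"] = top
        summary["motif_top_k_overlap"] = {f"{a}&{b}": n for (a, b), n in overlaps.items()}

    # ---- miRNA ----------------------------------------------------------
    if data["mirna"] is not None:
        categorized = mirna.categorize_mirna(
            data["mirna"], pseudocount=params["pseudocount"],
            threshold=params["de_threshold"],
        )
        categorized.to_csv(out / "mirna_categories.tsv", sep="\t")
        summary["mirna_category_counts"] = mirna.category_counts(categorized)
        summary["mirna_opposing"] = mirna.opposing_counts(categorized)

    # ---- CpG proximity ---------------------------------------------------
    if data["islands"] is not None:
        calls = {}
        rows = []
        for g in genes:
            assoc, dist = cpg_mod.classify_cpg(
                g.chrom, g.primary_tss, data["islands"], max_dist=params["cpg_max_dist"]
            )
            calls[g.gene_id] = assoc
            rows.append({"gene_id": g.gene_id, "tss": g.primary_tss,
                         "associated": assoc,
                         "distance": dist if dist != float("inf") else -1})
        pd.DataFrame(rows).to_csv(out / "cpg_calls.tsv", sep="\t", index=False)
        prop_sets = {
            label: [g for g in gene_sets[label] if g in calls]
            for label in params["profile_sets"]
        }
        prop_table, _ = cpg_mod.set_proportions(
            {k: v for k, v in prop_sets.items() if v}, calls
        )
        prop_table.to_csv(out / "cpg_proportions.tsv", sep="\t", index=False)
        summary["cpg_fraction"] = {
            row["gene_set"]: row["fraction"] for _, row in prop_table.iterrows()
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
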