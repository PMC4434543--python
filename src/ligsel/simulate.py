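"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study design — resting splenic B cells
versus 2 h BCR or LPS stimulation — on a single synthetic chromosome:

* RNA Pol II coverage per condition: a Gaussian promoter peak at each
  TSS plus a uniform gene-body density, with per-class, per-condition
  scaling of peak and body (promoter accumulation vs. transition to
  elongation).
* H3K4me3: two Gaussian peaks flanking the TSS (the bimodal promoter
  signature); H3K27me3: a broad uniform domain centred on the TSS.
* A normalized expression table drawn negative-binomially with planted
  per-class fold changes, and a miRNA table likewise with planted
  categories.
* Promoter sequences with class-specific consensus motifs planted at
  configurable rates into otherwise iid-uniform ACGT sequence.
* CpG islands placed on a configurable fraction of promoters.

Coverage is generated directly as per-base Poisson counts around the
expected RPM profile rather than by simulating and aligning reads;
per-base counts are exactly what RPM profiling consumes.  Everything is
driven by one seed: a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genes import GeneModel, write_bed12, write_gtf
from .mirna import MIRNA_CATEGORIES
from .motifs import PWM, write_pwms
from .tracks import CoverageTrack, write_bedgraph

__all__ = ["SimConfig", "GroundTruth", "SimulatedDataset", "generate_dataset",
           "generate_expression", "write_standard_files"]

SIGNALS = ("polII", "h3k4me3", "h3k27me3")
CONDITIONS = ("rest", "BCR", "LPS")

# ---------------------------------------------------------------- defaults

def _default_classes() -> dict[str, int]:
    return {"shared_up": 60, "bcr_pref_up": 60, "lps_pref_up": 60, "unchanged": 60}


def _default_fold_map() -> dict[str, tuple[float, float]]:
    return {
        "shared_up": (4.0, 4.0),
        "bcr_pref_up": (8.0, 1.0),
        "lps_pref_up": (1.0, 8.0),
        "unchanged": (1.0, 1.0),
    }


def _default_promoter_scale() -> dict[str, dict[str, float]]:
    # BCR: genome-wide Pol II recruitment, strongest at BCR-preferential
    # promoters; LPS: promoter occupancy near resting levels.
    return {
        "shared_up": {"rest": 1.0, "BCR": 2.0, "LPS": 1.2},
        "bcr_pref_up": {"rest": 1.0, "BCR": 2.5, "LPS": 1.0},
        "lps_pref_up": {"rest": 1.0, "BCR": 1.2, "LPS": 1.0},
        "unchanged": {"rest": 1.0, "BCR": 1.3, "LPS": 1.0},
        "default": {"rest": 1.0, "BCR": 1.0, "LPS": 1.0},
    }


def _default_body_density() -> dict[str, dict[str, float]]:
    # RPM per bp; LPS enhances transition into the body at its targets.
    return {
        "shared_up": {"rest": 0.3, "BCR": 0.45, "LPS": 0.6},
        "bcr_pref_up": {"rest": 0.3, "BCR": 0.36, "LPS": 0.3},
        "lps_pref_up": {"rest": 0.3, "BCR": 0.3, "LPS": 0.6},
        "unchanged": {"rest": 0.3, "BCR": 0.3, "LPS": 0.3},
        "default": {"rest": 0.3, "BCR": 0.3, "LPS": 0.3},
    }


def _default_h3k4_scale() -> dict[str, dict[str, float]]:
    # increased by both stimuli, more by LPS, most at LPS-preferential genes
    return {
        "shared_up": {"rest": 1.0, "BCR": 1.3, "LPS": 1.6},
        "bcr_pref_up": {"rest": 1.0, "BCR": 1.3, "LPS": 1.2},
        "lps_pref_up": {"rest": 1.0, "BCR": 1.1, "LPS": 1.8},
        "unchanged": {"rest": 1.0, "BCR": 1.1, "LPS": 1.4},
        "default": {"rest": 1.0, "BCR": 1.0, "LPS": 1.0},
    }


def _default_h3k27_scale() -> dict[str, dict[str, float]]:
    # repressive mark lost during BCR activation, near-unchanged with LPS
    return {
        "shared_up": {"rest": 1.0, "BCR": 0.5, "LPS": 0.95},
        "bcr_pref_up": {"rest": 1.0, "BCR": 0.5, "LPS": 0.9},
        "lps_pref_up": {"rest": 1.0, "BCR": 0.8, "LPS": 1.0},
        "unchanged": {"rest": 1.0, "BCR": 0.6, "LPS": 1.0},
        "default": {"rest": 1.0, "BCR": 1.0, "LPS": 1.0},
    }


def _default_motif_rates() -> dict[str, float]:
    return {"shared_up": 0.5, "bcr_pref_up": 0.5, "lps_pref_up": 0.5}


def _default_mirna_categories() -> dict[str, int]:
    return {
        "up_both": 8, "down_both": 8, "up_bcr_only": 6, "up_lps_only": 6,
        "down_bcr_only": 6, "down_lps_only": 6, "up_bcr_down_lps": 4,
        "down_bcr_up_lps": 4, "unchanged": 20,
    }


def _default_mirna_folds() -> dict[str, tuple[float, float]]:
    return {
        "up_both": (4.0, 4.0), "down_both": (0.25, 0.25),
        "up_bcr_only": (4.0, 1.0), "up_lps_only": (1.0, 4.0),
        "down_bcr_only": (0.25, 1.0), "down_lps_only": (1.0, 0.25),
        "up_bcr_down_lps": (4.0, 0.25), "down_bcr_up_lps": (0.25, 4.0),
        "unchanged": (1.0, 1.0),
    }


@dataclass
class SimConfig:
    """Parameters of the generative model; defaults are the stated world.

    Coverage units are RPM (so expected per-base counts are
    ``rpm * library_size / 1e6``); lengths and offsets are in bp.
    A dispersion of 0 makes the corresponding table noise-free
    (values equal their means exactly).
    """

    seed: int = 0
    n_genes_per_class: dict[str, int] = field(default_factory=_default_classes)
    chrom_length: int | None = None  # None: computed from gene count
    chrom_name: str = "chrSim"
    library_size: float = 1e7
    # geometry
    gene_length: int = 4000
    flank: int = 5000
    max_transcripts: int = 3
    # alternative-TSS offsets are drawn from [tss_jitter_min, tss_jitter];
    # the lower bound keeps TSSs resolvable at the +/-300 bp promoter
    # window scale (closer "alternatives" are the same promoter and make
    # the max-Pol II anchor an arbitrary pick between identical windows)
    tss_jitter: int = 200
    tss_jitter_min: int = 100
    # Pol II model
    promoter_peak_height: float = 30.0  # RPM at the TSS, resting scale
    promoter_peak_sd: float = 100.0
    secondary_tss_peak_fraction: float = 0.3
    promoter_scale: dict = field(default_factory=_default_promoter_scale)
    body_density: dict = field(default_factory=_default_body_density)
    background_rpm: float = 0.0
    # histone marks
    h3k4_peak_offsets: tuple[int, int] = (-250, 500)
    h3k4_height: float = 20.0
    h3k4_sd: float = 150.0
    h3k4_scale: dict = field(default_factory=_default_h3k4_scale)
    h3k27_domain_halfwidth: int = 4000
    h3k27_height: float = 3.0
    h3k27_scale: dict = field(default_factory=_default_h3k27_scale)
    # expression
    expr_dispersion: float = 0.2
    expr_rest_mean_range: tuple[float, float] = (20.0, 500.0)
    fold_map: dict[str, tuple[float, float]] = field(default_factory=_default_fold_map)
    # motifs
    motif_plant_rate: dict[str, float] = field(default_factory=_default_motif_rates)
    motif_bg_rate: float = 0.05
    motif_length: int = 10
    n_decoy_motifs: int = 30
    # decoys model generally activation-associated motifs: planted in every
    # responsive class at this rate (background rate elsewhere), so induced
    # sets share a large pool of co-enriched motifs
    decoy_plant_rate: float = 0.3
    # miRNA
    n_mirna_per_category: dict[str, int] = field(default_factory=_default_mirna_categories)
    mirna_fold_map: dict[str, tuple[float, float]] = field(default_factory=_default_mirna_folds)
    mirna_dispersion: float = 0.2
    mirna_rest_mean_range: tuple[float, float] = (50.0, 2000.0)
    mirna_library_sizes: dict[str, float] = field(
        default_factory=lambda: {"rest": 20.2e6, "BCR": 28.6e6, "LPS": 14.8e6}
    )
    # CpG islands
    cpg_assoc_rate: float | dict[str, float] = 0.7
    cpg_island_halfwidth: int = 300
    cpg_decoy_gap: int = 1500  # offset of non-associated decoy islands

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_genes_per_class.values()):
            raise ConfigError("gene class sizes must be >= 0")
        for cls, (fb, fl) in self.fold_map.items():
            if fb <= 0 or fl <= 0:
                raise ConfigError(f"fold_map[{cls!r}]: folds must be > 0")
        for cat, (fb, fl) in self.mirna_fold_map.items():
            if fb <= 0 or fl <= 0:
                raise ConfigError(f"mirna_fold_map[{cat!r}]: folds must be > 0")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        if self.gene_length < 1 or self.flank < 0:
            raise ConfigError("invalid geometry")

    @property
    def slot_width(self) -> int:
        return self.gene_length + 2 * self.flank

    def required_length(self) -> int:
        n = sum(self.n_genes_per_class.values())
        return n * self.slot_width + 2 * self.flank

    def resolved_chrom_length(self) -> int:
        need = self.required_length()
        if self.chrom_length is None:
            return need
        if self.chrom_length < need:
            raise ConfigError(
                f"chrom_length {self.chrom_length} too small: {need} bp needed "
                f"for {sum(self.n_genes_per_class.values())} genes with "
                f"{self.flank} bp flanks"
            )
        return self.chrom_length

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation parameters: {sorted(unknown)}")
        d = dict(d)
        for key in ("h3k4_peak_offsets", "expr_rest_mean_range", "mirna_rest_mean_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("fold_map", "mirna_fold_map"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


def _class_param(mapping: dict, cls: str, condition: str | None = None):
    entry = mapping.get(cls, mapping.get("default"))
    if entry is None:
        raise ConfigError(f"no parameters for class {cls!r} and no default entry")
    if condition is None:
        return entry
    return entry[condition]


@dataclass
class GroundTruth:
    """The planted structure of a simulated dataset (a partition: every
    gene, motif and miRNA appears exactly once)."""

    gene_class: dict[str, str]
    dominant_tss: dict[str, int]
    true_tr: dict[str, dict[str, float]]  # gene -> condition -> expected TR
    class_motif: dict[str, str]  # class -> planted motif id
    motif_planted_in: dict[str, list[str]]  # gene -> motif ids planted
    mirna_category: dict[str, str]
    cpg_associated: dict[str, bool]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list[GeneModel]
    genome: str
    tracks: dict[str, CoverageTrack]  # "signal_condition" -> track
    expression: pd.DataFrame
    pwms: list[PWM]
    mirna: pd.DataFrame
    cpg_islands: list[tuple[str, int, int]]
    truth: GroundTruth


# ---------------------------------------------------------------- pieces

def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Deterministic non-overlapping slots, alternating strand per class,
    1..max_transcripts TSSs with <= tss_jitter bp jitter."""
    genes: list[GeneModel] = []
    slot = 0
    chrom = cfg.chrom_name
    for cls in sorted(cfg.n_genes_per_class):
        for i in range(cfg.n_genes_per_class[cls]):
            body_start = cfg.flank + slot * cfg.slot_width + cfg.flank
            body_end = body_start + cfg.gene_length
            strand = "+" if i % 2 == 0 else "-"
            primary = body_start if strand == "+" else body_end - 1
            n_tx = int(rng.integers(1, cfg.max_transcripts + 1))
            tss = [primary]
            for _ in range(n_tx - 1):
                delta = int(rng.integers(cfg.tss_jitter_min, cfg.tss_jitter + 1))
                sign = -1 if rng.random() < 0.5 else 1
                tss.append(primary + sign * delta)
            start = min(body_start, min(tss))
            end = max(body_end, max(tss) + 1)
            genes.append(
                GeneModel(f"{cls}_g{i:04d}", chrom, start, end, strand, tuple(tss))
            )
            slot += 1
    return genes


def _add_gaussian(arr: np.ndarray, center: int, height: float, sd: float) -> None:
    lo = max(0, int(center - 4 * sd))
    hi = min(len(arr), int(center + 4 * sd) + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _expected_profile(
    cfg: SimConfig, genes: list[GeneModel], signal: str, condition: str, length: int
) -> np.ndarray:
    arr = np.full(length, cfg.background_rpm, dtype=float)
    for g in genes:
        cls = g.gene_id.rsplit("_g", 1)[0]
        if signal == "polII":
            peak = cfg.promoter_peak_height * _class_param(
                cfg.promoter_scale, cls, condition
            )
            for j, tss in enumerate(g.tss_list):
                h = peak if j == 0 else peak * cfg.secondary_tss_peak_fraction
                _add_gaussian(arr, tss, h, cfg.promoter_peak_sd)
            dens = _class_param(cfg.body_density, cls, condition)
            if g.strand == "+":
                arr[g.primary_tss : g.end] += dens
            else:
                arr[g.start : g.primary_tss + 1] += dens
        elif signal == "h3k4me3":
            h = cfg.h3k4_height * _class_param(cfg.h3k4_scale, cls, condition)
            sign = 1 if g.strand == "+" else -1
            for off in cfg.h3k4_peak_offsets:
                _add_gaussian(arr, g.primary_tss + sign * off, h, cfg.h3k4_sd)
        elif signal == "h3k27me3":
            h = cfg.h3k27_height * _class_param(cfg.h3k27_scale, cls, condition)
            lo = max(0, g.primary_tss - cfg.h3k27_domain_halfwidth)
            hi = min(length, g.primary_tss + cfg.h3k27_domain_halfwidth + 1)
            arr[lo:hi] += h
        else:  # pragma: no cover
            raise ConfigError(f"unknown signal {signal!r}")
    return arr


def _expected_dominant_tss(expected: np.ndarray, gene: GeneModel) -> int:
    """The TSS with maximal expected +/-300 bp Pol II occupancy.

    Usually the primary TSS (its peak is tallest), but closely stacked
    secondary peaks can shift the true occupancy maximum — the ground
    truth records what the model actually makes dominant."""
    sums = [float(expected[t - 300 : t + 301].sum()) for t in gene.tss_list]
    return gene.tss_list[int(np.argmax(sums))]


def _expected_tr(expected: np.ndarray, gene: GeneModel) -> float:
    """Model-expected traveling ratio of one gene from its expected RPM
    profile (promoter -300..+300, body +301..+2250, oriented)."""
    tss, sign = gene.primary_tss, (1 if gene.strand == "+" else -1)
    prom = expected[min(tss - 300, tss + 300) : max(tss - 300, tss + 300) + 1].sum()
    b_lo, b_hi = tss + sign * 301, tss + sign * 2250
    body = expected[min(b_lo, b_hi) : max(b_lo, b_hi) + 1].sum()
    return float(body / prom) if prom > 0 else float("nan")


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2; 0 -> exact means."""
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return means.copy()
    size = 1.0 / dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p).astype(float)


def _expression_table(
    cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = cfg.expr_rest_mean_range
    rows = []
    for g in genes:
        cls = g.gene_id.rsplit("_g", 1)[0]
        fb, fl = cfg.fold_map.get(cls, (1.0, 1.0))
        rest_mean = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        means = np.array([rest_mean, rest_mean * fb, rest_mean * fl])
        vals = _nb_draw(rng, means, cfg.expr_dispersion)
        rows.append({"gene_id": g.gene_id, "rest": vals[0], "BCR120": vals[1],
                     "LPS120": vals[2]})
    return pd.DataFrame(rows).set_index("gene_id")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}


def _make_motif(rng: np.random.Generator, motif_id: str, length: int) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), 0.01)
    mat[np.arange(length), consensus] = 0.97
    return PWM(motif_id, mat / mat.sum(axis=1, keepdims=True), name=motif_id)


def _plant_motifs(
    cfg: SimConfig,
    genes: list[GeneModel],
    genome: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[PWM], dict[str, str], dict[str, list[str]]]:
    """Plant one consensus occurrence per selected promoter, uniform
    random offset and strand within -1000/+1000 of the primary TSS."""
    class_motif: dict[str, str] = {}
    pwms: list[PWM] = []
    for cls in sorted(cfg.motif_plant_rate):
        m = _make_motif(rng, f"PLANT_{cls.upper()}", cfg.motif_length)
        class_motif[cls] = m.id
        pwms.append(m)
    for d in range(cfg.n_decoy_motifs):
        pwms.append(_make_motif(rng, f"DECOY_{d:03d}", cfg.motif_length))

    motif_by_id = {p.id: p for p in pwms}
    planted_in: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    L = cfg.motif_length
    responsive = set(cfg.motif_plant_rate)
    for g in genes:
        cls = g.gene_id.rsplit("_g", 1)[0]
        for pwm in pwms:
            if pwm.id.startswith("PLANT_"):
                target_cls = next(c for c, m in class_motif.items() if m == pwm.id)
                rate = (
                    cfg.motif_plant_rate[target_cls]
                    if cls == target_cls
                    else cfg.motif_bg_rate
                )
            else:  # decoy: a general activation-associated motif
                rate = cfg.decoy_plant_rate if cls in responsive else cfg.motif_bg_rate
            if rng.random() >= rate:
                continue
            seq = np.frombuffer(pwm.consensus.encode(), dtype=np.uint8)
            if rng.random() < 0.5:  # minus strand
                seq = np.array([_COMP[b] for b in seq[::-1]], dtype=np.uint8)
            offset = int(rng.integers(g.primary_tss - 1000, g.primary_tss + 1000 - L + 2))
            genome[offset : offset + L] = seq
            planted_in[g.gene_id].append(pwm.id)
    return pwms, class_motif, planted_in


def _mirna_table(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str]]:
    lo, hi = cfg.mirna_rest_mean_range
    rows, categories = [], {}
    idx = 0
    for cat in MIRNA_CATEGORIES:
        n = cfg.n_mirna_per_category.get(cat, 0)
        fb, fl = cfg.mirna_fold_map.get(cat, (1.0, 1.0))
        for _ in range(n):
            mid = f"sim-mir-{idx:04d}"
            idx += 1
            rest_mean = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
            means = np.array([rest_mean, rest_mean * fb, rest_mean * fl])
            vals = _nb_draw(rng, means, cfg.mirna_dispersion)
            rows.append({"mirna_id": mid, "rest": vals[0], "BCR": vals[1], "LPS": vals[2]})
            categories[mid] = cat
    return pd.DataFrame(rows).set_index("mirna_id"), categories


def _cpg_islands(
    cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator, length: int
) -> tuple[list[tuple[str, int, int]], dict[str, bool]]:
    islands, assoc = [], {}
    hw = cfg.cpg_island_halfwidth
    for g in genes:
        cls = g.gene_id.rsplit("_g", 1)[0]
        rate = (
            cfg.cpg_assoc_rate.get(cls, cfg.cpg_assoc_rate.get("default", 0.0))
            if isinstance(cfg.cpg_assoc_rate, dict)
            else cfg.cpg_assoc_rate
        )
        if rng.random() < rate:
            islands.append((g.chrom, max(0, g.primary_tss - hw),
                            min(length, g.primary_tss + hw)))
            assoc[g.gene_id] = True
        else:
            assoc[g.gene_id] = False
            if rng.random() < 0.5:  # distant decoy island, well past 200 bp
                s = g.primary_tss + cfg.cpg_decoy_gap
                islands.append((g.chrom, s, min(length, s + 2 * hw)))
    return islands, assoc


# ---------------------------------------------------------------- main ops

def generate_expression(config: SimConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression table and gene->class truth only, skipping coverage,
    sequence and miRNA generation (a much cheaper path when only the
    classification stage is exercised).  The random stream differs from
    :func:`generate_dataset` at the same seed."""
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    table = _expression_table(config, genes, rng)
    return table, {g.gene_id: g.gene_id.rsplit("_g", 1)[0] for g in genes}


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full dataset: annotation, nine coverage tracks
    (3 signals x 3 conditions), expression and miRNA tables, a genome
    with planted promoter motifs, a PWM library, CpG islands, and the
    ground truth that downstream recovery is tested against."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    length = cfg.resolved_chrom_length()
    genes = _place_genes(cfg, rng)

    tracks: dict[str, CoverageTrack] = {}
    true_tr: dict[str, dict[str, float]] = {g.gene_id: {} for g in genes}
    dominant: dict[str, int] = {}
    scale = cfg.library_size / 1e6
    for signal in SIGNALS:
        for condition in CONDITIONS:
            expected = _expected_profile(cfg, genes, signal, condition, length)
            counts = rng.poisson(expected * scale).astype(np.int32)
            tracks[f"{signal}_{condition}"] = CoverageTrack(
                {cfg.chrom_name: counts},
                total_mapped_reads=cfg.library_size,
                name=f"{signal}_{condition}",
            )
            if signal == "polII":
                for g in genes:
                    true_tr[g.gene_id][condition] = _expected_tr(expected, g)
                if condition == "rest":
                    dominant = {
                        g.gene_id: _expected_dominant_tss(expected, g) for g in genes
                    }

    expression = _expression_table(cfg, genes, rng)
    genome_arr = _BASES[rng.integers(0, 4, size=length)].copy()
    pwms, class_motif, planted_in = _plant_motifs(cfg, genes, genome_arr, rng)
    mirna, mirna_cat = _mirna_table(cfg, rng)
    islands, cpg_assoc = _cpg_islands(cfg, genes, rng, length)

    truth = GroundTruth(
        gene_class={g.gene_id: g.gene_id.rsplit("_g", 1)[0] for g in genes},
        dominant_tss=dominant,
        true_tr=true_tr,
        class_motif=class_motif,
        motif_planted_in=planted_in,
        mirna_category=mirna_cat,
        cpg_associated=cpg_assoc,
    )
    return SimulatedDataset(
        config=cfg,
        genes=genes,
        genome=genome_arr.tobytes().decode(),
        tracks=tracks,
        expression=expression,
        pwms=pwms,
        mirna=mirna,
        cpg_islands=islands,
        truth=truth,
    )


def write_standard_files(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, str]:
    """Write the dataset in standard formats and return a path manifest.

    BED/bedGraph coordinates are 0-based half-open, GTF 1-based closed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    manifest: dict[str, str] = {}

    def _p(key: str, name: str) -> Path:
        manifest[key] = name
        return out / name

    write_gtf(dataset.genes, _p("annotation_gtf", "annotation.gtf"))
    write_bed12(dataset.genes, _p("annotation_bed", "annotation.bed"))

    with open(_p("genome_fasta", "genome.fa"), "w") as fh:
        fh.write(f">{cfg.chrom_name}\n")
        for i in range(0, len(dataset.genome), 80):
            fh.write(dataset.genome[i : i + 80] + "\n")
    with open(_p("chrom_sizes", "chrom.sizes"), "w") as fh:
        fh.write(f"{cfg.chrom_name}\t{len(dataset.genome)}\n")

    for key, track in dataset.tracks.items():
        write_bedgraph(track, _p(f"track_{key}", f"{key}.bedgraph"))

    dataset.expression.to_csv(_p("expression", "expression.tsv"), sep="\t")
    dataset.mirna.to_csv(_p("mirna", "mirna.tsv"), sep="\t")
    with open(_p("mirna_library_sizes", "mirna_library_sizes.tsv"), "w") as fh:
        fh.write("condition\tlibrary_size\n")
        for cond in CONDITIONS:
            fh.write(f"{cond}\t{cfg.mirna_library_sizes[cond]}\n")

    write_pwms(dataset.pwms, _p("pwms", "pwms.txt"))

    with open(_p("cpg_bed", "cpg_islands.bed"), "w") as fh:
        for chrom, s, e in sorted(dataset.cpg_islands):
            fh.write(f"{chrom}\t{s}\t{e}\n")

    dataset.truth.to_json(_p("ground_truth", "ground_truth.json"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["manifest"] = "manifest.json"
    return manifest
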