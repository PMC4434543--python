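"""Generator contracts: determinism, planted structure, file round trips."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from ligsel.errors import ConfigError
from ligsel.expression import classify_table
from ligsel.genes import read_gtf
from ligsel.simulate import (
    SimConfig,
    generate_dataset,
    generate_expression,
    write_standard_files,
)
from ligsel.tracks import read_bedgraph

TINY = dict(
    n_genes_per_class={"shared_up": 6, "bcr_pref_up": 6, "lps_pref_up": 6,
                       "unchanged": 6},
    library_size=5e5,
)


def dir_checksums(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
        if p.is_file()
    }


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            ds = generate_dataset(SimConfig(seed=5, **TINY))
            write_standard_files(ds, tmp_path / sub)
        assert dir_checksums(tmp_path / "a") == dir_checksums(tmp_path / "b")

    def test_different_seeds_differ(self):
        d1 = generate_dataset(SimConfig(seed=1, **TINY))
        d2 = generate_dataset(SimConfig(seed=2, **TINY))
        assert not np.array_equal(
            d1.tracks["polII_rest"].chroms["chrSim"],
            d2.tracks["polII_rest"].chroms["chrSim"],
        )


class TestPlantedStructure:
    def test_class_sizes_and_partition(self, small_dataset):
        truth = small_dataset.truth
        counts = {}
        for cls in truth.gene_class.values():
            counts[cls] = counts.get(cls, 0) + 1
        assert counts == small_dataset.config.n_genes_per_class
        assert len(truth.gene_class) == len(small_dataset.genes)

    def test_strand_balance_per_class(self, small_dataset):
        by_class = {}
        for g in small_dataset.genes:
            cls = small_dataset.truth.gene_class[g.gene_id]
            by_class.setdefault(cls, []).append(g.strand)
        for strands in by_class.values():
            assert abs(strands.count("+") - strands.count("-")) <= 1

    def test_tss_jitter_bounded(self, small_dataset):
        for g in small_dataset.genes:
            primary = g.tss_list[0]
            assert all(abs(t - primary) <= 200 for t in g.tss_list[1:])
            assert 1 <= len(g.tss_list) <= 3

    def test_mean_coverage_matches_model_body_density(self, small_dataset):
        """Empirical Pol II body coverage averaged over genes recovers
        the configured per-bp density."""
        ds = small_dataset
        cfg = ds.config
        track = ds.tracks["polII_LPS"]
        rpm = track.rpm(cfg.chrom_name)
        dens = []
        for g in ds.genes:
            if ds.truth.gene_class[g.gene_id] != "lps_pref_up":
                continue
            tss = g.primary_tss
            # interior body, away from the promoter peak and gene end
            if g.strand == "+":
                dens.append(rpm[tss + 1000 : tss + 3000].mean())
            else:
                dens.append(rpm[tss - 3000 : tss - 1000].mean())
        expected = cfg.body_density["lps_pref_up"]["LPS"]
        assert np.mean(dens) == pytest.approx(expected, rel=0.05)

    def test_noise_free_expression_recovers_planted_classes(self):
        cfg = SimConfig(
            seed=3,
            n_genes_per_class={"shared_up": 30, "bcr_pref_up": 30,
                               "lps_pref_up": 30, "unchanged": 30},
            fold_map={"shared_up": (4, 4), "bcr_pref_up": (8, 1),
                      "lps_pref_up": (1, 8), "unchanged": (1, 1)},
            expr_dispersion=0.0,
        )
        table, truth = generate_expression(cfg)
        labels = classify_table(table)["label"]
        assert (labels == labels.index.map(truth)).all()

    def test_expected_tr_truth_reflects_body_doubling(self, small_dataset):
        """The stored model-expected TR doubles (approximately) for the
        class whose LPS body density is twice its resting density."""
        truth = small_dataset.truth
        ratios = [
            tr["LPS"] / tr["rest"]
            for gid, tr in truth.true_tr.items()
            if truth.gene_class[gid] == "lps_pref_up"
        ]
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    ds = generate_dataset(SimConfig(seed=9, **TINY))
    manifest = write_standard_files(ds, out)
    return ds, out, manifest


class TestWrittenFiles:
    def test_bedgraph_round_trip(self, written):
        ds, out, manifest = written
        back = read_bedgraph(out / manifest["track_polII_rest"])
        orig = ds.tracks["polII_rest"]
        assert np.array_equal(back.chroms["chrSim"], orig.chroms["chrSim"])
        assert back.total_mapped_reads == orig.total_mapped_reads

    def test_gtf_round_trip(self, written):
        ds, out, manifest = written
        back = {g.gene_id: g for g in read_gtf(out / manifest["annotation_gtf"])}
        for g in ds.genes:
            b = back[g.gene_id]
            assert (b.chrom, b.start, b.end, b.strand) == (
                g.chrom, g.start, g.end, g.strand
            )
            assert sorted(b.tss_list) == sorted(g.tss_list)

    def test_bed12_strand_column(self, written):
        ds, out, manifest = written
        strands = {}
        for line in (out / manifest["annotation_bed"]).read_text().splitlines():
            f = line.split("\t")
            strands[f[3].rsplit(".t", 1)[0]] = f[5]
        for g in ds.genes:
            assert strands[g.gene_id] == g.strand

    def test_ground_truth_json_round_trip(self, written):
        ds, out, manifest = written
        loaded = json.loads((out / manifest["ground_truth"]).read_text())
        assert loaded["gene_class"] == ds.truth.gene_class

    def test_genome_fasta_length(self, written):
        ds, out, manifest = written
        seq = "".join(
            l for l in (out / manifest["genome_fasta"]).read_text().splitlines()
            if not l.startswith(">")
        )
        assert len(seq) == ds.config.resolved_chrom_length()


class TestGeometryValidation:
    def test_chrom_too_small_raises(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=0, chrom_length=10_000, **TINY).resolved_chrom_length()

    def test_invalid_folds_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(fold_map={"x": (0.0, 1.0)})

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig.from_dict({"not_a_field": 1})
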