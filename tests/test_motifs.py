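"""PWM scanning, promoter extraction, hypergeometric enrichment and the
lowest-30-P overlap machinery."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from conftest import make_gene
from ligsel.errors import ConfigError, DataError
from ligsel.motifs import (
    PWM,
    enrichment_test,
    extract_promoters,
    load_pwms,
    scan_promoter,
    top_k_overlap,
    write_pwms,
)

REV = str.maketrans("ACGT", "TGCA")


def consensus_pwm(seq: str, motif_id: str = "M1") -> PWM:
    mat = np.full((len(seq), 4), 0.01)
    for i, base in enumerate(seq):
        mat[i, "ACGT".index(base)] = 0.97
    return PWM(motif_id, mat / mat.sum(axis=1, keepdims=True))


class TestPWM:
    def test_row_sum_validation(self):
        with pytest.raises(ConfigError):
            PWM("bad", np.full((6, 4), 0.3))

    def test_zero_probability_rejected(self):
        mat = np.tile([1.0, 0.0, 0.0, 0.0], (6, 1))
        with pytest.raises(ConfigError):
            PWM("bad", mat)

    def test_consensus_and_floor_round_trip(self, tmp_path):
        p = consensus_pwm("ACGTTGCA")
        path = tmp_path / "pwms.txt"
        write_pwms([p], path)
        (back,) = load_pwms(path)
        assert back.consensus == "ACGTTGCA"
        assert np.all(back.matrix > 0)


class TestScan:
    def test_single_forward_hit_at_planted_offset(self):
        pwm = consensus_pwm("ACGTACGTGG")
        seq = "T" * 40 + "ACGTACGTGG" + "T" * 30
        hits = scan_promoter(seq, pwm)
        assert hits == [(40, "+", pytest.approx(hits[0][2]))]
        assert hits[0][2] > 0

    def test_reverse_complement_hit(self):
        pwm = consensus_pwm("ACGTACGTGG")
        seq = "T" * 40 + "ACGTACGTGG" + "T" * 30
        rc = seq.translate(REV)[::-1]
        hits = scan_promoter(rc, pwm)
        assert len(hits) == 1
        offset, strand, _ = hits[0]
        assert strand == "-"
        assert offset == len(seq) - 40 - 10  # mirrored position

    def test_all_n_sequence_has_no_hits(self):
        pwm = consensus_pwm("ACGTAC")
        assert scan_promoter("N" * 100, pwm) == []

    def test_sequence_shorter_than_motif(self):
        pwm = consensus_pwm("ACGTACGTGG")
        assert scan_promoter("ACG", pwm) == []

    def test_strand_symmetry_of_hit_counts(self):
        rng = np.random.default_rng(4)
        pwm = consensus_pwm("ACGTACGTGG")
        n_fwd = n_rc = 0
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 300))
            seq = seq[:100] + "ACGTACGTGG" + seq[110:]
            n_fwd += len(scan_promoter(seq, pwm))
            n_rc += len(scan_promoter(seq.translate(REV)[::-1], pwm))
        assert n_fwd == n_rc


class TestExtractPromoters:
    def test_plus_strand_coordinates(self):
        genome = {"chr1": "A" * 4000 + "C" * 2001 + "A" * 4000}
        gene = make_gene("g", tss=5000, strand="+")
        seqs = extract_promoters([gene], genome, window=(-1000, 1000))
        assert seqs["g"] == genome["chr1"][4000:6001]
        assert len(seqs["g"]) == 2001

    def test_minus_strand_reverse_complement(self):
        core = "ACGTA" * 400 + "A"
        genome = {"chr1": "G" * 4000 + core + "G" * 4000}
        gene = make_gene("g", tss=5000, strand="-")
        seqs = extract_promoters([gene], genome, window=(-1000, 1000))
        expected = genome["chr1"][4000:6001].translate(REV)[::-1]
        assert seqs["g"] == expected

    def test_degenerate_window_single_base(self):
        genome = {"chr1": "A" * 5000 + "G" + "A" * 5000}
        gene = make_gene("g", tss=5000, strand="+")
        assert extract_promoters([gene], genome, window=(0, 0))["g"] == "G"

    def test_out_of_bounds_gene_skipped(self):
        genome = {"chr1": "A" * 3000}
        gene = make_gene("g", tss=500, strand="+", length=100)
        assert extract_promoters([gene], genome, window=(-1000, 1000)) == {}


def hypergeom_tail_fraction(fg_hits, fg_total, bg_hits, bg_total) -> Fraction:
    """Exact-rational oracle: P(X >= fg_hits) drawing fg_total from the
    pooled collection with fg_hits+bg_hits marked."""
    M = fg_total + bg_total
    K = fg_hits + bg_hits
    total = comb(M, fg_total)
    acc = Fraction(0)
    for k in range(fg_hits, min(K, fg_total) + 1):
        acc += Fraction(comb(K, k) * comb(M - K, fg_total - k), total)
    return acc


class TestEnrichment:
    def test_worked_example_against_rational_oracle(self):
        p = enrichment_test(8, 10, 10, 100)
        oracle = float(hypergeom_tail_fraction(8, 10, 10, 100))
        assert p == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize(
        "fg_hits,fg_total,bg_hits,bg_total",
        [(10, 10, 100, 100), (0, 10, 5, 50), (0, 3, 0, 7)],
    )
    def test_boundary_cases_p_one(self, fg_hits, fg_total, bg_hits, bg_total):
        assert enrichment_test(fg_hits, fg_total, bg_hits, bg_total) == 1.0

    def test_swapping_fg_bg_moves_p_toward_one(self):
        p_enriched = enrichment_test(40, 50, 10, 50)
        p_swapped = enrichment_test(10, 50, 40, 50)
        assert p_enriched < 1e-6
        assert p_swapped > p_enriched
        assert p_swapped > 0.999

    def test_empty_foreground_rejected(self):
        with pytest.raises(DataError):
            enrichment_test(0, 0, 1, 10)


class TestTopKOverlap:
    def make_results(self, pvals, fg_hits=None):
        import pandas as pd

        n = len(pvals)
        return pd.DataFrame(
            {
                "motif": [f"m{i:02d}" for i in range(n)],
                "fg_hits": fg_hits if fg_hits is not None else [1] * n,
                "fg_total": [10] * n,
                "bg_hits": [1] * n,
                "bg_total": [10] * n,
                "p_value": pvals,
                "neg_log10_p": [-np.log10(p) for p in pvals],
            }
        )

    def test_identical_lists_full_overlap(self):
        df = self.make_results([0.01 * (i + 1) for i in range(10)])
        top, overlaps, _ = top_k_overlap({"a": df, "b": df.copy()}, k=5)
        assert overlaps[("a", "b")] == 5

    def test_disjoint_top_k(self):
        pa = [1e-6] * 5 + [0.9] * 5
        pb = [0.9] * 5 + [1e-6] * 5
        top, overlaps, _ = top_k_overlap(
            {"a": self.make_results(pa), "b": self.make_results(pb)}, k=5
        )
        assert overlaps[("a", "b")] == 0

    def test_tie_break_prefers_more_hits_then_id(self):
        df = self.make_results([0.5] * 4, fg_hits=[1, 9, 9, 2])
        top, _, _ = top_k_overlap({"a": df}, k=2)
        assert top["a"] == ["m01", "m02"]

    def test_too_few_motifs_raises(self):
        df = self.make_results([0.5] * 3)
        with pytest.raises(ConfigError):
            top_k_overlap({"a": df}, k=5)
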