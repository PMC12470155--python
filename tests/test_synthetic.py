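"""Synthetic genome generator: determinism, composition, truth recovery."""

import numpy as np
import pytest

from dnascape import (DINUCLEOTIDES, AnchorFlankSpec, GenomeSpec,
                      RepeatInsertionSpec, count_dinucleotides,
                      generate_genome, insert_repeats, place_anchors)
from dnascape.synthetic import ALU_LIKE_CONSENSUS


def dinuc_index(xy):
    return DINUCLEOTIDES.index(xy)


class TestGenerateGenome:
    def test_uniform_composition_within_binomial_bound(self):
        spec = GenomeSpec({"c1": 100_000}, seed=1)
        genome, _ = generate_genome(spec)
        freqs = np.bincount(genome.chromosomes["c1"], minlength=4) / 100_000
        assert np.all(np.abs(freqs - 0.25) < 0.01)

    def test_degenerate_single_letter(self):
        spec = GenomeSpec({"c1": 1000}, base_frequencies=(1, 0, 0, 0),
                          resolution=100, seed=0)
        genome, _ = generate_genome(spec)
        assert genome.sequence("c1") == "A" * 1000

    def test_determinism(self):
        spec = GenomeSpec({"c1": 50_000, "c2": 20_000}, seed=42)
        g1, t1 = generate_genome(spec)
        g2, t2 = generate_genome(spec)
        for name in g1.names:
            assert np.array_equal(g1.chromosomes[name], g2.chromosomes[name])
        assert t1 == t2

    def test_fasta_round_trip_byte_identical(self, tmp_path):
        from dnascape import Genome
        spec = GenomeSpec({"c1": 12_000}, seed=9)
        genome, _ = generate_genome(spec)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        genome.to_fasta(p1)
        generate_genome(spec)[0].to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = Genome.from_fasta(p1)
        assert np.array_equal(back.chromosomes["c1"], genome.chromosomes["c1"])

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            GenomeSpec({"c1": 50_000}, base_frequencies=(0.5, 0.5, 0.5, -0.5))

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="length"):
            GenomeSpec({"c1": 500}, resolution=1000)

    def test_markov_background_transition_frequencies(self):
        T = np.array([[0.7, 0.1, 0.1, 0.1],
                      [0.25, 0.25, 0.25, 0.25],
                      [0.1, 0.4, 0.4, 0.1],
                      [0.25, 0.25, 0.25, 0.25]])
        spec = GenomeSpec({"c1": 200_000}, transition=T, seed=5)
        genome, truth = generate_genome(spec)
        seq = genome.chromosomes["c1"]
        emp = np.zeros((4, 4))
        np.add.at(emp, (seq[:-1], seq[1:]), 1)
        emp /= emp.sum(axis=1, keepdims=True)
        assert np.all(np.abs(emp - T) < 0.02)
        assert truth["order"] == 1


class TestInsertRepeats:
    def test_tandem_array_written_at_recorded_coordinate(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 20_000}, seed=2))
        spec = RepeatInsertionSpec("CA_tr", unit="CA", copies=10, length=20)
        out, ins = insert_repeats(genome, spec, 7)
        assert len(ins) == 10
        for r in ins:
            assert out.sequence("c1")[r.start:r.end] == "CA" * 10

    def test_zero_copies_leaves_genome_unchanged(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 20_000}, seed=2))
        out, ins = insert_repeats(
            genome, RepeatInsertionSpec("x", unit="AG", copies=0, length=10), 1)
        assert ins == []
        assert np.array_equal(out.chromosomes["c1"], genome.chromosomes["c1"])

    def test_alu_like_insertions_raise_ag_content(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 100_000}, seed=3))
        before = count_dinucleotides(genome.chromosomes["c1"], 1000)
        spec = RepeatInsertionSpec("AluLike", consensus=ALU_LIKE_CONSENSUS,
                                   copies=50, length=120)
        out, ins = insert_repeats(genome, spec, 4)
        after = count_dinucleotides(out.chromosomes["c1"], 1000)
        j = dinuc_index("AG")
        assert after.dinuc_counts[:, j].sum() > before.dinuc_counts[:, j].sum()

    def test_chromosome_length_conserved(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 30_000}, seed=2))
        out, _ = insert_repeats(
            genome, RepeatInsertionSpec("x", unit="A", copies=20, length=25), 5)
        assert out.length("c1") == 30_000

    def test_insertion_longer_than_chromosome_rejected(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 10_000}, seed=2))
        spec = RepeatInsertionSpec("big", consensus="ACGT", copies=1, length=20_000)
        with pytest.raises(ValueError, match="exceeds"):
            insert_repeats(genome, spec, 1)

    def test_truth_intervals_match_emitted_sequence_exactly(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 50_000}, seed=8))
        spec = RepeatInsertionSpec("AG_tr", unit="AG", copies=15, length=30)
        out, ins = insert_repeats(genome, spec, 3)
        for r in ins:
            sub = out.sequence(r.chrom)[r.start:r.end]
            assert sub == ("AG" * 15)

    def test_unit_length_validation(self):
        with pytest.raises(ValueError, match="1..6"):
            RepeatInsertionSpec("x", unit="ACGTACG", copies=1, length=14)


class TestPlaceAnchors:
    def test_null_enrichment_flanks_match_background(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 400_000}, seed=10))
        spec = AnchorFlankSpec(50, 10, 2000)   # all factors 1.0
        out, anchors, truth = place_anchors(genome, spec, 11,
                                            truth_resolution=500)
        ef = np.array(truth["expected_dinucleotide_frequencies"])
        bg = np.array(truth["background_dinucleotide_frequencies"])
        assert np.all(np.abs(ef - bg) < 1e-12)
        # empirical flank content within 3 SE of background
        seq = out.chromosomes["c1"]
        counts = np.zeros(16)
        n_pairs = 0
        for a in anchors:
            c = (a.start + a.end) // 2
            w = seq[c - 2000:c + 2000]
            pair = w[:-1].astype(int) * 4 + w[1:]
            counts += np.bincount(pair, minlength=16)
            n_pairs += pair.size
        freq = counts / n_pairs
        se = np.sqrt(bg * (1 - bg) / n_pairs)
        assert np.all(np.abs(freq - bg) < 3.5 * se)

    def test_cc_enrichment_recovered_from_truth_record(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 1_500_000}, seed=12))
        spec = AnchorFlankSpec(60, 10, 5000, enrichment={"CC": 1.5, "GG": 1.5},
                               shape="flat")
        out, anchors, truth = place_anchors(genome, spec, 13,
                                            truth_resolution=1000)
        ef = np.array(truth["expected_dinucleotide_frequencies"])
        j = dinuc_index("CC")
        bg_cc = truth["background_dinucleotide_frequencies"][j]
        center_bin = ef.shape[0] // 2
        # chain-realized central elevation is close to the nominal 1.5x
        assert 1.3 < ef[center_bin, j] / bg_cc < 1.6
        # empirical counts around centers agree with the truth within 3 SE
        seq = out.chromosomes["c1"]
        counts = 0
        n_pairs = 0
        for a in anchors:
            c = (a.start + a.end) // 2
            w = seq[c - 500:c + 500]
            counts += int(np.sum((w[:-1] == 1) & (w[1:] == 1)))
            n_pairs += w.size - 1
        freq = counts / n_pairs
        p = ef[center_bin, j]
        se = np.sqrt(p * (1 - p) / n_pairs)
        assert abs(freq - p) < 3.5 * se

    def test_zero_anchor_length_rejected(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 100_000}, seed=1))
        with pytest.raises(ValueError, match="anchor length"):
            place_anchors(genome, AnchorFlankSpec(5, 0, 1000), 1)

    def test_infeasible_packing_rejected(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 100_000}, seed=1))
        with pytest.raises(ValueError, match="place anchors"):
            place_anchors(genome, AnchorFlankSpec(100, 10, 5000), 1)

    def test_support_too_large_rejected(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 100_000}, seed=1))
        with pytest.raises(ValueError, match="support"):
            place_anchors(genome, AnchorFlankSpec(1, 10, 30_000), 1)

    def test_windows_do_not_overlap_and_length_conserved(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 300_000}, seed=4))
        out, anchors, _ = place_anchors(genome, AnchorFlankSpec(20, 10, 3000), 5)
        assert out.length("c1") == 300_000
        centers = sorted((a.start + a.end) // 2 for a in anchors)
        assert all(b - a >= 6000 for a, b in zip(centers, centers[1:]))

    def test_determinism(self):
        genome, _ = generate_genome(GenomeSpec({"c1": 200_000}, seed=4))
        spec = AnchorFlankSpec(10, 10, 2000, enrichment={"AT": 1.4})
        r1 = place_anchors(genome, spec, 6)
        r2 = place_anchors(genome, spec, 6)
        assert np.array_equal(r1[0].chromosomes["c1"], r2[0].chromosomes["c1"])
        assert r1[1] == r2[1]
        assert r1[2] == r2[2]
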