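import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pikw.are_scan import (
    ARE_CONSENSUS,
    IUPAC_SETS,
    compile_pattern,
    count_ares,
    extract_upstream,
    scan,
)
from pikw.synthetic_data import generate_promoters


class TestCompilePattern:
    def test_n_has_degeneracy_four(self):
        assert compile_pattern("N").degeneracy == 4

    def test_are_consensus_degeneracy(self):
        # S, W, M, K contribute 2 each; N contributes 4
        assert compile_pattern(ARE_CONSENSUS).degeneracy == 64

    def test_invalid_symbol_named(self):
        with pytest.raises(ValueError, match="X"):
            compile_pattern("TGAX")


def _expansions(consensus):
    return ["".join(p) for p in itertools.product(*(IUPAC_SETS[c] for c in consensus))]


def _brute_force(seq, consensus):
    """Test every offset against all 64 expansions, both strands."""
    m = len(consensus)
    fwd = set(_expansions(consensus))
    hits = set()
    for start in range(len(seq) - m + 1):
        word = seq[start:start + m]
        if word in fwd:
            hits.add((start, "+"))
        if str(Seq(word).reverse_complement()) in fwd:
            hits.add((start, "-"))
    return hits


class TestScan:
    def test_forward_hand_example(self):
        hits = scan("TGACTCAGCA", ARE_CONSENSUS, strands="forward")
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 10, "+")]
        assert hits[0].matched_text == "TGACTCAGCA"

    def test_reverse_complement_hand_example(self):
        hits = scan("TGCTGAGTCA", ARE_CONSENSUS, strands="both")
        assert [(h.start, h.strand) for h in hits] == [(0, "-")]
        assert hits[0].matched_text == "TGCTGAGTCA"  # forward-strand slice

    def test_sequence_shorter_than_pattern(self):
        assert scan("AAAAAAAAA", ARE_CONSENSUS) == []

    def test_ambiguous_base_only_matches_pattern_n(self):
        # N at a constrained position must not count as a match
        assert scan("TGACTCAGCN", ARE_CONSENSUS, strands="forward") != []
        assert scan("NGACTCAGCA", ARE_CONSENSUS, strands="forward") == []

    def test_matches_expansion_oracle_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        hits = {(h.start, h.strand) for h in scan(seq, ARE_CONSENSUS)}
        assert hits == _brute_force(seq, ARE_CONSENSUS)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        rc = str(Seq(seq).reverse_complement())
        L, m = len(seq), len(ARE_CONSENSUS)
        minus = {(h.start, h.strand) for h in scan(seq, ARE_CONSENSUS) if h.strand == "-"}
        plus_on_rc = {
            (L - h.start - m, "-")
            for h in scan(rc, ARE_CONSENSUS)
            if h.strand == "+"
        }
        assert minus == plus_on_rc

    def test_overlapping_hits_all_reported(self):
        # TGA[C/G]... expansions can chain; verify with a tandem repeat
        seq = "TGACACAGCA" * 2
        hits = scan(seq, ARE_CONSENSUS, strands="forward")
        assert {h.start for h in hits} >= {0, 10}

    def test_expected_hit_count_on_uniform_background(self):
        # E[hits] = 2 (L - 9) * 64 / 4^10 per sequence, i.i.d. uniform ACGT
        rng = np.random.default_rng(2)
        L, n_seq = 5000, 120
        expected = 2 * (L - 9) * 64 / 4**10
        counts = []
        for _ in range(n_seq):
            seq = "".join(rng.choice(list("ACGT"), size=L))
            counts.append(len(scan(seq, ARE_CONSENSUS)))
        se = np.std(counts, ddof=1) / np.sqrt(n_seq)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestExtractUpstream:
    def test_plus_strand_window(self):
        seq = "A" * 3000
        win = extract_upstream(seq, "g1", "chr1", 1500, 3000, "+", window=1000)
        assert (win.start, win.end) == (500, 1500)
        assert not win.truncated

    def test_plus_strand_truncated_at_contig_edge(self):
        seq = "A" * 3000
        win = extract_upstream(seq, "g1", "chr1", 300, 900, "+", window=1000)
        assert (win.start, win.end) == (0, 300)
        assert win.truncated

    def test_minus_strand_reverse_complemented(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        win = extract_upstream(seq, "g1", "chr1", 500, 1500, "-", window=1000)
        assert (win.start, win.end) == (1500, 2500)
        assert win.sequence == str(Seq(seq[1500:2500]).reverse_complement())

    def test_locus_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_upstream("ACGT", "g1", "chr1", 2, 10, "+")


class TestCountAres:
    def test_planted_positions_recovered(self):
        records, bed, truth = generate_promoters(
            4, 2000, [2, 0, 3, 1], gc=0.5, seed=0
        )
        table = count_ares(dict(records), bed, ARE_CONSENSUS, window=1000)
        hits_by_seq = {
            row.sequence_id: {(h.start, h.strand) for h in row.hits}
            for row in table.itertuples()
        }
        for plant in truth:
            assert (plant["start"], plant["strand"]) in hits_by_seq[plant["sequence_id"]]

    def test_zero_hit_loci_retained(self):
        seqs = {"chr1": "C" * 1200}
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 1000, "end": 1100, "name": "gene1",
              "score": "0", "strand": "+"}]
        )
        table = count_ares(seqs, bed, ARE_CONSENSUS, window=1000)
        assert list(table.n_hits) == [0]
        assert list(table.locus_id) == ["gene1"]

    def test_shared_window_scanned_per_locus(self):
        seq = "C" * 500 + "TGACTCAGCA" + "C" * 690
        seqs = {"chr1": seq}
        bed = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 1000, "end": 1100, "name": "geneA",
                 "score": "0", "strand": "+"},
                {"chrom": "chr1", "start": 1050, "end": 1150, "name": "geneB",
                 "score": "0", "strand": "+"},
            ]
        )
        table = count_ares(seqs, bed, ARE_CONSENSUS, window=1000)
        assert list(table.n_hits) == [1, 1]

    def test_missing_sequence_ids_listed(self):
        bed = pd.DataFrame(
            [{"chrom": "chrMissing", "start": 10, "end": 20, "name": "g",
              "score": "0", "strand": "+"}]
        )
        with pytest.raises(ValueError, match="chrMissing"):
            count_ares({"chr1": "ACGT" * 100}, bed)
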