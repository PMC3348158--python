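"""Column classification, block filtering, concatenation, missing data."""

import numpy as np
import pytest

import divtime as dt
from divtime.supermatrix import Alignment, BlockFilterParams


def aln_from_columns(columns):
    """Build an alignment from a list of column strings (each of length
    n_taxa)."""
    n_taxa = len(columns[0])
    seqs = ["".join(col[i] for col in columns) for i in range(n_taxa)]
    return Alignment.from_records([(f"t{i}", s) for i, s in enumerate(seqs)])


GOOD = "AAAAAA"          # 6/6 identical -> highly conserved
JUNK = "ACGTAC"          # modal freq 1/6 -> nonconserved
HALF = "AAATTT"          # modal freq exactly 0.5 -> nonconserved (strict >)
MOSTLY = "AAAAAT"        # 5/6 = 0.83 -> conserved but not highly (>0.85)


class TestClassify:
    def test_identical_column_highly_conserved(self):
        aln = aln_from_columns([GOOD])
        assert dt.classify_positions(aln) == ["highly_conserved"]

    def test_gap_rule_strictly_over_half(self):
        four_gaps = "AA----"
        three_gaps = "AAA---"
        labels = dt.classify_positions(aln_from_columns([four_gaps, three_gaps]))
        assert labels[0] == "gap_excluded"
        # 3/6 gaps is allowed, so the column is evaluated normally:
        # modal residue A has frequency 3/6, not strictly > 0.5
        assert labels[1] == "nonconserved"

    def test_modal_frequency_thresholds_are_strict(self):
        labels = dt.classify_positions(aln_from_columns([HALF, MOSTLY, JUNK]))
        assert labels == ["nonconserved", "conserved", "nonconserved"]

    def test_gaps_never_count_toward_modal_residue(self):
        col = "AAA--?"  # 3 gaps of 6 allowed; modal residue A freq 3/6
        labels = dt.classify_positions(aln_from_columns([col]))
        assert labels == ["nonconserved"]  # 0.5 not strictly > 0.5

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment.from_records([("a", "ACGT"), ("b", "ACG")])


class TestFilterBlocks:
    def test_all_conserved_retained(self):
        aln = aln_from_columns([GOOD] * 12)
        filtered, fraction, blocks = dt.filter_blocks(aln)
        assert filtered.n_sites == 12
        assert fraction == 1.0
        assert blocks == [(0, 12)]

    def test_short_block_dropped(self):
        aln = aln_from_columns([GOOD] * 9)
        filtered, fraction, blocks = dt.filter_blocks(aln)
        assert filtered.n_sites == 0 and fraction == 0.0 and blocks == []

    def test_sixty_column_fixture(self):
        """Two 15-column conserved blocks split by a 6-column nonconserved
        run and flanked by junk: blocks kept, runs dropped, fraction 0.5."""
        cols = [JUNK] * 12 + [GOOD] * 15 + [JUNK] * 6 + [GOOD] * 15 + [JUNK] * 12
        aln = aln_from_columns(cols)
        filtered, fraction, blocks = dt.filter_blocks(aln)
        assert blocks == [(12, 27), (33, 48)]
        assert filtered.n_sites == 30
        assert fraction == 0.5

    def test_short_nonconserved_run_survives_inside_block(self):
        # 5 nonconserved in a row is within the allowance
        cols = [GOOD] * 10 + [JUNK] * 5 + [GOOD] * 10
        filtered, fraction, blocks = dt.filter_blocks(aln_from_columns(cols))
        assert blocks == [(0, 25)]
        assert filtered.n_sites == 25

    def test_six_nonconserved_run_splits(self):
        cols = [GOOD] * 10 + [JUNK] * 6 + [GOOD] * 10
        _, _, blocks = dt.filter_blocks(aln_from_columns(cols))
        assert blocks == [(0, 10), (16, 26)]

    def test_segments_trimmed_to_highly_conserved_anchors(self):
        cols = [MOSTLY] * 3 + [GOOD] * 12 + [MOSTLY] * 3
        _, _, blocks = dt.filter_blocks(aln_from_columns(cols))
        assert blocks == [(3, 15)]

    def test_columns_are_subsequence_of_input(self):
        rng = np.random.default_rng(0)
        pool = [GOOD, JUNK, MOSTLY, HALF]
        cols = [pool[i] for i in rng.integers(0, 4, 200)]
        aln = aln_from_columns(cols)
        filtered, _, blocks = dt.filter_blocks(aln)
        rebuilt = np.concatenate(
            [aln.matrix[:, lo:hi] for lo, hi in blocks], axis=1
        ) if blocks else np.empty((6, 0))
        assert np.array_equal(filtered.matrix, rebuilt)
        params = BlockFilterParams()
        for lo, hi in blocks:
            assert hi - lo >= params.min_block_length
            labels = dt.classify_positions(aln)
            assert labels[lo] == "highly_conserved"
            assert labels[hi - 1] == "highly_conserved"


class TestConcatenate:
    def test_widths_additive_and_partitions_tile(self):
        loci = dt.make_alignment_fixture([2, 3, 4], n_taxa=3, seed=1)
        sm = dt.concatenate(
            {k: Alignment.from_records(v) for k, v in loci.items()}
        )
        assert sm.n_sites == 9
        intervals = sorted(sm.partitions.values())
        assert intervals[0][0] == 0 and intervals[-1][1] == 9
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            assert b == c

    def test_absent_taxon_padded_with_missing(self):
        loci = {
            "l1": Alignment.from_records([("x", "ACGT"), ("y", "ACGT")]),
            "l2": Alignment.from_records([("x", "GG")]),
        }
        sm = dt.concatenate(loci)
        row = sm.alignment.sequence("y")
        assert row == "ACGT??"
        assert dt.missing_stats(sm) == pytest.approx(2 / 12)

    def test_printed_locus_lengths_sum_to_supermatrix(self):
        """The six post-filter locus lengths (12S, 16S, COX1, CYB, RHO,
        RAG1) concatenate to a 4,263-site supermatrix."""
        loci = dt.make_alignment_fixture(
            [297, 376, 622, 1107, 437, 1424], n_taxa=10, seed=2
        )
        sm = dt.concatenate(
            {k: Alignment.from_records(v) for k, v in loci.items()}
        )
        assert sm.n_sites == 4263

    def test_partition_slice_recovers_input(self):
        loci = {
            "l1": Alignment.from_records([("x", "ACGT"), ("y", "TTTT")]),
            "l2": Alignment.from_records([("y", "GG"), ("x", "CC")]),
        }
        sm = dt.concatenate(loci)
        s1 = sm.slice_locus("l1")
        assert s1.sequence("x") == "ACGT" and s1.sequence("y") == "TTTT"
        s2 = sm.slice_locus("l2")
        assert s2.sequence("x") == "CC" and s2.sequence("y") == "GG"

    def test_duplicate_taxon_within_locus_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment.from_records([("x", "AC"), ("x", "GT")])

    def test_partition_file_one_based_inclusive(self):
        loci = {
            "l1": Alignment.from_records([("x", "ACGT")]),
            "l2": Alignment.from_records([("x", "GG")]),
        }
        sm = dt.concatenate(loci)
        text = sm.partition_file_text()
        assert "DNA, l1 = 1-4" in text
        assert "DNA, l2 = 5-6" in text


class TestMissingStats:
    def test_quarter_missing(self):
        sm = dt.concatenate(
            {"l": Alignment.from_records([("x", "A?"), ("y", "CG")])}
        )
        assert dt.missing_stats(sm) == 0.25

    def test_none_missing(self):
        sm = dt.concatenate(
            {"l": Alignment.from_records([("x", "AC"), ("y", "GT")])}
        )
        assert dt.missing_stats(sm) == 0.0

    def test_matches_generator_bookkeeping(self):
        loci = dt.make_alignment_fixture(
            [40] * 6, n_taxa=50, missing_fraction=0.59, seed=7
        )
        n_missing_blocks = sum(
            1 for records in loci.values() for _, seq in records
            if set(seq) == {"?"}
        )
        sm = dt.concatenate(
            {k: Alignment.from_records(v) for k, v in loci.items()}
        )
        assert dt.missing_stats(sm) == pytest.approx(
            n_missing_blocks * 40 / (50 * 240)
        )
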