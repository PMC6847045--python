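import numpy as np
import pytest
from hypothesis import given, strategies as st

from pdcovar.alignments import (
    ColumnLabel,
    TargetSite,
    anchor_and_trim,
    concatenate,
    filter_columns,
    read_concatenated,
    read_protein_alignment,
    read_sites_table,
    write_concatenated,
)
from pdcovar.errors import (
    AlignmentShapeError,
    AlphabetError,
    PairingError,
    TrimmingError,
)

# the I-OnuI target context: central four CAAC with 9 bases each side,
# embedded in the 26-nt duplex used for co-crystallization
IONUI_SEQ = "CTTTCCACTTATTCAACCTTTTACCC"
IONUI_SITE = TargetSite("I-OnuI", IONUI_SEQ, 13, 17)


class TestReadProteinAlignment:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nMA-DE\n>b\nmagde\n")
        rows = read_protein_alignment(p)
        assert rows == {"a": "MA-DE", "b": "MAGDE"}

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(AlignmentShapeError):
            read_protein_alignment(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nMADE\n>b\nMAGDE\n")
        with pytest.raises(AlignmentShapeError):
            read_protein_alignment(p)

    def test_bad_symbol_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMA*DE\n>b\nMAGDE\n")
        with pytest.raises(AlphabetError):
            read_protein_alignment(p)


class TestTargetSite:
    def test_ambiguity_codes_rejected(self):
        with pytest.raises(AlphabetError):
            TargetSite("x", "ACGTNACGTACG", 4, 8)

    def test_central4_span_must_be_four(self):
        with pytest.raises(ValueError):
            TargetSite("x", "ACGTACGTACGT", 4, 9)

    def test_central4_extraction(self):
        assert IONUI_SITE.central4 == "CAAC"


class TestAnchorAndTrim:
    def test_ionui_central_four_labeled_plus2_to_plus5(self):
        # wild-type central four must read CAAC at positions +2..+5
        row, labels = anchor_and_trim(IONUI_SITE, flank=9)
        assert len(row) == 22
        by_label = dict(zip((str(l) for l in labels), row))
        assert "".join(by_label[p] for p in ("+2", "+3", "+4", "+5")) == "CAAC"

    def test_labels_form_contiguous_signed_range_without_zero(self):
        _, labels = anchor_and_trim(IONUI_SITE, flank=9)
        idx = [l.index for l in labels]
        assert 0 not in idx
        walked = [idx[0]]
        while len(walked) < len(idx):
            nxt = walked[-1] + 1
            walked.append(nxt if nxt != 0 else 1)
        assert idx == walked

    def test_zero_flank_returns_central_four(self):
        row, labels = anchor_and_trim(IONUI_SITE, flank=0)
        assert row == "CAAC"
        assert [str(l) for l in labels] == ["+2", "+3", "+4", "+5"]

    def test_insufficient_flank_raises(self):
        short = TargetSite("s", "ACGTACGTCAACTTTTACGTA", 8, 12)  # 8 upstream
        with pytest.raises(TrimmingError):
            anchor_and_trim(short, flank=9)

    @given(flank=st.integers(min_value=0, max_value=9))
    def test_output_length_is_two_flank_plus_four(self, flank):
        row, labels = anchor_and_trim(IONUI_SITE, flank=flank)
        assert len(row) == 2 * flank + 4 == len(labels)


def _toy_family(n=4, plen=6, flank=2):
    rng = np.random.default_rng(0)
    prot = {
        f"m{i}": "".join(rng.choice(list("ACDEFG"), size=plen)) for i in range(n)
    }
    sites = [
        TargetSite(f"m{i}", "".join(rng.choice(list("ACGT"), size=2 * flank + 4)),
                   flank, flank + 4)
        for i in range(n)
    ]
    return prot, sites, flank


class TestConcatenate:
    def test_shape_and_column_order(self):
        prot, sites, flank = _toy_family()
        aln = concatenate(prot, sites, flank=flank)
        assert aln.matrix.shape == (4, 6 + 2 * flank + 4)
        kinds = [c.kind for c in aln.columns]
        assert kinds == ["protein"] * 6 + ["nucleotide"] * (2 * flank + 4)

    def test_site_order_does_not_matter(self):
        prot, sites, flank = _toy_family()
        a = concatenate(prot, sites, flank=flank)
        b = concatenate(prot, sites[::-1], flank=flank)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.member_ids == b.member_ids

    def test_missing_site_rejected(self):
        prot, sites, flank = _toy_family()
        with pytest.raises(PairingError):
            concatenate(prot, sites[:-1], flank=flank)

    def test_duplicate_site_rejected(self):
        prot, sites, flank = _toy_family()
        with pytest.raises(PairingError):
            concatenate(prot, sites + [sites[0]], flank=flank)

    def test_single_member_alignment_is_valid(self):
        prot, sites, flank = _toy_family(n=1)
        aln = concatenate(prot, sites, flank=flank)
        assert aln.n_members == 1

    def test_split_inverts_concatenate(self):
        prot, sites, flank = _toy_family()
        aln = concatenate(prot, sites, flank=flank)
        prot2, sites2 = aln.split()
        assert prot2 == prot
        assert sites2 == {s.member_id: s.sequence for s in sites}


class TestFilterColumns:
    def _gappy(self):
        # column 2 has 3/4 gaps, column 4 has 2/4; the rest are gap-free
        rows = ["A-CD", "A-C-", "A-CD", "AEC-"]
        prot = {f"m{i}": r for i, r in enumerate(rows)}
        sites = [TargetSite(f"m{i}", "ACGTACGT", 2, 6) for i in range(4)]
        return concatenate(prot, sites, flank=2)

    def test_gap_rich_columns_removed_and_reported(self):
        aln = self._gappy()
        filtered, excluded = filter_columns(aln, 0.5)
        assert [str(c) for c in excluded] == ["2"]
        assert filtered.n_columns == aln.n_columns - 1

    def test_threshold_one_removes_nothing(self):
        aln = self._gappy()
        filtered, excluded = filter_columns(aln, 1.0)
        assert excluded == [] and filtered.n_columns == aln.n_columns

    def test_all_gap_column_always_removed_below_one(self):
        prot = {"a": "-K", "b": "-K"}
        sites = [TargetSite(m, "ACGTACGT", 2, 6) for m in ("a", "b")]
        aln = concatenate(prot, sites, flank=2)
        _, excluded = filter_columns(aln, 0.99)
        assert [str(c) for c in excluded] == ["1"]

    def test_nucleotide_columns_never_removed(self):
        aln = self._gappy()
        filtered, _ = filter_columns(aln, 0.0)
        assert len(filtered.nucleotide_column_indices) == len(
            aln.nucleotide_column_indices
        )

    @given(t1=st.floats(0, 1), t2=st.floats(0, 1))
    def test_monotone_and_idempotent(self, t1, t2):
        aln = self._gappy()
        lo, hi = sorted((t1, t2))
        f_lo, ex_lo = filter_columns(aln, lo)
        f_hi, ex_hi = filter_columns(aln, hi)
        assert len(ex_hi) <= len(ex_lo)
        again, ex_again = filter_columns(f_lo, lo)
        assert ex_again == [] and again.n_columns == f_lo.n_columns


def test_serialization_round_trip(tmp_path, planted_family):
    aln = planted_family.alignment
    write_concatenated(aln, tmp_path / "c.fasta", tmp_path / "c.json")
    back = read_concatenated(tmp_path / "c.fasta", tmp_path / "c.json")
    assert back.member_ids == aln.member_ids
    assert back.columns == aln.columns
    assert np.array_equal(back.matrix, aln.matrix)


def test_sites_table_round_trip(tmp_path):
    p = tmp_path / "sites.tsv"
    p.write_text(
        "member_id\tsequence\ttop_cut\tbottom_cut\n"
        f"I-OnuI\t{IONUI_SEQ}\t13\t17\n"
    )
    sites = read_sites_table(p)
    assert sites == [IONUI_SITE]


def test_column_label_rejects_position_zero():
    with pytest.raises(ValueError):
        ColumnLabel("nucleotide", 0)
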