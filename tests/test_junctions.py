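"""Junction I/O, merging, and annotation-status classification."""

import numpy as np
import pandas as pd
import pytest

from djsplice.junctions import (
    ANNOTATED,
    NOVEL_ACCEPTOR,
    NOVEL_BOTH,
    NOVEL_COMBINATION,
    NOVEL_DONOR,
    UNASSIGNED,
    GeneAnnotation,
    GeneModel,
    Junction,
    JunctionParseError,
    JunctionTable,
    annotate_junctions,
    merge_samples,
    read_sj_tab,
    write_sj_tab,
)


def _single_sample_table(juncs, counts, sample="s1", libsize=None):
    df = pd.DataFrame({sample: counts}, index=[j.key for j in juncs])
    libs = None if libsize is None else {sample: libsize}
    return JunctionTable(juncs, df, libs)


class TestSjTab:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "x.SJ.out.tab"
        p.write_text("chr9\t35718407\t35718500\t2\t2\t1\t42\t0\t38\n")
        t = read_sj_tab(p, "s1")
        assert t.junctions == [Junction("chr9", "-", 35718407, 35718500)]
        assert t.counts.iloc[0, 0] == 42

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "e.SJ.out.tab"
        p.write_text("")
        assert len(read_sj_tab(p, "s1")) == 0

    @pytest.mark.parametrize("row", [
        "chr1\t100\t200\t3\t0\t0\t5\t0\t20",     # strand code outside dialect
        "chr1\t100\t200\t1\t0\t0",               # too few columns
        "chr1\t100\tweird\t1\t0\t0\t5\t0\t20",   # non-numeric coordinate
    ])
    def test_malformed_rows_raise_with_line_number(self, tmp_path, row):
        p = tmp_path / "bad.tab"
        p.write_text(row + "\n")
        with pytest.raises(JunctionParseError, match="line 1"):
            read_sj_tab(p, "s1")

    def test_sj_round_trip(self, tmp_path):
        juncs = [Junction("chr1", "+", 100, 200), Junction("chr2", "-", 5, 9)]
        t = _single_sample_table(juncs, [7, 3], libsize=1000)
        write_sj_tab(t, "s1", tmp_path / "rt.tab")
        back = read_sj_tab(tmp_path / "rt.tab", "s1", library_size=1000)
        assert back == t


class TestTableRoundTrip:
    def test_matrix_tsv_round_trip_exact(self, tmp_path, cassette_cohort):
        table, _, _ = cassette_cohort
        table.to_tsv(tmp_path / "m.tsv")
        back = JunctionTable.from_tsv(tmp_path / "m.tsv")
        assert back.counts.equals(table.counts)
        np.testing.assert_allclose(back.library_sizes, table.library_sizes,
                                   atol=0.5)

    def test_library_size_below_colsum_rejected(self):
        j = [Junction("chr1", "+", 10, 20)]
        df = pd.DataFrame({"s1": [100]}, index=[j[0].key])
        with pytest.raises(ValueError, match="library sizes"):
            JunctionTable(j, df, {"s1": 10})

    def test_duplicate_junction_keys_rejected(self):
        j = [Junction("chr1", "+", 10, 20), Junction("chr1", "+", 10, 20)]
        df = pd.DataFrame({"s1": [1, 2]}, index=[x.key for x in j])
        with pytest.raises(ValueError, match="duplicate"):
            JunctionTable(j, df)


class TestMerge:
    def test_single_fragment_identity(self):
        t = _single_sample_table([Junction("chr1", "+", 10, 20)], [4])
        assert merge_samples(t) == t

    def test_disjoint_junctions_zero_filled(self):
        a = _single_sample_table([Junction("chr1", "+", 10, 20)], [4], "s1")
        b = _single_sample_table([Junction("chr2", "-", 30, 40)], [9], "s2")
        m = merge_samples(a, b)
        assert m.counts.shape == (2, 2)
        assert m.counts.loc[a.junctions[0].key, "s2"] == 0
        assert m.counts.loc[b.junctions[0].key, "s1"] == 0

    def test_shared_junction_single_row(self):
        j = Junction("chr1", "+", 10, 20)
        a = _single_sample_table([j], [4], "s1")
        b = _single_sample_table([j], [6], "s2")
        m = merge_samples(a, b)
        assert list(m.counts.loc[j.key]) == [4, 6]

    def test_duplicate_sample_id_rejected(self):
        a = _single_sample_table([Junction("chr1", "+", 10, 20)], [4], "s1")
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_samples(a, a)


@pytest.fixture(scope="module")
def mini_annotation():
    """One minus-strand gene with exons [100,199],[400,499],[700,799] and a
    nested plus-strand gene for tie-breaking."""
    g = GeneModel("gm", "chr1", "-", {
        "gm.t1": ((100, 199), (400, 499), (700, 799))})
    return GeneAnnotation([g])


class TestAnnotate:
    @pytest.mark.parametrize("start,end,expected", [
        (200, 399, ANNOTATED),          # exon1-exon2 pairing present
        (200, 699, NOVEL_COMBINATION),  # both sites known, pairing absent
        (200, 650, NOVEL_DONOR),        # right (txn-upstream on '-') site new
        (250, 399, NOVEL_ACCEPTOR),     # left (txn-downstream on '-') site new
        (250, 650, NOVEL_BOTH),
    ])
    def test_class_enumeration_minus_strand(self, mini_annotation, start, end,
                                            expected):
        t = _single_sample_table([Junction("chr1", "-", start, end)], [5])
        st = annotate_junctions(t, mini_annotation)
        assert st.iloc[0]["status"] == expected
        assert st.iloc[0]["gene_id"] == "gm"

    def test_junction_outside_any_gene_unassigned(self, mini_annotation):
        t = _single_sample_table([Junction("chr1", "-", 5000, 6000)], [5])
        st = annotate_junctions(t, mini_annotation)
        assert st.iloc[0]["status"] == UNASSIGNED
        assert st.iloc[0]["gene_id"] is None

    def test_annotation_is_pure(self, cassette_cohort):
        table, ann, _ = cassette_cohort
        a = annotate_junctions(table, ann)
        b = annotate_junctions(table, ann)
        pd.testing.assert_frame_equal(a, b)

    def test_cassette_flanks_novel_skip_annotated(self, cassette_cohort,
                                                  cassette_statuses):
        _, _, truth = cassette_cohort
        g = truth["genes"]["gene_1"]
        inc_status = {cassette_statuses.at[k, "status"]
                      for k in g["inclusion_junctions"]}
        assert inc_status == {NOVEL_DONOR, NOVEL_ACCEPTOR}
        assert cassette_statuses.at[g["skipping_junction"],
                                    "status"] == ANNOTATED

    def test_minus_strand_txn_index_reverses_genomic_order(
            self, cassette_cohort, cassette_statuses):
        table, ann, _ = cassette_cohort
        st = cassette_statuses
        for gid, gene in ann.genes.items():
            sub = st[st.gene_id == gid].copy()
            keys = sub.index
            genomic_order = sorted(
                keys, key=lambda k: (Junction.from_key(k).intron_start,
                                     Junction.from_key(k).intron_end))
            idx = [int(sub.at[k, "txn_index"]) for k in genomic_order]
            if gene.strand == "-":
                assert idx == list(range(len(idx), 0, -1))
            else:
                assert idx == list(range(1, len(idx) + 1))

    def test_gene_assignment_prefers_matching_strand_then_span(self):
        big = GeneModel("big", "chr1", "+", {"big.t": ((100, 199), (900, 999))})
        small = GeneModel("small", "chr1", "-",
                          {"small.t": ((150, 299), (700, 849))})
        ann = GeneAnnotation([big, small])
        t = _single_sample_table([Junction("chr1", "-", 300, 699),
                                  Junction("chr1", "+", 300, 699)], [3, 4])
        st = annotate_junctions(t, ann)
        assert st.iloc[0]["gene_id"] == "small"   # strand match wins
        assert st.iloc[1]["gene_id"] == "big"


class TestGtfRoundTrip:
    def test_gtf_write_read_preserves_models(self, tmp_path, cassette_cohort):
        _, ann, _ = cassette_cohort
        ann.to_gtf(tmp_path / "a.gtf")
        back = GeneAnnotation.from_gtf(tmp_path / "a.gtf")
        assert set(back.genes) == set(ann.genes)
        for gid, g in ann.genes.items():
            assert back[gid].strand == g.strand
            assert back[gid].transcripts == g.transcripts
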