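from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtscan.genome_model import (
    Bed12Error,
    GenomicInterval,
    Gff3ParseError,
    merge_intervals,
    polya_site,
    read_cage,
    read_gff3_genes,
    read_transcripts,
    write_transcripts_bed12,
)

from conftest import make_transcript
from oracles import interval_union_oracle


# ---------------------------------------------------------------------------
# GenomicInterval
# ---------------------------------------------------------------------------


def test_interval_rejects_empty_and_inverted():
    with pytest.raises(ValueError):
        GenomicInterval("c", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", 10, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", 0, 5, strand="*")


def test_overlap_len():
    a = GenomicInterval("c", 0, 100)
    assert a.overlap_len(GenomicInterval("c", 50, 150)) == 50
    assert a.overlap_len(GenomicInterval("c", 100, 150)) == 0
    assert a.overlap_len(GenomicInterval("d", 0, 100)) == 0


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 200), st.integers(1, 50)).map(lambda p: (p[0], p[0] + p[1])),
        min_size=1,
        max_size=8,
    )
)
def test_merge_matches_boolean_mask_oracle(pairs):
    ivs = [GenomicInterval("c", s, e) for s, e in pairs]
    merged = merge_intervals(ivs)
    assert [(iv.start, iv.end) for iv in merged] == interval_union_oracle(pairs)
    # idempotence: merging a merged set is a no-op
    assert merge_intervals(merged) == merged


# ---------------------------------------------------------------------------
# GFF3 reading
# ---------------------------------------------------------------------------

GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneX
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=geneX.1;Parent=geneX
chr1\tsrc\tCDS\t121\t180\t.\t+\t0\tID=geneX.1.c;Parent=geneX.1
"""


def test_gff3_coordinate_conversion(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF_ONE_GENE)
    (gene,) = read_gff3_genes(p)
    assert (gene.span.start, gene.span.end) == (100, 200)
    assert [(c.start, c.end) for c in gene.cds_intervals] == [(120, 180)]


def test_gff3_multi_isoform_cds_union(tmp_path):
    text = """##gff-version 3
chr1\tsrc\tgene\t101\t300\t.\t+\t.\tID=geneY
chr1\tsrc\tmRNA\t101\t300\t.\t+\t.\tID=geneY.1;Parent=geneY
chr1\tsrc\tCDS\t121\t180\t.\t+\t0\tID=c1;Parent=geneY.1
chr1\tsrc\tmRNA\t101\t300\t.\t+\t.\tID=geneY.2;Parent=geneY
chr1\tsrc\tCDS\t151\t210\t.\t+\t0\tID=c2;Parent=geneY.2
"""
    p = tmp_path / "b.gff3"
    p.write_text(text)
    (gene,) = read_gff3_genes(p)
    # sweep-line union oracle over the 1-based-closed inputs converted
    assert [(c.start, c.end) for c in gene.cds_intervals] == interval_union_oracle(
        [(120, 180), (150, 210)]
    )
    assert [(c.start, c.end) for c in gene.cds_intervals] == [(120, 210)]


def test_gff3_biotype_filter_drops_ncrna(tmp_path):
    text = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=ncg;biotype=ncRNA
chr1\tsrc\tncRNA\t101\t200\t.\t+\t.\tID=ncg.1;Parent=ncg
"""
    p = tmp_path / "c.gff3"
    p.write_text(text)
    assert read_gff3_genes(p, biotype_filter="protein_coding") == []


def test_gff3_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nchr1\tsrc\tgene\tnotanint\t200\t.\t+\t.\tID=g\n")
    with pytest.raises(Gff3ParseError, match="line 2"):
        read_gff3_genes(p)


def test_gff3_orphan_cds_skipped_with_warning(tmp_path, caplog):
    text = GFF_ONE_GENE + "chr1\tsrc\tCDS\t500\t560\t.\t+\t0\tID=orphan;Parent=missing\n"
    p = tmp_path / "d.gff3"
    p.write_text(text)
    with caplog.at_level("WARNING"):
        genes = read_gff3_genes(p)
    assert len(genes) == 1
    assert any("without a parent" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------


def test_bed12_block_arithmetic(tmp_path):
    line = "chr1\t1000\t1160\tr1\t0\t+\t1000\t1160\t0\t2\t50,60\t0,100\n"
    p = tmp_path / "t.bed"
    p.write_text(line)
    (t,) = read_transcripts(p, format="bed12", sample_id="s")
    assert [(e.start, e.end) for e in t.exons] == [(1000, 1050), (1100, 1160)]
    assert [(iv.start, iv.end) for iv in t.introns()] == [(1050, 1100)]


def test_bed12_inconsistent_blocks_rejected(tmp_path):
    line = "chr1\t1000\t1200\tbadrec\t0\t+\t1000\t1200\t0\t2\t50,60\t0,100\n"
    p = tmp_path / "t.bed"
    p.write_text(line)
    with pytest.raises(Bed12Error, match="badrec"):
        read_transcripts(p)


def test_gff3_single_exon_transcript(tmp_path):
    text = """##gff-version 3
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=tx1
"""
    p = tmp_path / "t.gff3"
    p.write_text(text)
    (t,) = read_transcripts(p, format="gff3")
    assert len(t.exons) == 1
    assert t.introns() == ()


def test_duplicate_records_stay_distinct(tmp_path):
    line = "chr1\t100\t200\tr\t0\t+\t100\t200\t0\t1\t100\t0\n"
    p = tmp_path / "t.bed"
    p.write_text(line * 3)
    ts = read_transcripts(p)
    assert len(ts) == 3
    assert len(set(ts)) == 3  # identity-hashed, no silent collapsing


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 100), st.integers(1, 100)),
        min_size=1,
        max_size=5,
    ),
    st.sampled_from(["+", "-"]),
    st.integers(0, 1000),
)
def test_bed12_round_trip_preserves_exons(gaps_lens, strand, origin):
    exons = []
    pos = origin
    for gap, ex_len in gaps_lens:
        start = pos + gap
        exons.append((start, start + ex_len))
        pos = start + ex_len
    t = make_transcript("rt", exons, strand=strand)
    import tempfile, os

    fd, path = tempfile.mkstemp(suffix=".bed")
    os.close(fd)
    try:
        write_transcripts_bed12([t], path)
        (back,) = read_transcripts(path)
        assert [(e.start, e.end) for e in back.exons] == exons
        assert back.strand == strand
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# polyA site
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "exons,strand,expected",
    [
        ([(100, 200)], "+", 199),
        ([(100, 200)], "-", 100),
        ([(0, 50), (80, 120)], "+", 119),
    ],
)
def test_polya_site_definition(exons, strand, expected):
    t = make_transcript("t", exons, strand=strand)
    assert polya_site(t) == ("chr1", strand, expected)


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 50), st.integers(1, 50)), min_size=1, max_size=4
    )
)
def test_polya_site_strand_flip_symmetry(gaps_lens):
    """Mirroring coordinates around L and flipping strand mirrors the polyA site."""
    exons = []
    pos = 0
    for gap, ex_len in gaps_lens:
        start = pos + gap
        exons.append((start, start + ex_len))
        pos = start + ex_len
    L = pos + 10
    fwd = make_transcript("f", exons, strand="+")
    mirrored = sorted((L - e, L - s) for s, e in exons)
    rev = make_transcript("r", mirrored, strand="-")
    assert polya_site(rev)[2] == L - 1 - polya_site(fwd)[2]


# ---------------------------------------------------------------------------
# CAGE
# ---------------------------------------------------------------------------


def test_read_cage_converts_to_zero_based(tmp_path):
    p = tmp_path / "cage.tsv"
    p.write_text("chrom\tstrand\tposition\ttpm\nchr1\t+\t101\t0.5\n")
    track = read_cage(p)
    assert track.entries == {("chr1", "+", 100): 0.5}
    assert track.max_tpm_in("chr1", "+", 90, 110) == 0.5
    assert track.max_tpm_in("chr1", "-", 90, 110) == 0.0


def test_read_cage_rejects_duplicates(tmp_path):
    p = tmp_path / "cage.tsv"
    p.write_text("chrom\tstrand\tposition\ttpm\nchr1\t+\t101\t0.5\nchr1\t+\t101\t0.7\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_cage(p)
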