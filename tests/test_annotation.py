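"""Gene-model reading, intron derivation and U2 reference selection."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from minorsplice.annotation import (
    U2,
    U12,
    UNKNOWN,
    Exon,
    Gene,
    GeneModelSet,
    Intron,
    Transcript,
    build_reference_pairs,
    read_gene_models,
    read_intron_types,
    select_reference_u2_introns,
    write_gtf,
    write_intron_types,
)
from minorsplice.errors import DataError, GTFParseError, ValidationError
from minorsplice.simulate import SimulationConfig, simulate_gene_set


def gtf_line(chrom, start1, end1, strand, gene, tx):
    return (
        f'{chrom}\tsim\texon\t{start1}\t{end1}\t.\t{strand}\t.\t'
        f'gene_id "{gene}"; transcript_id "{tx}";\n'
    )


def make_gene(splice_types, strand="+", gene_id="gA"):
    """Gene with len(splice_types)+1 exons; introns labelled in transcript order."""
    n_exons = len(splice_types) + 1
    exons = []
    pos = 100
    for _ in range(n_exons):
        exons.append(Exon("chr1", pos, pos + 100, strand))
        pos += 100 + 200
    t = Transcript("t1", gene_id, exons)
    t.derive_introns()
    by_index = {i.intron_index: j for j, i in enumerate(t.introns)}
    for order, stype in enumerate(splice_types, start=1):
        j = by_index[order]
        from dataclasses import replace
        t.introns[j] = replace(t.introns[j], splice_type=stype)
    return Gene(gene_id=gene_id, transcripts={"t1": t}, canonical_transcript_id="t1")


class TestReadGeneModels:
    def test_coordinate_conversion_and_intron_derivation(self):
        gtf = gtf_line("chr1", 101, 200, "+", "g1", "t1") + gtf_line("chr1", 301, 400, "+", "g1", "t1")
        models = read_gene_models(io.StringIO(gtf))
        t = models.genes["g1"].canonical_transcript
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in t.introns] == [(200, 300)]

    def test_empty_gtf(self):
        models = read_gene_models(io.StringIO(""))
        assert models.genes == {}

    def test_single_exon_transcript_kept_with_zero_introns(self):
        models = read_gene_models(io.StringIO(gtf_line("chr1", 1, 500, "+", "g1", "t1")))
        assert models.genes["g1"].canonical_transcript.introns == []

    def test_malformed_line_names_line_number(self):
        gtf = gtf_line("chr1", 101, 200, "+", "g1", "t1") + "chr1\tnot-a-gtf-line\n"
        with pytest.raises(GTFParseError, match="line 2"):
            read_gene_models(io.StringIO(gtf))

    def test_overlapping_exons_rejected(self):
        gtf = gtf_line("chr1", 101, 300, "+", "g1", "t1") + gtf_line("chr1", 200, 400, "+", "g1", "t1")
        with pytest.raises(ValidationError, match="overlapping"):
            read_gene_models(io.StringIO(gtf))

    def test_canonical_transcript_longest_exonic_tie_by_id(self):
        gtf = (
            gtf_line("chr1", 101, 200, "+", "g1", "t_b")
            + gtf_line("chr1", 301, 400, "+", "g1", "t_b")
            + gtf_line("chr1", 101, 300, "+", "g1", "t_a")
        )
        models = read_gene_models(io.StringIO(gtf))
        # both transcripts have exonic length 200; tie broken lexicographically
        assert models.genes["g1"].canonical_transcript_id == "t_a"

    def test_minus_strand_intron_index_is_transcript_order(self):
        gtf = (
            gtf_line("chr1", 101, 200, "-", "g1", "t1")
            + gtf_line("chr1", 301, 400, "-", "g1", "t1")
            + gtf_line("chr1", 501, 600, "-", "g1", "t1")
        )
        t = read_gene_models(io.StringIO(gtf)).genes["g1"].canonical_transcript
        ordered = t.introns_in_transcript_order()
        # first intron in transcript order is the genomically rightmost one
        assert (ordered[0].start, ordered[0].end) == (400, 500)
        assert (ordered[1].start, ordered[1].end) == (200, 300)


class TestRoundTrips:
    def test_gtf_round_trip_on_simulated_models(self, tmp_path):
        state = simulate_gene_set(SimulationConfig(n_genes=40, seed=3))
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(state.models, str(p1))
        models2 = read_gene_models(str(p1), genome=state.models.genome)
        write_gtf(models2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
        assert set(models2.genes) == set(state.models.genes)
        for gid, gene in state.models.genes.items():
            t1 = gene.canonical_transcript
            t2 = models2.genes[gid].canonical_transcript
            assert [(e.start, e.end) for e in t1.exons] == [(e.start, e.end) for e in t2.exons]
            assert [(i.start, i.end) for i in t1.introns] == [(i.start, i.end) for i in t2.introns]

    def test_intron_type_labels_round_trip(self, tmp_path):
        state = simulate_gene_set(SimulationConfig(n_genes=40, seed=3))
        gtf, tsv = tmp_path / "m.gtf", tmp_path / "t.tsv"
        write_gtf(state.models, str(gtf))
        write_intron_types(state.models, str(tsv))
        models2 = read_gene_models(str(gtf), genome=state.models.genome)
        models2, report = read_intron_types(str(tsv), models2)
        assert report["n_skipped_rows"] == 0
        for gid, gene in state.models.genes.items():
            want = {(i.start, i.end) for i in gene.u12_introns}
            got = {(i.start, i.end) for i in models2.genes[gid].u12_introns}
            assert want == got, gid


class TestIntronTypes:
    def make_models(self):
        gtf = "".join(
            gtf_line("chr1", s, e, "+", "g1", "t1")
            for s, e in [(101, 200), (301, 400), (501, 600), (701, 800)]
        )
        return read_gene_models(io.StringIO(gtf), genome={"chr1": 1000})

    def tsv(self, rows):
        header = "chrom\tstart\tend\tstrand\tgene_id\tsplice_type\n"
        return io.StringIO(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_labeling_marks_u12_gene(self):
        models = self.make_models()
        models, _ = read_intron_types(
            self.tsv([("chr1", 401, 500, "+", "g1", "U12")]), models
        )
        assert [(i.start, i.end) for i in models.genes["g1"].u12_introns] == [(400, 500)]

    def test_empty_table_leaves_all_unknown(self):
        models = self.make_models()
        models, _ = read_intron_types(self.tsv([]), models)
        assert models.u12_genes() == []
        t = models.genes["g1"].canonical_transcript
        assert all(i.splice_type == UNKNOWN for i in t.introns)

    def test_unmatched_row_skipped_and_reported(self):
        models = self.make_models()
        _, report = read_intron_types(
            self.tsv([("chr1", 999, 1000, "+", "g1", "U12")]), models
        )
        assert report["n_skipped_rows"] == 1

    def test_conflicting_labels_error(self):
        models = self.make_models()
        with pytest.raises(DataError, match="conflicting"):
            read_intron_types(
                self.tsv(
                    [("chr1", 401, 500, "+", "g1", "U12"), ("chr1", 401, 500, "+", "g1", "U2")]
                ),
                models,
            )

    def test_label_application_independent_of_row_order(self):
        rows = [
            ("chr1", 201, 300, "+", "g1", "U2"),
            ("chr1", 401, 500, "+", "g1", "U12"),
            ("chr1", 601, 700, "+", "g1", "U2"),
        ]
        m1, _ = read_intron_types(self.tsv(rows), self.make_models())
        m2, _ = read_intron_types(self.tsv(rows[::-1]), self.make_models())
        t1 = m1.genes["g1"].canonical_transcript
        t2 = m2.genes["g1"].canonical_transcript
        assert [i.splice_type for i in t1.introns] == [i.splice_type for i in t2.introns]


class TestReferenceSelection:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_flanking_u2_selected(self, strand):
        gene = make_gene([U2, U2, U12, U2], strand=strand)
        u12 = gene.u12_introns[0]
        pair = select_reference_u2_introns(gene, u12)
        assert pair.u2_ref_a.intron_index == 2
        assert pair.u2_ref_b.intron_index == 4

    def test_terminal_u12_falls_back_to_one_side(self):
        gene = make_gene([U12, U2, U2])
        pair = select_reference_u2_introns(gene, gene.u12_introns[0])
        assert {pair.u2_ref_a.intron_index, pair.u2_ref_b.intron_index} == {2, 3}

    def test_insufficient_references_marks_unquantifiable(self):
        gene = make_gene([U12, U2])
        assert select_reference_u2_introns(gene, gene.u12_introns[0]) is None
        models = GeneModelSet(genome={"chr1": 10000}, genes={"gA": gene})
        pairs, exclusions = build_reference_pairs(models)
        assert pairs == []
        assert exclusions == {"gA": "insufficient_U2_references"}

    def test_unknown_introns_ineligible_as_references(self):
        gene = make_gene([U2, UNKNOWN, U12, UNKNOWN, U2])
        pair = select_reference_u2_introns(gene, gene.u12_introns[0])
        assert pair.u2_ref_a.intron_index == 1
        assert pair.u2_ref_b.intron_index == 5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    exon_lens=st.lists(st.integers(50, 300), min_size=2, max_size=8),
    intron_lens=st.lists(st.integers(60, 2000), min_size=7, max_size=7),
    strand=st.sampled_from("+-"),
)
def test_exons_and_introns_tile_the_transcript_span(exon_lens, intron_lens, strand):
    """Concatenating exons and introns in coordinate order exactly tiles
    [first exon start, last exon end)."""
    pos = 10
    exons = []
    for i, el in enumerate(exon_lens):
        exons.append(Exon("chrX", pos, pos + el, strand))
        pos += el
        if i < len(exon_lens) - 1:
            pos += intron_lens[i]
    t = Transcript("t", "g", exons)
    t.derive_introns()
    pieces = sorted(
        [(e.start, e.end) for e in t.exons] + [(i.start, i.end) for i in t.introns]
    )
    assert pieces[0][0] == t.exons[0].start
    assert pieces[-1][1] == t.exons[-1].end
    for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
        assert e1 == s2
    assert len(t.introns) == len(t.exons) - 1
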