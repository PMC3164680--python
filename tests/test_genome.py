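"""Genome model: parsing, spacer extraction, orientation, orthology matching."""

import pytest

from igsfootprint.genome import (
    GenomeFormatError,
    ValidationError,
    classify_orientation,
    extract_igs,
    filter_analyzable,
    match_orthologous_igs,
    read_genome,
    summarize_genome,
)
from igsfootprint.align import MultipleAlignment

from conftest import make_genome


GENBANK = """\
LOCUS       chr                     1000 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  toy.
ACCESSION   chr
VERSION     chr
FEATURES             Location/Qualifiers
     source          1..1000
     CDS             101..200
                     /locus_tag="g1"
     CDS             complement(301..400)
                     /locus_tag="g2"
ORIGIN
"""


def _write_genbank(tmp_path, seq="AT" * 500):
    lines = [GENBANK]
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped}\n")
    lines.append("//\n")
    path = tmp_path / "toy.gb"
    path.write_text("".join(lines))
    return str(path)


def _write_fasta_gff(tmp_path, seq="AT" * 500):
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(f">chr\n{seq}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr\ttest\tCDS\t101\t200\t.\t+\t.\tID=g1;locus_tag=g1\n"
        "chr\ttest\tCDS\t301\t400\t.\t-\t.\tID=g2;locus_tag=g2\n"
    )
    return str(fasta), str(gff)


class TestReadGenome:
    def test_genbank_parse(self, tmp_path):
        g = read_genome(_write_genbank(tmp_path), taxon_id="toy")
        assert len(g.features) == 2
        assert [f.feature_id for f in g.features] == ["g1", "g2"]
        assert (g.features[0].start, g.features[0].end) == (100, 200)
        assert g.features[1].strand == "-"
        assert len(g.contigs["chr"]) == 1000

    def test_fasta_gff_equivalent_to_genbank(self, tmp_path):
        gb = read_genome(_write_genbank(tmp_path), taxon_id="toy")
        fasta, gff = _write_fasta_gff(tmp_path)
        fg = read_genome(fasta, gff, taxon_id="toy")
        assert fg.contigs == gb.contigs
        assert [
            (f.feature_id, f.start, f.end, f.strand, f.kind) for f in fg.features
        ] == [(f.feature_id, f.start, f.end, f.strand, f.kind) for f in gb.features]

    def test_feature_beyond_contig_is_validation_error(self, tmp_path):
        fasta, _ = _write_fasta_gff(tmp_path)
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\nchr\ttest\tCDS\t900\t1200\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValidationError):
            read_genome(fasta, str(gff))

    def test_unparseable_file_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text("not a fasta at all")
        with pytest.raises(GenomeFormatError):
            read_genome(str(bad), str(bad))


class TestSummaries:
    def test_feature_tally(self):
        g = make_genome(
            "t",
            [("a", 0, 90, "+", "CDS"), ("b", 100, 190, "+", "CDS"),
             ("c", 200, 290, "+", "CDS"), ("p", 300, 390, "+", "pseudogene")],
        )
        s = summarize_genome(g)
        assert s["CDS"] == 3 and s["pseudogenes"] == 1

    def test_all_at_contig_has_zero_gc(self):
        g = make_genome("t", [("a", 0, 10, "+", "CDS")], seq="AT" * 500)
        assert summarize_genome(g)["gc_percent"] == 0.0

    def test_mutation_classes(self):
        g = make_genome("t", [("p", 0, 90, "+", "pseudogene")])
        s = summarize_genome(
            g, pseudogene_mutations={"p1": 1, "p2": 2, "p3": 5},
            homopolymeric={"p1": True, "p2": False},
        )
        assert s["mutation_classes"] == {
            "1 mutation": 1, "2 mutations": 1, ">=3 mutations": 1
        }
        assert s["homopolymeric_frameshifts"] == 1


class TestOrientation:
    @pytest.mark.parametrize(
        "left,right,expected",
        [("+", "+", "tandem"), ("-", "-", "tandem"),
         ("+", "-", "convergent"), ("-", "+", "divergent")],
    )
    def test_all_strand_pairs(self, left, right, expected):
        assert classify_orientation(left, right) == expected

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValidationError):
            classify_orientation("+", "x")

    def test_tandem_iff_equal_strands(self):
        for a in "+-":
            for b in "+-":
                assert (classify_orientation(a, b) == "tandem") == (a == b)


class TestExtractIgs:
    def test_simple_gap(self):
        g = make_genome("t", [("a", 0, 100, "+", "CDS"), ("b", 150, 250, "+", "CDS")])
        recs = extract_igs(g)
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.end, r.length, r.orientation) == (100, 150, 50, "tandem")
        assert not r.excluded

    def test_overlapping_genes_flagged(self):
        g = make_genome("t", [("a", 0, 100, "+", "CDS"), ("b", 90, 200, "+", "CDS")])
        (r,) = extract_igs(g)
        assert r.length == 0 and r.excluded

    def test_alternating_strands_match_classifier(self):
        strands = ["+", "-", "+", "-", "+"]
        genes = [
            (f"g{i}", i * 100, i * 100 + 50, s, "CDS") for i, s in enumerate(strands)
        ]
        recs = extract_igs(make_genome("t", genes))
        assert len(recs) == 4
        for r, (ls, rs) in zip(recs, zip(strands, strands[1:])):
            assert r.orientation == classify_orientation(ls, rs)

    def test_pseudogene_merging_flag(self):
        g = make_genome(
            "t",
            [("a", 0, 100, "+", "CDS"), ("p", 150, 200, "+", "pseudogene"),
             ("b", 250, 350, "+", "CDS")],
        )
        assert len(extract_igs(g, include_pseudogenes=True)) == 2
        merged = extract_igs(g, include_pseudogenes=False)
        assert len(merged) == 1 and merged[0].length == 150

    def test_contig_bookkeeping(self):
        """Feature lengths + spacer lengths + flanks tile the contig exactly."""
        genes = [("a", 37, 120, "+", "CDS"), ("b", 180, 333, "-", "CDS"),
                 ("c", 400, 512, "+", "CDS")]
        g = make_genome("t", genes, length=600, seq="ACGT" * 150)
        recs = extract_igs(g)
        total = sum(e - s for _, s, e, _, _ in genes) + sum(r.length for r in recs)
        total += genes[0][1] + (600 - genes[-1][2])  # unannotated flanks
        assert total == 600


class TestOrthologousMatching:
    def _three_gene_genomes(self, n=4, drop_b_in=None):
        out = []
        for i in range(n):
            genes = [("A", 0, 100, "+", "CDS"), ("B", 150, 250, "+", "CDS"),
                     ("C", 300, 400, "+", "CDS")]
            if drop_b_in == i:
                genes = [genes[0], genes[2]]
            out.append(make_genome(f"t{i}", genes))
        return out

    def test_identical_layout(self):
        sets = match_orthologous_igs(self._three_gene_genomes(), min_taxa=4)
        assert len(sets) == 2
        assert all(s.n_taxa == 4 for s in sets)
        assert {s.key for s in sets} == {("A", "B"), ("B", "C")}

    def test_deletion_splits_matching(self):
        sets = match_orthologous_igs(self._three_gene_genomes(drop_b_in=3), min_taxa=3)
        by_key = {s.key: s for s in sets}
        assert set(by_key) == {("A", "B"), ("B", "C")}
        assert all(by_key[k].n_taxa == 3 for k in by_key)
        assert "t3" not in by_key[("A", "B")].members

    def test_symmetric_under_input_order(self):
        genomes = self._three_gene_genomes()
        a = match_orthologous_igs(genomes, min_taxa=4)
        b = match_orthologous_igs(list(reversed(genomes)), min_taxa=4)
        assert {s.key for s in a} == {s.key for s in b}
        for sa in a:
            sb = next(s for s in b if s.key == sa.key)
            assert sa.members.keys() == sb.members.keys()

    def test_duplicate_ortholog_rejected(self):
        g = make_genome("t", [("A", 0, 100, "+", "CDS"), ("A2", 150, 250, "+", "CDS")])
        g.features[1] = g.features[1].__class__(
            "A2", "chr", 150, 250, "+", "CDS", ortholog_id="A"
        )
        with pytest.raises(ValidationError):
            match_orthologous_igs([g, make_genome("u", [("A", 0, 100, "+", "CDS"),
                                                        ("B", 150, 250, "+", "CDS")])])


class TestFilterAnalyzable:
    def _set_with_alignment(self, igs_len, aln_len):
        genomes = [
            make_genome(t, [("A", 0, 100, "+", "CDS"),
                            ("B", 100 + igs_len, 200 + igs_len, "+", "CDS")])
            for t in ("x", "y")
        ]
        sets = match_orthologous_igs(genomes, min_taxa=2)
        aln = MultipleAlignment("k", ["x", "y"], ["A" * aln_len, "A" * aln_len])
        return sets, {sets[0].key: aln}

    def test_alignment_length_threshold(self):
        sets, alns = self._set_with_alignment(igs_len=49, aln_len=49)
        assert filter_analyzable(sets, alns) == []
        sets, alns = self._set_with_alignment(igs_len=50, aln_len=50)
        assert len(filter_analyzable(sets, alns)) == 1

    def test_zero_length_member_excluded(self):
        sets, alns = self._set_with_alignment(igs_len=0, aln_len=60)
        log = []
        assert filter_analyzable(sets, alns, filter_log=log) == []
        assert log and log[0][1] == "zero_length_member"
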