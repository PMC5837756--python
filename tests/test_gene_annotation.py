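import textwrap

import pytest

from cnarec.gene_annotation import (
    GeneModel,
    GeneModelError,
    annotate_regions,
    build_mutation_matrix,
    carrier_status,
    load_gene_models,
    write_gene_models_bed,
)
from cnarec.recurrent_caller import RecurrentRegion
from cnarec.segment_io import GenomicInterval, PatientRecord

from conftest import iv, seg


def region(chrom, start, end, alt="gain", patients=("A", "B"), genes=()):
    inner = GenomicInterval(chrom, start, end)
    return RecurrentRegion(
        chrom=chrom, alteration_type=alt, inner=inner,
        outer=GenomicInterval(chrom, max(0, start - 5000), end + 5000),
        patient_set=frozenset(patients), genes=genes,
    )


def gene(symbol, chrom, start, end, coding=True, exons=()):
    return GeneModel(
        symbol=symbol, chrom=chrom, span=GenomicInterval(chrom, start, end),
        is_protein_coding=coding, exons=exons,
    )


class TestLoadGeneModels:
    def test_bed_two_genes_with_strand(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t100\t5000\tGENE1\t0\t+\nchr2\t200\t9000\tGENE2\t0\t-\n")
        models = load_gene_models(path)
        by_symbol = {m.symbol: m for m in models}
        assert by_symbol["GENE1"].strand == "+"
        assert by_symbol["GENE2"].strand == "-"
        assert by_symbol["GENE2"].chrom == "2"
        assert by_symbol["GENE1"].span == iv("1", 100, 5000)

    def test_gtf_gene_with_three_exons(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(
            textwrap.dedent(
                """\
                1\tsrc\tgene\t101\t5000\t.\t+\t.\tgene_id "G1"; gene_name "GENE1";
                1\tsrc\texon\t101\t500\t.\t+\t.\tgene_id "G1"; gene_name "GENE1";
                1\tsrc\texon\t1001\t1500\t.\t+\t.\tgene_id "G1"; gene_name "GENE1";
                1\tsrc\texon\t4001\t5000\t.\t+\t.\tgene_id "G1"; gene_name "GENE1";
                """
            )
        )
        (model,) = load_gene_models(path)
        assert model.span == iv("1", 100, 5000)  # 1-based closed -> half-open
        assert len(model.exons) == 3
        assert all(model.span.contains(e) for e in model.exons)

    def test_bed_gtf_same_spans(self, tmp_path):
        spans = [("1", 100, 5000), ("2", 0, 900), ("3", 10, 20), ("X", 7, 70),
                 ("11", 4_931_741, 4_932_834)]
        bed = tmp_path / "g.bed"
        bed.write_text(
            "".join(f"{c}\t{s}\t{e}\tG{i}\t0\t+\n" for i, (c, s, e) in enumerate(spans))
        )
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            "".join(
                f'{c}\tsrc\tgene\t{s + 1}\t{e}\t.\t+\t.\tgene_id "G{i}";\n'
                for i, (c, s, e) in enumerate(spans)
            )
        )
        bed_models = {m.symbol: m.span for m in load_gene_models(bed)}
        gtf_models = {m.symbol: m.span for m in load_gene_models(gtf)}
        assert bed_models == gtf_models

    def test_unparseable_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t100\t5000\tGENE1\n1\tnotanumber\t10\tG2\n")
        with pytest.raises(GeneModelError, match="line 2"):
            load_gene_models(path)

    def test_duplicate_symbol_keeps_widest(self, tmp_path):
        path = tmp_path / "dup.bed"
        path.write_text("1\t100\t500\tGENE1\n1\t50\t5000\tGENE1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            models = load_gene_models(path)
        (model,) = models
        assert model.span == iv("1", 50, 5000)

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("whatever")
        with pytest.raises(GeneModelError, match="format"):
            load_gene_models(path)

    def test_bed_round_trip(self, tmp_path):
        models = [gene("GENE1", "1", 100, 5000), gene("GENE2", "7", 0, 800)]
        path = tmp_path / "out.bed"
        write_gene_models_bed(models, path)
        loaded = load_gene_models(path)
        assert {m.symbol: m.span for m in loaded} == {m.symbol: m.span for m in models}

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gene("G", "1", 100, 200, exons=(iv("1", 150, 300),))


class TestAnnotateRegions:
    def test_intergenic_desert_non_coding(self):
        (annotated,) = annotate_regions(
            [region("1", 1_000_000, 1_010_000)], [gene("FAR", "1", 5_000_000, 5_100_000)]
        )
        assert annotated.genes == ()
        assert annotated.genome_class == "non-coding"

    def test_two_adjacent_genes_both_reported(self):
        genes = [gene("MMP26X", "11", 4_931_000, 4_932_000),
                 gene("OR51A2X", "11", 4_932_100, 4_933_500)]
        (annotated,) = annotate_regions([region("11", 4_931_741, 4_932_834)], genes)
        assert annotated.genes == ("MMP26X", "OR51A2X")
        assert annotated.genome_class == "coding"

    def test_non_coding_gene_gives_non_coding_class(self):
        (annotated,) = annotate_regions(
            [region("1", 100, 2000)], [gene("LINC", "1", 0, 5000, coding=False)]
        )
        assert annotated.genes == ("LINC",)
        assert annotated.genome_class == "non-coding"

    def test_exon_level_refinement(self):
        # Protein-coding gene overlaps only through an intron: non-coding.
        g = gene("G", "1", 0, 10_000,
                 exons=(iv("1", 0, 1000), iv("1", 9_000, 10_000)))
        (annotated,) = annotate_regions([region("1", 3_000, 5_000)], [g])
        assert annotated.genes == ("G",)
        assert annotated.genome_class == "non-coding"
        (hit,) = annotate_regions([region("1", 500, 5_000)], [g])
        assert hit.genome_class == "coding"

    def test_outer_assignment_option(self):
        g = gene("EDGE", "1", 96_000, 98_000)  # overlaps outer pad only
        (inner_only,) = annotate_regions([region("1", 100_000, 105_000)], [g])
        assert inner_only.genes == ()
        (outer,) = annotate_regions([region("1", 100_000, 105_000)], [g], use_outer=True)
        assert outer.genes == ("EDGE",)

    def test_coding_fraction_on_constructed_regions(self):
        # 12 of 50 regions overlap a coding gene -> fraction 0.24.
        regions = [region("1", 100_000 * i, 100_000 * i + 10_000) for i in range(50)]
        genes = [gene(f"G{i}", "1", 100_000 * i + 1_000, 100_000 * i + 3_000)
                 for i in range(12)]
        annotated = annotate_regions(regions, genes)
        frac = sum(r.genome_class == "coding" for r in annotated) / len(annotated)
        assert frac == pytest.approx(0.24)
        # coding + non-coding fractions sum to one
        non = sum(r.genome_class == "non-coding" for r in annotated) / len(annotated)
        assert frac + non == pytest.approx(1.0)

    def test_assigned_genes_overlap_inner(self):
        genes = [gene(f"G{i}", "1", 1_000 * i, 1_000 * i + 800) for i in range(100)]
        annotated = annotate_regions([region("1", 10_500, 20_000)], genes)
        for r in annotated:
            for symbol in r.genes:
                g = next(m for m in genes if m.symbol == symbol)
                assert g.span.overlaps(r.inner)


def make_patients(n, prefix="P"):
    return [PatientRecord(f"{prefix}{i}", 40.0, 5.0, 1) for i in range(n)]


class TestCarrierStatus:
    def test_requires_overlap_and_matching_type(self):
        patients = make_patients(3)
        r = region("1", 10_000, 20_000, alt="gain")
        segments = [
            seg("P0", "1", 5_000, 15_000, cn=3),   # overlapping gain: carrier
            seg("P1", "1", 5_000, 15_000, cn=1),   # loss: not a carrier
            seg("P2", "1", 50_000, 60_000, cn=3),  # elsewhere: not a carrier
        ]
        status = carrier_status(r, segments, patients)
        assert status.tolist() == [True, False, False]


class TestMutationMatrix:
    def test_row_frequency(self):
        patients = make_patients(10)
        r = region("1", 10_000, 20_000, genes=("GENE1",))
        segments = [seg(f"P{i}", "1", 8_000, 22_000, cn=3) for i in range(5)]
        matrix = build_mutation_matrix([r], segments, patients)
        assert matrix.frequency("GENE1") == pytest.approx(0.5)
        assert matrix.gene_types["GENE1"] == "gain"

    def test_patient_with_no_segments_all_none(self):
        patients = make_patients(3)
        r = region("1", 10_000, 20_000, genes=("GENE1",))
        segments = [seg("P0", "1", 8_000, 22_000, cn=3)]
        matrix = build_mutation_matrix([r], segments, patients)
        assert (matrix.states["P2"] == "none").all()

    def test_rows_ordered_by_descending_frequency(self):
        patients = make_patients(10)
        r1 = region("1", 10_000, 20_000, genes=("AAA",))
        r2 = region("2", 10_000, 20_000, genes=("BBB",))
        segments = [seg(f"P{i}", "1", 8_000, 22_000, cn=3) for i in range(4)] + [
            seg(f"P{i}", "2", 8_000, 22_000, cn=3) for i in range(6)
        ]
        matrix = build_mutation_matrix([r1, r2], segments, patients)
        assert matrix.genes == ["BBB", "AAA"]  # 0.6 before 0.4

    def test_tie_broken_alphabetically(self):
        patients = make_patients(4)
        r1 = region("1", 10_000, 20_000, genes=("ZZZ",))
        r2 = region("2", 10_000, 20_000, genes=("AAA",))
        segments = [seg("P0", "1", 8_000, 22_000), seg("P0", "2", 8_000, 22_000)]
        matrix = build_mutation_matrix([r1, r2], segments, patients)
        assert matrix.genes == ["AAA", "ZZZ"]

    def test_loss_region_gene_reports_losses(self):
        patients = make_patients(2)
        r = region("1", 10_000, 20_000, alt="loss", genes=("DEL1",))
        segments = [seg("P0", "1", 8_000, 22_000, cn=1)]
        matrix = build_mutation_matrix([r], segments, patients)
        assert matrix.states.loc["DEL1", "P0"] == "loss"
        assert matrix.states.loc["DEL1", "P1"] == "none"

    def test_tsv_export_symbols(self, tmp_path):
        patients = make_patients(2)
        r = region("1", 10_000, 20_000, genes=("GENE1",))
        segments = [seg("P0", "1", 8_000, 22_000, cn=3)]
        matrix = build_mutation_matrix([r], segments, patients)
        out = tmp_path / "matrix.tsv"
        matrix.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "gene\tP0\tP1"
        assert lines[1] == "GENE1\tG\t."

    def test_empty_regions(self):
        matrix = build_mutation_matrix([], [], make_patients(2))
        assert matrix.genes == []

    def test_frequency_equals_region_fraction_when_gene_covers_mcr(self):
        # Carriers of the defining region are exactly the gene's mutated set.
        patients = make_patients(20)
        carriers = [seg(f"P{i}", "1", 9_000, 21_000, cn=3) for i in range(7)]
        r = region("1", 10_000, 20_000, genes=("GENE1",),
                   patients=tuple(f"P{i}" for i in range(7)))
        matrix = build_mutation_matrix([r], carriers, patients)
        assert matrix.frequency("GENE1") == pytest.approx(7 / 20)
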