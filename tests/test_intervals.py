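"""Coordinate types, peak I/O, overlap algebra and TSS association."""

import numpy as np
import pytest

from cistromedose.intervals import (
    CistromeSet,
    GeneModel,
    GenomicInterval,
    Peak,
    classify_annotation,
    map_to_tss,
    overlap_sets,
    read_peaks,
    write_peaks,
    read_refflat,
)


def peak(chrom, start, end, summit=None, score=1.0, fe=1.0, pid=""):
    return Peak(
        GenomicInterval(chrom, start, end),
        (start + end) // 2 if summit is None else summit,
        score, fe, pid or f"{chrom}:{start}",
    )


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_summit_must_lie_inside_peak(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("chr1", 100, 200), 200)
        Peak(GenomicInterval("chr1", 100, 200), 199)  # end-exclusive boundary

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            CistromeSet("x", [peak("chr1", 0, 10, pid="a"), peak("chr1", 20, 30, pid="a")])


class TestPeakIO:
    def test_bed_round_trip(self, tmp_path):
        peaks = [
            peak("chr1", 100, 700, summit=400, score=864.12, fe=3.48, pid="p1"),
            peak("chr2", 50, 950, summit=500, score=886.86, fe=5.6, pid="p2"),
            peak("chr2", 2000, 2600, summit=2100, score=633.63, fe=8.63, pid="p3"),
        ]
        path = tmp_path / "x.bed"
        write_peaks(CistromeSet("x", peaks), path)
        back = read_peaks(path)
        assert len(back) == 3
        for orig, rp in zip(peaks, back):
            assert rp.interval == orig.interval
            assert rp.summit == orig.summit
            assert rp.score == pytest.approx(orig.score)
            assert rp.fold_enrichment == pytest.approx(orig.fold_enrichment)

    def test_validated_qpcr_site_round_trips(self, tmp_path):
        # strongest bench-validated site: chr19 region, score 3100, FE 42.11
        p = peak("chr19", 51353679, 51354605, score=3100, fe=42.11, pid="chr19site")
        path = tmp_path / "t.bed"
        write_peaks(CistromeSet("t", [p]), path)
        (rp,) = read_peaks(path).peaks
        assert rp.score == 3100 and rp.fold_enrichment == pytest.approx(42.11)

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(read_peaks(path)) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tp\t5\t.\n" "chr1\tnotanumber\t300\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(path)

    def test_macs_dialect_converts_to_zero_based(self, tmp_path):
        path = tmp_path / "m.xls"
        path.write_text("# comment\nchr1\t101\t200\t100\t50\t120\t500\t20\n")
        (p,) = read_peaks(path, dialect="macs-xls-like").peaks
        assert (p.interval.start, p.interval.end) == (100, 200)
        assert p.summit == 150


class TestOverlap:
    def test_one_shared_bp_counts(self):
        a = CistromeSet("a", [peak("chr1", 100, 200, pid="a1")])
        b = CistromeSet("b", [peak("chr1", 199, 300, pid="b1")])
        res = overlap_sets(a, b)
        assert res.shared_a == 1 and res.shared_b == 1

    def test_half_open_adjacency_is_not_overlap(self):
        a = CistromeSet("a", [peak("chr1", 100, 200, pid="a1")])
        b = CistromeSet("b", [peak("chr1", 200, 300, pid="b1")])
        res = overlap_sets(a, b)
        assert res.shared_a == 0 and res.unique_a == 1

    def test_different_chromosomes_never_overlap(self):
        a = CistromeSet("a", [peak("chr1", 100, 200, pid="a1")])
        b = CistromeSet("b", [peak("chr2", 100, 200, pid="b1")])
        assert overlap_sets(a, b).shared_a == 0

    def test_symmetric_on_identical_sets(self):
        peaks = [peak("chr1", i * 1000, i * 1000 + 500, pid=f"p{i}") for i in range(5)]
        a = CistromeSet("a", peaks)
        res = overlap_sets(a, a)
        assert res.shared_a == res.shared_b == 5
        assert res.unique_a == res.unique_b == 0

    def test_counts_sum_to_set_sizes(self):
        rng = np.random.default_rng(0)
        mk = lambda n, tag: CistromeSet(
            tag,
            [
                peak("chr1", s, s + 300, pid=f"{tag}{i}")
                for i, s in enumerate(sorted(rng.choice(50_000, n, replace=False) * 7))
            ],
        )
        a, b = mk(40, "a"), mk(40, "b")
        res = overlap_sets(a, b)
        assert res.shared_a + res.unique_a == len(a)
        assert res.shared_b + res.unique_b == len(b)


class TestMapToTSS:
    def gene(self, tss, chrom="chr1", strand="+", name="G1"):
        return GeneModel(name, tss, strand, chrom)

    @pytest.mark.parametrize(
        "offset,associated",
        [(24_999, True), (25_000, True), (25_001, False)],
    )
    def test_distance_boundary_is_inclusive(self, offset, associated):
        cis = CistromeSet("c", [peak("chr1", 99_000 + offset, 101_000 + offset,
                                     summit=100_000 + offset, pid="p")])
        got = map_to_tss(cis, [self.gene(100_000)], max_dist=25_000)
        assert ("G1" in got) is associated

    def test_strand_independent_distance(self):
        cis = CistromeSet("c", [peak("chr1", 99_000, 101_000, summit=100_500, pid="p")])
        fwd = map_to_tss(cis, [self.gene(100_000, strand="+")])
        rev = map_to_tss(cis, [self.gene(100_000, strand="-")])
        assert fwd["G1"][0].distance == rev["G1"][0].distance == 500

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(42)
        peaks = [
            peak("chr1", int(s), int(s) + 200, pid=f"p{i}")
            for i, s in enumerate(rng.integers(0, 500_000, 100))
        ]
        genes = [self.gene(int(t), name=f"G{j}") for j, t in
                 enumerate(rng.integers(0, 500_000, 100))]
        cis = CistromeSet("c", peaks)
        got = map_to_tss(cis, genes, max_dist=25_000)
        expected = {}
        for g in genes:
            for p in peaks:
                if abs(p.summit - g.tss) <= 25_000:
                    expected.setdefault(g.gene, set()).add(p.id)
        assert {g: {a.peak.id for a in v} for g, v in got.items()} == expected

    def test_unknown_chromosome_skipped(self):
        cis = CistromeSet("c", [peak("chr1", 0, 100, pid="p")])
        got = map_to_tss(cis, [self.gene(50, chrom="chrUn")], max_dist=100)
        assert got == {}


class TestAnnotation:
    def make_genes(self):
        exon1 = GenomicInterval("chr1", 10_000, 10_500)
        exon2 = GenomicInterval("chr1", 15_000, 15_500)
        return [GeneModel("G1", 10_000, "+", "chr1", (exon1, exon2))]

    def test_counts_sum_and_precedence(self):
        genes = self.make_genes()
        sizes = {"chr1": 100_000}
        cis = CistromeSet("c", [
            peak("chr1", 9_400, 9_800, summit=9_600, pid="prom"),     # upstream window
            peak("chr1", 10_000, 10_400, summit=10_050, pid="p_or_e"),  # promoter wins over exon
            peak("chr1", 10_100, 10_600, summit=10_300, pid="exon"),
            peak("chr1", 12_000, 12_400, summit=12_200, pid="intron"),
            peak("chr1", 50_000, 50_400, summit=50_200, pid="desert"),
        ])
        res = classify_annotation(cis, genes, sizes)
        assert sum(res.counts.values()) == len(cis)
        assert res.counts == {"promoter": 2, "exonic": 1, "intronic": 1, "intergenic": 1}

    def test_enrichment_is_fraction_ratio(self):
        genes = self.make_genes()
        sizes = {"chr1": 100_000}
        cis = CistromeSet("c", [peak("chr1", 9_400, 9_800, summit=9_600, pid="p")])
        res = classify_annotation(cis, genes, sizes)
        bg = res.background_fractions["promoter"]
        assert res.enrichment["promoter"] == pytest.approx(1.0 / bg)

    def test_all_peaks_in_gene_desert(self):
        cis = CistromeSet("c", [peak("chr1", 80_000 + i * 1000, 80_400 + i * 1000,
                                     pid=f"p{i}") for i in range(4)])
        res = classify_annotation(cis, self.make_genes(), {"chr1": 100_000})
        assert res.counts["intergenic"] == 4


def test_refflat_reader_sets_tss_by_strand(tmp_path):
    path = tmp_path / "genes.refflat"
    path.write_text(
        "GPLUS\tGPLUS_tx\tchr1\t+\t1000\t5000\t1000\t5000\t2\t1000,3000,\t1500,5000,\n"
        "GMINUS\tGMINUS_tx\tchr1\t-\t1000\t5000\t1000\t5000\t1\t1000,\t5000,\n"
    )
    plus, minus = read_refflat(path)
    assert plus.tss == 1000 and minus.tss == 4999
    assert len(plus.exons) == 2
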