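import numpy as np
import pytest

from introkit import genio
from introkit.errors import ArgumentError, ContractError, FormatError
from introkit.genio import (
    GenomicWindow,
    HaplotypePanel,
    PopulationMap,
    SVRecord,
    make_windows,
    read_bed,
    read_phased_vcf,
    read_popmap,
    read_sv_vcf,
    write_bed,
    write_phased_vcf,
    write_popmap,
    write_sv_vcf,
)

from .conftest import make_panel


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


class TestHaplotypePanel:
    def test_row_count_must_match_samples(self):
        with pytest.raises(ContractError):
            HaplotypePanel(
                chrom="chr1",
                positions=np.array([1]),
                alleles=np.zeros((3, 1), dtype=np.int8),
                sample_ids=["a"],
            )

    def test_positions_strictly_increasing(self):
        with pytest.raises(ContractError):
            make_panel(np.zeros((2, 3)), positions=[5, 5, 6])

    def test_region_is_one_based_inclusive(self, toy_panel):
        sub = toy_panel.region(11, 20)
        assert list(sub.positions) == [15, 20]
        assert sub.alleles.shape == (6, 2)

    def test_genotype_dosages_with_missing(self):
        panel = make_panel([[0, 1], [1, -1], [1, 1], [1, 0]])
        dos = panel.genotype_dosages()
        assert dos[0, 0] == 1
        assert dos[0, 1] == genio.MISSING  # one allele missing
        assert dos[1, 0] == 2

    def test_subset_preserves_order(self, toy_panel):
        sub = toy_panel.subset_samples(["s3", "s1"])
        assert sub.sample_ids == ["s3", "s1"]
        np.testing.assert_array_equal(sub.alleles[0], toy_panel.alleles[4])


class TestSVRecord:
    def test_maf_and_missingness_hand_count(self):
        # genotypes 0/0, 0/1, 1/1, ./. -> 3 alt alleles over 6 called, 25% missing
        sv = SVRecord(
            sv_id="sv1",
            svtype="DEL",
            chrom="chr1",
            pos=100,
            end=200,
            genotypes=np.array([0, 1, 2, genio.MISSING], dtype=np.int8),
            sample_ids=["a", "b", "c", "d"],
        )
        assert sv.maf == pytest.approx(0.5)
        assert sv.missingness == pytest.approx(0.25)

    def test_end_before_pos_rejected(self):
        with pytest.raises(ContractError):
            SVRecord("x", "DEL", "chr1", 100, 50, np.array([0]), ["a"])

    def test_unknown_type_rejected(self):
        with pytest.raises(ContractError):
            SVRecord("x", "TRA", "chr1", 1, 2, np.array([0]), ["a"])


# ---------------------------------------------------------------------------
# VCF round-trips
# ---------------------------------------------------------------------------


class TestPhasedVcf:
    def test_toy_round_trip(self, toy_panel, tmp_path):
        path = str(tmp_path / "toy.vcf")
        write_phased_vcf(toy_panel, path, contig_length=1000)
        back = read_phased_vcf(path)
        np.testing.assert_array_equal(back.positions, toy_panel.positions)
        np.testing.assert_array_equal(back.alleles, toy_panel.alleles)
        assert back.sample_ids == toy_panel.sample_ids
        assert back.alleles.shape == (6, 4)

    def test_double_round_trip_idempotent(self, toy_panel, tmp_path):
        p1, p2 = str(tmp_path / "a.vcf"), str(tmp_path / "b.vcf")
        write_phased_vcf(toy_panel, p1, contig_length=1000)
        write_phased_vcf(read_phased_vcf(p1), p2, contig_length=1000)
        assert open(p1).read() == open(p2).read()

    def test_region_query(self, toy_panel, tmp_path):
        path = str(tmp_path / "toy.vcf")
        write_phased_vcf(toy_panel, path, contig_length=1000)
        back = read_phased_vcf(path, region="chr1:11-20")
        assert list(back.positions) == [15, 20]

    def test_multiallelic_skipped_with_count(self, tmp_path):
        path = str(tmp_path / "multi.vcf")
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
        ]
        for i, pos in enumerate([10, 20, 30, 40, 50]):
            alt = "C,G" if pos == 30 else "C"
            lines.append(f"chr1\t{pos}\tv{i}\tA\t{alt}\t.\tPASS\t.\tGT\t0|1")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        panel = read_phased_vcf(path)
        assert panel.n_sites == 4
        assert panel.n_skipped == 1

    def test_unphased_het_rejected(self, tmp_path):
        path = str(tmp_path / "unphased.vcf")
        with open(path, "w") as fh:
            fh.write(
                "##fileformat=VCFv4.2\n"
                "##contig=<ID=chr1,length=100>\n"
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
                "chr1\t10\tv\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
            )
        with pytest.raises(FormatError):
            read_phased_vcf(path)

    def test_missing_file(self):
        with pytest.raises(IOError):
            read_phased_vcf("/no/such/file.vcf")


class TestSvVcf:
    def _write(self, tmp_path, svs):
        path = str(tmp_path / "svs.vcf")
        write_sv_vcf(svs, path, contig_length=10_000_000)
        return path

    def _sv(self, sv_id, svtype, pos, end, genos):
        return SVRecord(
            sv_id=sv_id,
            svtype=svtype,
            chrom="chr1",
            pos=pos,
            end=end,
            genotypes=np.array(genos, dtype=np.int8),
            sample_ids=["a", "b", "c"],
        )

    def test_round_trip(self, tmp_path):
        svs = [
            self._sv("d1", "DEL", 100, 600, [0, 1, 2]),
            self._sv("i1", "INS", 700, 700, [1, 1, genio.MISSING]),
        ]
        back = read_sv_vcf(self._write(tmp_path, svs))
        assert [s.sv_id for s in back] == ["d1", "i1"]
        assert back[0].end == 600
        np.testing.assert_array_equal(back[1].genotypes, svs[1].genotypes)

    def test_oversized_sv_dropped(self, tmp_path):
        svs = [
            self._sv("big", "DEL", 100, 6_000_200, [0, 1, 2]),
            self._sv("ok", "DEL", 100, 200, [0, 1, 2]),
        ]
        back = read_sv_vcf(self._write(tmp_path, svs))
        assert [s.sv_id for s in back] == ["ok"]

    def test_translocation_dropped(self, tmp_path):
        path = str(tmp_path / "bnd.vcf")
        with open(path, "w") as fh:
            fh.write(
                "##fileformat=VCFv4.2\n"
                "##contig=<ID=chr1,length=1000>\n"
                '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
                '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
                "chr1\t10\tb\tN\t<BND>\t.\tPASS\tSVTYPE=BND;END=20\tGT\t0/1\n"
                "chr1\t30\td\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=90\tGT\t0/1\n"
            )
        back = read_sv_vcf(path)
        assert [s.sv_id for s in back] == ["d"]

    def test_missing_svtype_is_format_error(self, tmp_path):
        path = str(tmp_path / "bad.vcf")
        with open(path, "w") as fh:
            fh.write(
                "##fileformat=VCFv4.2\n"
                "##contig=<ID=chr1,length=1000>\n"
                '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
                "chr1\t10\tx\tN\t<DEL>\t.\tPASS\tEND=20\tGT\t0/1\n"
            )
        with pytest.raises(FormatError):
            read_sv_vcf(path)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


class TestMakeWindows:
    def test_canonical_grid(self):
        wins = make_windows(100_000, 50_000, 25_000)
        spans = [(w.start, w.end) for w in wins]
        assert spans == [(0, 50_000), (25_000, 75_000), (50_000, 100_000), (75_000, 100_000)]

    def test_short_chromosome(self):
        wins = make_windows(40_000, 50_000, 25_000)
        assert [(w.start, w.end) for w in wins] == [(0, 40_000), (25_000, 40_000)]

    def test_length_equals_window(self):
        wins = make_windows(50_000, 50_000, 25_000)
        assert [(w.start, w.end) for w in wins] == [(0, 50_000), (25_000, 50_000)]
        assert not wins[0].truncated and wins[1].truncated

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ArgumentError):
            make_windows(1000, 100, 200)

    def test_union_covers_chromosome(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            window = int(rng.integers(10, 1000))
            step = int(rng.integers(1, window + 1))
            length = int(rng.integers(window, 10_000))
            wins = make_windows(length, window, step)
            covered = np.zeros(length, dtype=bool)
            for w in wins:
                covered[w.start : w.end] = True
            assert covered.all()
            assert all(w.end - w.start <= window for w in wins)


# ---------------------------------------------------------------------------
# BED and pop-map
# ---------------------------------------------------------------------------


class TestBed:
    def test_simple_line(self, tmp_path):
        path = str(tmp_path / "x.bed")
        write_bed([("chr1", 25_000, 75_000)], path)
        assert open(path).read() == "chr1\t25000\t75000\n"

    def test_unsorted_input_sorted(self, tmp_path):
        path = str(tmp_path / "x.bed")
        write_bed([("chr1", 500, 700), ("chr1", 100, 300)], path)
        rows = read_bed(path)
        assert rows == [("chr1", 100, 300), ("chr1", 500, 700)]

    def test_overlaps_written_verbatim(self, tmp_path):
        path = str(tmp_path / "x.bed")
        write_bed([("chr1", 0, 100), ("chr1", 50, 150)], path)
        assert len(read_bed(path)) == 2

    def test_empty(self, tmp_path):
        path = str(tmp_path / "x.bed")
        write_bed([], path)
        assert open(path).read() == ""
        assert read_bed(path) == []


class TestPopmap:
    def test_round_trip(self, tmp_path):
        path = str(tmp_path / "pops.tsv")
        pm = PopulationMap(assignments={"s1": "A", "s2": "B"})
        write_popmap(pm, path)
        back = read_popmap(path)
        assert back.assignments == pm.assignments

    def test_samples_of(self, toy_popmap):
        assert toy_popmap.samples_of("POP1") == ["s1", "s2"]

    def test_missing_sample_raises(self, toy_popmap):
        from introkit.errors import MappingError

        with pytest.raises(MappingError):
            toy_popmap.population_of("nope")

    def test_malformed_line(self, tmp_path):
        path = str(tmp_path / "bad.tsv")
        with open(path, "w") as fh:
            fh.write("just_one_column\n")
        with pytest.raises(FormatError):
            read_popmap(path)


class TestGenomicWindow:
    def test_empty_window_rejected(self):
        with pytest.raises(ContractError):
            GenomicWindow("chr1", 10, 10)

    def test_overlap_half_open(self):
        w = GenomicWindow("chr1", 100, 200)
        assert w.overlaps(150, 250)
        assert not w.overlaps(200, 300)  # book-ended, no overlap
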