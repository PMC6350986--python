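"""Count-table I/O, site filters and dataset summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolseq_assoc import (
    CountsFormatError,
    CountsTable,
    GeneModel,
    coverage_summary,
    filter_sites,
    flag_monomorphic,
    read_category_map,
    read_gene_models,
    read_manifest,
    sites_per_aligned_nt_ratio,
    write_category_map,
    write_gff3,
    write_manifest,
)
from poolseq_assoc.counts_io import _parse_library_id

from .conftest import make_counts, make_libraries


class TestRoundTrip:
    def test_writer_reader_identity(self, three_site_table, tmp_path):
        path = tmp_path / "counts.tsv"
        three_site_table.write(path)
        back = CountsTable.read(path)
        assert np.array_equal(back.counts, three_site_table.counts)
        pd.testing.assert_frame_equal(back.sites, three_site_table.sites)
        assert [l.library_id for l in back.libraries] == [
            l.library_id for l in three_site_table.libraries
        ]

    def test_empty_body_valid_header(self, three_site_table, tmp_path):
        path = tmp_path / "counts.tsv"
        three_site_table.subset(np.zeros(3, dtype=bool)).write(path)
        back = CountsTable.read(path)
        assert back.n_sites == 0
        assert len(back.libraries) == 4

    def test_roster_inferred_from_columns(self, three_site_table, tmp_path):
        path = tmp_path / "counts.tsv"
        three_site_table.write(path)
        back = CountsTable.read(path)
        assert {l.phenotype for l in back.libraries} == {"resistant", "susceptible"}
        assert all(l.collection_id == "X" for l in back.libraries)

    def test_manifest_cross_check(self, three_site_table, tmp_path):
        cpath, mpath = tmp_path / "c.tsv", tmp_path / "m.tsv"
        three_site_table.write(cpath)
        write_manifest(three_site_table.libraries, mpath)
        manifest = read_manifest(mpath)
        back = CountsTable.read(cpath, manifest=manifest)
        assert [l.library_id for l in back.libraries] == [
            l.library_id for l in manifest
        ]
        with pytest.raises(CountsFormatError, match="absent from manifest"):
            CountsTable.read(cpath, manifest=manifest[:2])


class TestMalformedInput:
    def _write_rows(self, tmp_path, mutate):
        path = tmp_path / "c.tsv"
        table = make_counts(
            [("1", 10, "A"), ("1", 20, "A")],
            np.full((2, 4, 4), 5),
        )
        table.write(path)
        lines = path.read_text().splitlines()
        mutate(lines)
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_depth_mismatch_names_site_and_line(self, tmp_path):
        def mutate(lines):
            fields = lines[2].split("\t")
            fields[7] = "99"  # X.R1:depth of the second site
            lines[2] = "\t".join(fields)

        path = self._write_rows(tmp_path, mutate)
        with pytest.raises(CountsFormatError, match=r"line 3.*1:20"):
            CountsTable.read(path)

    def test_duplicate_site_rejected(self, tmp_path):
        def mutate(lines):
            lines[2] = lines[1]

        path = self._write_rows(tmp_path, mutate)
        with pytest.raises(CountsFormatError, match="duplicate site"):
            CountsTable.read(path)

    def test_unknown_nucleotide_column(self, tmp_path):
        def mutate(lines):
            lines[0] = lines[0].replace("X.R1:T", "X.R1:N")

        path = self._write_rows(tmp_path, mutate)
        with pytest.raises(CountsFormatError, match="unknown nucleotide"):
            CountsTable.read(path)

    def test_bad_position_and_ref(self, tmp_path):
        def mutate(lines):
            fields = lines[1].split("\t")
            fields[1] = "0"
            lines[1] = "\t".join(fields)

        path = self._write_rows(tmp_path, mutate)
        with pytest.raises(CountsFormatError, match="line 2.*position"):
            CountsTable.read(path)

    def test_unparseable_library_id(self):
        with pytest.raises(CountsFormatError, match="manifest"):
            _parse_library_id("nonsense")


class TestCoverageFilter:
    def test_one_library_below_threshold_removes_site(self):
        counts = np.full((1, 4, 4), 5)  # depth 20 per library
        counts[0, 2] = (4, 4, 3, 3)  # one library at depth 14
        table = make_counts([("1", 5, "A")], counts)
        kept, report = filter_sites(table, 15)
        assert kept.n_sites == 0
        assert report.n_low_coverage == 1

    def test_threshold_is_inclusive(self):
        counts = np.zeros((1, 4, 4), dtype=int)
        counts[:, :, 0] = 15  # every library at exactly 15
        table = make_counts([("1", 5, "A")], counts)
        kept, report = filter_sites(table, 15)
        assert kept.n_sites == 1
        assert report.n_low_coverage == 0

    def test_kept_sites_have_total_depth_at_least_four_times_threshold(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, size=(50, 4, 4))
        table = make_counts(
            [("1", int(p), "A") for p in range(1, 51)], counts
        )
        kept, _ = filter_sites(table, 15)
        if kept.n_sites:
            assert (kept.total_depth() >= 60).all()

    def test_filter_and_monomorphic_commute(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 8, size=(200, 4, 4))
        counts[rng.random(200) < 0.3, :, 1:] = 0  # make some monomorphic
        table = make_counts(
            [("1", int(p), "A") for p in range(1, 201)], counts
        )
        a, _ = flag_monomorphic(filter_sites(table, 6)[0])
        b, _ = filter_sites(flag_monomorphic(table)[0], 6)
        pd.testing.assert_frame_equal(a.sites, b.sites)


class TestMonomorphic:
    def test_counted_by_construction(self):
        counts = np.zeros((10, 4, 4), dtype=int)
        counts[:, :, 0] = 10  # all reference reads
        counts[4:, :, 2] = 1  # six sites gain a second allele
        table = make_counts(
            [("1", int(p), "A") for p in range(1, 11)], counts
        )
        poly, report = flag_monomorphic(table)
        assert report.n_monomorphic == 4
        assert poly.n_sites == 6

    def test_minimal_polymorphism_retained(self):
        counts = np.zeros((1, 4, 4), dtype=int)
        counts[0, :, 0] = (25, 25, 25, 24)  # ref 99
        counts[0, 0, 2] = 1  # single alternate read in one library
        table = make_counts([("1", 5, "A")], counts)
        poly, report = flag_monomorphic(table)
        assert poly.n_sites == 1
        assert report.n_monomorphic == 0

    def test_zero_total_count_is_no_data_not_monomorphic(self):
        counts = np.zeros((1, 4, 4), dtype=int)
        table = make_counts([("1", 5, "A")], counts)
        poly, report = flag_monomorphic(table)
        assert poly.n_sites == 0
        assert report.n_no_data == 1
        assert report.n_monomorphic == 0


class TestCoverageSummary:
    @pytest.mark.parametrize(
        "per_lib_depths, expected",
        [
            ([(15, 15, 15, 15)], dict(min=60, max=60, mean=60, median=60)),
            (
                [(15, 15, 15, 15), (25, 25, 25, 25), (35, 35, 35, 35)],
                dict(min=60, max=140, mean=100, median=100),
            ),
            (
                [(15, 15, 15, 15), (20, 20, 20, 20), (25, 25, 25, 25),
                 (250, 250, 250, 250)],
                dict(min=60, max=1000, mean=310, median=90),
            ),
        ],
    )
    def test_summary_arithmetic(self, per_lib_depths, expected):
        n = len(per_lib_depths)
        counts = np.zeros((n, 4, 4), dtype=int)
        for i, depths in enumerate(per_lib_depths):
            counts[i, :, 0] = depths
        table = make_counts(
            [("1", i + 1, "A") for i in range(n)], counts
        )
        summary = coverage_summary(table)
        for key, value in expected.items():
            assert getattr(summary, key) == pytest.approx(value)

    def test_empty_input_is_an_error(self, three_site_table):
        with pytest.raises(ValueError):
            coverage_summary(three_site_table.subset(np.zeros(3, dtype=bool)))


class TestAlignedNtRatio:
    def test_direct_arithmetic(self):
        assert sites_per_aligned_nt_ratio(5_000, 10_000, 100) == pytest.approx(5.0)

    def test_zero_numerator(self):
        assert sites_per_aligned_nt_ratio(0, 10_000, 100) == 0.0

    def test_homogeneity(self):
        one = sites_per_aligned_nt_ratio(777, 12_345, 100)
        assert sites_per_aligned_nt_ratio(777, 2 * 12_345, 100) == pytest.approx(one / 2)

    def test_zero_aligned_nucleotides(self):
        with pytest.raises(ValueError):
            sites_per_aligned_nt_ratio(5, 0, 100)


class TestGeneModels:
    def test_gff3_round_trip(self, tmp_path):
        genes = [
            GeneModel("G1", "1", 100, 900, "TRP", "sodium channel"),
            GeneModel("G2", "2", 50, 400),
        ]
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gene_models(path, {"G1": "TRP"})
        assert [(g.gene_id, g.chromosome, g.start, g.end) for g in back] == [
            ("G1", "1", 100, 900), ("G2", "2", 50, 400)
        ]
        assert back[0].category_code == "TRP"
        assert back[1].category_code == "UNK"

    def test_bed_converted_to_one_based_inclusive(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t99\t900\tG1\t0\t+\n")
        (gene,) = read_gene_models(path)
        assert (gene.start, gene.end) == (100, 900)

    def test_invalid_interval_and_category(self):
        with pytest.raises(ValueError):
            GeneModel("G1", "1", 10, 5)
        with pytest.raises(ValueError):
            GeneModel("G1", "1", 1, 5, category_code="NOPE")

    def test_category_map_round_trip(self, tmp_path):
        cats = {"G1": "TRP", "G2": "MIT"}
        path = tmp_path / "cats.tsv"
        write_category_map(cats, path)
        assert read_category_map(path) == cats
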