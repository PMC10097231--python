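"""Parsing, binning, binary recoding and the bundled table fixtures."""

import warnings

import numpy as np
import pytest

from plumprint.genotype_io import (
    bin_fragment_sizes,
    load_fixture,
    read_genotype_table,
    to_binary_matrix,
    write_genotype_table,
    write_structure_format,
)
from plumprint.structure import read_structure_file

from conftest import make_profile, random_profiles


class TestGenotypeTable:
    def _write(self, tmp_path, lines):
        path = tmp_path / "g.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_parses_slash_separated_allele_sets(self, tmp_path):
        path = self._write(
            tmp_path,
            ["accession\tgroup\tBPPCT040", "Gyne\tLT-origin\t124/128/134"],
        )
        (prof,) = read_genotype_table(path)
        assert prof.accession_id == "Gyne"
        assert prof.calls["BPPCT040"] == frozenset({124, 128, 134})

    def test_deduplicates_repeated_sizes(self, tmp_path):
        path = self._write(
            tmp_path, ["accession\tgroup\tL1", "X\tG\t185/185/202"]
        )
        (prof,) = read_genotype_table(path)
        assert prof.calls["L1"] == frozenset({185, 202})

    def test_more_than_six_alleles_names_the_locus(self, tmp_path):
        path = self._write(
            tmp_path,
            ["accession\tgroup\tL9", "X\tG\t100/102/104/106/108/110/112"],
        )
        with pytest.raises(ValueError, match="L9"):
            read_genotype_table(path)

    def test_non_numeric_size_is_an_error(self, tmp_path):
        path = self._write(tmp_path, ["accession\tgroup\tL1", "X\tG\t12a"])
        with pytest.raises(ValueError, match="non-numeric"):
            read_genotype_table(path)

    def test_empty_cell_is_missing_locus(self, tmp_path):
        path = self._write(
            tmp_path, ["accession\tgroup\tL1\tL2", "X\tG\t100\t"]
        )
        (prof,) = read_genotype_table(path)
        assert "L2" not in prof.calls

    def test_round_trip_is_lossless(self, tmp_path, toy_profiles):
        path = tmp_path / "rt.tsv"
        write_genotype_table(toy_profiles, path)
        back = read_genotype_table(path)
        assert [(p.accession_id, p.group, p.calls) for p in back] == [
            (p.accession_id, p.group, p.calls) for p in toy_profiles
        ]

    def test_unknown_group_label_warns_but_keeps(self, tmp_path):
        path = self._write(tmp_path, ["accession\tgroup\tL1", "X\tOdd\t100"])
        with pytest.warns(UserWarning, match="unknown group"):
            (prof,) = read_genotype_table(path, known_groups=["G1"])
        assert prof.group == "Odd"


class TestFragmentBinning:
    def test_single_linkage_three_points(self):
        mapping = bin_fragment_sizes([149.8, 150.1, 153.9], min_step=2)
        assert mapping == {149.8: 150, 150.1: 150, 153.9: 154}

    def test_chained_linkage_merges_to_median(self):
        mapping = bin_fragment_sizes([100.4, 101.3, 102.2], min_step=2)
        assert set(mapping.values()) == {101}

    def test_integers_already_spaced_is_identity(self):
        sizes = [100.0, 104.0, 110.0]
        assert bin_fragment_sizes(sizes, min_step=2) == {s: int(s) for s in sizes}

    def test_idempotent_on_binned_integers(self):
        first = bin_fragment_sizes([120.3, 120.9, 126.1, 130.0], min_step=2)
        binned = sorted(set(first.values()))
        again = bin_fragment_sizes([float(b) for b in binned], min_step=2)
        assert again == {float(b): b for b in binned}

    def test_monotone_mapping(self):
        rng = np.random.default_rng(7)
        raws = sorted(rng.uniform(100, 160, size=40))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mapping = bin_fragment_sizes(raws, min_step=2)
        bins = [mapping[r] for r in raws]
        assert bins == sorted(bins)

    def test_empty_input(self):
        assert bin_fragment_sizes([]) == {}

    def test_over_merged_bin_warns(self):
        with pytest.warns(UserWarning, match="over-merged"):
            bin_fragment_sizes([100, 101.5, 103, 104.5, 106, 107.5], min_step=2)


class TestBinaryMatrix:
    def test_direct_recoding(self):
        profs = [
            make_profile("X", "G", {"A": {100}}),
            make_profile("Y", "G", {"A": {100, 104}}),
        ]
        m = to_binary_matrix(profs)
        assert m.columns == (("A", 100), ("A", 104))
        assert m.values.tolist() == [[1, 0], [1, 1]]

    def test_missing_locus_marked_and_excluded(self):
        profs = [
            make_profile("X", "G", {"A": {100}, "B": {200}}),
            make_profile("Y", "G", {"A": {100, 104}}),
        ]
        m = to_binary_matrix(profs)
        j = m.columns.index(("B", 200))
        assert m.values[1, j] == -1

    def test_column_count_equals_distinct_pairs(self, toy_profiles):
        m = to_binary_matrix(toy_profiles)
        distinct = {
            (l, s) for p in toy_profiles for l, sizes in p.calls.items() for s in sizes
        }
        assert len(m.columns) == len(distinct)

    def test_panel_order_respected(self, toy_profiles):
        from plumprint.model import LocusDef, MarkerPanel

        panel = MarkerPanel(
            tuple(
                LocusDef(n, "ACGT", "ACGT", "HEX", 58)
                for n in ("L3", "L1", "L2")
            )
        )
        m = to_binary_matrix(toy_profiles, panel)
        locus_order = [l for l, _ in m.columns]
        assert locus_order == sorted(locus_order, key=["L3", "L1", "L2"].index)

    def test_frequencies_match_profile_route(self):
        from plumprint.diversity import allele_frequencies

        rng = np.random.default_rng(5)
        profs = random_profiles(rng, n_acc=15, missing_rate=0.1)
        freqs = allele_frequencies(profs, "G1")
        m = to_binary_matrix(profs)
        for j, (locus, size) in enumerate(m.columns):
            col = m.values[:, j]
            scored = col[col >= 0]
            assert freqs[(locus, size)] == pytest.approx(
                100.0 * (scored == 1).sum() / len(scored)
            )


class TestStructureFormat:
    def test_six_slot_padding(self, tmp_path):
        profs = [make_profile("X", "G", {"L1": {128, 124}})]
        path = tmp_path / "x.str"
        write_structure_format(profs, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert [r[1] for r in rows] == ["124", "128", "-9", "-9", "-9", "-9"]

    def test_full_locus_has_no_missing(self, tmp_path):
        profs = [make_profile("X", "G", {"L1": {100, 102, 104, 106, 108, 110}})]
        path = tmp_path / "x.str"
        write_structure_format(profs, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert "-9" not in [r[1] for r in rows]

    def test_missing_locus_is_all_missing(self, tmp_path):
        profs = [
            make_profile("X", "G", {"L1": {100}, "L2": {200}}),
            make_profile("Y", "G", {"L1": {100}}),
        ]
        path = tmp_path / "x.str"
        write_structure_format(profs, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert [r[2] for r in rows[6:]] == ["-9"] * 6

    def test_round_trip_through_loader(self, tmp_path):
        rng = np.random.default_rng(9)
        profs = random_profiles(rng, n_acc=8, missing_rate=0.15)
        path = tmp_path / "rt.str"
        write_structure_format(profs, path)
        data = read_structure_file(path)
        back = data.profiles_back()
        for p in profs:
            assert back[p.accession_id] == dict(p.calls)


class TestFixtures:
    def test_table2_common_column_anchor(self):
        fixture = load_fixture("table2")
        bp40 = [
            r for r in fixture.records
            if r["locus"] == "BPPCT040" and r["category"] == "common"
        ]
        assert len(bp40) == 8
        assert bp40[0]["allele_size"] == 116 and bp40[0]["freq_pct"] == 20

    def test_table2_partition_sums_per_locus(self):
        fixture = load_fixture("table2")
        loci = {r["locus"] for r in fixture.records}
        for locus in loci:
            recs = [r for r in fixture.records if r["locus"] == locus]
            by_cat = {
                c: sum(1 for r in recs if r["category"] == c)
                for c in ("common", "unique_lt", "unique_ref")
            }
            assert sum(by_cat.values()) == len(recs)
        assert len(fixture.records) == 157

    def test_table2_preserves_printed_quirks(self):
        """The printed catalogue lists BPPCT007 134 in two columns and bolds
        UDP98-407 179 (25%) despite the 10% rare rule; both kept verbatim."""
        fixture = load_fixture("table2")
        cats_134 = {
            r["category"]
            for r in fixture.records
            if r["locus"] == "BPPCT007" and r["allele_size"] == 134
        }
        assert cats_134 == {"common", "unique_lt"}
        (rec_179,) = [
            r
            for r in fixture.records
            if r["locus"] == "UDP98-407" and r["allele_size"] == 179
        ]
        assert rec_179["printed_rare"] and rec_179["freq_pct"] == 25

    def test_table4_panel(self):
        panel = load_fixture("table4")
        assert len(panel) == 9
        cpsct = next(l for l in panel.loci if l.name == "CPSCT026")
        assert cpsct.annealing_temp_c == 46
        assert set(panel.locus_names) == {
            "BPPCT040", "BPPCT034", "BPPCT039", "BPPCT014", "UDP98-407",
            "PacA33", "BPPCT007", "CPSCT026", "UDP96-005",
        }

    def test_table3_hybrid_allele_total(self):
        rows = load_fixture("table3")
        assert sum(r.allele_number for r in rows if r.group == "hybrid") == 191
        assert sum(r.allele_number for r in rows if r.group == "parent") == 109

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            load_fixture("table9")
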