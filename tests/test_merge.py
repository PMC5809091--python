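"""Horizontal (location/key) and vertical (append) merging."""

import random
import shutil
import subprocess

import pytest

from genotab.core import MISSING, make_table
from genotab.errors import SchemaError, SpecificationError
from genotab.location import LocationSchema, overlaps, extract_intervals
from genotab.merge import JoinSpec, append, merge_by_keys, merge_by_location

from conftest import random_intervals, tables_equal

BED = LocationSchema("three_column", ("chrom", "start", "end"),
                     "zero_half_open")
GFF = LocationSchema("three_column", ("chrom", "start", "end"), "one_closed")


def bed_table(rows, label="bed"):
    return make_table(["chrom", "start", "end"], rows, label, BED)


class TestMergeByLocation:
    def test_cross_convention_overlap(self):
        left = bed_table([["chr1", 100, 200]])
        right = make_table(["chrom", "start", "end"],
                           [["chr1", 151, 250]], "gff", GFF)
        out = merge_by_location(left, right, JoinSpec())
        assert out.n_rows == 1
        assert out.column_names == ["chrom", "start", "end", "chrom_2",
                                    "start_2", "end_2"]
        assert out.provenance == ["bed+gff"]

    def test_exact_interval_inner_vs_left_outer(self):
        left = bed_table([["chr1", 100, 200]])
        right = make_table(["chrom", "start", "end"],
                           [["chr1", 151, 250]], "gff", GFF)
        inner = merge_by_location(
            left, right, JoinSpec(predicate="exact_interval"))
        assert inner.n_rows == 0
        outer = merge_by_location(
            left, right,
            JoinSpec(mode="left_outer", predicate="exact_interval"))
        assert outer.n_rows == 1
        assert outer.cell(0, "chrom_2") is MISSING
        assert outer.provenance == ["bed"]

    def test_exact_interval_matches_across_conventions(self):
        left = bed_table([["chr1", 100, 200]])
        right = make_table(["chrom", "start", "end"],
                           [["chr1", 101, 200]], "gff", GFF)
        out = merge_by_location(
            left, right, JoinSpec(predicate="exact_interval"))
        assert out.n_rows == 1

    def test_multiplicity(self):
        left = bed_table([["chr1", 0, 100]])
        right = bed_table([["chr1", 10, 20], ["chr1", 30, 40],
                           ["chr1", 50, 60]], "r")
        expand = merge_by_location(left, right, JoinSpec())
        assert expand.n_rows == 3
        first = merge_by_location(
            left, right, JoinSpec(multiplicity="first_match"))
        assert first.n_rows == 1
        assert first.cell(0, "start_2") == "10"  # lowest right index wins

    def test_row_order_is_left_then_right_index(self):
        left = bed_table([["chr1", 0, 50], ["chr1", 0, 100]])
        right = bed_table([["chr1", 60, 70], ["chr1", 10, 20]], "r")
        out = merge_by_location(left, right, JoinSpec())
        pairs = [(out.cell(i, "start"), out.cell(i, "start_2"))
                 for i in range(out.n_rows)]
        assert pairs == [("0", "10"), ("0", "60"), ("0", "10")]

    def test_missing_schema_is_schema_error(self):
        left = make_table(["a"], [["x"]], "f")
        with pytest.raises(SchemaError):
            merge_by_location(left, bed_table([["chr1", 0, 1]]), JoinSpec())

    def test_matches_nested_loop_oracle(self):
        """Indexed join == brute-force all-pairs scan (row-pair set equality)."""
        rng = random.Random(7)
        left = bed_table(
            [[iv.chrom, iv.start, iv.end]
             for iv in random_intervals(rng, 200)], "L")
        right = bed_table(
            [[iv.chrom, iv.start, iv.end]
             for iv in random_intervals(rng, 200)], "R")
        out = merge_by_location(left, right, JoinSpec())
        got = {
            (out.cell(i, "chrom"), out.cell(i, "start"), out.cell(i, "end"),
             out.cell(i, "start_2"), out.cell(i, "end_2"))
            for i in range(out.n_rows)
        }
        liv, riv = extract_intervals(left), extract_intervals(right)
        expected = {
            (a.chrom, str(a.start), str(a.end), str(b.start), str(b.end))
            for a in liv for b in riv if overlaps(a, b)
        }
        assert got == expected

    def test_cardinality_bounds(self):
        rng = random.Random(8)
        left = bed_table(
            [[iv.chrom, iv.start, iv.end]
             for iv in random_intervals(rng, 100)], "L")
        right = bed_table(
            [[iv.chrom, iv.start, iv.end]
             for iv in random_intervals(rng, 100)], "R")
        inner = merge_by_location(left, right, JoinSpec()).n_rows
        outer = merge_by_location(
            left, right, JoinSpec(mode="left_outer")).n_rows
        first = merge_by_location(
            left, right,
            JoinSpec(mode="left_outer", multiplicity="first_match")).n_rows
        assert inner <= outer
        assert first == left.n_rows

    @pytest.mark.skipif(shutil.which("bedtools") is None,
                        reason="bedtools not on PATH")
    def test_matches_bedtools_intersect(self, tmp_path):
        """Second independent oracle: bedtools intersect -wa -wb."""
        rng = random.Random(9)
        liv = random_intervals(rng, 50)
        riv = random_intervals(rng, 50)
        a = tmp_path / "a.bed"
        b = tmp_path / "b.bed"
        a.write_text("".join(f"{v.chrom}\t{v.start}\t{v.end}\n" for v in liv))
        b.write_text("".join(f"{v.chrom}\t{v.start}\t{v.end}\n" for v in riv))
        res = subprocess.run(
            ["bedtools", "intersect", "-wa", "-wb", "-a", str(a), "-b", str(b)],
            capture_output=True, text=True, check=True)
        theirs = sorted(
            tuple(line.split("\t")) for line in res.stdout.splitlines())
        left = bed_table([[v.chrom, v.start, v.end] for v in liv], "L")
        right = bed_table([[v.chrom, v.start, v.end] for v in riv], "R")
        out = merge_by_location(left, right, JoinSpec())
        ours = sorted(
            tuple(str(out.cell(i, c)) for c in out.column_names)
            for i in range(out.n_rows))
        assert ours == theirs


class TestMergeByKeys:
    def make_pair(self):
        left = make_table(["CHROM", "POS", "QUAL"],
                          [["chr1", 100, 50], ["chr1", 200, 60],
                           ["chr2", 5, 70]], "vcf")
        right = make_table(["chrom", "position", "gene"],
                           [["chr1", 100, "BRCA1"], ["chr2", 5, "LZTR1"],
                            ["chr3", 9, "TP53"]], "anno")
        return left, right

    def test_two_key_inner_join(self):
        left, right = self.make_pair()
        spec = JoinSpec(predicate="key_equality",
                        key_columns=[("CHROM", "chrom"), ("POS", "position")])
        out = merge_by_keys(left, right, spec)
        assert out.n_rows == 2
        assert out["gene"].values == ["BRCA1", "LZTR1"]

    def test_five_key_pairs_rejected(self):
        left, right = self.make_pair()
        spec = JoinSpec(predicate="key_equality",
                        key_columns=[("CHROM", "chrom")] * 5)
        with pytest.raises(SpecificationError, match="max 4"):
            merge_by_keys(left, right, spec)

    def test_missing_never_matches_missing(self):
        left = make_table(["k", "v"], [[None, 1]], "L")
        right = make_table(["k", "w"], [[None, 2]], "R")
        spec = JoinSpec(predicate="key_equality", key_columns=[("k", "k")])
        assert merge_by_keys(left, right, spec).n_rows == 0

    def test_keys_compared_as_trimmed_text_not_numbers(self):
        left = make_table(["k"], [["1"], [" 2 "]], "L")
        right = make_table(["k"], [["1.0"], ["2"]], "R")
        spec = JoinSpec(predicate="key_equality", key_columns=[("k", "k")])
        out = merge_by_keys(left, right, spec)
        assert out.n_rows == 1  # " 2 " == "2" after trim; "1" != "1.0"

    def test_absent_key_column_named(self):
        left, right = self.make_pair()
        spec = JoinSpec(predicate="key_equality",
                        key_columns=[("nope", "chrom")])
        with pytest.raises(SchemaError, match="nope"):
            merge_by_keys(left, right, spec)


class TestAppend:
    def test_column_union_with_missing_fill(self):
        t1 = make_table(["a", "b"], [[1, 2], [3, 4]], "f1")
        t2 = make_table(["b", "c"], [[5, 6], [7, 8], [9, 10]], "f2")
        out = append([t1, t2])
        assert out.column_names == ["a", "b", "c"]
        assert out.n_rows == 5
        assert out["a"].values[2:] == [MISSING] * 3
        assert out["b"].values == ["2", "4", "5", "7", "9"]
        assert out.provenance == ["f1", "f1", "f2", "f2", "f2"]

    def test_single_table_returns_identical_copy(self):
        t = make_table(["a"], [[1], [2]], "f")
        assert tables_equal(append([t]), t)

    def test_associativity(self):
        a = make_table(["x"], [[1]], "a")
        b = make_table(["y"], [[2]], "b")
        c = make_table(["x", "y"], [[3, 4]], "c")
        assert tables_equal(append([a, append([b, c])]), append([a, b, c]))

    def test_every_input_column_survives_merge_and_append(self):
        t1 = make_table(["a", "b"], [[1, 2]], "f1")
        t2 = make_table(["b", "c"], [[3, 4]], "f2")
        assert set(append([t1, t2]).column_names) == {"a", "b", "c"}
        left = bed_table([["chr1", 0, 10]])
        right = bed_table([["chr1", 5, 15]], "r")
        merged = merge_by_location(left, right, JoinSpec())
        assert len(merged.column_names) == 6
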