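"""Predicate, list, criteria-track and sample-presence filtering."""

import random

import pytest

from genotab.core import make_table
from genotab.errors import (
    ColumnTypeError,
    DataError,
    SchemaError,
    SpecificationError,
)
from genotab.filters import (
    CriteriaSpec,
    Predicate,
    SampleSpec,
    filter_by_criteria,
    filter_by_list,
    filter_by_sample_presence,
    filter_rows,
)
from genotab.location import LocationSchema

BED = LocationSchema("three_column", ("chrom", "start", "end"),
                     "zero_half_open")


def located(rows, label="data"):
    return make_table(["chrom", "start", "end"], rows, label, BED)


class TestFilterRows:
    def test_conservation_threshold_drops_missing(self):
        t = make_table(["cons"], [[0.9], [0.5], [None]], "f")
        out = filter_rows(t, [Predicate("cons", "gt", 0.85)])
        assert out.n_rows == 1
        assert out["cons"].values == ["0.9"]

    def test_on_missing_keep(self):
        t = make_table(["cons"], [[0.9], [None]], "f")
        out = filter_rows(
            t, [Predicate("cons", "gt", 0.85, on_missing="keep")])
        assert out.n_rows == 2

    def test_empty_predicate_list_is_vacuous_truth(self):
        t = make_table(["a"], [[1], [2]], "f")
        assert filter_rows(t, [], "all").n_rows == 2
        assert filter_rows(t, [], "any").n_rows == 0

    def test_any_keeps_at_least_as_many_as_all(self):
        t = make_table(["a", "b"], [[1, 10], [2, 0], [3, 10], [4, 0]], "f")
        preds = [Predicate("a", "le", 2), Predicate("b", "ge", 5)]
        n_all = filter_rows(t, preds, "all").n_rows
        n_any = filter_rows(t, preds, "any").n_rows
        assert n_all == 1 and n_any == 3
        assert n_any >= n_all

    def test_numeric_predicate_on_text_column_names_column(self):
        t = make_table(["gene"], [["TP53"]], "f")
        with pytest.raises(ColumnTypeError, match="gene"):
            filter_rows(t, [Predicate("gene", "gt", 1)])

    @pytest.mark.parametrize(
        "op,operand,expected",
        [
            ("eq", "TP53", ["TP53"]),
            ("ne", "TP53", ["BRCA1", "EGFR"]),
            ("contains", "BR", ["BRCA1"]),
            ("in_list", ["EGFR", "KRAS"], ["EGFR"]),
        ],
    )
    def test_text_operators(self, op, operand, expected):
        t = make_table(["gene"], [["TP53"], ["BRCA1"], ["EGFR"]], "f")
        out = filter_rows(t, [Predicate("gene", op, operand)])
        assert out["gene"].values == expected

    def test_row_subset_property(self):
        t = make_table(["a"], [[3], [1], [2]], "f")
        out = filter_rows(t, [Predicate("a", "ge", 2)])
        assert out["a"].values == ["3", "2"]  # original order preserved
        assert out.column_names == t.column_names


class TestFilterByList:
    def test_membership(self, writefile):
        t = make_table(["gene"], [["BRCA1"], ["TP53"], ["EGFR"]], "f")
        path = writefile("genes.txt", "# shortlist\nTP53\nLZTR1\n")
        assert filter_by_list(t, "gene", path)["gene"].values == ["TP53"]
        out = filter_by_list(t, "gene", path, negate=True)
        assert out["gene"].values == ["BRCA1", "EGFR"]

    def test_all_comment_list_is_specification_error(self, writefile):
        t = make_table(["gene"], [["TP53"]], "f")
        path = writefile("empty.txt", "# nothing\n\n# here\n")
        with pytest.raises(SpecificationError):
            filter_by_list(t, "gene", path)

    def test_missing_never_matches(self, writefile):
        t = make_table(["gene"], [["TP53"], [None]], "f")
        path = writefile("genes.txt", "TP53\n")
        assert filter_by_list(t, "gene", path).n_rows == 1
        # under negate, the MISSING row is kept (it is not in the list)
        assert filter_by_list(t, "gene", path, negate=True).n_rows == 1


class TestFilterByCriteria:
    def variants(self):
        return located(
            [["chr1", 100, 101], ["chr1", 500, 501], ["chr2", 50, 51]],
            "variants")

    def test_keep_overlapping_accessible_regions(self):
        regions = located([["chr1", 0, 200], ["chr2", 0, 10]], "regions")
        out = filter_by_criteria(
            self.variants(), CriteriaSpec(criteria_table=regions))
        assert out["start"].values == ["100"]

    def test_criteria_predicate_prefilters_track(self):
        track = make_table(
            ["chrom", "start", "end", "score"],
            [["chr1", 0, 200, 0.9], ["chr1", 400, 600, 0.5],
             ["chr2", 0, 100, 0.99]],
            "cons", BED)
        spec = CriteriaSpec(
            criteria_table=track,
            criteria_predicate=Predicate("score", "gt", 0.85))
        out = filter_by_criteria(self.variants(), spec)
        # the chr1:500 variant overlaps only the low-score interval
        assert out["start"].values == ["100", "50"]

    def test_empty_criteria_boundary(self):
        empty = located([], "empty")
        keep = filter_by_criteria(
            self.variants(), CriteriaSpec(criteria_table=empty))
        drop = filter_by_criteria(
            self.variants(),
            CriteriaSpec(criteria_table=empty, polarity="drop_overlapping"))
        assert keep.n_rows == 0
        assert drop.n_rows == 3

    @pytest.mark.parametrize("frac", [0.0, 0.5])
    def test_keep_and_drop_partition_the_input(self, frac):
        rng = random.Random(11)
        rows = []
        for i in range(50):
            start = rng.randrange(1000)
            rows.append([rng.choice(["chr1", "chr2"]), start, start + 10])
        data = located(rows, "d")
        data = make_table(["chrom", "start", "end", "rowid"],
                          [r + [i] for i, r in enumerate(rows)], "d", BED)
        crit = located(
            [["chr1", s, s + 50] for s in range(0, 1000, 120)], "c")
        keep = filter_by_criteria(
            data, CriteriaSpec(criteria_table=crit, min_fraction=frac))
        drop = filter_by_criteria(
            data, CriteriaSpec(criteria_table=crit, min_fraction=frac,
                               polarity="drop_overlapping"))
        kept = set(keep["rowid"].values)
        dropped = set(drop["rowid"].values)
        assert kept | dropped == {str(i) for i in range(50)}
        assert kept & dropped == set()

    def test_min_fraction_monotonicity(self):
        data = located([["chr1", s, s + 100] for s in range(0, 2000, 90)],
                       "d")
        crit = located([["chr1", 50, 120], ["chr1", 800, 1100]], "c")
        counts = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            out = filter_by_criteria(
                data, CriteriaSpec(criteria_table=crit, min_fraction=frac))
            counts.append(out.n_rows)
        assert counts == sorted(counts, reverse=True)

    def test_criteria_without_schema_is_schema_error(self):
        bare = make_table(["x"], [["y"]], "c")
        with pytest.raises(SchemaError):
            filter_by_criteria(
                self.variants(), CriteriaSpec(criteria_table=bare))


class TestSamplePresence:
    def test_hand_counted_example(self):
        t = make_table(
            ["locus", "sample"],
            [["chr1:100", "S1"], ["chr1:100", "S2"], ["chr2:5", "S1"]],
            "f")
        spec = SampleSpec(sample_columns=["sample"], threshold=0.75)
        out = filter_by_sample_presence(t, spec)
        # observed samples = {S1, S2}; chr1:100 presence 1.0, chr2:5 0.5
        assert out["locus"].values == ["chr1:100", "chr1:100"]

    def test_threshold_one_keeps_only_universal_identities(self):
        t = make_table(
            ["locus", "sample"],
            [["A", "S1"], ["A", "S2"], ["A", "S3"], ["B", "S1"]], "f")
        spec = SampleSpec(sample_columns=["sample"], threshold=1.0)
        out = filter_by_sample_presence(t, spec)
        assert set(out["locus"].values) == {"A"}

    def test_single_sample_everything_kept(self):
        t = make_table(["locus", "sample"], [["A", "S1"], ["B", "S1"]], "f")
        spec = SampleSpec(sample_columns=["sample"], threshold=0.5)
        assert filter_by_sample_presence(t, spec).n_rows == 2

    def test_at_most_direction(self):
        t = make_table(
            ["locus", "sample"],
            [["A", "S1"], ["A", "S2"], ["B", "S1"]], "f")
        spec = SampleSpec(sample_columns=["sample"], threshold=0.5,
                          direction="at_most")
        assert set(filter_by_sample_presence(t, spec)["locus"].values) == {"B"}

    def test_external_roster_override(self):
        t = make_table(
            ["locus", "sample"], [["A", "S1"], ["A", "S2"]], "f")
        spec = SampleSpec(sample_columns=["sample"], threshold=0.75,
                          total_samples=4)
        assert filter_by_sample_presence(t, spec).n_rows == 0

    def test_all_missing_samples_is_data_error(self):
        t = make_table(["locus", "sample"], [["A", None]], "f")
        with pytest.raises(DataError):
            filter_by_sample_presence(
                t, SampleSpec(sample_columns=["sample"]))

    def test_overlapping_sample_and_identity_columns_rejected(self):
        with pytest.raises(SpecificationError):
            SampleSpec(sample_columns=["s"], identity_columns=["s", "x"])

    @pytest.mark.parametrize("threshold", [0.25, 0.5, 0.75, 1.0])
    def test_agrees_with_explicit_double_loop(self, threshold):
        """Independent brute-force recomputation on a random fixture."""
        rng = random.Random(13)
        rows = []
        for i in range(400):
            rows.append([f"locus{rng.randrange(60)}",
                         f"S{rng.randrange(1, 9)}",
                         rng.choice(["0/1", "1/1"])])
        t = make_table(["locus", "sample", "gt"], rows, "f")
        spec = SampleSpec(sample_columns=["sample"],
                          identity_columns=["locus"], threshold=threshold)
        out = filter_by_sample_presence(t, spec)

        # oracle: explicit double loop, no grouping library
        observed = []
        for r in rows:
            if r[1] not in observed:
                observed.append(r[1])
        expected_rows = []
        for i, r in enumerate(rows):
            carriers = []
            for r2 in rows:
                if r2[0] == r[0] and r2[1] not in carriers:
                    carriers.append(r2[1])
            if len(carriers) / len(observed) >= threshold:
                expected_rows.append(i)
        assert out.n_rows == len(expected_rows)
        assert out["locus"].values == [rows[i][0] for i in expected_rows]
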