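import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildflux.expression import (
    NOT_ENCODED,
    UNDETECTABLE,
    AlignmentRecord,
    CDSRecord,
    ExpressionTable,
    FunctionMap,
    complex_expression,
    compute_tpm,
    count_reads,
    filter_alignments,
    mag_expression_fraction,
    mag_relative_abundance,
    metagenomic_filter,
    metatranscriptomic_filter,
    pathway_expression,
    reaction_expression,
    relativize_to_median,
)


def aln(read, target, rlen, alen, ident):
    return AlignmentRecord(read, target, rlen, alen, ident)


class TestFilterAlignments:
    def test_metagenomic_dialect_removes_on_equality(self):
        rec = aln("r1", "t1", 100, 90, 0.99)  # frac exactly 0.90
        assert metagenomic_filter([rec]) == []

    def test_metatranscriptomic_dialect_keeps_equality(self):
        rec = aln("r1", "t1", 100, 95, 0.97)  # both exactly at thresholds
        assert metatranscriptomic_filter([rec]) == [rec]

    def test_empty_input(self):
        assert filter_alignments([]) == []

    def test_identity_threshold(self):
        good = aln("r1", "t1", 100, 100, 0.98)
        bad = aln("r2", "t1", 100, 100, 0.96)
        assert metatranscriptomic_filter([good, bad]) == [good]

    def test_order_preserved(self):
        recs = [aln(f"r{i}", "t", 100, 100, 1.0) for i in range(5)]
        assert filter_alignments(recs) == recs

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            filter_alignments([], min_aligned_frac=0.0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            aln("r", "t", 100, 150, 0.9)  # aligned > read length
        with pytest.raises(ValueError):
            aln("r", "t", 100, 90, 1.5)


class TestCountReads:
    def test_best_alignment_wins(self):
        recs = [
            aln("r1", "a", 100, 100, 0.98),
            aln("r1", "b", 100, 100, 0.99),
            aln("r2", "a", 100, 100, 1.0),
        ]
        counts, ties = count_reads(recs)
        assert counts == {"b": 1, "a": 1}
        assert ties == 0

    def test_ties_go_to_first_listed(self):
        recs = [aln("r1", "a", 100, 100, 0.99), aln("r1", "b", 100, 100, 0.99)]
        counts, ties = count_reads(recs)
        assert counts == {"a": 1}
        assert ties == 1


class TestComputeTpm:
    def test_symmetric(self):
        assert compute_tpm([10, 10], [100, 100]) == pytest.approx([500000, 500000])

    def test_length_normalization(self):
        # rates 0.1 and 0.05 -> 2/3 and 1/3 of a million
        tpm = compute_tpm([10, 20], [100, 400])
        assert tpm == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_all_zero_counts(self):
        assert compute_tpm([0, 0], [100, 200]) == pytest.approx([0.0, 0.0])

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            compute_tpm([1], [0])

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=1, max_size=30),
        data=st.data(),
    )
    def test_sums_to_million(self, counts, data):
        lengths = data.draw(
            st.lists(
                st.integers(50, 5000),
                min_size=len(counts),
                max_size=len(counts),
            )
        )
        tpm = compute_tpm(counts, lengths)
        if any(c > 0 for c in counts):
            assert tpm.sum() == pytest.approx(1e6, rel=1e-9)
        else:
            assert tpm.sum() == 0.0


def build_table(rows):
    """rows: (cds_id, genome, gene, complex, length, count)"""
    records = [CDSRecord(r[0], r[1], r[2], r[3], r[4]) for r in rows]
    counts = {r[0]: r[5] for r in rows}
    return ExpressionTable.from_counts(records, counts)


@pytest.fixture
def pmo_map():
    return FunctionMap(
        complexes={
            "pmoCAB": ("pmoC", "pmoA", "pmoB"),
            "nar": ("narG", "narH"),
            "nap": ("napA", "napB"),
            "nirS": ("nirS",),
        },
        reactions={
            "nitrate_reduction": ("nar", "nap"),
            "nitrite_reduction": ("nirS",),
            "methane_oxidation": ("pmoCAB",),
        },
        pathways={
            "denitrification": ("nitrate_reduction", "nitrite_reduction"),
            "methane": ("methane_oxidation",),
        },
    )


class TestFunctionMap:
    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            FunctionMap(complexes={"x": ()})

    def test_undefined_complex_rejected(self):
        with pytest.raises(ValueError, match="undefined complex"):
            FunctionMap(complexes={"a": ("g",)}, reactions={"r": ("b",)})

    def test_undefined_reaction_rejected(self):
        with pytest.raises(ValueError, match="undefined reaction"):
            FunctionMap(
                complexes={"a": ("g",)},
                reactions={"r": ("a",)},
                pathways={"p": ("other",)},
            )


class TestComplexExpression:
    def equal_length_table(self, gene_tpm):
        # equal lengths and a fixed total make TPM proportional to counts
        rows = [
            (f"c{i}", "g1", gene, "", 100, int(v))
            for i, (gene, v) in enumerate(gene_tpm)
        ]
        return build_table(rows)

    def test_mean_of_subunits(self, pmo_map):
        # TPM pmoC:pmoA:pmoB = 30:60:90 scaled to the million
        table = self.equal_length_table([("pmoC", 30), ("pmoA", 60), ("pmoB", 90)])
        result = complex_expression(table, pmo_map, "g1")
        expected = (table.gene_tpm("g1", "pmoC") + table.gene_tpm("g1", "pmoA")
                    + table.gene_tpm("g1", "pmoB")) / 3
        assert result.values["pmoCAB"] == pytest.approx(expected)

    def test_single_gene_complex_is_identity(self, pmo_map):
        table = self.equal_length_table([("nirS", 42), ("pmoC", 10)])
        result = complex_expression(table, pmo_map, "g1")
        assert result.values["nirS"] == pytest.approx(table.gene_tpm("g1", "nirS"))

    def test_gene_copies_summed_before_averaging(self, pmo_map):
        # oracle: explicit two-stage computation
        rows = [
            ("c1", "g1", "narG", "", 100, 10),
            ("c2", "g1", "narG", "", 100, 30),  # second copy of the subunit
            ("c3", "g1", "narH", "", 100, 20),
        ]
        table = build_table(rows)
        narg = table.gene_tpm("g1", "narG")   # summed copies
        narh = table.gene_tpm("g1", "narH")
        result = complex_expression(table, pmo_map, "g1")
        assert result.values["nar"] == pytest.approx((narg + narh) / 2)

    def test_missing_subunit_contributes_zero_with_flag(self, pmo_map):
        table = self.equal_length_table([("pmoC", 30)])
        result = complex_expression(table, pmo_map, "g1")
        assert result.values["pmoCAB"] == pytest.approx(
            table.gene_tpm("g1", "pmoC") / 3
        )
        assert "pmoA" in result.flags["pmoCAB"]

    def test_not_encoded_complex_absent(self, pmo_map):
        table = self.equal_length_table([("pmoC", 30)])
        result = complex_expression(table, pmo_map, "g1")
        assert "nirS" not in result.values
        assert result.flags["nirS"] == NOT_ENCODED

    def test_scale_equivariance(self, pmo_map):
        t1 = self.equal_length_table([("pmoC", 10), ("pmoA", 20), ("pmoB", 30)])
        # doubling every count leaves TPM (and hence outputs) unchanged;
        # instead scale TPM directly
        r1 = complex_expression(t1, pmo_map, "g1")
        scaled = ExpressionTable(t1.data.assign(tpm=t1.data["tpm"] * 3.0))
        r2 = complex_expression(scaled, pmo_map, "g1")
        for cx in r1.values:
            assert r2.values[cx] == pytest.approx(3.0 * r1.values[cx])


class TestReactionPathway:
    def test_alternates_sum(self, pmo_map):
        result = reaction_expression({"nar": 10.0, "nap": 5.0}, pmo_map)
        assert result.values["nitrate_reduction"] == pytest.approx(15.0)

    def test_single_alternate_identity(self, pmo_map):
        result = reaction_expression({"nirS": 7.0}, pmo_map)
        assert result.values["nitrite_reduction"] == pytest.approx(7.0)

    def test_no_alternates_expressed_is_zero(self, pmo_map):
        result = reaction_expression({}, pmo_map)
        assert result.values["nitrate_reduction"] == 0.0
        assert result.flags["nitrate_reduction"] == NOT_ENCODED

    def test_additivity_in_alternates(self, pmo_map):
        a = reaction_expression({"nar": 3.0}, pmo_map).values["nitrate_reduction"]
        b = reaction_expression({"nap": 4.0}, pmo_map).values["nitrate_reduction"]
        ab = reaction_expression({"nar": 3.0, "nap": 4.0}, pmo_map)
        assert ab.values["nitrate_reduction"] == pytest.approx(a + b)

    def test_pathway_mean(self, pmo_map):
        result = pathway_expression(
            {"nitrate_reduction": 15.0, "nitrite_reduction": 5.0}, pmo_map
        )
        assert result.values["denitrification"] == pytest.approx(10.0)

    def test_single_reaction_pathway_identity(self, pmo_map):
        result = pathway_expression({"methane_oxidation": 9.0}, pmo_map)
        assert result.values["methane"] == pytest.approx(9.0)

    def test_all_reactions_absent_flags_not_encoded(self, pmo_map):
        result = pathway_expression({}, pmo_map)
        assert result.values["denitrification"] == 0.0
        assert result.flags["denitrification"] == NOT_ENCODED

    def test_pathway_invariant_under_subunit_reorder(self):
        fm1 = FunctionMap(
            complexes={"abc": ("a", "b", "c")},
            reactions={"r": ("abc",)},
            pathways={"p": ("r",)},
        )
        fm2 = FunctionMap(
            complexes={"abc": ("c", "a", "b")},
            reactions={"r": ("abc",)},
            pathways={"p": ("r",)},
        )
        rows = [("c1", "g", "a", "", 100, 5), ("c2", "g", "b", "", 100, 10),
                ("c3", "g", "c", "", 100, 15)]
        table = build_table(rows)
        for fm in (fm1, fm2):
            cx = complex_expression(table, fm, "g")
            rx = reaction_expression(cx, fm)
            pw = pathway_expression(rx, fm)
            assert pw.values["p"] == pytest.approx(
                (table.gene_tpm("g", "a") + table.gene_tpm("g", "b")
                 + table.gene_tpm("g", "c")) / 3
            )


class TestMagFractions:
    def test_single_genome_is_hundred(self):
        table = build_table([("c1", "g1", "x", "", 100, 10)])
        frac = mag_expression_fraction(table)
        assert frac["g1"] == pytest.approx(100.0)

    def test_two_equal_genomes(self):
        rows = [("c1", "g1", "x", "", 100, 10), ("c2", "g2", "y", "", 100, 10)]
        frac = mag_expression_fraction(build_table(rows))
        assert frac["g1"] == pytest.approx(50.0)
        assert frac["g2"] == pytest.approx(50.0)

    def test_fractions_sum_to_hundred(self):
        rows = [
            ("c1", "g1", "x", "", 150, 31),
            ("c2", "g2", "y", "", 420, 17),
            ("c3", "unbinned", "z", "", 300, 5),
        ]
        frac = mag_expression_fraction(build_table(rows))
        assert frac.sum() == pytest.approx(100.0, rel=1e-9)

    def test_known_fractions_from_expectation_counts(self):
        # counts proportional to target fraction x length recover the
        # fractions exactly (single CDS per genome, uniform weights)
        targets = {"g1": 0.604, "g2": 0.30, "g3": 0.096}
        lengths = {"g1": 500, "g2": 800, "g3": 250}
        scale = 100000
        rows = [
            (f"c_{g}", g, "x", "", lengths[g], int(round(targets[g] * lengths[g] * scale)))
            for g in targets
        ]
        frac = mag_expression_fraction(build_table(rows))
        for g, t in targets.items():
            assert frac[g] == pytest.approx(100 * t, rel=1e-9)


class TestMagRelativeAbundance:
    @pytest.mark.parametrize("mapped,total,expected", [(50, 100, 50.0), (0, 100, 0.0)])
    def test_simple_ratio(self, mapped, total, expected):
        percents, _ = mag_relative_abundance({"g": mapped}, total)
        assert percents["g"] == pytest.approx(expected)

    def test_unmapped_remainder(self):
        percents, remainder = mag_relative_abundance(
            {"g1": 40, "g2": 36}, 100
        )
        assert remainder == pytest.approx(24.0)
        assert sum(percents.values()) + remainder == pytest.approx(100.0)

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            mag_relative_abundance({"g": 101}, 100)


class TestRelativizeToMedian:
    def table_with_tpm(self, tpm_by_cds, genome="g"):
        records = [CDSRecord(c, genome, c, "", 100) for c in tpm_by_cds]
        df = pd.DataFrame(
            {
                "cds_id": list(tpm_by_cds),
                "genome_id": genome,
                "gene_symbol": list(tpm_by_cds),
                "complex_id": "",
                "length": 100,
                "count": 1,
                "tpm": list(tpm_by_cds.values()),
            }
        )
        return ExpressionTable(df)

    def test_median_maps_to_zero(self):
        table = self.table_with_tpm({"a": 5.0, "b": 10.0, "c": 20.0})
        out = relativize_to_median(table).set_index("cds_id")
        assert out.loc["b", "value"] == pytest.approx(0.0)

    def test_twice_median_maps_to_one(self):
        table = self.table_with_tpm({"a": 5.0, "b": 10.0, "c": 20.0})
        out = relativize_to_median(table).set_index("cds_id")
        assert out.loc["c", "value"] == pytest.approx(1.0)

    def test_zero_tpm_flagged_undetectable(self):
        table = self.table_with_tpm({"a": 0.0, "b": 10.0, "c": 20.0})
        out = relativize_to_median(table).set_index("cds_id")
        assert out.loc["a", "flag"] == UNDETECTABLE
        assert np.isnan(out.loc["a", "value"])

    def test_zero_median_flags_all(self):
        table = self.table_with_tpm({"a": 0.0, "b": 0.0, "c": 1.0})
        out = relativize_to_median(table)
        assert (out["flag"] == UNDETECTABLE).all()

    def test_ratio_mode(self):
        table = self.table_with_tpm({"a": 5.0, "b": 10.0, "c": 20.0})
        out = relativize_to_median(table, mode="ratio").set_index("cds_id")
        assert out.loc["c", "value"] == pytest.approx(2.0)
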