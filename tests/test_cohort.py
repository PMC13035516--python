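"""Lexicon matching, primary-suspect cohorting, fourfold tables, demographics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from basalvig.cohort import (
    ContingencyTable,
    DEFAULT_LEXICONS,
    DrugLexicon,
    OCULAR_PTS,
    PTSet,
    VISUAL_IMPAIRMENT,
    age_group,
    age_in_years,
    all_target_cohorts,
    build_contingency,
    match_drug,
    pair_count_universe,
    primary_suspect_reports,
    summarize_demographics,
    weight_in_kg,
)
from basalvig.faers_io import CaseStore, deduplicate, exclude_incomplete
from tests.conftest import frame


class TestMatchDrug:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("LEVEMIR FLEXPEN", "insulin_detemir"),
            ("TRESIBA.", "insulin_degludec"),
            ("Lantus SoloStar", "insulin_glargine"),
            ("BASAGLAR KWIKPEN", "insulin_glargine"),
            ("METFORMIN", None),
            ("", None),
        ],
    )
    def test_examples(self, name, expected):
        label, _ = match_drug(name)
        assert label == expected

    def test_combination_product_matches_with_flag(self):
        label, flags = match_drug("INSULIN GLARGINE AND LIXISENATIDE")
        assert label == "insulin_glargine"
        assert "combination" in flags

    def test_conflicting_ingredients_flagged_ambiguous(self):
        label, flags = match_drug("LEVEMIR / LANTUS")
        assert label is None
        assert "ambiguous" in flags

    def test_prod_ai_field_also_matched(self):
        label, _ = match_drug("UNKNOWN PEN", "INSULIN DETEMIR")
        assert label == "insulin_detemir"

    def test_exact_mode_rejects_substring(self):
        lex = (DrugLexicon("insulin_detemir", ("LEVEMIR",), match_mode="exact"),)
        assert match_drug("LEVEMIR", lexicons=lex)[0] == "insulin_detemir"
        assert match_drug("LEVEMIR FLEXPEN", lexicons=lex)[0] is None


class TestPrimarySuspect:
    def test_role_filter(self, micro_store):
        store = deduplicate(micro_store, deleted=[])
        # case 4 carries detemir only as SS: not in the detemir cohort
        assert "4001" not in primary_suspect_reports(store, "insulin_detemir")
        # case 1 is degludec PS (concomitant metformin is irrelevant)
        assert "1003" in primary_suspect_reports(store, "insulin_degludec")

    def test_planted_counts_recovered(self, small_quarter, small_store):
        cohorts = all_target_cohorts(small_store)
        truth = small_quarter.ground_truth.case_counts
        assert {k: len(v) for k, v in cohorts.items()} == truth


class TestContingency:
    def test_construction_at_independence(self):
        t = ContingencyTable(10, 90, 100, 900)
        assert t.n == 1100
        assert t.expected == pytest.approx(100 * 110 / 1100)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_report_counted_once_with_two_matching_pts(self, micro_store):
        store = deduplicate(micro_store, deleted=[])
        table = build_contingency(store, "insulin_degludec", OCULAR_PTS)
        # case 1 has both VISUAL IMPAIRMENT and CATARACT but a == 1
        assert table.a == 1

    def test_planted_cells_recovered_exactly(self, small_quarter, small_store):
        store, _ = exclude_incomplete(small_store, stage="signal")
        truth = small_quarter.ground_truth.contingency
        for (label, pt), cells in truth.items():
            table = build_contingency(store, label, PTSet(pt, (pt,)))
            assert table.as_tuple() == cells, (label, pt)

    def test_cells_partition_universe(self, small_store):
        table = build_contingency(small_store, "insulin_detemir", VISUAL_IMPAIRMENT)
        assert table.n == small_store.n_reports

    def test_empty_comparator_raises(self):
        demo = frame([("1", "1", "20200101")], ["primaryid", "caseid", "fda_dt"])
        drug = frame(
            [("1", "1", "1", "PS", "TRESIBA", "INSULIN DEGLUDEC")],
            ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        )
        reac = frame([("1", "1", "NAUSEA")], ["primaryid", "caseid", "pt"])
        store = CaseStore(demo=demo, drug=drug, reac=reac, ther=demo.iloc[:0].copy())
        with pytest.raises(ValueError, match="comparator"):
            build_contingency(store, "insulin_degludec", VISUAL_IMPAIRMENT)


class TestPairUniverse:
    def test_margins_and_positivity(self, small_store):
        universe = pair_count_universe(small_store)
        assert (universe["expected"] > 0).all()
        reac = small_store.reac.copy()
        from basalvig.cohort import normalize_name

        reac["pt"] = reac["pt"].map(normalize_name)
        n_pairs_expected = len(reac.drop_duplicates(["primaryid", "pt"]))
        assert universe["observed"].sum() == n_pairs_expected


class TestDemographics:
    def test_units(self):
        assert age_in_years(6.5, "DEC") == pytest.approx(65.0)
        assert age_in_years(24, "MON") == pytest.approx(2.0)
        assert np.isnan(age_in_years("", "YR"))
        assert weight_in_kg(150, "LBS") == pytest.approx(68.0388)
        assert weight_in_kg(70, "KG") == 70

    def test_age_boundary_65_goes_to_oldest_group(self):
        assert age_group(age_in_years(6.5, "DEC")) == ">65"
        assert age_group(64.99) == "18-64"
        assert age_group(17.9) == "<18"

    def test_female_percentage_worked_example(self):
        """A 156-report cohort with 101 female reports summarizes to 64.7%."""
        sexes = ["F"] * 101 + ["M"] * 52 + [""] * 3
        demo = frame(
            [(str(i), str(i), "20200101") for i in range(156)],
            ["primaryid", "caseid", "fda_dt"],
        )
        demo["sex"] = sexes
        store = CaseStore(demo=demo, drug=demo.iloc[:0].copy(),
                          reac=demo.iloc[:0].copy(), ther=demo.iloc[:0].copy())
        out = summarize_demographics(store, set(demo["primaryid"]))
        female = out[(out.variable == "sex") & (out.level == "Female")]
        assert round(float(female["percent"].iloc[0]), 1) == 64.7

    def test_all_missing_sex_degenerate(self):
        demo = frame([(str(i), str(i), "20200101") for i in range(5)],
                     ["primaryid", "caseid", "fda_dt"])
        demo["sex"] = ""
        store = CaseStore(demo=demo, drug=demo.iloc[:0].copy(),
                          reac=demo.iloc[:0].copy(), ther=demo.iloc[:0].copy())
        out = summarize_demographics(store, set(demo["primaryid"]))
        na = out[(out.variable == "sex") & (out.level == "NA")]
        assert float(na["percent"].iloc[0]) == 100.0

    def test_counts_sum_to_cohort_n(self, small_store):
        ids = primary_suspect_reports(small_store, "insulin_glargine")
        out = summarize_demographics(small_store, ids)
        for var in ("sex", "country", "age_group", "year"):
            assert out[out.variable == var]["count"].sum() == len(ids)

    def test_marginals_match_generator_targets(self, small_store, small_quarter):
        """Emitted female/US fractions sit within 3 sigma of the configured mix."""
        ids = primary_suspect_reports(small_store, "insulin_glargine")
        out = summarize_demographics(small_store, ids)
        n = len(ids)
        f = float(out[(out.variable == "sex") & (out.level == "Female")]["count"].iloc[0])
        p = 0.647 * (1 - 0.04)
        assert abs(f - n * p) < 3 * np.sqrt(n * p * (1 - p))
        us = float(out[(out.variable == "country") & (out.level == "United States")]["count"].iloc[0])
        assert us / n > 0.9


_cache: dict = {}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.permutations(range(8)))
def test_contingency_input_order_invariance(order):
    """Permuting report row order never changes the fourfold cells."""
    if "store" not in _cache:
        demo = frame([(str(i), str(i), "20200101") for i in range(8)],
                     ["primaryid", "caseid", "fda_dt"])
        drug = frame(
            [(str(i), str(i), "1", "PS",
              "TRESIBA" if i < 4 else "OTHER", "") for i in range(8)],
            ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        )
        reac = frame([(str(i), str(i), "VISUAL IMPAIRMENT" if i % 2 else "NAUSEA")
                      for i in range(8)], ["primaryid", "caseid", "pt"])
        _cache["store"] = (demo, drug, reac)
        base = CaseStore(demo=demo, drug=drug, reac=reac, ther=demo.iloc[:0].copy())
        _cache["cells"] = build_contingency(base, "insulin_degludec", VISUAL_IMPAIRMENT).as_tuple()
    demo, drug, reac = _cache["store"]
    permuted = CaseStore(
        demo=demo.iloc[list(order)].reset_index(drop=True),
        drug=drug.iloc[list(order)].reset_index(drop=True),
        reac=reac.iloc[list(order)].reset_index(drop=True),
        ther=demo.iloc[:0].copy(),
    )
    assert build_contingency(permuted, "insulin_degludec", VISUAL_IMPAIRMENT).as_tuple() == _cache["cells"]
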