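"""Deduplication, age standardisation, PS selection and TTO categorisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faersig as fs
from faersig.preprocess import (
    assign_primary_suspect_frame,
    compute_tto_days,
    compute_tto_series,
    deduplicate,
    filter_pediatric,
    select_primary_suspect,
    standardize_age,
    standardize_age_series,
)


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"], dtype=str)


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        demo = _demo([["5501", "55", "20200101"], ["5502", "55", "20210101"]])
        kept, counts = deduplicate(demo)
        assert list(kept["primaryid"]) == ["5502"]
        assert counts["duplicates_removed"] == 1

    def test_tie_broken_by_largest_primaryid(self):
        demo = _demo([["5502", "55", "20200101"], ["5501", "55", "20200101"]])
        kept, _ = deduplicate(demo)
        assert list(kept["primaryid"]) == ["5502"]

    def test_missing_caseid_excluded_and_counted(self):
        demo = _demo([["1", "", "20200101"], ["2", "c", "20200101"]])
        kept, counts = deduplicate(demo)
        assert counts["missing_caseid"] == 1
        assert list(kept["caseid"]) == ["c"]

    def test_idempotent(self):
        demo = _demo(
            [["1", "a", "20200101"], ["2", "a", "20200301"], ["3", "b", "20200101"]]
        )
        once, _ = deduplicate(demo)
        twice, counts = deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert counts["duplicates_removed"] == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, order):
        rows = [
            ["10", "a", "20200101"], ["11", "a", "20200101"], ["12", "a", "20190101"],
            ["20", "b", "20210101"], ["21", "b", "20220101"], ["30", "c", "20200101"],
        ]
        base, _ = deduplicate(_demo(rows))
        shuffled, _ = deduplicate(_demo([rows[i] for i in order]))
        pd.testing.assert_frame_equal(base, shuffled)

    def test_synthetic_kept_equals_distinct_caseids(self):
        world = fs.generate(
            fs.GeneratorConfig(n_reports=10_000, seed=3, duplicate_fraction=0.2)
        )
        demo = world.bundle.table("DEMO")
        kept, _ = deduplicate(demo)
        assert len(kept) == demo["caseid"].nunique() == 10_000
        # the kept version is the one the generator marked as current
        truth = world.truth.frame
        merged = kept.merge(truth, on="caseid")
        assert (merged["primaryid"] == merged["kept_primaryid"]).all()


class TestStandardizeAge:
    @pytest.mark.parametrize(
        "value, code, expected",
        [
            (24, "MON", 2.0),
            (730, "DY", 2.0),
            (1.2, "DEC", 12.0),
            (104, "WK", 2.0),
            (17, "YR", 17.0),
            (17, "yr ", 17.0),  # case/whitespace-insensitive codes
        ],
    )
    def test_unit_conversions(self, value, code, expected):
        assert standardize_age(value, code) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "value, code",
        [(-5, "YR"), (5, "HR"), (5, ""), ("", "YR"), (None, "YR"), ("abc", "YR")],
    )
    def test_unusable_values_map_to_missing(self, value, code):
        assert math.isnan(standardize_age(value, code))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=120.0, allow_nan=False))
    def test_unit_consistency(self, years):
        yr = standardize_age(years, "YR")
        assert standardize_age(years * 12, "MON") == pytest.approx(yr, rel=1e-12, abs=1e-12)
        assert standardize_age(years * 365, "DY") == pytest.approx(yr, rel=1e-12, abs=1e-12)
        assert standardize_age(years / 10, "DEC") == pytest.approx(yr, rel=1e-12, abs=1e-12)

    def test_series_agrees_with_scalar(self):
        vals = pd.Series(["24", "730", "-1", "", "1.2"])
        cods = pd.Series(["MON", "DY", "YR", "YR", "DEC"])
        out = standardize_age_series(vals, cods)
        expected = [standardize_age(v, c) for v, c in zip(vals, cods)]
        np.testing.assert_allclose(out.to_numpy(), expected)


class TestFilterPediatric:
    def test_strict_boundaries(self):
        df = pd.DataFrame({"age_years": [0.0, 0.5, 17.99, 18.0]})
        kept, counts = filter_pediatric(df)
        assert list(kept["age_years"]) == [0.5, 17.99]
        assert counts["age_out_of_range"] == 2

    def test_all_missing_gives_empty(self):
        df = pd.DataFrame({"age_years": [np.nan, np.nan]})
        kept, counts = filter_pediatric(df)
        assert kept.empty and counts["age_missing"] == 2

    def test_idempotent(self):
        df = pd.DataFrame({"age_years": np.linspace(-1, 20, 43)})
        once, _ = filter_pediatric(df)
        twice, _ = filter_pediatric(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_retained_fraction_matches_generator(self, mixed_age_world):
        demo = mixed_age_world.bundle.table("DEMO")
        kept, _ = deduplicate(demo)
        kept = kept.assign(age_years=standardize_age_series(kept["age"], kept["age_cod"]))
        ped, _ = filter_pediatric(kept)
        frac = len(ped) / len(kept)
        cfg = mixed_age_world.config
        expected = cfg.age.pediatric_fraction * (1 - cfg.age.missing_prob)
        assert abs(frac - expected) < 0.02
        # and the pipeline's retained set is exactly the truth's background set
        assert set(ped["caseid"]) == set(mixed_age_world.truth.background["caseid"])


class TestPrimarySuspect:
    def _rows(self, specs):
        return [
            {"role_cod": r, "drug_seq": s, "drugname": n} for r, s, n in specs
        ]

    def test_lowest_drug_seq_among_ps(self):
        rows = self._rows([("PS", "3", "A"), ("PS", "1", "B"), ("PS", "2", "C")])
        got = select_primary_suspect(rows, "7")
        assert got.verbatim_name == "B" and got.drug_seq == 1

    def test_no_ps_row_returns_none(self):
        rows = self._rows([("C", "1", "A"), ("SS", "2", "B"), ("I", "3", "C")])
        assert select_primary_suspect(rows, "7") is None

    def test_non_numeric_seq_orders_last(self):
        rows = self._rows([("PS", "x", "A"), ("PS", "2", "B")])
        assert select_primary_suspect(rows, "7").verbatim_name == "B"
        only = self._rows([("PS", "x", "A")])
        assert select_primary_suspect(only, "7").verbatim_name == "A"

    def test_frame_assignment_matches_generator_truth(self, paper_world, paper_dataset):
        dataset, _ = paper_dataset
        truth = paper_world.truth.background.set_index("caseid")
        merged = dataset.set_index("caseid").join(truth, rsuffix="_t")
        assert (merged["ps_entity"] == merged["ps_entity_t"]).all()


class TestComputeTTO:
    @pytest.mark.parametrize(
        "start, event, days, reason",
        [
            ("20200101", "20200131", 30, "ok"),
            ("20200131", "20200101", None, "inconsistent"),
            ("20200101", "20200101", None, "inconsistent"),
            ("202001", "20200301", None, "incomplete"),
            ("20200101", "2020", None, "incomplete"),
            ("", "20200301", None, "missing"),
            ("20200101", "", None, "missing"),
            ("20200101", "20390101", None, "implausible"),
            ("20200101", "20200102", 1, "ok"),
        ],
    )
    def test_categorisation(self, start, event, days, reason):
        got_days, got_reason = compute_tto_days(start, event)
        assert (got_days, got_reason) == (days, reason)

    def test_implausible_threshold_is_configurable(self):
        days, reason = compute_tto_days("20200101", "20200301", implausible_days=30)
        assert (days, reason) == (None, "implausible")

    def test_series_agrees_with_scalar(self):
        starts = pd.Series(["20200101", "20200131", "202001", "", "20200101"])
        events = pd.Series(["20200131", "20200101", "20200301", "20200301", ""])
        days, reasons = compute_tto_series(starts, events)
        for i in range(len(starts)):
            d, r = compute_tto_days(starts[i], events[i])
            assert reasons.iloc[i] == r
            if d is None:
                assert np.isnan(days.iloc[i])
            else:
                assert days.iloc[i] == d

    def test_rejection_category_counts_match_generator_exactly(
        self, paper_world, paper_dataset
    ):
        dataset, _ = paper_dataset
        pipeline_counts = dataset["tto_reason"].value_counts().to_dict()
        truth_counts = paper_world.truth.rejection_counts()
        assert pipeline_counts == {k: v for k, v in truth_counts.items() if v}
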