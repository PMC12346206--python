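"""Cost aggregation: human-capital indirect costs, category totals,
permutation/additivity invariants, independent recomputation oracles."""

import csv
import statistics
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handcost import (
    COST_CATEGORIES,
    CostBreakdown,
    CostItem,
    DataError,
    WageModel,
    aggregate_cohort,
    aggregate_patient,
    indirect_cost,
    summarize_cohort,
    write_cohort,
)


class TestIndirectCost:
    def test_zero_days_zero_cost(self):
        item = indirect_cost(0, WageModel(50.0))
        assert item.amount == 0.0 and item.category == "incapacity"

    def test_days_times_wage(self):
        assert indirect_cost(14, WageModel(50.0)).amount == 700.0

    def test_wage_tag_carried(self):
        item = indirect_cost(3, WageModel(8.54, "USD", 2020))
        assert (item.currency, item.year) == ("USD", 2020)

    def test_negative_days_rejected(self):
        with pytest.raises(DataError):
            indirect_cost(-1, WageModel(50.0))

    def test_cohort_maximum_spell(self, fixture_cohort):
        """The longest incapacity spell in the fixture is 102 days and its
        indirect cost is the cohort maximum."""
        days = [r.incapacity_days for r in fixture_cohort]
        assert max(days) == 102
        wage = WageModel(8.54, "USD", 2020)
        costs = [indirect_cost(d, wage).amount for d in days]
        assert max(costs) == 102 * 8.54


class TestAggregatePatient:
    def test_no_items_all_zero(self, fixture_cohort, tables):
        rec = replace(fixture_cohort[0], cost_items=())
        bd = aggregate_patient(rec, tables)
        assert bd.total == 0.0
        assert all(v == 0.0 for v in bd.as_dict().values())

    def test_single_item_worked_example(self, fixture_cohort, toy_tables):
        rec = replace(
            fixture_cohort[0],
            cost_items=(CostItem("drug", 100.0, "TRY", 2020),),
        )
        bd = aggregate_patient(rec, toy_tables)
        assert bd["drug"] == pytest.approx(24.0)
        assert bd.total == pytest.approx(24.0)
        assert bd.subtotal_without_surgical == pytest.approx(24.0)

    def test_subtotal_is_total_minus_surgical(self, fixture_cohort, tables):
        for rec in fixture_cohort[:10]:
            bd = aggregate_patient(rec, tables)
            assert bd.subtotal_without_surgical == pytest.approx(
                bd.total - bd["surgical"]
            )

    @settings(max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_permutation_and_split_additivity(
        self, data, fixture_cohort, tables
    ):
        """Category totals ignore item order, and splitting one item into
        two of equal sum leaves the breakdown unchanged."""
        items = data.draw(
            st.lists(
                st.tuples(
                    st.sampled_from(COST_CATEGORIES),
                    st.floats(0, 1e5),
                    st.sampled_from(range(2015, 2021)),
                ),
                min_size=1,
                max_size=6,
            )
        )
        cost_items = tuple(
            CostItem(cat, amt, "TRY", yr) for cat, amt, yr in items
        )
        rec = replace(fixture_cohort[0], cost_items=cost_items)
        base = aggregate_patient(rec, tables)

        perm = data.draw(st.permutations(cost_items))
        shuffled = aggregate_patient(
            replace(rec, cost_items=tuple(perm)), tables
        )
        assert shuffled.totals == pytest.approx(base.totals)

        first = cost_items[0]
        frac = data.draw(st.floats(0.0, 1.0))
        split = (
            replace(first, amount=first.amount * frac),
            replace(first, amount=first.amount * (1 - frac)),
        ) + cost_items[1:]
        assert aggregate_patient(
            replace(rec, cost_items=split), tables
        ).totals == pytest.approx(base.totals)


class TestSummaries:
    def test_single_patient_degenerate_sd(self, fixture_cohort, tables):
        df = summarize_cohort(aggregate_cohort(fixture_cohort[:1], tables))
        assert (df["sd"] == 0.0).all()
        assert df["degenerate"].all()

    def test_two_patient_mean_median(self):
        a = CostBreakdown(totals=(10, 0, 0, 0, 0, 0, 0))
        b = CostBreakdown(totals=(30, 0, 0, 0, 0, 0, 0))
        df = summarize_cohort([a, b])
        assert df.loc["drug", "mean"] == 20 and df.loc["drug", "median"] == 20
        assert df.loc["total", "mean"] == 20

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            summarize_cohort([])

    def test_brute_force_recomputation_small_cohort(
        self, fixture_cohort, tables
    ):
        """Summary statistics agree with the statistics stdlib on n<=10."""
        bds = aggregate_cohort(fixture_cohort[:10], tables)
        df = summarize_cohort(bds)
        totals = [b.total for b in bds]
        assert df.loc["total", "mean"] == pytest.approx(statistics.fmean(totals))
        assert df.loc["total", "sd"] == pytest.approx(statistics.stdev(totals))
        assert df.loc["total", "median"] == pytest.approx(
            statistics.median(totals)
        )
        drug = [b["drug"] for b in bds]
        assert df.loc["drug", "mean"] == pytest.approx(statistics.fmean(drug))
        assert df.loc["drug", "min"] == min(drug)
        assert df.loc["drug", "max"] == max(drug)


def test_fixture_means_match_spreadsheet_pass(fixture_cohort, tables, tmp_path):
    """Category means recomputed from the written CSV by an independent
    spreadsheet-style pass (csv module + raw FX/CPI arithmetic) equal the
    package's aggregation."""
    path = tmp_path / "cohort.csv"
    write_cohort(fixture_cohort, path)

    sums = dict.fromkeys(COST_CATEGORIES, 0.0)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if not row["cost_category"]:
                continue
            amount = float(row["cost_amount"])
            year = row["cost_year"]
            usd = amount if row["cost_currency"] == "USD" else (
                amount / tables.fx[int(year)]
            )
            usd *= tables.cpi["2022Q4"] / tables.cpi[year]
            sums[row["cost_category"]] += usd
    independent_means = {k: v / len(fixture_cohort) for k, v in sums.items()}

    df = summarize_cohort(aggregate_cohort(fixture_cohort, tables))
    for cat in COST_CATEGORIES:
        assert df.loc[cat, "mean"] == pytest.approx(
            independent_means[cat], rel=1e-9
        ), cat


def test_fixture_median_outpatient_visits_is_20(fixture_cohort):
    visits = [r.outpatient_visits for r in fixture_cohort]
    assert np.median(visits) == 20
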