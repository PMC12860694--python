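"""Episode midpoint coding, DUIC(-)/(+) allocation, the burden
decomposition and its bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from duicdid import (AllocationScheme, PRIMARY_SCHEME, allocate_episodes,
                     bootstrap_burden, burden_decomposition,
                     code_count_category, sensitivity_schemes)
from duicdid.config import COUSE_LEVELS, USE_FREQ_LEVELS
from duicdid.errors import (ConfigurationError, IncompleteRecordError,
                            UndefinedShareError)

from conftest import make_sample3


@pytest.mark.parametrize("category,exact,expected", [
    ("once", None, 1.0),
    ("2-3", None, 2.5),
    ("4-9", None, 6.5),
    ("10-15", None, 12.5),
    ("more", 60, 60.0),  # 60 is the study's reported maximum
    ("more", 16, 16.0),
])
def test_midpoint_coding(category, exact, expected):
    assert code_count_category(category, exact) == expected


def test_midpoint_coding_errors():
    with pytest.raises(IncompleteRecordError):
        code_count_category("more")
    with pytest.raises(IncompleteRecordError):
        code_count_category("more", 12)
    with pytest.raises(ConfigurationError):
        code_count_category("16-20")


@pytest.mark.parametrize("count,category,minus,plus", [
    (8.0, "cannabis_only", 8.0, 0.0),
    (2.5, "occasionally", 1.875, 0.625),
    (12.5, "mostly", 3.125, 9.375),
    (6.5, "always", 0.0, 6.5),
])
def test_primary_allocation(count, category, minus, plus):
    m, p = allocate_episodes(count, category, PRIMARY_SCHEME)
    assert m == pytest.approx(minus) and p == pytest.approx(plus)


def test_scheme_validation():
    with pytest.raises(ConfigurationError):
        AllocationScheme(1.0, 1.2, 0.2, 0.0)


FIXTURE = make_sample3(
    freqs=["daily", "daily", "weekly", "weekly", "monthly",
           "less_than_monthly"],
    categories=["more", "10-15", "4-9", "2-3", "once", "once"],
    exacts=[20, None, None, None, None, None],
    couses=["cannabis_only", "occasionally", "mostly", "always",
            "cannabis_only", "occasionally"],
)


def test_decomposition_matches_hand_computed_sums():
    # daily: 20*1 + 12.5*0.75 = 29.375 minus, 0 + 3.125 plus
    # weekly: 6.5*0.25 + 2.5*0 = 1.625 minus, 4.875 + 2.5 = 7.375 plus
    # monthly: 1 minus, 0 plus; ltm: 0.75 minus, 0.25 plus
    bt = burden_decomposition(FIXTURE, PRIMARY_SCHEME)
    total_minus = 29.375 + 1.625 + 1.0 + 0.75
    total_plus = 3.125 + 7.375 + 0.0 + 0.25
    assert bt.totals["duic_minus_episodes"] == pytest.approx(total_minus)
    assert bt.totals["duic_plus_episodes"] == pytest.approx(total_plus)
    assert bt.totals["total_episodes"] == pytest.approx(total_minus
                                                        + total_plus)
    assert bt.table.loc["daily", "minus_share_pct"] == pytest.approx(
        100 * 29.375 / total_minus)
    assert bt.table.loc["weekly", "plus_share_pct"] == pytest.approx(
        100 * 7.375 / total_plus)


def test_single_group_holds_all_shares():
    fx = make_sample3(["weekly"] * 3, ["once", "2-3", "4-9"],
                      [None] * 3, ["cannabis_only", "mostly", "always"])
    bt = burden_decomposition(fx, PRIMARY_SCHEME)
    assert bt.table.loc["weekly", "minus_share_pct"] == pytest.approx(100.0)
    assert bt.table.loc["weekly", "plus_share_pct"] == pytest.approx(100.0)


def test_all_minus_scheme_zeroes_plus_and_mirrors_totals():
    scheme = AllocationScheme(1.0, 1.0, 1.0, 1.0)
    bt = burden_decomposition(FIXTURE, scheme)
    assert bt.totals["duic_plus_episodes"] == 0.0
    totals_by_group = FIXTURE.assign(
        count=[20, 12.5, 6.5, 2.5, 1, 1]).groupby("cannabis_freq")[
        "count"].sum()
    expect = 100 * totals_by_group / totals_by_group.sum()
    for grp in totals_by_group.index:
        assert bt.table.loc[grp, "minus_share_pct"] == pytest.approx(
            expect[grp])
    assert np.isnan(bt.table["plus_share_pct"]).all()


def test_population_share_denominator_uses_all_users():
    users = pd.DataFrame({
        "cannabis_freq": ["daily"] * 10 + ["weekly"] * 30
        + ["monthly"] * 20 + ["less_than_monthly"] * 40})
    bt = burden_decomposition(FIXTURE, PRIMARY_SCHEME, users=users)
    assert bt.table["pop_share_pct"].sum() == pytest.approx(100.0)
    assert bt.table.loc["less_than_monthly", "pop_share_pct"] == \
        pytest.approx(40.0)


@given(st.lists(
    st.tuples(st.sampled_from(USE_FREQ_LEVELS),
              st.sampled_from(["once", "2-3", "4-9", "10-15"]),
              st.sampled_from(COUSE_LEVELS)),
    min_size=1, max_size=25))
def test_conservation_and_normalisation_properties(rows):
    fx = make_sample3([r[0] for r in rows], [r[1] for r in rows],
                      [None] * len(rows), [r[2] for r in rows])
    bt = burden_decomposition(fx, PRIMARY_SCHEME)
    t = bt.totals
    assert t["duic_minus_episodes"] + t["duic_plus_episodes"] == \
        pytest.approx(t["total_episodes"], abs=1e-9)
    for col in ("pop_share_pct", "minus_share_pct", "plus_share_pct"):
        if bt.table[col].isna().all():
            continue  # that episode type has zero total under this scheme
        assert bt.table[col].sum() == pytest.approx(100.0, abs=1e-6)


def test_raising_occasional_fraction_never_lowers_minus_total():
    lo = burden_decomposition(FIXTURE, AllocationScheme(1.0, 0.6, 0.25, 0.0))
    hi = burden_decomposition(FIXTURE, AllocationScheme(1.0, 0.9, 0.25, 0.0))
    assert hi.totals["duic_minus_episodes"] >= lo.totals[
        "duic_minus_episodes"]


def test_zero_total_episodes_rejected():
    fx = FIXTURE.iloc[0:0]
    with pytest.raises((UndefinedShareError, ValueError)):
        burden_decomposition(fx, PRIMARY_SCHEME)


class TestBootstrap:
    def test_single_resample_ci_is_degenerate_at_its_value(self):
        bt = bootstrap_burden(FIXTURE, PRIMARY_SCHEME, B=1, seed=4)
        low = bt.table["minus_share_pct_low"]
        high = bt.table["minus_share_pct_high"]
        assert np.allclose(low, high, equal_nan=True)

    def test_same_seed_identical_cis(self):
        a = bootstrap_burden(FIXTURE, PRIMARY_SCHEME, B=300, seed=6)
        b = bootstrap_burden(FIXTURE, PRIMARY_SCHEME, B=300, seed=6)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_point_estimate_inside_percentile_ci(self, clean_samples):
        _, _, _, s3 = clean_samples
        from duicdid import past_year_users
        users = past_year_users(clean_samples[0])
        bt = bootstrap_burden(s3.rows, PRIMARY_SCHEME, B=400, seed=8,
                              users=users)
        for col in ("pop_share_pct", "minus_share_pct", "plus_share_pct"):
            ok = ((bt.table[f"{col}_low"] <= bt.table[col] + 1e-9)
                  & (bt.table[col] <= bt.table[f"{col}_high"] + 1e-9))
            assert ok[bt.table[col].notna()].all(), col

    def test_stratified_resampling_runs(self):
        bt = bootstrap_burden(FIXTURE, PRIMARY_SCHEME, B=50, seed=2,
                              stratify="country")
        assert bt.totals["bootstrap_B"] == 50


class TestSensitivitySchemes:
    def test_primary_only_matches_decomposition(self):
        out = sensitivity_schemes(FIXTURE, [PRIMARY_SCHEME])
        ref = burden_decomposition(FIXTURE, PRIMARY_SCHEME)
        pd.testing.assert_frame_equal(out[0]["table"].table, ref.table)

    def test_rank_stability_when_one_group_dominates_couse(self):
        fx = make_sample3(
            ["weekly"] * 4 + ["daily", "monthly"],
            ["10-15", "10-15", "4-9", "4-9", "once", "once"],
            [None] * 6,
            ["always", "mostly", "mostly", "always", "cannabis_only",
             "cannabis_only"])
        out = sensitivity_schemes(
            fx, [AllocationScheme(1, 0.9, 0.1, 0),
                 AllocationScheme(1, 0.6, 0.4, 0)])
        assert all(e["plus_rank_order"][0] == "weekly" for e in out)

    def test_empty_scheme_list_rejected(self):
        with pytest.raises(ConfigurationError):
            sensitivity_schemes(FIXTURE, [])
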