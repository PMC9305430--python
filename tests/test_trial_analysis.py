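"""Period aggregation, nonparametric tests, sample size, sensitivity."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy import stats

from nutribasket.synthetic_data import CohortConfig, ParticipantRecord, TrialDataset
from nutribasket.trial_analysis import (
    aggregate_periods,
    analyze_trial,
    mann_whitney_u,
    pearson_chi_square,
    sample_size,
    sensitivity_analysis,
    summarize_group,
    wilcoxon_signed_rank,
)

from conftest import START


# --------------------------------------------------------------------------
# aggregation


def make_stub(pid="p1", group="control", steps=None, dropout=None, age=40):
    return ParticipantRecord(
        participant_id=pid, group=group, age=age, gender="female",
        bmi_class="<25", household_size=2, steps=steps or {}, baskets=[],
        logins={}, surveys={}, dropout_week=dropout, food_connected=False,
    )


def test_constant_steps_give_equal_period_means(mini_catalog):
    steps = {START + dt.timedelta(days=d): 6000.0 for d in range(12 * 7)}
    steps.update({START - dt.timedelta(days=d): 5000.0 for d in (1, 2, 3, 4, 5, 6)})
    agg = aggregate_periods(make_stub(steps=steps), mini_catalog, START)["steps"]
    assert agg.get("T0") == pytest.approx(5000.0)
    assert agg.get("T1") == agg.get("T2") == agg.get("T3") == pytest.approx(6000.0)


def test_dropout_week_4_blanks_T2_T3(mini_catalog):
    steps = {START + dt.timedelta(days=d): 6000.0 for d in range(28)}
    agg = aggregate_periods(make_stub(steps=steps, dropout=4), mini_catalog, START)
    assert agg["steps"].get("T1") == pytest.approx(6000.0)
    assert agg["steps"].get("T2") is None and agg["steps"].get("T3") is None


def test_period_means_match_brute_force_windows(mini_catalog):
    rng = np.random.default_rng(8)
    steps = {START + dt.timedelta(days=int(d)): float(rng.uniform(0, 12000))
             for d in rng.choice(84, size=60, replace=False)}
    agg = aggregate_periods(make_stub(steps=steps), mini_catalog, START)["steps"]
    for period, (a, b) in {"T1": (0, 28), "T2": (28, 56), "T3": (56, 84)}.items():
        window = [v for d, v in steps.items() if a <= (d - START).days < b]
        assert agg.get(period) == pytest.approx(np.mean(window))


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


def brute_force_wilcoxon_p(before, after):
    d = np.asarray(after, float) - np.asarray(before, float)
    ranks = stats.rankdata(np.abs(d))
    nz = d != 0
    w_obs = ranks[nz & (d > 0)].sum()
    nzr = ranks[nz]
    ws = np.array([
        sum(r for r, s in zip(nzr, signs) if s)
        for signs in itertools.product([0, 1], repeat=int(nz.sum()))
    ])
    return min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean()))


def test_wilcoxon_all_ties_p_one():
    r = wilcoxon_signed_rank([3, 4, 5], [3, 4, 5])
    assert r.p_value == 1.0 and "all_zero" in r.flags


def test_wilcoxon_all_positive_n6_extreme_tail():
    r = wilcoxon_signed_rank([0] * 6, [1, 2, 3, 4, 5, 6])
    assert r.p_value == pytest.approx(2 / 64)


def test_wilcoxon_n8_matches_sign_enumeration():
    before = [10.0, 12, 9, 14, 11, 8, 13, 10]
    after = [12.0, 11, 13, 14.5, 10, 12, 15, 9]
    r = wilcoxon_signed_rank(before, after)
    assert r.p_value == pytest.approx(brute_force_wilcoxon_p(before, after), abs=1e-12)


def test_wilcoxon_random_fixtures_match_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(5, 11))
        before = rng.integers(0, 6, n).astype(float)
        after = before + rng.integers(-3, 4, n)
        if np.all(after == before):
            continue
        r = wilcoxon_signed_rank(before, after)
        assert r.p_value == pytest.approx(brute_force_wilcoxon_p(before, after), abs=1e-12)


def test_wilcoxon_large_n_matches_scipy_normal_approx():
    rng = np.random.default_rng(6)
    before = rng.normal(0, 1, 40)
    after = before + rng.normal(0.3, 1, 40)
    r = wilcoxon_signed_rank(before, after)
    assert "normal_approx" in r.flags
    expect = stats.wilcoxon(after - before, correction=False, method="approx").pvalue
    assert r.p_value == pytest.approx(expect, rel=1e-9)


def test_wilcoxon_complete_case_and_underpowered_flag():
    before = [1.0, 2, np.nan, 4]
    after = [2.0, 1, 5, np.nan]
    r = wilcoxon_signed_rank(before, after)
    assert r.n_used == 2 and "underpowered" in r.flags
    assert 0 <= r.p_value <= 1


def test_wilcoxon_zero_methods_differ_on_zero_heavy_data():
    before = [0.0] * 6 + [0.0, 0.0]
    after = [0.0] * 6 + [1.0, 2.0]
    pratt = wilcoxon_signed_rank(before, after, zero_method="pratt")
    wilcox = wilcoxon_signed_rank(before, after, zero_method="wilcox")
    # Pratt keeps the zeros in the ranking, pushing the nonzero ranks up
    assert pratt.statistic > wilcox.statistic


# --------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_identical_groups():
    r = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.statistic == pytest.approx(8.0)  # n*m/2
    assert r.p_value == pytest.approx(1.0)


def test_mwu_complete_separation_exact():
    r = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(0.1)  # 2/20 orderings


def test_mwu_random_fixtures_match_enumeration():
    rng = np.random.default_rng(10)
    for _ in range(25):
        n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = rng.integers(0, 8, n).astype(float)
        b = rng.integers(0, 8, m).astype(float)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        us = np.array([
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in itertools.combinations(range(n + m), n)
        ])
        expect = min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))
        assert mann_whitney_u(a, b).p_value == pytest.approx(expect, abs=1e-12)


def test_mwu_large_n_matches_scipy():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 60), rng.normal(0.4, 1, 55)
    r = mann_whitney_u(a, b)
    assert "normal_approx" in r.flags
    assert r.p_value == pytest.approx(stats.mannwhitneyu(a, b).pvalue, rel=1e-9)


def test_mwu_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# --------------------------------------------------------------------------
# chi-square


def test_chi_square_proportional_table_is_null():
    r = pearson_chi_square([[10, 20], [20, 40]])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0)


def test_chi_square_matches_hand_formula():
    table = np.array([[12, 8], [5, 15]])
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    by_hand = ((table - exp) ** 2 / exp).sum()
    r = pearson_chi_square(table)
    assert r.statistic == pytest.approx(by_hand)
    assert r.p_value == pytest.approx(stats.chi2.sf(by_hand, 1))


def test_chi_square_reference_gender_table_is_balanced():
    # 19/23 vs 24/29 male/female split: statistic ~ 0, p rounds above .99
    r = pearson_chi_square([[19, 23], [24, 29]])
    assert r.p_value > 0.99


def test_chi_square_guards():
    with pytest.raises(ValueError, match="marginal"):
        pearson_chi_square([[0, 0], [1, 2]])
    with pytest.raises(ValueError):
        pearson_chi_square([[1, 2]])
    r = pearson_chi_square([[1, 2], [3, 4]])
    assert "low_expected_counts" in r.flags


# --------------------------------------------------------------------------
# summaries and sample size


def test_summarize_group_examples():
    assert summarize_group([1, 2, 3, 4, 5]) == {"median": 3.0, "iqr": 2.0, "n": 5}
    assert summarize_group([7.5]) == {"median": 7.5, "iqr": 0.0, "n": 1}
    assert summarize_group([None, np.nan]) is None


def test_summarize_group_matches_sort_and_interpolate_oracle():
    rng = np.random.default_rng(3)
    v = rng.uniform(0, 10, 37)
    s = summarize_group(v)
    x = np.sort(v)

    def q(p):  # type-7: linear interpolation on (n-1)p
        h = (len(x) - 1) * p
        lo = int(np.floor(h))
        return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

    assert s["median"] == pytest.approx(q(0.5))
    assert s["iqr"] == pytest.approx(q(0.75) - q(0.25))


def test_sample_size_unit_effect():
    # delta = sd: per-group 2*(z_.975+z_.80)^2 = 15.70 -> 16, total 32
    r = sample_size(delta=1.0, sd=1.0)
    assert r == {"per_group": 16, "total": 32, "inflated_total": 32}


def test_sample_size_trial_inputs_give_88():
    r = sample_size(delta=1566.0, sd=2620.0, alpha=0.05, power=0.80)
    assert r["total"] == 88


def test_sample_size_dropout_inflation():
    r = sample_size(delta=1566.0, sd=2620.0, dropout_rate=0.20)
    assert r["inflated_total"] == 110  # ceil(88 / 0.8)


def test_sample_size_guards():
    with pytest.raises(ValueError):
        sample_size(0, 1)
    with pytest.raises(ValueError):
        sample_size(1, 1, dropout_rate=1.0)


# --------------------------------------------------------------------------
# sensitivity analysis


def null_cohort(rng, n=40, n_drop=15, age_shift=0.0):
    participants = []
    for i in range(n):
        drop = i < n_drop
        age = 40 + rng.normal(0, 10) + (age_shift if drop else 0)
        steps = {
            START - dt.timedelta(days=d): float(rng.lognormal(8.4, 0.5))
            for d in range(1, 7)
        }
        participants.append(
            make_stub(
                pid=f"p{i}", group="control" if i % 2 else "intervention",
                steps=steps, dropout=4 if drop else None, age=int(np.clip(age, 18, 90)),
            )
        )
    return TrialDataset(
        config=CohortConfig(n_total=n, allocation=(n // 2, n - n // 2),
                            attrition_schedule=(n, n - n_drop, n - n_drop)),
        catalog=null_cohort.catalog,
        participants=participants,
    )


def test_sensitivity_no_dropouts_reports_status(gen_catalog):
    ds = TrialDataset(
        config=CohortConfig(n_total=4, allocation=(2, 2), attrition_schedule=(4, 4, 4)),
        catalog=gen_catalog,
        participants=[make_stub(pid=f"p{i}") for i in range(4)],
    )
    out = sensitivity_analysis(ds)
    assert "_status" in out


def test_sensitivity_mcar_type_one_error_near_alpha(gen_catalog):
    """MCAR dropout: the baseline-steps dropouts-vs-completers test should
    reject at about the nominal 5% rate across replicates."""
    null_cohort.catalog = gen_catalog
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 400
    for _ in range(reps):
        out = sensitivity_analysis(null_cohort(rng))
        rejections += out["steps_T0"]["test"].p_value < 0.05
    rate = rejections / reps
    assert 0.02 <= rate <= 0.09  # 0.05 +/- ~3 MC SE


def test_sensitivity_age_linked_dropout_detected_more_often(gen_catalog):
    null_cohort.catalog = gen_catalog
    rng = np.random.default_rng(100)
    reps = 120
    rej_null = sum(
        sensitivity_analysis(null_cohort(rng))["age"]["test"].p_value < 0.05
        for _ in range(reps)
    )
    rej_aged = sum(
        sensitivity_analysis(null_cohort(rng, age_shift=8.0))["age"]["test"].p_value < 0.05
        for _ in range(reps)
    )
    assert rej_aged > rej_null + reps * 0.1


# --------------------------------------------------------------------------
# whole-trial report smoke


def test_analyze_trial_report_shape(gen_catalog):
    from nutribasket.synthetic_data import generate_cohort

    cfg = CohortConfig(
        n_total=10, allocation=(5, 5), attrition_schedule=(9, 8, 7),
        loyalty_connect_failures=2, seed=21, n_products=625,
    )
    ds = generate_cohort(cfg, catalog=gen_catalog)
    rep = analyze_trial(ds)
    assert rep["n"] == {"intervention": 5, "control": 5}
    assert rep["completers"] == 7
    assert "steps" in rep["outcomes"] and "solid_di" in rep["outcomes"]
    by_period = rep["outcomes"]["steps"]["by_period"]
    assert by_period["T0"]["intervention"]["n"] == 5
    # complete-case discipline: every test carries its n
    for outcome in rep["outcomes"].values():
        for res in outcome["between_group"].values():
            assert res.n_used > 0
    assert rep["sample_size"]["total"] == 88
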