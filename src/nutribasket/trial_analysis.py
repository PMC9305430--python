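"""Nonparametric trial analysis: period aggregation, tests, power.

Implements the analysis machinery of a two-arm 12-week mHealth trial with
continuously collected streams: aggregation into 4-week periods (T1 =
weeks 1–4, T2 = 5–8, T3 = 9–12, with outcome-specific baselines), Wilcoxon
signed-rank within-group comparisons, Mann-Whitney U between-group
comparisons, Pearson chi-square for categorical tables, median/IQR
summaries, a dropouts-vs-completers sensitivity analysis, and the
two-sample normal-approximation sample-size formula.

Small-sample p-values are exact: the Wilcoxon null distribution is built by
a rank generating-function convolution (zero differences handled by the
Pratt method), and the Mann-Whitney null distribution by enumeration over
group-label assignments, which remains exact under ties.  Larger samples
use the tie-corrected normal approximations.  Missing values are never
imputed; every test reports the complete-case n it used.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .basket_scoring import COMPONENT_KEYS, Catalog, period_di
from .synthetic_data import SURVEY_CONSTRUCTS, ParticipantRecord, TrialDataset

__all__ = [
    "PeriodSummary",
    "TestResult",
    "aggregate_periods",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "pearson_chi_square",
    "summarize_group",
    "sample_size",
    "sensitivity_analysis",
    "simulate_trial_power",
    "analyze_trial",
    "PERIODS",
    "CONTINUOUS_OUTCOMES",
]

PERIODS = ("T0", "T1", "T2", "T3")

#: continuously collected outcomes (steps, solid DI, 6 subcategories, logins)
CONTINUOUS_OUTCOMES = ("steps", "solid_di") + tuple(
    k for k in COMPONENT_KEYS if k != "energy_pts"
) + ("logins",)


@dataclass
class PeriodSummary:
    participant_id: str
    outcome: str
    group: str
    values: dict[str, float | None]  # period -> value or None (absent)

    def get(self, period: str) -> float | None:
        return self.values.get(period)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_used: int
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# --------------------------------------------------------------------------
# period aggregation


def _week_window(start: dt.date, weeks: tuple[int, int]) -> tuple[dt.date, dt.date]:
    """Half-open date window [first day of week a, day after week b]."""
    a, b = weeks
    return (
        start + dt.timedelta(days=(a - 1) * 7),
        start + dt.timedelta(days=b * 7),
    )


_PERIOD_WEEKS = {"T1": (1, 4), "T2": (5, 8), "T3": (9, 12)}


def aggregate_periods(
    participant: ParticipantRecord,
    catalog: Catalog,
    start_date: dt.date,
    baseline_food_weeks: int = 4,
    weighting: str = "energy",
) -> dict[str, PeriodSummary]:
    """T0–T3 values of every continuously collected outcome.

    Steps: T0 is the mean of the baseline days before ``start_date``;
    T1/T2/T3 are means over available daily values in weeks 1–4 / 5–8 /
    9–12.  Food outcomes: pooled item-level DI (and component means) over
    each window, with T0 covering the ``baseline_food_weeks`` weeks before
    the start.  Logins: weekly means per period (no baseline).  Periods
    with no data are absent (None), never zero.
    """
    out: dict[str, PeriodSummary] = {}

    def put(outcome: str, values: dict[str, float | None]) -> None:
        out[outcome] = PeriodSummary(
            participant_id=participant.participant_id,
            outcome=outcome,
            group=participant.group,
            values=values,
        )

    # steps
    step_vals: dict[str, float | None] = {}
    baseline_days = [v for d, v in participant.steps.items() if d < start_date]
    step_vals["T0"] = float(np.mean(baseline_days)) if baseline_days else None
    for period, weeks in _PERIOD_WEEKS.items():
        lo, hi = _week_window(start_date, weeks)
        vals = [v for d, v in participant.steps.items() if lo <= d < hi]
        step_vals[period] = float(np.mean(vals)) if vals else None
    put("steps", step_vals)

    # food outcomes
    windows = {"T0": (start_date - dt.timedelta(days=7 * baseline_food_weeks), start_date)}
    windows.update({p: _week_window(start_date, w) for p, w in _PERIOD_WEEKS.items()})
    food: dict[str, dict[str, float | None]] = {
        o: {} for o in ("solid_di", *COMPONENT_KEYS)
    }
    for period, (lo, hi) in windows.items():
        score = (
            period_di(participant.baskets, lo, hi, catalog, weighting)
            if participant.baskets
            else None
        )
        food["solid_di"][period] = None if score is None else score.solid_di
        for k in COMPONENT_KEYS:
            food[k][period] = (
                None
                if score is None or score.component_means is None
                else score.component_means[k]
            )
    for outcome, values in food.items():
        put(outcome, values)

    # logins
    login_vals: dict[str, float | None] = {"T0": None}
    for period, (a, b) in _PERIOD_WEEKS.items():
        weekly = [participant.logins[w] for w in range(a, b + 1) if w in participant.logins]
        login_vals[period] = float(np.mean(weekly)) if weekly else None
    put("logins", login_vals)

    # surveys (T0/T3 only)
    for construct in SURVEY_CONSTRUCTS:
        s = participant.surveys.get(construct, {})
        put(construct, {"T0": s.get("T0"), "T3": s.get("T3"), "T1": None, "T2": None})

    return out


# --------------------------------------------------------------------------
# Wilcoxon signed-rank (exact via generating-function DP, Pratt zeros)


def _wilcoxon_exact_sf_counts(double_ranks: list[int]) -> np.ndarray:
    """Counts of the W+ distribution over all sign assignments.

    ``double_ranks`` are the (tied-midrank) ranks times two, so they are
    integers; the returned array c has c[w] = number of sign vectors with
    doubled W+ equal to w.
    """
    total = sum(double_ranks)
    c = np.zeros(total + 1, dtype=float)
    c[0] = 1.0
    for r in double_ranks:
        c[r:] += c[: total + 1 - r].copy()
    return c


def wilcoxon_signed_rank(
    before,
    after,
    zero_method: str = "pratt",
    exact_max_n: int = 25,
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Pairs with a missing member are dropped (complete-case).  Zero
    differences follow the Pratt method by default: they enter the ranking
    of |d| then leave the statistic ("wilcox" drops them before ranking).
    P-values are exact (conditional on the observed zero/tie pattern) for
    up to ``exact_max_n`` nonzero differences, else a normal approximation
    with zero- and tie-corrections.  All-zero differences give p = 1.
    """
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.shape != a.shape:
        raise ValueError("before and after must have equal length")
    keep = ~(np.isnan(b) | np.isnan(a))
    d = (a - b)[keep]
    n_used = int(d.size)
    flags = []
    if n_used < 5:
        flags.append("underpowered")
    if n_used == 0:
        return TestResult("wilcoxon_signed_rank", math.nan, 1.0, 0, alpha, flags + ["no_pairs"])

    if zero_method not in ("pratt", "wilcox"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        d = d[d != 0]
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n_used, alpha, flags + ["all_zero"])

    ranks = stats.rankdata(np.abs(d))  # zeros (Pratt) share the smallest ranks
    nz_mask = d != 0
    w_plus = float(ranks[nz_mask & (d > 0)].sum())

    if nz.size <= exact_max_n:
        # zeros keep their (smallest) ranks in the ranking but never enter
        # W+, so the exact null distribution is over sign flips of the
        # nonzero ranks only; doubling makes tied midranks integral
        dbl = [int(round(2 * r)) for r in ranks[nz_mask]]
        counts = _wilcoxon_exact_sf_counts(dbl)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        cum = np.cumsum(counts)
        p_le = cum[min(w2, len(counts) - 1)] / total
        p_ge = (total - (cum[w2 - 1] if w2 >= 1 else 0.0)) / total
        p = min(1.0, 2 * min(p_le, p_ge))
    else:
        n_all = ranks.size
        n0 = int((~nz_mask).sum())
        mean = (n_all * (n_all + 1) - n0 * (n0 + 1)) / 4.0
        var = (
            n_all * (n_all + 1) * (2 * n_all + 1)
            - n0 * (n0 + 1) * (2 * n0 + 1)
        ) / 24.0
        _, tie_counts = np.unique(np.abs(d[nz_mask]), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
        flags.append("normal_approx")
    return TestResult("wilcoxon_signed_rank", w_plus, float(min(p, 1.0)), n_used, alpha, flags)


# --------------------------------------------------------------------------
# Mann-Whitney U (exact via label-assignment enumeration)


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j, ties 1/2."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    group_a,
    group_b,
    exact_max_comb: int = 20000,
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for the first group).

    Exact p by enumerating all group-label assignments of the pooled values
    when their number C(n+m, n) does not exceed ``exact_max_comb`` (valid
    under ties); otherwise the tie-corrected normal approximation with
    continuity correction.  n_used is the total complete-case count.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    n, m = a.size, b.size
    u = _mwu_statistic(a, b)
    flags = []

    if math.comb(n + m, n) <= exact_max_comb:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        us = np.array(
            [ranks[list(idx)].sum() - offset for idx in combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_le = np.mean(us <= u + eps)
        p_ge = np.mean(us >= u - eps)
        p = min(1.0, 2 * min(p_le, p_ge))
    else:
        mean = n * m / 2.0
        nm = n + m
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
        var = n * m / 12.0 * (nm + 1 - tie_term)
        if var <= 0:
            return TestResult("mann_whitney_u", u, 1.0, n + m, alpha, ["degenerate"])
        z = (abs(u - mean) - 0.5) / math.sqrt(var)  # continuity-corrected
        p = min(1.0, 2 * stats.norm.sf(max(z, 0.0)))
        flags.append("normal_approx")
    return TestResult("mann_whitney_u", u, float(p), n + m, alpha, flags)


# --------------------------------------------------------------------------
# Pearson chi-square


def pearson_chi_square(table, alpha: float = 0.05) -> TestResult:
    """Pearson chi-square on an r x c count table (no Yates correction)."""
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("table must hold non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    flags = ["low_expected_counts"] if (expected < 5).any() else []
    return TestResult("pearson_chi_square", float(chi2), float(p), int(t.sum()), alpha, flags)


# --------------------------------------------------------------------------
# summaries, sample size, sensitivity


def summarize_group(values) -> dict[str, float] | None:
    """Median and IQR (Q3 − Q1, linear-interpolation/type-7 quantiles)."""
    v = np.asarray([x for x in values if x is not None and not np.isnan(x)], float)
    if v.size == 0:
        return None
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "n": int(v.size)}


def sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    dropout_rate: float = 0.0,
) -> dict[str, int]:
    """Two-sample normal-approximation sample size for a continuous outcome.

    per-group n = ceil(2·sd²·(z_{1−α/2} + z_{power})² / delta²); the total
    is doubled, and inflated by 1/(1 − dropout_rate) when anticipating
    attrition.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if dropout_rate >= 1 or dropout_rate < 0:
        raise ValueError("dropout_rate must be in [0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    per_group = math.ceil(2 * (sd / delta) ** 2 * z**2)
    total = 2 * per_group
    return {
        "per_group": per_group,
        "total": total,
        "inflated_total": math.ceil(total / (1 - dropout_rate)),
    }


_BMI_ORDER = {"<25": 0, "25-30": 1, ">30": 2}


def sensitivity_analysis(
    dataset: TrialDataset, alpha: float = 0.05
) -> dict[str, dict]:
    """Dropouts vs completers at baseline (attrition-bias check).

    Continuous variables (age, household size, baseline steps and solid DI)
    use Mann-Whitney; categorical ones (gender, BMI class) use Pearson
    chi-square.  Variables with an empty stratum are skipped with a status.
    """
    drop = dataset.dropouts
    comp = dataset.completers
    out: dict[str, dict] = {}
    if not drop or not comp:
        return {"_status": {"skipped": "a stratum is empty", "n_dropouts": len(drop), "n_completers": len(comp)}}

    start = dataset.config.start_date

    def baseline_steps(p):
        vals = [v for d, v in p.steps.items() if d < start]
        return float(np.mean(vals)) if vals else None

    def baseline_di(p):
        if not p.baskets:
            return None
        s = period_di(
            p.baskets,
            start - dt.timedelta(days=7 * dataset.config.baseline_food_weeks),
            start,
            dataset.catalog,
        )
        return None if s is None else s.solid_di

    continuous = {
        "age": lambda p: float(p.age),
        "household_size": lambda p: float(p.household_size),
        "steps_T0": baseline_steps,
        "solid_di_T0": baseline_di,
    }
    for name, f in continuous.items():
        a = [f(p) for p in drop]
        b = [f(p) for p in comp]
        a = [x for x in a if x is not None]
        b = [x for x in b if x is not None]
        if not a or not b:
            out[name] = {"status": "skipped_empty_stratum"}
            continue
        res = mann_whitney_u(a, b, alpha=alpha)
        out[name] = {
            "test": res,
            "dropouts": summarize_group(a),
            "completers": summarize_group(b),
        }

    categorical = {
        "gender": (lambda p: p.gender, ["male", "female"]),
        "bmi_class": (lambda p: p.bmi_class, ["<25", "25-30", ">30"]),
    }
    for name, (f, levels) in categorical.items():
        tab = [
            [sum(1 for p in grp if f(p) == lv) for lv in levels]
            for grp in (drop, comp)
        ]
        cols = [j for j in range(len(levels)) if sum(t[j] for t in tab) > 0]
        tab = [[row[j] for j in cols] for row in tab]
        if len(cols) < 2 or any(sum(row) == 0 for row in tab):
            out[name] = {"status": "skipped_empty_stratum"}
            continue
        out[name] = {"test": pearson_chi_square(tab, alpha=alpha), "table": tab}
    return out


# --------------------------------------------------------------------------
# power closure


def simulate_trial_power(
    n_per_group: int = 44,
    delta: float = 1566.0,
    sd: float = 2620.0,
    median0: float = 4624.0,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical Mann-Whitney power of a two-arm endpoint comparison.

    Participant endpoint means are drawn from the generator's step model — a
    lognormal with the given median, scaled so the group SD matches ``sd`` —
    and the intervention arm is shifted by ``delta``.  Returns the fraction
    of ``n_reps`` simulated trials rejecting at ``alpha`` (two-sided).
    """
    # solve e^{s²}(e^{s²} − 1) = (sd/median)² for the lognormal sigma
    r2 = (sd / median0) ** 2
    sigma = math.sqrt(math.log((1 + math.sqrt(1 + 4 * r2)) / 2))
    rng = np.random.default_rng(seed)
    mu = math.log(median0)
    rej = 0
    for _ in range(n_reps):
        a = rng.lognormal(mu, sigma, n_per_group) + delta
        b = rng.lognormal(mu, sigma, n_per_group)
        if mann_whitney_u(a, b, alpha=alpha).p_value < alpha:
            rej += 1
    return rej / n_reps


# --------------------------------------------------------------------------
# whole-trial report


def analyze_trial(dataset: TrialDataset, alpha: float = 0.05) -> dict:
    """Full trial report: per-period group summaries, within- and
    between-group tests, sensitivity analysis, and the power calculation.

    All tests are complete-case; the report mirrors the standard baseline /
    by-period / sensitivity table shapes.
    """
    start = dataset.config.start_date
    summaries: dict[str, list[PeriodSummary]] = {}
    for p in dataset.participants:
        for outcome, s in aggregate_periods(
            p, dataset.catalog, start, dataset.config.baseline_food_weeks
        ).items():
            summaries.setdefault(outcome, []).append(s)

    outcomes_report: dict[str, dict] = {}
    for outcome, rows in summaries.items():
        rep: dict[str, dict] = {"by_period": {}, "between_group": {}, "within_group": {}}
        for period in PERIODS:
            per_group = {}
            for g in ("intervention", "control"):
                vals = [r.get(period) for r in rows if r.group == g]
                per_group[g] = summarize_group(vals)
            rep["by_period"][period] = per_group
            a = [r.get(period) for r in rows if r.group == "intervention" and r.get(period) is not None]
            b = [r.get(period) for r in rows if r.group == "control" and r.get(period) is not None]
            if a and b:
                rep["between_group"][period] = mann_whitney_u(a, b, alpha=alpha)
        for g in ("intervention", "control"):
            pairs = [
                (r.get("T0"), r.get("T3"))
                for r in rows
                if r.group == g and r.get("T0") is not None and r.get("T3") is not None
            ]
            if pairs:
                before, after = zip(*pairs)
                rep["within_group"][g] = wilcoxon_signed_rank(before, after, alpha=alpha)
        outcomes_report[outcome] = rep

    demo_tables = {}
    counts = {
        g: sum(1 for p in dataset.participants if p.group == g)
        for g in ("intervention", "control")
    }
    gender_tab = [
        [
            sum(1 for p in dataset.participants if p.group == g and p.gender == sex)
            for sex in ("male", "female")
        ]
        for g in ("intervention", "control")
    ]
    if all(sum(r) for r in gender_tab) and all(sum(c) for c in zip(*gender_tab)):
        demo_tables["gender"] = {
            "table": gender_tab,
            "test": pearson_chi_square(gender_tab, alpha=alpha),
        }

    return {
        "n": counts,
        "completers": len(dataset.completers),
        "demographics": demo_tables,
        "outcomes": outcomes_report,
        "sensitivity": sensitivity_analysis(dataset, alpha=alpha),
        "sample_size": sample_size(
            delta=1566.0, sd=2620.0, alpha=0.05, power=0.80, dropout_rate=0.20
        ),
    }
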