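"""Seeded synthetic cohorts: catalogs, receipts, steps, logins, surveys.

No participant-level data from the motivating trial are publicly available,
so this module generates them: a product catalog with per-category nutrient
distributions, participant streams (daily steps, weekly-ish receipt
baskets, weekly app logins, Likert surveys at T0/T3) and a two-arm cohort
with configurable group effects and attrition.  Defaults reproduce the
trial's study conditions: 95 participants allocated 42/53, 12 intervention
weeks, baseline medians of 4624 steps/day and 6.13 solid-food FSA-NPS DI
points, a 125-category catalog, and an attrition funnel ending at 30
completers.

Steps follow a participant-level lognormal with weekly autocorrelation
(step data are right-skewed); basket composition is sampled from the
catalog with participant category preferences and an exponential tilt on
product FSA-NPS scores, calibrated by bisection so the expected
energy-weighted basket DI hits the participant's target.  Group effects are
additive per-period drifts applied to the intervention arm.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from . import reference
from .basket_scoring import Basket, Catalog, ProductRecord, ReceiptItem
from .nutrient_profiling import NutrientProfile

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "TrialDataset",
    "generate_catalog",
    "generate_participant",
    "generate_cohort",
    "SURVEY_CONSTRUCTS",
]

SURVEY_CONSTRUCTS = (
    "motivational_self_efficacy",
    "recovery_self_efficacy",
    "outcome_expectancy",
    "intrinsic_motivation",
    "extrinsic_motivation",
)

#: number of Likert items per construct (scores are item means)
_SURVEY_ITEMS = {
    "motivational_self_efficacy": 4,
    "recovery_self_efficacy": 2,
    "outcome_expectancy": 6,
    "intrinsic_motivation": 3,
    "extrinsic_motivation": 3,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated trial.

    Attrition is expressed as the number of participants still delivering
    data in each 4-week period (T1, T2, T3); the last entry is the
    completer count.  Group effects are additive drifts per period applied
    to the intervention arm: ``group_effect_steps`` in steps/day,
    ``group_effect_di`` in DI points (negative = healthier).
    """

    n_total: int = 95
    allocation: tuple[int, int] = (42, 53)
    weeks: int = 12
    baseline_step_days: int = 6
    baseline_food_weeks: int = 4
    group_effect_steps: float = 0.0
    group_effect_di: float = 0.0
    attrition_schedule: tuple[int, ...] = (78, 42, 30)
    loyalty_connect_failures: int = 28
    age_dropout_beta: float = 0.0  # >0 links dropout to older age
    start_date: dt.date = dt.date(2020, 11, 16)
    seed: int = 0
    # catalog scale (desk-scale emulation of a 55,000-product database)
    n_products: int = 2000
    n_categories: int = 125
    # step noise model (lognormal, participant random effect, weekly AR(1))
    step_median: float = reference.BASELINE["steps"]["median"]
    step_sigma_between: float = 0.6
    step_sigma_week: float = 0.25
    step_weekly_rho: float = 0.5
    step_sigma_day: float = 0.35
    # basket model
    di_mean: float = reference.BASELINE["solid_di"]["median"]
    di_sd_between: float = 2.5
    di_sd_basket: float = 0.8
    items_per_basket: float = 15.0
    beverage_prob: float = 0.5  # chance a basket carries one beverage item

    def __post_init__(self) -> None:
        if sum(self.allocation) != self.n_total:
            raise ValueError(
                f"allocation {self.allocation} must sum to n_total {self.n_total}"
            )
        sched = (self.n_total, *self.attrition_schedule)
        if any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError(
                f"retention must be non-increasing, got {self.attrition_schedule}"
            )
        if len(self.attrition_schedule) != 3:
            raise ValueError("attrition_schedule must give T1, T2, T3 counts")


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str  # "intervention" | "control"
    age: int
    gender: str  # "female" | "male"
    bmi_class: str  # "<25" | "25-30" | ">30"
    household_size: int
    steps: dict[dt.date, float]
    baskets: list[Basket]
    logins: dict[int, int]  # week index (1-based) -> login count
    surveys: dict[str, dict[str, float | None]]
    dropout_week: int | None  # no data after this week; None = completer
    food_connected: bool = True


@dataclass
class TrialDataset:
    config: CohortConfig
    catalog: Catalog
    participants: list[ParticipantRecord]

    @property
    def completers(self) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.dropout_week is None]

    @property
    def dropouts(self) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.dropout_week is not None]


# --------------------------------------------------------------------------
# catalog generation


def generate_catalog(
    n_products: int = 2000,
    n_categories: int = 125,
    seed: int = 0,
    beverage_category_fraction: float = 0.08,
) -> Catalog:
    """Random product catalog with per-category nutrient distributions.

    Each category draws archetype nutrient means once; products scatter
    around them, giving within-category FSA-NPS score spread so healthier
    in-category substitutes exist.  The trailing
    ``beverage_category_fraction`` of categories holds beverages.  Every
    category is non-empty (requires ``n_products >= n_categories``).
    """
    if n_products < n_categories:
        raise ValueError(
            f"n_products ({n_products}) must be >= n_categories ({n_categories})"
        )
    rng = np.random.default_rng(seed)
    n_bev = max(1, int(round(beverage_category_fraction * n_categories)))
    bev_cats = set(range(n_categories - n_bev + 1, n_categories + 1))

    cat_means = {}
    for cat in range(1, n_categories + 1):
        is_bev = cat in bev_cats
        fvln_rich = rng.random() < 0.3
        cat_means[cat] = {
            "energy_kj": rng.uniform(60, 400) if is_bev else rng.uniform(150, 2600),
            "sugars_g": rng.uniform(0, 12) if is_bev else rng.uniform(0, 35),
            "satfat_g": 0.0 if is_bev else rng.uniform(0, 12),
            "sodium_mg": rng.uniform(0, 60) if is_bev else rng.uniform(0, 1000),
            "fvln_pct": rng.uniform(40, 95) if fvln_rich else rng.uniform(0, 20),
            "fiber_g": rng.uniform(0, 6),
            "protein_g": rng.uniform(0, 4) if is_bev else rng.uniform(0, 20),
            "is_beverage": is_bev,
        }

    # one product per category first, remainder spread uniformly
    cats = list(range(1, n_categories + 1))
    extra = rng.integers(1, n_categories + 1, size=n_products - n_categories)
    assignment = cats + extra.tolist()

    unit_masses = np.array([100, 150, 200, 250, 300, 400, 500, 750, 1000], float)
    products = []
    for i, cat in enumerate(assignment, start=1):
        m = cat_means[cat]
        profile = NutrientProfile(
            energy_kj=float(np.clip(rng.normal(m["energy_kj"], 0.30 * m["energy_kj"] + 50), 0, 3900)),
            sugars_g=float(np.clip(rng.normal(m["sugars_g"], 0.5 * m["sugars_g"] + 1.5), 0, 95)),
            satfat_g=float(np.clip(rng.normal(m["satfat_g"], 0.4 * m["satfat_g"] + 0.5), 0, 60)),
            sodium_mg=float(np.clip(rng.normal(m["sodium_mg"], 0.4 * m["sodium_mg"] + 40), 0, 3500)),
            fvln_pct=float(np.clip(rng.normal(m["fvln_pct"], 12.0), 0, 100)),
            fiber_g=float(np.clip(rng.normal(m["fiber_g"], 1.2), 0, 25)),
            protein_g=float(np.clip(rng.normal(m["protein_g"], 0.4 * m["protein_g"] + 1.0), 0, 60)),
            is_beverage=bool(m["is_beverage"]),
        )
        products.append(
            ProductRecord(
                product_id=f"P{i:05d}",
                name=f"Product {i:05d} (category {cat})",
                category_id=int(cat),
                profile=profile,
                unit_mass_g=float(rng.choice(unit_masses)),
            )
        )
    return Catalog(products, n_categories=n_categories)


# --------------------------------------------------------------------------
# participant generation


class _BasketSampler:
    """Samples basket items whose expected solid DI hits a target.

    Item probabilities are participant category preferences times an
    exponential tilt ``exp(-lam * score)``; ``lam`` is solved by bisection
    on the energy-weighted expected score (monotone in ``lam``).
    """

    LAM_RANGE = (-3.0, 3.0)

    def __init__(self, catalog: Catalog, prefs: np.ndarray):
        solids = [p for p in catalog if not p.profile.is_beverage]
        self.solid_ids = [p.product_id for p in solids]
        self.scores = np.array([catalog.fsa_score(p.product_id) for p in solids], float)
        mass = np.array([p.unit_mass_g for p in solids])
        energy = np.array([p.profile.energy_kj for p in solids])
        self.base_p = prefs[np.array([p.category_id - 1 for p in solids])]
        self.base_p = self.base_p / self.base_p.sum()
        self.energy_w = mass * energy / 100.0
        self.bev_ids = [p.product_id for p in catalog if p.profile.is_beverage]
        self._lam_cache: dict[float, np.ndarray] = {}

    def _expected_di(self, lam: float) -> float:
        w = self.base_p * np.exp(-lam * self.scores) * self.energy_w
        return float(np.dot(w, self.scores) / w.sum())

    def probs_for_target(self, target: float) -> np.ndarray:
        key = round(target, 2)
        if key in self._lam_cache:
            return self._lam_cache[key]
        lo, hi = self.LAM_RANGE
        # expected DI is decreasing in lam; clip infeasible targets
        t = min(max(target, self._expected_di(hi)), self._expected_di(lo))
        a, b = lo, hi
        for _ in range(40):
            mid = 0.5 * (a + b)
            if self._expected_di(mid) > t:
                a = mid
            else:
                b = mid
        lam = 0.5 * (a + b)
        q = self.base_p * np.exp(-lam * self.scores)
        q = q / q.sum()
        self._lam_cache[key] = q
        return q


def _likert(rng: np.random.Generator, mean: float, n_items: int, sd: float = 1.3) -> float:
    items = np.clip(np.rint(rng.normal(mean, sd, size=n_items)), 1, 7)
    return float(items.mean())


def generate_participant(
    config: CohortConfig,
    group: str,
    catalog: Catalog,
    seed: int | np.random.SeedSequence,
    participant_id: str = "p001",
    dropout_week: int | None = None,
    food_connected: bool = True,
) -> ParticipantRecord:
    """One participant's streams under the configured study conditions.

    ``dropout_week = k`` truncates all post-baseline streams after week
    ``k`` (0 = baseline only); baseline data are always present.  Group
    effects apply to the intervention arm only, as additive per-period
    drifts (period = ceil(week/4)).
    """
    if group not in ("intervention", "control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    start = config.start_date

    age = int(np.clip(np.rint(rng.normal(45, 14)), 18, 85))
    gender = "female" if rng.random() < 0.55 else "male"
    bmi_class = str(rng.choice(["<25", "25-30", ">30"], p=[0.59, 0.29, 0.12]))
    household = int(np.clip(rng.geometric(0.45), 1, 6))

    active_weeks = config.weeks if dropout_week is None else min(dropout_week, config.weeks)
    drift_on = group == "intervention"

    # ---- steps: lognormal, participant effect, weekly AR(1), daily noise.
    # The anchor is the median of participant *mean* steps/day; a mean of
    # exp(level + N(0, s_day)) exceeds exp(level) by e^{s_day^2/2}, so the
    # log-median is shifted down by that factor.
    mu_p = (
        np.log(config.step_median)
        - config.step_sigma_day**2 / 2.0
        + rng.normal(0.0, config.step_sigma_between)
    )
    steps: dict[dt.date, float] = {}
    level = mu_p + rng.normal(0.0, config.step_sigma_week)
    for d in range(config.baseline_step_days, 0, -1):
        day = start - dt.timedelta(days=d)
        steps[day] = float(np.exp(level + rng.normal(0.0, config.step_sigma_day)))
    rho, sw = config.step_weekly_rho, config.step_sigma_week
    for week in range(1, active_weeks + 1):
        period = (week - 1) // 4 + 1
        shift = period * config.group_effect_steps if drift_on else 0.0
        level = mu_p + rho * (level - mu_p) + rng.normal(0.0, sw * np.sqrt(1 - rho**2))
        for dow in range(7):
            day = start + dt.timedelta(days=(week - 1) * 7 + dow)
            val = np.exp(level + rng.normal(0.0, config.step_sigma_day)) + shift
            steps[day] = float(max(val, 0.0))

    # ---- baskets
    baskets: list[Basket] = []
    if food_connected:
        prefs = rng.dirichlet(np.full(config.n_categories, 0.3))
        sampler = _BasketSampler(catalog, prefs)
        di_lo = sampler._expected_di(sampler.LAM_RANGE[1])
        di_hi = sampler._expected_di(sampler.LAM_RANGE[0])
        b_p = float(np.clip(rng.normal(config.di_mean, config.di_sd_between), di_lo, di_hi))
        k = 0

        def make_basket(date: dt.date, target: float) -> Basket:
            nonlocal k
            k += 1
            n_items = 1 + rng.poisson(config.items_per_basket - 1)
            q = sampler.probs_for_target(target)
            idx = rng.choice(len(q), size=n_items, p=q)
            items = [ReceiptItem(product_id=sampler.solid_ids[i]) for i in idx]
            if sampler.bev_ids and rng.random() < config.beverage_prob:
                items.append(
                    ReceiptItem(product_id=sampler.bev_ids[rng.integers(len(sampler.bev_ids))])
                )
            return Basket(
                basket_id=f"{participant_id}-B{k:03d}",
                participant_id=participant_id,
                timestamp=date,
                items=tuple(items),
                retailer="A" if rng.random() < 0.5 else "B",
            )

        for j in range(1, config.baseline_food_weeks + 1):
            date = start - dt.timedelta(days=28 - (j - 1) * 7 - int(rng.integers(0, 7)))
            target = b_p + rng.normal(0.0, config.di_sd_basket)
            baskets.append(make_basket(date, target))
        for week in range(1, active_weeks + 1):
            period = (week - 1) // 4 + 1
            shift = period * config.group_effect_di if drift_on else 0.0
            date = start + dt.timedelta(days=(week - 1) * 7 + int(rng.integers(0, 7)))
            target = b_p + shift + rng.normal(0.0, config.di_sd_basket)
            baskets.append(make_basket(date, target))
        baskets.sort(key=lambda b: (b.timestamp, b.basket_id))

    # ---- logins (weekly) and surveys
    person_rate = float(np.exp(rng.normal(0.0, 0.4)))
    period_rate = {1: 4.5, 2: 1.5, 3: 1.5}
    logins = {
        week: int(rng.poisson(period_rate[(week - 1) // 4 + 1] * person_rate))
        for week in range(1, active_weeks + 1)
    }

    surveys: dict[str, dict[str, float | None]] = {}
    for construct in SURVEY_CONSTRUCTS:
        m = reference.BASELINE[construct]["median"]
        t0 = _likert(rng, m, _SURVEY_ITEMS[construct])
        t3 = (
            _likert(rng, t0 + rng.normal(0.0, 0.8), _SURVEY_ITEMS[construct])
            if dropout_week is None
            else None
        )
        surveys[construct] = {"T0": t0, "T3": t3}

    return ParticipantRecord(
        participant_id=participant_id,
        group=group,
        age=age,
        gender=gender,
        bmi_class=bmi_class,
        household_size=household,
        steps=steps,
        baskets=baskets,
        logins=logins,
        surveys=surveys,
        dropout_week=dropout_week,
        food_connected=food_connected,
    )


# --------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig, catalog: Catalog | None = None) -> TrialDataset:
    """Two-arm cohort honoring allocation and the attrition funnel exactly.

    Group sizes match ``config.allocation``; the number of participants
    with data in each period matches ``config.attrition_schedule`` exactly
    (dropout is assigned MCAR by default, or weighted by age when
    ``age_dropout_beta > 0``).  Fully deterministic given the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    cat_seed, assign_seed, *p_seeds = ss.spawn(2 + config.n_total)
    if catalog is None:
        catalog = generate_catalog(config.n_products, config.n_categories, seed=cat_seed)
    rng = np.random.default_rng(assign_seed)

    ids = [f"p{i:03d}" for i in range(1, config.n_total + 1)]
    order = rng.permutation(config.n_total)
    groups = {}
    for rank, i in enumerate(order):
        groups[ids[i]] = "intervention" if rank < config.allocation[0] else "control"

    # provisional ages drive (optional) age-linked dropout; regenerated
    # identically inside generate_participant from the same child seed
    ages = {
        pid: int(np.clip(np.rint(np.random.default_rng(s).normal(45, 14)), 18, 85))
        for pid, s in zip(ids, p_seeds)
    }

    def pick_retained(pool: list[str], n_keep: int) -> set[str]:
        if config.age_dropout_beta <= 0:
            keep = rng.choice(len(pool), size=n_keep, replace=False)
        else:
            a = np.array([ages[pid] for pid in pool], float)
            z = (a - a.mean()) / (a.std() or 1.0)
            w = np.exp(-config.age_dropout_beta * z)  # younger more likely to stay
            keep = rng.choice(len(pool), size=n_keep, replace=False, p=w / w.sum())
        return {pool[i] for i in keep}

    pool = list(ids)
    dropout_week: dict[str, int | None] = {pid: None for pid in ids}
    for period, n_keep in enumerate(config.attrition_schedule, start=1):
        retained = pick_retained(pool, n_keep)
        for pid in pool:
            if pid not in retained:
                dropout_week[pid] = (period - 1) * 4
        pool = sorted(retained)

    n_fail = min(config.loyalty_connect_failures, config.n_total)
    failed = {ids[i] for i in rng.choice(config.n_total, size=n_fail, replace=False)}

    participants = [
        generate_participant(
            config,
            group=groups[pid],
            catalog=catalog,
            seed=s,
            participant_id=pid,
            dropout_week=dropout_week[pid],
            food_connected=pid not in failed,
        )
        for pid, s in zip(ids, p_seeds)
    ]
    return TrialDataset(config=config, catalog=catalog, participants=participants)
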