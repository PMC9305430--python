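"""Future-self avatar feature states from steps and basket history.

The avatar shows the user aged +20 years with five health features, each in
one of five states (5 = best).  Drivers follow the intervention's system
rules: fitness is the mean steps/day over the past 7 days; the four
nutritional features are weighted combinations of FSA-NPS component-point
means over the past 12 baskets —

    heart health      = 50 % sodium points + 50 % saturated-fat points
    mental well-being = 50 % fruit/vegetable points + 50 % fiber points
    bone health       = 100 % protein points
    blood sugar       = 100 % sugar points

Negative-point drivers (heart health, blood sugar) worsen as points rise;
positive-point drivers and steps improve as they rise.  State cut-offs are
a package default (overridable via config): the fitness bands are anchored
on the intervention's >=7500 steps/day activity target, point drivers use
equal bins over their scales.  Missing data yields an explicit "no data"
condition, never the worst state.
"""

from __future__ import annotations

import datetime as dt
import logging
from bisect import bisect_right
from dataclasses import dataclass

from .basket_scoring import Basket, Catalog, rolling_component_means

__all__ = [
    "FEATURES",
    "AvatarFeature",
    "AvatarState",
    "StateThresholds",
    "DEFAULT_THRESHOLDS",
    "compute_drivers",
    "map_state",
    "feedback_message",
    "compute_avatar_state",
]

log = logging.getLogger(__name__)

FEATURES = (
    "fitness_state",
    "heart_health",
    "mental_wellbeing",
    "bone_health",
    "blood_sugar",
)

#: (component-mean key, weight) pairs defining each nutritional driver
DRIVER_WEIGHTS: dict[str, tuple[tuple[str, float], ...]] = {
    "heart_health": (("sodium_pts", 0.5), ("satfat_pts", 0.5)),
    "mental_wellbeing": (("fvln_pts", 0.5), ("fiber_pts", 0.5)),
    "bone_health": (("protein_pts", 1.0),),
    "blood_sugar": (("sugar_pts", 1.0),),
}

#: driver domain per feature: (kind, lo, hi); "higher_better" direction
_DRIVER_KIND = {
    "fitness_state": ("steps", 0.0, float("inf"), True),
    "heart_health": ("negative_points", 0.0, 10.0, False),
    "mental_wellbeing": ("positive_points", 0.0, 5.0, True),
    "bone_health": ("positive_points", 0.0, 5.0, True),
    "blood_sugar": ("negative_points", 0.0, 10.0, False),
}

STEPS_WINDOW_DAYS = 7
BASKETS_WINDOW = 12


@dataclass(frozen=True)
class StateThresholds:
    """Ordered state boundaries per feature, lower-inclusive.

    For an ascending feature (higher driver is better) the boundaries are
    increasing and state = 1 + number of boundaries <= driver; for a
    descending feature they are decreasing and state = 1 + number of
    boundaries > driver.  Four boundaries yield five states.
    """

    boundaries: dict[str, tuple[float, float, float, float]]

    def state_for(self, feature: str, driver: float) -> int:
        bs = self.boundaries[feature]
        ascending = _DRIVER_KIND[feature][3]
        if ascending:
            return 1 + bisect_right(sorted(bs), driver)
        return 1 + sum(1 for b in bs if b > driver)


DEFAULT_THRESHOLDS = StateThresholds(
    boundaries={
        "fitness_state": (2500.0, 5000.0, 7500.0, 10000.0),
        "heart_health": (8.0, 6.0, 4.0, 2.0),
        "mental_wellbeing": (1.0, 2.0, 3.0, 4.0),
        "bone_health": (1.0, 2.0, 3.0, 4.0),
        "blood_sugar": (8.0, 6.0, 4.0, 2.0),
    }
)


@dataclass(frozen=True)
class AvatarFeature:
    name: str
    driver: float | None  # None <=> no data
    state: int | None  # None <=> no data
    window_used: int

    @property
    def has_data(self) -> bool:
        return self.state is not None


@dataclass(frozen=True)
class AvatarState:
    features: dict[str, AvatarFeature]
    avatar_age: float
    as_of: dt.date

    def __post_init__(self) -> None:
        if set(self.features) != set(FEATURES):
            raise ValueError("exactly one feature per enum value required")

    def as_dict(self) -> dict:
        return {
            "as_of": self.as_of.isoformat(),
            "avatar_age": self.avatar_age,
            "features": {
                f.name: {
                    "driver": f.driver,
                    "state": f.state,
                    "window_used": f.window_used,
                }
                for f in self.features.values()
            },
        }


def compute_drivers(
    step_history: dict[dt.date, float],
    basket_history: list[Basket],
    catalog: Catalog,
    as_of: dt.date,
    weighting: str = "energy",
) -> dict[str, tuple[float | None, int]]:
    """Per-feature (driver, window_used) as of a date.

    The fitness driver is the mean steps/day over the 7 calendar days ending
    at ``as_of`` (inclusive), using the days with data; nutritional drivers
    combine the rolling component means of the 12 most recent baskets dated
    on or before ``as_of``.  A feature with no data in its window maps to
    ``(None, 0)``.
    """
    window_start = as_of - dt.timedelta(days=STEPS_WINDOW_DAYS - 1)
    step_days = [
        v for d, v in step_history.items() if window_start <= d <= as_of
    ]
    drivers: dict[str, tuple[float | None, int]] = {}
    if step_days:
        drivers["fitness_state"] = (sum(step_days) / len(step_days), len(step_days))
    else:
        drivers["fitness_state"] = (None, 0)

    past = sorted(
        (b for b in basket_history if b.timestamp <= as_of),
        key=lambda b: (b.timestamp, b.basket_id),
    )
    rolled = rolling_component_means(past, BASKETS_WINDOW, catalog, weighting)
    for feat, weights in DRIVER_WEIGHTS.items():
        if rolled.means is None:
            drivers[feat] = (None, 0)
        else:
            drivers[feat] = (
                sum(w * rolled.means[k] for k, w in weights),
                rolled.used,
            )
    return drivers


def map_state(
    driver: float, feature: str, thresholds: StateThresholds | None = None
) -> int:
    """Map a driver value onto a 1..5 state (5 best), lower-inclusive bands."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    _, lo, hi, _ = _DRIVER_KIND[feature]
    if not lo <= driver <= hi:
        raise ValueError(
            f"{feature}: driver {driver!r} outside domain [{lo}, {hi}]"
        )
    return thresholds.state_for(feature, driver)


_TEMPLATES: dict[tuple[str, int | None], str] = {
    ("fitness_state", 5): "You were very active last week and took an average {driver:,.0f} steps/day! Physical activity improves your heart health, strengthens your bones, and also benefits your mental well-being! Well done, next week you can do even more.",
    ("fitness_state", 4): "Great pace — {driver:,.0f} steps/day last week. You are close to a very active week; a short daily walk will get you there.",
    ("fitness_state", 3): "You averaged {driver:,.0f} steps/day last week. Nice base! Aim for 7,500 steps a day to unlock real health benefits.",
    ("fitness_state", 2): "You took about {driver:,.0f} steps/day last week. Every extra walk counts — try adding one stop on foot each day.",
    ("fitness_state", 1): "You averaged {driver:,.0f} steps/day last week. Small steps add up: a ten-minute stroll today is a great start.",
    ("heart_health", 5): "Your recent baskets were low in salt and saturated fat ({driver:.1f} points). Your future heart thanks you — keep it up!",
    ("heart_health", 4): "Salt and saturated fat in your baskets are on a good track ({driver:.1f} points). A little less cheese or cured meat gets you to the top.",
    ("heart_health", 3): "Your baskets carry a moderate amount of salt and saturated fat ({driver:.1f} points). Swapping one salty snack for nuts or fruit helps your heart.",
    ("heart_health", 2): "Salt and saturated fat are adding up in your baskets ({driver:.1f} points). Lower-salt alternatives of your favourites can make a real difference.",
    ("heart_health", 1): "Your recent baskets were rich in salt and saturated fat ({driver:.1f} points). You can turn this around — start with one lower-salt swap this week.",
    ("mental_wellbeing", 5): "Plenty of fruit, vegetables and fiber in your baskets ({driver:.1f} points) — that nourishes body and mind. Wonderful!",
    ("mental_wellbeing", 4): "Good amounts of fruit, vegetables and fiber ({driver:.1f} points). One more portion of veggies a day and you are at the top.",
    ("mental_wellbeing", 3): "A fair share of fruit, vegetables and fiber ({driver:.1f} points). Adding a salad or whole-grain bread lifts your well-being further.",
    ("mental_wellbeing", 2): "Fruit, vegetables and fiber were a small part of your baskets ({driver:.1f} points). Try putting two colourful vegetables in your next basket.",
    ("mental_wellbeing", 1): "Your baskets had little fruit, vegetables or fiber ({driver:.1f} points). A few fresh items in your next shop is an easy win for your mood and health.",
    ("bone_health", 5): "Your baskets provide plenty of protein ({driver:.1f} points) — strong support for your bones and muscles!",
    ("bone_health", 4): "Solid protein in your baskets ({driver:.1f} points). Legumes, dairy or fish keep your bones well supplied.",
    ("bone_health", 3): "Moderate protein in your baskets ({driver:.1f} points). A portion of beans, yogurt or fish a day strengthens your future bones.",
    ("bone_health", 2): "Protein was a small part of your baskets ({driver:.1f} points). Adding lentils, eggs or dairy helps your bones stay strong.",
    ("bone_health", 1): "Your baskets contained little protein ({driver:.1f} points). Your bones will love a protein boost — beans and dairy are easy options.",
    ("blood_sugar", 5): "Very little added sugar in your recent baskets ({driver:.1f} points) — excellent for steady blood sugar!",
    ("blood_sugar", 4): "Sugar in your baskets is nicely low ({driver:.1f} points). Keep choosing the less sweet option and you stay on top.",
    ("blood_sugar", 3): "A moderate amount of sugar in your baskets ({driver:.1f} points). Swapping one sweet snack for fruit keeps your blood sugar happy.",
    ("blood_sugar", 2): "Sugar is adding up in your baskets ({driver:.1f} points). Smaller packs or less sweet alternatives are an easy improvement.",
    ("blood_sugar", 1): "Your recent baskets were high in sugar ({driver:.1f} points). You can change this one product at a time — your future self will notice.",
    ("fitness_state", None): "No step data yet — allow the app to read your phone's step counter to bring your avatar to life.",
    ("heart_health", None): "No purchase data yet — connect your loyalty card so your avatar can reflect your shopping.",
    ("mental_wellbeing", None): "No purchase data yet — connect your loyalty card so your avatar can reflect your shopping.",
    ("bone_health", None): "No purchase data yet — connect your loyalty card so your avatar can reflect your shopping.",
    ("blood_sugar", None): "No purchase data yet — connect your loyalty card so your avatar can reflect your shopping.",
}

_FALLBACK = "Keep going — every healthy choice shapes your future self."


def feedback_message(
    feature: AvatarFeature, templates: dict | None = None
) -> str:
    """Encouraging feedback for a feature, driver value interpolated."""
    pack = templates or _TEMPLATES
    key = (feature.name, feature.state)
    tpl = pack.get(key)
    if tpl is None:
        log.warning("missing feedback template for %s", key)
        return _FALLBACK
    if feature.driver is None:
        return tpl
    return tpl.format(driver=feature.driver)


def compute_avatar_state(
    step_history: dict[dt.date, float],
    basket_history: list[Basket],
    catalog: Catalog,
    as_of: dt.date,
    user_age: float,
    thresholds: StateThresholds | None = None,
    weighting: str = "energy",
) -> AvatarState:
    """Full avatar state (all five features) as of a date; age shifted +20 y."""
    drivers = compute_drivers(step_history, basket_history, catalog, as_of, weighting)
    feats = {}
    for name in FEATURES:
        driver, used = drivers[name]
        state = None if driver is None else map_state(driver, name, thresholds)
        feats[name] = AvatarFeature(name=name, driver=driver, state=state, window_used=used)
    return AvatarState(features=feats, avatar_age=user_age + 20, as_of=as_of)
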