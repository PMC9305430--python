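"""Personalized basket analysis: problem categories, substitutes, tips.

Over a user's most recent baskets (default 7) the engine attributes the
four negative FSA-NPS dimensions — sugar, sodium, saturated fat and energy
density — to food categories.  For dimension ``d`` and category ``c``,

    contribution(c, d) = sum_{items in c} mass_i * points_d(i) / total mass

so contributions over all categories sum exactly to the mass-weighted mean
points of the pooled item set (conservation).  The combined contribution is
the unweighted mean over the four dimensions.  Up to four top categories
are reported, each with healthier in-category substitutes (strictly lower
FSA-NPS score than the user's purchases) and a nutrition tip keyed to the
top category; mapped tips rotate across calls so repeat visits see fresh
advice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .basket_scoring import Basket, Catalog, ProductRecord, UnknownProductError

__all__ = [
    "NEGATIVE_DIMENSIONS",
    "CategoryContribution",
    "RecommendationReport",
    "TipPack",
    "category_contributions",
    "rank_problem_categories",
    "healthier_alternatives",
    "select_tip",
    "recommend",
]

#: component-point keys of the four negative dimensions
NEGATIVE_DIMENSIONS = ("sugar_pts", "sodium_pts", "satfat_pts", "energy_pts")

RECOMMENDER_BASKETS = 7
MAX_PROBLEM_CATEGORIES = 4


@dataclass(frozen=True)
class CategoryContribution:
    category_id: int
    per_dimension: dict[str, float]
    combined: float
    share_of_mass: float


@dataclass
class RecommendationReport:
    problem_categories: list[CategoryContribution]
    alternatives: dict[int, list[ProductRecord]]
    tip_id: str
    baskets_used: int
    status: str = "ok"


def category_contributions(
    baskets: list[Basket], catalog: Catalog, max_baskets: int = RECOMMENDER_BASKETS
) -> tuple[list[CategoryContribution], int]:
    """Mass-weighted negative-point contributions per category.

    Items of the ``max_baskets`` most recent baskets are pooled (baskets
    must be sorted by timestamp).  Returns (contributions, baskets_used);
    an empty item pool yields ``([], 0)``.
    """
    window = baskets[-max_baskets:] if max_baskets else list(baskets)
    pairs = []  # (category, mass, points)
    for b in window:
        for it in b.items:
            if it.product_id not in catalog:
                raise UnknownProductError([it.product_id])
            p = catalog.get(it.product_id)
            m = it.resolved_mass(p)
            if m > 0:
                pairs.append((p.category_id, m, catalog.points(it.product_id)))
    total_mass = sum(m for _, m, _ in pairs)
    if total_mass <= 0:
        return [], 0

    acc: dict[int, dict[str, float]] = {}
    mass_by_cat: dict[int, float] = {}
    for cat, m, pts in pairs:
        row = acc.setdefault(cat, {d: 0.0 for d in NEGATIVE_DIMENSIONS})
        for d in NEGATIVE_DIMENSIONS:
            row[d] += m * getattr(pts, d)
        mass_by_cat[cat] = mass_by_cat.get(cat, 0.0) + m

    out = []
    for cat in sorted(acc):
        per_dim = {d: acc[cat][d] / total_mass for d in NEGATIVE_DIMENSIONS}
        combined = sum(per_dim.values()) / len(NEGATIVE_DIMENSIONS)
        out.append(
            CategoryContribution(
                category_id=cat,
                per_dimension=per_dim,
                combined=combined,
                share_of_mass=mass_by_cat[cat] / total_mass,
            )
        )
    return out, len(window)


def rank_problem_categories(
    contributions: list[CategoryContribution], k: int = MAX_PROBLEM_CATEGORIES
) -> list[CategoryContribution]:
    """Top-k categories by combined contribution.

    Descending by combined contribution; ties broken by larger mass share,
    then smaller category id.  Zero-contribution categories never rank.
    """
    ranked = sorted(
        (c for c in contributions if c.combined > 0),
        key=lambda c: (-c.combined, -c.share_of_mass, c.category_id),
    )
    return ranked[:k]


def healthier_alternatives(
    category_id: int,
    purchased: list[tuple[ProductRecord, float]],
    catalog: Catalog,
    n_max: int = 5,
) -> list[ProductRecord]:
    """Same-category products scoring strictly below the user's purchases.

    ``purchased`` is (product, mass) pairs for the user's items in the
    category; the benchmark is their mass-weighted mean FSA-NPS score.
    Candidates are sorted ascending by score (best first), ties by product
    id, purchased products excluded, truncated to ``n_max``.
    """
    in_cat = [(p, m) for p, m in purchased if p.category_id == category_id]
    if not in_cat:
        return []
    tot = sum(m for _, m in in_cat)
    if tot <= 0:
        return []
    benchmark = sum(m * catalog.fsa_score(p.product_id) for p, m in in_cat) / tot
    bought_ids = {p.product_id for p, _ in in_cat}
    cands = [
        p
        for p in catalog.in_category(category_id)
        if p.product_id not in bought_ids
        and catalog.fsa_score(p.product_id) < benchmark
    ]
    cands.sort(key=lambda p: (catalog.fsa_score(p.product_id), p.product_id))
    return cands[:n_max]


@dataclass
class TipPack:
    """Nutrition tips keyed by category, with rotation across calls.

    ``by_category`` maps category id to an ordered list of tip ids; each
    successful selection advances that category's cursor so consecutive
    calls cycle through every mapped tip before repeating.
    """

    by_category: dict[int, list[str]]
    fallback: str = "tip-generic-balance"
    _cursors: dict[int, int] = field(default_factory=dict, repr=False)

    def next_tip(self, category_id: int) -> str | None:
        tips = self.by_category.get(category_id)
        if not tips:
            return None
        i = self._cursors.get(category_id, 0)
        self._cursors[category_id] = i + 1
        return tips[i % len(tips)]


def select_tip(
    top_categories: list[CategoryContribution], tip_pack: TipPack
) -> str:
    """Tip for the highest-ranked category with a mapped tip; else fallback."""
    for c in top_categories:
        tip = tip_pack.next_tip(c.category_id)
        if tip is not None:
            return tip
    return tip_pack.fallback


def recommend(
    baskets: list[Basket],
    catalog: Catalog,
    tip_pack: TipPack | None = None,
    k: int = MAX_PROBLEM_CATEGORIES,
    n_alternatives: int = 5,
    max_baskets: int = RECOMMENDER_BASKETS,
) -> RecommendationReport:
    """Full basket analysis over the last ``max_baskets`` receipts."""
    tip_pack = tip_pack if tip_pack is not None else TipPack(by_category={})
    contributions, used = category_contributions(baskets, catalog, max_baskets)
    if not contributions:
        return RecommendationReport(
            problem_categories=[],
            alternatives={},
            tip_id=tip_pack.fallback,
            baskets_used=used,
            status="no_scoreable_items",
        )
    top = rank_problem_categories(contributions, k)

    window = baskets[-max_baskets:] if max_baskets else list(baskets)
    purchased_by_cat: dict[int, dict[str, float]] = {}
    for b in window:
        for it in b.items:
            p = catalog.get(it.product_id)
            m = it.resolved_mass(p)
            if m > 0:
                purchased_by_cat.setdefault(p.category_id, {})
                purchased_by_cat[p.category_id][p.product_id] = (
                    purchased_by_cat[p.category_id].get(p.product_id, 0.0) + m
                )

    alternatives = {}
    for c in top:
        pur = [
            (catalog.get(pid), m)
            for pid, m in purchased_by_cat.get(c.category_id, {}).items()
        ]
        alternatives[c.category_id] = healthier_alternatives(
            c.category_id, pur, catalog, n_alternatives
        )
    return RecommendationReport(
        problem_categories=top,
        alternatives=alternatives,
        tip_id=select_tip(top, tip_pack),
        baskets_used=used,
    )
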