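"""Receipt baskets and their FSA-NPS dietary-index (DI) scores.

A basket is one digital loyalty-card receipt.  Its dietary index is the
intake-weighted mean of the per-product FSA-NPS scores over the scoreable
items, computed separately for solid foods and beverages (headline results
use solids only).  Weighting defaults to purchased energy, following the
energy-intake-weighted DI construction; purchased mass is available as an
alternative mode.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .nutrient_profiling import (
    BandTable,
    ComponentPoints,
    NutrientProfile,
    default_band_table,
    score_profile,
)

__all__ = [
    "ProductRecord",
    "ReceiptItem",
    "Basket",
    "BasketScore",
    "Catalog",
    "RollingMeans",
    "score_basket",
    "rolling_component_means",
    "period_di",
    "COMPONENT_KEYS",
]

COMPONENT_KEYS = (
    "energy_pts",
    "sugar_pts",
    "satfat_pts",
    "sodium_pts",
    "fvln_pts",
    "fiber_pts",
    "protein_pts",
)


class CatalogError(ValueError):
    """Catalog construction or lookup failure."""


class UnknownProductError(KeyError):
    """A receipt references product ids absent from the catalog."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"unknown product ids: {', '.join(map(str, missing))}")


@dataclass(frozen=True)
class ProductRecord:
    product_id: str
    name: str
    category_id: int
    profile: NutrientProfile
    unit_mass_g: float = 100.0

    def __post_init__(self) -> None:
        if self.unit_mass_g <= 0:
            raise CatalogError(
                f"product {self.product_id}: unit_mass_g must be > 0"
            )


@dataclass(frozen=True)
class ReceiptItem:
    product_id: str
    quantity: float = 1.0
    mass_g: float | None = None  # explicit mass overrides quantity*unit_mass

    def resolved_mass(self, product: ProductRecord) -> float:
        if self.mass_g is not None:
            return self.mass_g
        return self.quantity * product.unit_mass_g


@dataclass(frozen=True)
class Basket:
    basket_id: str
    participant_id: str
    timestamp: dt.date
    items: tuple[ReceiptItem, ...]
    retailer: str = "A"

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"basket {self.basket_id}: at least one item required")
        object.__setattr__(self, "items", tuple(self.items))


@dataclass
class BasketScore:
    """Scores of one basket (or one pooled set of items)."""

    solid_di: float | None
    beverage_di: float | None
    component_means: dict[str, float] | None
    total_mass_g: float
    total_energy_kj: float
    n_items_scored: int
    n_items_skipped: int = 0


class Catalog:
    """Product lookup with cached per-product FSA-NPS points."""

    def __init__(
        self,
        products: list[ProductRecord],
        n_categories: int = 125,
        bands: BandTable | None = None,
        protein_cap: bool = True,
    ):
        self.n_categories = n_categories
        self.bands = bands or default_band_table()
        self.protein_cap = protein_cap
        self._products: dict[str, ProductRecord] = {}
        for p in products:
            if p.product_id in self._products:
                raise CatalogError(f"duplicate product id: {p.product_id}")
            if not 1 <= p.category_id <= n_categories:
                raise CatalogError(
                    f"product {p.product_id}: category {p.category_id} outside 1..{n_categories}"
                )
            self._products[p.product_id] = p
        self._points: dict[str, ComponentPoints] = {}
        self._scores: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self._products)

    def __contains__(self, product_id: str) -> bool:
        return product_id in self._products

    def __iter__(self):
        return iter(self._products.values())

    def get(self, product_id: str) -> ProductRecord:
        try:
            return self._products[product_id]
        except KeyError:
            raise UnknownProductError([product_id]) from None

    def points(self, product_id: str) -> ComponentPoints:
        if product_id not in self._points:
            self._points[product_id] = score_profile(
                self.get(product_id).profile, self.bands
            )
        return self._points[product_id]

    def fsa_score(self, product_id: str) -> int:
        if product_id not in self._scores:
            from .nutrient_profiling import total_fsa_score

            self._scores[product_id] = total_fsa_score(
                self.points(product_id), self.protein_cap
            )
        return self._scores[product_id]

    def in_category(self, category_id: int) -> list[ProductRecord]:
        return [p for p in self if p.category_id == category_id]


def _item_weights(
    items: list[tuple[ReceiptItem, ProductRecord]], weighting: str
) -> list[float]:
    if weighting == "mass":
        return [it.resolved_mass(p) for it, p in items]
    if weighting == "energy":
        # purchased energy in kJ; falls back to mass when the selection
        # carries no energy at all (e.g. water only)
        w = [it.resolved_mass(p) / 100.0 * p.profile.energy_kj for it, p in items]
        if sum(w) > 0:
            return w
        return [it.resolved_mass(p) for it, p in items]
    raise ValueError(f"unknown weighting mode: {weighting!r}")


def _resolve(basket_items, catalog: Catalog):
    missing = [it.product_id for it in basket_items if it.product_id not in catalog]
    if missing:
        raise UnknownProductError(sorted(set(missing)))
    return [(it, catalog.get(it.product_id)) for it in basket_items]


def _pooled_score(
    items: list[ReceiptItem], catalog: Catalog, weighting: str
) -> BasketScore:
    """Weighted-mean DI and component means over a pooled item list."""
    resolved = _resolve(items, catalog)
    scoreable = [(it, p) for it, p in resolved if it.resolved_mass(p) > 0]
    skipped = len(resolved) - len(scoreable)

    solids = [(it, p) for it, p in scoreable if not p.profile.is_beverage]
    bevs = [(it, p) for it, p in scoreable if p.profile.is_beverage]

    def di(group):
        if not group:
            return None
        w = _item_weights(group, weighting)
        tot = sum(w)
        if tot <= 0:
            return None
        return sum(
            wi * catalog.fsa_score(it.product_id) for wi, (it, _) in zip(w, group)
        ) / tot

    total_mass = sum(it.resolved_mass(p) for it, p in scoreable)
    total_energy = sum(
        it.resolved_mass(p) / 100.0 * p.profile.energy_kj for it, p in scoreable
    )

    comp_means = None
    if solids:
        w = _item_weights(solids, weighting)
        tot = sum(w)
        if tot > 0:
            comp_means = {
                k: sum(
                    wi * getattr(catalog.points(it.product_id), k)
                    for wi, (it, _) in zip(w, solids)
                ) / tot
                for k in COMPONENT_KEYS
            }

    return BasketScore(
        solid_di=di(solids),
        beverage_di=di(bevs),
        component_means=comp_means,
        total_mass_g=total_mass,
        total_energy_kj=total_energy,
        n_items_scored=len(scoreable),
        n_items_skipped=skipped,
    )


def score_basket(
    basket: Basket, catalog: Catalog, weighting: str = "energy"
) -> BasketScore:
    """Score one receipt: solid and beverage DI plus component-point means.

    ``solid_di`` is the ``weighting``-weighted mean of per-product FSA-NPS
    scores over solid items; a basket with no scoreable solid mass reports
    ``solid_di=None`` (absent), never 0.  Beverages are scored separately
    and reported as ``beverage_di`` when present.
    """
    return _pooled_score(list(basket.items), catalog, weighting)


@dataclass
class RollingMeans:
    """Component-point means over the ``used`` most recent baskets."""

    means: dict[str, float] | None
    used: int
    status: str = "ok"


def rolling_component_means(
    baskets: list[Basket],
    window_n: int,
    catalog: Catalog,
    weighting: str = "energy",
) -> RollingMeans:
    """Equal-weight mean of per-basket component means over a basket window.

    Uses the ``min(window_n, len(baskets))`` most recent baskets (input must
    be sorted by timestamp); each basket contributes equally regardless of
    its size, matching a per-basket rolling average.  Baskets without
    scoreable solid items are skipped.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    window = baskets[-window_n:] if baskets else []
    per_basket = []
    for b in window:
        s = score_basket(b, catalog, weighting)
        if s.component_means is not None:
            per_basket.append(s.component_means)
    if not per_basket:
        return RollingMeans(means=None, used=0, status="insufficient_history")
    means = {
        k: sum(m[k] for m in per_basket) / len(per_basket) for k in COMPONENT_KEYS
    }
    return RollingMeans(means=means, used=len(per_basket))


def period_di(
    baskets: list[Basket],
    start: dt.date,
    end: dt.date,
    catalog: Catalog,
    weighting: str = "energy",
) -> BasketScore | None:
    """Pooled solid-food DI over every item purchased in ``[start, end)``.

    Items from all in-range baskets are pooled and weighted at item level
    (not a mean of basket means).  Returns ``None`` when no basket falls in
    the window.
    """
    if end <= start:
        raise ValueError("date range must satisfy start < end")
    in_range = [b for b in baskets if start <= b.timestamp < end]
    if not in_range:
        return None
    items = [it for b in in_range for it in b.items]
    return _pooled_score(items, catalog, weighting)
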