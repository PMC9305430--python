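"""FSA-NPS (Nutri-Score) point scoring of single products.

The British Food Standards Agency Nutrient Profiling System assigns, per
100 g of product, 0–10 "negative" points each for energy density, sugars,
saturated fat and sodium, and 0–5 "positive" points each for the
fruit/vegetable/legume/nut fraction, fiber and protein.  The total score is

    score = negative_total − counted positive points

and ranges from −15 (healthiest possible) to +40 (least healthy).  Protein
points are only counted when the product scores fewer than 11 negative
points or reaches the full 5 fruit-and-vegetable points (the "protein cap").

Band thresholds live in a YAML table shipped with the package
(``data/fsa_bands_2005.yaml``); alternative tables (e.g. NSP fiber bands or
beverage-specific bands) can be loaded with :func:`load_band_table`.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "NutrientProfile",
    "ComponentPoints",
    "BandTable",
    "NEGATIVE_COMPONENTS",
    "POSITIVE_COMPONENTS",
    "load_band_table",
    "default_band_table",
    "score_negative_components",
    "score_positive_components",
    "total_fsa_score",
    "score_profile",
    "sodium_from_salt",
]

#: negative components in scoring order (each 0..10 points)
NEGATIVE_COMPONENTS = ("energy_kj", "sugars_g", "satfat_g", "sodium_mg")
#: positive components in scoring order (each 0..5 points)
POSITIVE_COMPONENTS = ("fvln_pct", "fiber_g", "protein_g")

#: mg of sodium per gram of salt (NaCl molar mass ratio)
SODIUM_MG_PER_G_SALT = 393.4

SCORE_MIN = -15
SCORE_MAX = 40


class ProfileError(ValueError):
    """A nutrient profile violates its invariants."""


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient declaration of one product.

    Units: energy in kJ, sugars/saturated fat/fiber/protein in g, sodium in
    mg, ``fvln_pct`` the fruit/vegetable/legume/nut percentage in [0, 100].
    """

    energy_kj: float
    sugars_g: float
    satfat_g: float
    sodium_mg: float
    fvln_pct: float
    fiber_g: float
    protein_g: float
    is_beverage: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "is_beverage":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ProfileError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ProfileError(f"{f.name} must be >= 0, got {v!r}")
        if self.fvln_pct > 100:
            raise ProfileError(
                f"fvln_pct must be in [0, 100], got {self.fvln_pct!r}"
            )


@dataclass(frozen=True)
class ComponentPoints:
    """Integer FSA-NPS points of one product, component by component."""

    energy_pts: int
    sugar_pts: int
    satfat_pts: int
    sodium_pts: int
    fvln_pts: int
    fiber_pts: int
    protein_pts: int

    @property
    def negative_total(self) -> int:
        return self.energy_pts + self.sugar_pts + self.satfat_pts + self.sodium_pts

    @property
    def positive_total(self) -> int:
        return self.fvln_pts + self.fiber_pts + self.protein_pts

    def protein_counted(self, protein_cap: bool = True) -> bool:
        """Whether protein points enter the total under the cap rule."""
        if not protein_cap:
            return True
        return self.negative_total < 11 or self.fvln_pts == 5

    @property
    def fsa_score(self) -> int:
        return total_fsa_score(self)

    def as_dict(self) -> dict[str, int]:
        return {
            "energy_pts": self.energy_pts,
            "sugar_pts": self.sugar_pts,
            "satfat_pts": self.satfat_pts,
            "sodium_pts": self.sodium_pts,
            "fvln_pts": self.fvln_pts,
            "fiber_pts": self.fiber_pts,
            "protein_pts": self.protein_pts,
        }


#: maps profile field -> points attribute name
_POINTS_FIELD = {
    "energy_kj": "energy_pts",
    "sugars_g": "sugar_pts",
    "satfat_g": "satfat_pts",
    "sodium_mg": "sodium_pts",
    "fvln_pct": "fvln_pts",
    "fiber_g": "fiber_pts",
    "protein_g": "protein_pts",
}


class BandTable:
    """Threshold bands mapping a nutrient value to integer points.

    Bands are half-open, lower-exclusive / upper-inclusive: value ``v``
    earns the points of the first band whose ``upper_bound >= v``; the last
    band has an open upper bound.
    """

    def __init__(self, bands: dict[str, list[tuple[float | None, int]]], version: str = "custom"):
        self.version = version
        self._bounds: dict[str, list[float]] = {}
        self._points: dict[str, list[int]] = {}
        for comp, rows in bands.items():
            if not rows or rows[-1][0] is not None:
                raise ValueError(f"{comp}: last band must have open upper bound")
            ubs = [b for b, _ in rows[:-1]]
            if any(ubs[i] >= ubs[i + 1] for i in range(len(ubs) - 1)):
                raise ValueError(f"{comp}: upper bounds must be strictly increasing")
            pts = [p for _, p in rows]
            if any(pts[i] >= pts[i + 1] for i in range(len(pts) - 1)):
                raise ValueError(f"{comp}: points must be strictly increasing")
            self._bounds[comp] = ubs
            self._points[comp] = pts

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self._bounds)

    def points_for(self, component: str, value: float) -> int:
        """Points for ``value`` via interval bisection on the band bounds."""
        ubs = self._bounds[component]
        # upper-inclusive: value equal to a bound stays in the lower band
        return self._points[component][bisect_left(ubs, value)]

    def max_points(self, component: str) -> int:
        return self._points[component][-1]

    def band_rows(self, component: str) -> list[tuple[float | None, int]]:
        """The raw (upper_bound, points) rows, open bound last."""
        return list(zip(self._bounds[component] + [None], self._points[component]))


def load_band_table(path: str | Path) -> BandTable:
    """Load a band table from a YAML file in the shipped schema."""
    raw = yaml.safe_load(Path(path).read_text())
    bands: dict[str, list[tuple[float | None, int]]] = {}
    for side in ("negative", "positive"):
        for comp, rows in raw[side].items():
            bands[comp] = [(r["upper_bound"], int(r["points"])) for r in rows]
    return BandTable(bands, version=str(raw.get("version", "unversioned")))


_DEFAULT_TABLE: BandTable | None = None


def default_band_table() -> BandTable:
    """The 2005 UK FSA band table shipped with the package (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("nutribasket.data") / "fsa_bands_2005.yaml"
        ) as p:
            _DEFAULT_TABLE = load_band_table(p)
    return _DEFAULT_TABLE


def score_negative_components(
    profile: NutrientProfile, bands: BandTable | None = None
) -> dict[str, int]:
    """Energy, sugar, saturated-fat and sodium points (each 0..10)."""
    bands = bands or default_band_table()
    return {
        _POINTS_FIELD[c]: bands.points_for(c, getattr(profile, c))
        for c in NEGATIVE_COMPONENTS
    }


def score_positive_components(
    profile: NutrientProfile, bands: BandTable | None = None
) -> dict[str, int]:
    """Fruit/vegetable, fiber and protein points (each 0..5)."""
    bands = bands or default_band_table()
    return {
        _POINTS_FIELD[c]: bands.points_for(c, getattr(profile, c))
        for c in POSITIVE_COMPONENTS
    }


def total_fsa_score(points: ComponentPoints, protein_cap: bool = True) -> int:
    """Total FSA-NPS score in −15..+40.

    ``negative_total`` minus the counted positive points; protein points are
    dropped when ``negative_total >= 11`` and the product lacks full
    fruit-and-vegetable points (unless ``protein_cap`` is disabled).
    """
    positives = points.fvln_pts + points.fiber_pts
    if points.protein_counted(protein_cap):
        positives += points.protein_pts
    score = points.negative_total - positives
    if not SCORE_MIN <= score <= SCORE_MAX:  # pragma: no cover - guarded by bands
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return score


def score_profile(
    profile: NutrientProfile,
    bands: BandTable | None = None,
    protein_cap: bool = True,
) -> ComponentPoints:
    """All seven component points of a product in one call."""
    neg = score_negative_components(profile, bands)
    pos = score_positive_components(profile, bands)
    return ComponentPoints(**neg, **pos)


def sodium_from_salt(salt_g: float) -> float:
    """Convert g of salt per 100 g into mg of sodium per 100 g."""
    if salt_g < 0:
        raise ProfileError(f"salt_g must be >= 0, got {salt_g!r}")
    return salt_g * SODIUM_MG_PER_G_SALT
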