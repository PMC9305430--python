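import datetime as dt

import pytest

from nutribasket.basket_scoring import Basket, Catalog, ProductRecord, ReceiptItem
from nutribasket.nutrient_profiling import NutrientProfile
from nutribasket.synthetic_data import generate_catalog

START = dt.date(2020, 11, 16)


def make_product(
    pid,
    category=1,
    energy=800.0,
    sugars=5.0,
    satfat=2.0,
    sodium=300.0,
    fvln=0.0,
    fiber=1.0,
    protein=5.0,
    beverage=False,
    unit_mass=100.0,
):
    return ProductRecord(
        product_id=pid,
        name=f"fixture {pid}",
        category_id=category,
        profile=NutrientProfile(
            energy_kj=energy,
            sugars_g=sugars,
            satfat_g=satfat,
            sodium_mg=sodium,
            fvln_pct=fvln,
            fiber_g=fiber,
            protein_g=protein,
            is_beverage=beverage,
        ),
        unit_mass_g=unit_mass,
    )


def make_basket(items, basket_id="b1", pid="p1", day=0, retailer="A"):
    """items: list of (product_id, mass_g)."""
    return Basket(
        basket_id=basket_id,
        participant_id=pid,
        timestamp=START + dt.timedelta(days=day),
        items=tuple(ReceiptItem(product_id=p, mass_g=m) for p, m in items),
        retailer=retailer,
    )


@pytest.fixture(scope="session")
def mini_catalog():
    """Hand-built catalog with known, spread-out FSA-NPS scores."""
    products = [
        # category 1: scores span low..high at a fixed energy density
        make_product("lean", 1, energy=400, sugars=1, satfat=0.5, sodium=50, fiber=3, protein=9),
        make_product("mid", 1, energy=1200, sugars=10, satfat=4, sodium=400),
        make_product("rich", 1, energy=2400, sugars=30, satfat=9, sodium=800, protein=0, fiber=0),
        # category 2: sugary
        make_product("sweet", 2, energy=1700, sugars=50, satfat=1, sodium=100, fiber=0, protein=1),
        make_product("lighter", 2, energy=900, sugars=12, satfat=0.5, sodium=80, fiber=1, protein=1),
        # category 3: produce
        make_product("veg", 3, energy=150, sugars=2, satfat=0, sodium=10, fvln=100, fiber=5, protein=3),
        # category 4: beverages
        make_product("cola", 4, energy=180, sugars=11, satfat=0, sodium=10, beverage=True),
        make_product("water", 4, energy=0, sugars=0, satfat=0, sodium=2, beverage=True),
    ]
    return Catalog(products, n_categories=5)


@pytest.fixture(scope="session")
def gen_catalog():
    """Desk-scale generated catalog shared across statistical tests."""
    return generate_catalog(n_products=625, n_categories=125, seed=11)
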