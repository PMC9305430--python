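"""Score digital receipts: basket-level dietary index and rolling means.

Builds a small catalog and two receipts, scores each basket (solid foods
and beverages separately), then pools a date window the way trial periods
are aggregated.
"""

import datetime as dt

from nutribasket import Basket, Catalog, NutrientProfile, ProductRecord, ReceiptItem
from nutribasket import period_di, rolling_component_means, score_basket

catalog = Catalog(
    [
        ProductRecord("bread", "wholegrain bread", 1,
                      NutrientProfile(1000, 3, 0.5, 400, 0, 6, 9)),
        ProductRecord("cheese", "hard cheese", 2,
                      NutrientProfile(1650, 0.5, 21, 620, 0, 0, 25)),
        ProductRecord("apples", "apples", 3,
                      NutrientProfile(220, 10, 0, 1, 100, 2.4, 0.3)),
        ProductRecord("cola", "cola", 4,
                      NutrientProfile(180, 10.6, 0, 10, 0, 0, 0, is_beverage=True)),
    ],
    n_categories=4,
)

b1 = Basket("b1", "p1", dt.date(2021, 1, 4), (
    ReceiptItem("bread", mass_g=500), ReceiptItem("cheese", mass_g=200),
    ReceiptItem("cola", mass_g=1000),
))
b2 = Basket("b2", "p1", dt.date(2021, 1, 11), (
    ReceiptItem("apples", mass_g=1000), ReceiptItem("cheese", mass_g=150),
))

for b in (b1, b2):
    s = score_basket(b, catalog)
    print(f"{b.basket_id}: solid DI = {s.solid_di:.2f}", end="")
    print(f", beverage DI = {s.beverage_di:.2f}" if s.beverage_di is not None else ", no beverages")

roll = rolling_component_means([b1, b2], window_n=12, catalog=catalog)
print("rolling component means over", roll.used, "baskets:",
      {k: round(v, 2) for k, v in roll.means.items()})

pooled = period_di([b1, b2], dt.date(2021, 1, 1), dt.date(2021, 2, 1), catalog)
print(f"period DI (item-level pooled): {pooled.solid_di:.2f}")
# The DI is the energy-weighted mean FSA-NPS score of the purchased solid
# foods: lower is healthier. Pooling weights items, not baskets.
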