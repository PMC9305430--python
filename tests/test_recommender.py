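"""Category contributions, ranking, substitutes and tip selection."""

import itertools

import numpy as np
import pytest

from nutribasket.basket_scoring import Catalog
from nutribasket.recommender import (
    NEGATIVE_DIMENSIONS,
    CategoryContribution,
    TipPack,
    category_contributions,
    healthier_alternatives,
    rank_problem_categories,
    recommend,
    select_tip,
)

from conftest import make_basket, make_product


def brute_force_contributions(baskets, catalog, max_baskets=7):
    """Independent item-by-item accumulation over every (item, dimension)."""
    window = baskets[-max_baskets:]
    total = 0.0
    acc = {}
    mass = {}
    for b in window:
        for it in b.items:
            p = catalog.get(it.product_id)
            m = it.resolved_mass(p)
            if m <= 0:
                continue
            total += m
            pts = catalog.points(it.product_id)
            row = acc.setdefault(p.category_id, dict.fromkeys(NEGATIVE_DIMENSIONS, 0.0))
            for d in NEGATIVE_DIMENSIONS:
                row[d] += m * getattr(pts, d)
            mass[p.category_id] = mass.get(p.category_id, 0.0) + m
    return {
        c: {
            "per_dimension": {d: acc[c][d] / total for d in NEGATIVE_DIMENSIONS},
            "share": mass[c] / total,
        }
        for c in acc
    }


def test_single_category_contribution_equals_pool_mean(mini_catalog):
    baskets = [make_basket([("mid", 200.0), ("rich", 100.0)])]
    contribs, used = category_contributions(baskets, mini_catalog)
    assert used == 1 and len(contribs) == 1
    c = contribs[0]
    pts = {p: mini_catalog.points(p) for p in ("mid", "rich")}
    for d in NEGATIVE_DIMENSIONS:
        expect = (200 * getattr(pts["mid"], d) + 100 * getattr(pts["rich"], d)) / 300
        assert c.per_dimension[d] == pytest.approx(expect)
    assert c.combined == pytest.approx(np.mean(list(c.per_dimension.values())))
    assert c.share_of_mass == pytest.approx(1.0)


def test_zero_negative_category_contributes_zero(mini_catalog):
    contribs, _ = category_contributions([make_basket([("water", 1000.0)])], mini_catalog)
    (c,) = contribs
    assert all(v == 0.0 for v in c.per_dimension.values())
    assert c.combined == 0.0


def test_contributions_match_brute_force_over_7_baskets(mini_catalog):
    rng = np.random.default_rng(3)
    prods = ["lean", "mid", "rich", "sweet", "lighter", "veg", "cola"]
    baskets = [
        make_basket(
            [(p, float(rng.uniform(20, 600))) for p in rng.choice(prods, size=4)],
            basket_id=f"b{i}",
            day=i,
        )
        for i in range(9)  # more than the window: the oldest 2 must be ignored
    ]
    contribs, used = category_contributions(baskets, mini_catalog)
    assert used == 7
    oracle = brute_force_contributions(baskets, mini_catalog)
    assert {c.category_id for c in contribs} == set(oracle)
    for c in contribs:
        for d in NEGATIVE_DIMENSIONS:
            assert c.per_dimension[d] == pytest.approx(oracle[c.category_id]["per_dimension"][d], abs=1e-12)
        assert c.share_of_mass == pytest.approx(oracle[c.category_id]["share"])


def test_conservation_on_random_fixtures(gen_catalog):
    """Per-dimension contributions sum to the pooled mass-weighted mean
    points, to 1e-9, on random baskets from the generated catalog."""
    rng = np.random.default_rng(12)
    ids = [p.product_id for p in gen_catalog]
    for _ in range(20):
        baskets = [
            make_basket(
                [(pid, float(rng.uniform(10, 900))) for pid in rng.choice(ids, size=rng.integers(2, 12))],
                basket_id=f"b{i}",
                day=i,
            )
            for i in range(int(rng.integers(1, 8)))
        ]
        contribs, _ = category_contributions(baskets, gen_catalog)
        items = [(it, gen_catalog.get(it.product_id)) for b in baskets[-7:] for it in b.items]
        tot = sum(it.resolved_mass(p) for it, p in items)
        for d in NEGATIVE_DIMENSIONS:
            lhs = sum(c.per_dimension[d] for c in contribs)
            rhs = sum(
                it.resolved_mass(p) * getattr(gen_catalog.points(it.product_id), d)
                for it, p in items
            ) / tot
            assert abs(lhs - rhs) < 1e-9


def _cc(cat, combined, share):
    return CategoryContribution(
        category_id=cat,
        per_dimension=dict.fromkeys(NEGATIVE_DIMENSIONS, combined),
        combined=combined,
        share_of_mass=share,
    )


def test_ranking_empty_when_all_zero():
    assert rank_problem_categories([_cc(1, 0.0, 0.5), _cc(2, 0.0, 0.5)]) == []


def test_ranking_top4_of_5_distinct():
    cs = [_cc(i, float(i), 0.1) for i in (1, 2, 3, 4, 5)]
    ranked = rank_problem_categories(cs)
    assert [c.category_id for c in ranked] == [5, 4, 3, 2]


def test_ranking_tie_break_matches_enumeration():
    """Equal combined values: larger mass share wins, then smaller id; the
    result must be invariant to input permutation."""
    cs = [_cc(7, 2.0, 0.2), _cc(3, 2.0, 0.4), _cc(5, 2.0, 0.4), _cc(9, 3.0, 0.1)]
    expect = [9, 3, 5, 7]
    for perm in itertools.permutations(cs):
        ranked = rank_problem_categories(list(perm))
        assert [c.category_id for c in ranked] == expect


def test_ranking_stable_under_zero_category():
    cs = [_cc(1, 1.0, 0.3), _cc(2, 2.0, 0.3)]
    base = [c.category_id for c in rank_problem_categories(cs)]
    with_zero = [c.category_id for c in rank_problem_categories(cs + [_cc(3, 0.0, 0.4)])]
    assert base == with_zero


def test_alternatives_forced_ordering():
    cat = Catalog(
        [
            make_product("s10", 1, energy=2400, sugars=30, satfat=9, sodium=800, protein=0, fiber=0),
            make_product("s6", 1, energy=2000, sugars=18, satfat=5, sodium=500, protein=0, fiber=0),
            make_product("s2", 1, energy=1000, sugars=10, satfat=0, sodium=50, protein=0, fiber=0),
        ],
        n_categories=1,
    )
    scores = {p: cat.fsa_score(p) for p in ("s10", "s6", "s2")}
    assert scores["s2"] < scores["s6"] < scores["s10"]
    alts = healthier_alternatives(1, [(cat.get("s10"), 500.0)], cat)
    assert [p.product_id for p in alts] == ["s2", "s6"]
    # purchased the category best -> nothing healthier to offer
    assert healthier_alternatives(1, [(cat.get("s2"), 500.0)], cat) == []


def test_alternatives_match_filter_and_sort_brute_force(gen_catalog):
    rng = np.random.default_rng(21)
    for _ in range(25):
        cat_id = int(rng.integers(1, 126))
        prods = gen_catalog.in_category(cat_id)
        chosen = [prods[i] for i in rng.choice(len(prods), size=min(2, len(prods)), replace=False)]
        purchased = [(p, float(rng.uniform(50, 500))) for p in chosen]
        got = healthier_alternatives(cat_id, purchased, gen_catalog, n_max=4)
        tot = sum(m for _, m in purchased)
        bench = sum(m * gen_catalog.fsa_score(p.product_id) for p, m in purchased) / tot
        bought = {p.product_id for p, _ in purchased}
        expect = sorted(
            (
                p
                for p in prods
                if p.product_id not in bought and gen_catalog.fsa_score(p.product_id) < bench
            ),
            key=lambda p: (gen_catalog.fsa_score(p.product_id), p.product_id),
        )[:4]
        assert [p.product_id for p in got] == [p.product_id for p in expect]


def test_substitution_strictly_improves_mass_weighted_di(mini_catalog):
    """Swapping the worst purchased item in a flagged category for any
    emitted alternative (same mass) lowers the pooled mass-weighted DI."""
    baskets = [make_basket([("rich", 300.0), ("sweet", 200.0), ("veg", 100.0)])]
    rep = recommend(baskets, mini_catalog)
    assert rep.problem_categories

    def pooled_mass_di(item_list):
        tot = sum(m for _, m in item_list)
        return sum(m * mini_catalog.fsa_score(p) for p, m in item_list) / tot

    base_items = [("rich", 300.0), ("sweet", 200.0), ("veg", 100.0)]
    for c in rep.problem_categories:
        for alt in rep.alternatives[c.category_id]:
            worst = max(
                (pm for pm in base_items if mini_catalog.get(pm[0]).category_id == c.category_id),
                key=lambda pm: mini_catalog.fsa_score(pm[0]),
            )
            swapped = [pm for pm in base_items if pm != worst] + [(alt.product_id, worst[1])]
            assert pooled_mass_di(swapped) < pooled_mass_di(base_items)


def test_report_caps_categories_at_4(gen_catalog):
    rng = np.random.default_rng(5)
    ids = [p.product_id for p in gen_catalog]
    baskets = [
        make_basket(
            [(pid, float(rng.uniform(50, 400))) for pid in rng.choice(ids, size=15)],
            basket_id=f"b{i}",
            day=i,
        )
        for i in range(7)
    ]
    rep = recommend(baskets, gen_catalog)
    assert len(rep.problem_categories) <= 4
    assert rep.baskets_used == 7
    for c in rep.problem_categories:
        for alt in rep.alternatives[c.category_id]:
            assert alt.category_id == c.category_id


def test_empty_baskets_report_status(mini_catalog):
    rep = recommend([], mini_catalog)
    assert rep.status == "no_scoreable_items"
    assert rep.problem_categories == []
    assert rep.tip_id  # fallback tip still emitted


def test_tip_selection_and_fallback():
    pack = TipPack(by_category={4: ["tip-a"]})
    assert select_tip([_cc(4, 2.0, 0.5)], pack) == "tip-a"
    assert select_tip([_cc(9, 2.0, 0.5)], pack) == pack.fallback
    assert select_tip([], pack) == pack.fallback


def test_tips_rotate_before_repeating():
    pack = TipPack(by_category={4: ["t1", "t2", "t3"]})
    seen = [select_tip([_cc(4, 2.0, 0.5)], pack) for _ in range(4)]
    assert seen == ["t1", "t2", "t3", "t1"]
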