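"""Independent oracles, hand-transcribed and deliberately dumb.

These duplicate none of the production code paths: component scorers are
literal if/elif chains over weekly servings, the Mann-Whitney U oracle
counts pairs, and the odds-ratio oracle is the 2x2 cross-product.
"""

MONTH = 1.0 / 4.348  # one-per-month in servings/week


def _whole_grains(x):
    if x < 7:
        return 0.0
    if x < 21:
        return 0.5
    return 1.0


def _three_up(lo, mid):
    def f(x):
        if x < lo:
            return 0.0
        if x < mid:
            return 0.5
        return 1.0
    return f


def _three_down(lo, mid):
    def f(x):
        if x < lo:
            return 1.0
        if x < mid:
            return 0.5
        return 0.0
    return f


def _butter(x):
    if x < 7:
        return 1.0
    if x <= 14:
        return 0.5
    return 0.0


def _green_leafy_original(x):
    if x <= 2:
        return 0.0
    if x < 6:
        return 0.5
    return 1.0


def _beans(x):
    if x < 1:
        return 0.0
    if x <= 3:
        return 0.5
    return 1.0


def _wine(x):
    if x < MONTH:
        return 0.0
    if x <= 6:
        return 0.5
    if x <= 7:
        return 1.0
    return 0.0


MYMINDD_ORACLE = {
    "whole_grains": _whole_grains,
    "green_leafy": _three_up(3.5, 7),
    "other_vegetables": _three_up(7, 21),
    "flavonoid_fruits": _three_up(1, 2),
    "deep_sea_fish": _three_up(0.5, 1),
    "legumes_soy": _three_up(1, 3),
    "poultry": _three_up(1, 2),
    "desserts_kuih": _three_down(5, 7),
    "butter_margarine": _butter,
    "red_meat": _three_down(4, 7),
    "fried_fast_foods": _three_down(1, 4),
}

MIND_ORIGINAL_ORACLE = {
    "whole_grains": _whole_grains,
    "green_leafy": _green_leafy_original,
    "other_vegetables": _three_up(5, 7),
    "berries": _three_up(1, 2),
    "fish": _three_up(MONTH, 1),
    "beans": _beans,
    "nuts": _three_up(MONTH, 5),
    "poultry": _three_up(1, 2),
    "wine": _wine,
    "red_meat": _three_down(4, 7),
    "butter_margarine": _butter,
    "cheese": _three_down(1, 7),
    "pastries_sweets": _three_down(5, 7),
    "fried_fast_foods": _three_down(1, 4),
}


def mann_whitney_u(a, b):
    """U of sample a: count of (a_i, b_j) pairs won, ties worth half."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def crossprod_or(a, b, c, d):
    """Odds ratio of a 2x2 table [[a, b], [c, d]]."""
    return (a * d) / (b * c)
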