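"""Independent brute-force oracles used by the test suite.

These re-derive expected values by a different route than the package code
(table lookups, exhaustive enumeration, exact integer arithmetic) and must
stay independent of the implementations they check.
"""

import itertools
import math

import numpy as np

# --- scoring oracle: literal band tables, default configuration -------------

_DURATION_BANDS = ((0.0, 4.0), (4.0, 24.0001), (24.0001, 72.0001), (72.0001, math.inf))


def oracle_duration_category(hours):
    # bands: <4, [4,24], (24,72], >72 — encoded as half-open lookups
    if hours < 4:
        return 0
    if hours <= 24:
        return 1
    if hours <= 72:
        return 2
    return 3


_SYMPTOM_POINTS = {
    "nausea": 2,
    "vomiting": 1,
    "photophobia": 1,
    "phonophobia": 1,
    "visual_disturbances": 1,
}


def oracle_pre_existing_total(
    pre_nrs,
    post_nrs,
    pre_lat,
    post_lat,
    pre_hours,
    post_hours,
    pre_symptoms,
    post_symptoms,
    pre_mhd,
    post_mhd,
    similarity_rating,
):
    """Total score on the pre-existing pathway, by direct table lookup."""
    pts = 0
    # C1 intensity bands
    diff = post_nrs - pre_nrs
    if diff >= 4:
        pts += 4
    elif diff >= 2:
        pts += 2
    # C2 lateralization: the single scoring transition
    if (pre_lat, post_lat) == ("contralateral", "ipsilateral"):
        pts += 2
    # C3 duration category jump
    jump = oracle_duration_category(post_hours) - oracle_duration_category(pre_hours)
    if jump == 1:
        pts += 1
    elif jump >= 2:
        pts += 4
    # C4 new symptoms
    for s in set(post_symptoms) - set(pre_symptoms):
        pts += _SYMPTOM_POINTS[s]
    # C5 frequency
    if (post_mhd - pre_mhd) >= 5 and (pre_mhd == 0 or (post_mhd - pre_mhd) / pre_mhd >= 0.5):
        pts += 4
    # C6 dissimilarity from the similarity-scale rating
    dissim = 10 - similarity_rating
    if dissim >= 8:
        pts += 4
    elif dissim >= 6:
        pts += 2
    return pts


# --- Fisher 2x2 oracle: exact integer enumeration ---------------------------


def oracle_fisher_2x2(table):
    """Two-sided p by exhaustive enumeration with exact integer weights."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / math.comb(n, c1)


# --- Mann-Whitney oracle: full permutation enumeration ----------------------


def oracle_mannwhitney_two_sided(x, y):
    """Two-sided p by enumerating every assignment of the pooled sample."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)
    m = n1 * n2

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        # U = number of (x, y) pairs with x > y, counting ties as 1/2
        u = 0.0
        for xv in xs:
            for yv in ys:
                u += 1.0 if xv > yv else (0.5 if xv == yv else 0.0)
        return u

    u_obs = u_of(tuple(range(n1)))
    dev_obs = abs(u_obs - m / 2.0)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - m / 2.0) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


# --- three-point ROC oracle -------------------------------------------------


def oracle_trapezoid_auc(sens, spec):
    """Area of the polygon under {(0,0), (1-spec, sens), (1,1)} by the
    shoelace formula (closed with (1,0) and (0,0))."""
    pts = [(0.0, 0.0), (1.0 - spec, sens), (1.0, 1.0), (1.0, 0.0)]
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:] + pts[:1]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0
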