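"""Independent literal transcription of the published tomato reference
tables, with its own brute-force membership evaluator.

This module deliberately shares no code with ``optdeg.core``: anchors are
flat tuples, ramp memberships are evaluated with ``np.interp`` over the
anchor knots (0 at the failure borders, 1 on the plateau, 0.5 at the
stage-2 night half-anchor), and the VPD branches are evaluated point by
point from the printed coefficients.  The VPD branch signs are stored
exactly as published; ``normalize_signs`` independently re-derives the
sign correction by searching the per-term sign combination that best
satisfies the anchor semantics (~0 at the G0 border, ~1 at the G1 border).
"""

import itertools
import math

import numpy as np

# (g0_min, g0_5-or-None, g1_min, g1_max, g0_max); one_sided -> g0_max None
TEMP_ANCHORS = {
    ("GS1", "sun"): (9.0, None, 24.0, 26.1, 35.0),
    ("GS1", "cloud"): (9.0, None, 24.0, 26.1, 35.0),
    ("GS1", "night"): (9.0, None, 24.0, 26.1, 35.0),
    ("GS2", "sun"): (10.0, None, 24.0, 27.0, 40.0),
    ("GS2", "cloud"): (10.0, None, 22.0, 24.0, 40.0),
    ("GS2", "night"): (10.0, 17.0, 18.0, 20.0, 40.0),
}
for _l in ("sun", "cloud", "night"):  # stage 3-5 temperature: same as stage 2
    TEMP_ANCHORS[("GS3_5", _l)] = TEMP_ANCHORS[("GS2", _l)]

RH_ANCHORS = {
    "GS1": (60.0, 75.0, None, None),       # one-sided: no falling ramp
    "GS2": (40.0, 70.0, 80.0, 99.0),
    "GS3_5": (30.0, 60.0, 80.0, 99.0),
}

# VPD: anchors plus printed branch coefficients.
# quadratic: ("q", a, b, c); exponential pair: ("e", a1, k1, a2, k2)
VPD_TABLE = {
    ("GS1", "sun"): {
        "anchors": (0.011, 0.030, 0.845, 2.248),
        "rising": ("q", -1220.0, 103.6, -1.015),
        "falling": ("e", -0.1046, 0.5763, 2.296, -0.799),
    },
    ("GS2", "sun"): {  # printed first rising amplitude is negative (typo)
        "anchors": (0.012, 0.596, 1.069, 4.422),
        "rising": ("e", -0.626, 0.8509, -0.6655, -4.974),
        "falling": ("e", -0.0339, 0.4326, 1.711, -0.4562),
    },
    ("GS2", "cloud"): {
        "anchors": (0.012, 0.528, 0.895, 4.422),
        "rising": ("e", -0.6922, -4.889, 0.6492, 0.9212),
        "falling": ("e", -0.01505, 0.5616, 1.591, -0.4981),
    },
    ("GS2", "night"): {
        "anchors": (0.012, 0.412, 0.701, 4.422),
        "rising": ("e", 0.3573, 2.577, -0.3947, -7.396),
        "falling": ("e", -0.004572, 0.7733, 1.459, -0.5429),
    },
    ("GS3_5", "sun"): {
        "anchors": (0.012, 0.596, 1.425, 5.160),
        "rising": ("e", 0.626, 0.8509, -0.6655, -4.974),
        "falling": ("e", -0.03852, 0.3585, 1.864, -0.3953),
    },
    ("GS3_5", "cloud"): {  # printed rising amplitudes have swapped signs (typo)
        "anchors": (0.012, 0.528, 1.193, 5.160),
        "rising": ("e", 0.6922, -4.889, -0.6492, 0.92124),
        "falling": ("e", -0.01806, 0.4577, 1.711, -0.4284),
    },
    ("GS3_5", "night"): {
        "anchors": (0.012, 0.413, 0.935, 5.160),
        "rising": ("e", 0.3573, 2.577, -0.3947, -7.396),
        "falling": ("e", -0.005992, 0.6209, 1.546, -0.4643),
    },
}
VPD_GS1_LIGHT_INDEPENDENT = True
for _l in ("cloud", "night"):
    VPD_TABLE[("GS1", _l)] = VPD_TABLE[("GS1", "sun")]


def eval_branch(coeffs, v: float) -> float:
    if coeffs[0] == "q":
        _, a, b, c = coeffs
        return a * v * v + b * v + c
    _, a1, k1, a2, k2 = coeffs
    return a1 * math.exp(k1 * v) + a2 * math.exp(k2 * v)


def normalize_signs(coeffs, x0: float, y0: float, x1: float, y1: float):
    """Re-derive the sign correction: among all per-term amplitude sign
    choices keep the one minimizing the endpoint residuals."""
    if coeffs[0] == "q":
        return coeffs
    _, a1, k1, a2, k2 = coeffs
    best, best_res = None, math.inf
    for s1, s2 in itertools.product((1.0, -1.0), repeat=2):
        cand = ("e", s1 * abs(a1), k1, s2 * abs(a2), k2)
        res = (abs(eval_branch(cand, x0) - y0)
               + abs(eval_branch(cand, x1) - y1))
        if res < best_res:
            best, best_res = cand, res
    return best


def temp_membership(t: float, stage: str, light: str) -> float:
    """Ramp membership via np.interp over the anchor knots."""
    g0min, g05, g1min, g1max, g0max = TEMP_ANCHORS[(stage, light)]
    xs, ys = [g0min], [0.0]
    if g05 is not None:
        xs.append(g05)
        ys.append(0.5)
    xs += [g1min, g1max, g0max]
    ys += [1.0, 1.0, 0.0]
    if t <= g0min or t >= g0max:
        return 0.0
    return float(np.interp(t, xs, ys))


def rh_membership(rh: float, stage: str) -> float:
    g0min, g1min, g1max, g0max = RH_ANCHORS[stage]
    if g0max is None:  # one-sided
        if rh <= g0min:
            return 0.0
        return float(np.interp(rh, [g0min, g1min], [0.0, 1.0]))
    if rh <= g0min or rh >= g0max:
        return 0.0
    return float(np.interp(rh, [g0min, g1min, g1max, g0max],
                           [0.0, 1.0, 1.0, 0.0]))


def vpd_membership(v: float, stage: str, light: str,
                   sign_normalized: bool = True) -> float:
    entry = VPD_TABLE[(stage, light)]
    g0min, g1min, g1max, g0max = entry["anchors"]
    if v <= g0min or v >= g0max:
        return 0.0
    if g1min <= v <= g1max:
        return 1.0
    if v < g1min:
        c = entry["rising"]
        if sign_normalized:
            c = normalize_signs(c, g0min, 0.0, g1min, 1.0)
    else:
        c = entry["falling"]
        if sign_normalized:
            c = normalize_signs(c, g1max, 1.0, g0max, 0.0)
    return min(1.0, max(0.0, eval_branch(c, v)))
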