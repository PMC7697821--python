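"""Optimality degrees of greenhouse microclimate parameters for tomato.

The optimality degree (OptDeg) maps a raw microclimate measurement -- air
temperature T (degC), relative humidity RH (%) or vapor pressure deficit
VPD (kPa) -- onto a score in [0, 1] expressing how close the measurement is
to the crop's optimal range at a given growth stage and light condition.
A score of 1 means the measurement lies inside the optimal plateau
[G1_min, G1_max]; a score of 0 means it lies at or beyond the failure
borders G0_min / G0_max.  Between the borders the score follows
stage-specific membership functions: linear ramps for T and RH, fitted
quadratic/exponential branches for VPD.

Growth stages follow the tomato phenology convention GS1 (germination and
early growth), GS2 (vegetative growth) and GS3_5 (flowering through mature
fruiting); GS3_5 reuses the GS2 temperature anchors.  Light conditions are
sun, cloud and night; GS1 memberships are light-independent.

The anchor values and branch coefficients shipped as defaults are
transcribed from the published tomato reference tables.  Those tables
contain a handful of typographic inconsistencies (descending-ramp
denominators, duplicated night sub-interval, two sign errors in the VPD
exponential branches); the defaults here are the corrected forms, every
correction being verified by :func:`audit_membership_table`, which checks
that each VPD branch evaluates to ~0 at its G0 border and ~1 at its G1
border.  The as-published signs are retained in
:func:`literal_printed_params` so the audit can demonstrate the defect.

VPD is computed from T and RH with the Magnus-type saturation formula

    VPD(T, RH) = (1 - RH/100) * 0.611 * exp(17.27 T / (T + 237.3))   [kPa]
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Union

import numpy as np
import yaml

__all__ = [
    "GrowthStage",
    "LightCondition",
    "InvalidInputError",
    "Quadratic",
    "ExpPair",
    "TrapezoidParams",
    "VpdBranchSet",
    "MembershipParams",
    "OptDegRecord",
    "AuditEntry",
    "default_params",
    "literal_printed_params",
    "compute_vpd",
    "optdeg_temperature",
    "optdeg_humidity",
    "optdeg_vpd",
    "optdeg_record",
    "audit_membership_table",
]


class InvalidInputError(ValueError):
    """Raised when a physical input is out of range or non-finite."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


class GrowthStage(str, enum.Enum):
    """Tomato growth stage.  GS3_5 spans flowering through mature fruiting."""

    GS1 = "GS1"
    GS2 = "GS2"
    GS3_5 = "GS3_5"


class LightCondition(str, enum.Enum):
    SUN = "sun"
    CLOUD = "cloud"
    NIGHT = "night"


# --------------------------------------------------------------------------
# VPD (Magnus-type formula)
# --------------------------------------------------------------------------

def compute_vpd(T, RH):
    """Vapor pressure deficit in kPa from T (degC) and RH (%).

    VPD = (1 - RH/100) * 0.611 * exp(17.27 T / (T + 237.3)).

    Accepts scalars or arrays; raises :class:`InvalidInputError` on
    non-finite inputs, RH outside [0, 100] or T <= -237.3 degC.
    """
    t = np.asarray(T, dtype=float)
    rh = np.asarray(RH, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("T", "non-finite temperature")
    if not np.all(np.isfinite(rh)):
        raise InvalidInputError("RH", "non-finite relative humidity")
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise InvalidInputError("RH", "relative humidity outside [0, 100] %")
    if np.any(t <= -237.3):
        raise InvalidInputError("T", "temperature at or below -237.3 degC")
    out = (1.0 - rh / 100.0) * 0.611 * np.exp(17.27 * t / (t + 237.3))
    if out.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Quadratic:
    """a*v**2 + b*v + c."""

    a: float
    b: float
    c: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.a * v * v + self.b * v + self.c

    def to_dict(self):
        return {"kind": "quadratic", "a": self.a, "b": self.b, "c": self.c}


@dataclass(frozen=True)
class ExpPair:
    """a1*exp(k1*v) + a2*exp(k2*v) -- the fitted VPD branch form."""

    a1: float
    k1: float
    a2: float
    k2: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.a1 * np.exp(self.k1 * v) + self.a2 * np.exp(self.k2 * v)

    def to_dict(self):
        return {"kind": "exp_pair", "a1": self.a1, "k1": self.k1,
                "a2": self.a2, "k2": self.k2}


Branch = Union[Quadratic, ExpPair]


def _branch_from_dict(d: Mapping) -> Branch:
    kind = d.get("kind")
    if kind == "quadratic":
        return Quadratic(float(d["a"]), float(d["b"]), float(d["c"]))
    if kind == "exp_pair":
        return ExpPair(float(d["a1"]), float(d["k1"]),
                       float(d["a2"]), float(d["k2"]))
    raise ValueError(f"unknown branch kind {kind!r}")


@dataclass(frozen=True)
class TrapezoidParams:
    """Anchors of a linear-ramp membership function.

    Score is 0 at/below ``g0_min`` and at/above ``g0_max`` (open support),
    1 on the closed plateau [``g1_min``, ``g1_max``].  ``g0_5`` (stage-2
    night temperature only) anchors the 0.5-score point of a two-segment
    rising ramp.  ``one_sided`` (GS1 relative humidity) drops the falling
    ramp: the score stays 1 above ``g1_min`` and only the lower failure
    border applies.
    """

    g0_min: float
    g1_min: float
    g1_max: float
    g0_max: float
    g0_5: float | None = None
    one_sided: bool = False

    def __post_init__(self):
        if not self.one_sided:
            if not (self.g0_min < self.g1_min <= self.g1_max < self.g0_max):
                raise ValueError(
                    f"anchor ordering violated: {self.g0_min}, {self.g1_min}, "
                    f"{self.g1_max}, {self.g0_max}")
        else:
            if not (self.g0_min < self.g1_min):
                raise ValueError("one-sided ramp needs g0_min < g1_min")
        if self.g0_5 is not None and not (self.g0_min < self.g0_5 <= self.g1_min):
            raise ValueError("g0_5 must lie in (g0_min, g1_min]")

    def to_dict(self):
        d = {"G0_min": self.g0_min, "G1_min": self.g1_min,
             "G1_max": self.g1_max, "G0_max": self.g0_max}
        if self.g0_5 is not None:
            d["G0_5"] = self.g0_5
        if self.one_sided:
            d["one_sided"] = True
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrapezoidParams":
        return cls(float(d["G0_min"]), float(d["G1_min"]),
                   float(d["G1_max"]), float(d["G0_max"]),
                   g0_5=float(d["G0_5"]) if "G0_5" in d else None,
                   one_sided=bool(d.get("one_sided", False)))


@dataclass(frozen=True)
class VpdBranchSet:
    """VPD anchors plus the fitted rising and falling branch coefficients."""

    g0_min: float
    g1_min: float
    g1_max: float
    g0_max: float
    rising: Branch
    falling: Branch

    def __post_init__(self):
        if not (self.g0_min < self.g1_min <= self.g1_max < self.g0_max):
            raise ValueError("VPD anchor ordering violated")

    def to_dict(self):
        return {"G0_min": self.g0_min, "G1_min": self.g1_min,
                "G1_max": self.g1_max, "G0_max": self.g0_max,
                "rising": self.rising.to_dict(),
                "falling": self.falling.to_dict()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "VpdBranchSet":
        return cls(float(d["G0_min"]), float(d["G1_min"]),
                   float(d["G1_max"]), float(d["G0_max"]),
                   rising=_branch_from_dict(d["rising"]),
                   falling=_branch_from_dict(d["falling"]))


_ALL = "all"  # light key for light-independent parameterizations


@dataclass(frozen=True)
class MembershipParams:
    """The full anchor/coefficient table: variable x stage x light.

    Parameters are data, not code: the table serializes to/from YAML so a
    corrected or alternative crop table can be swapped in without touching
    the evaluators.  Stage GS3_5 temperature deliberately has no entry of
    its own -- lookups delegate to GS2.
    """

    temperature: Mapping[str, Mapping[str, TrapezoidParams]]
    humidity: Mapping[str, TrapezoidParams]
    vpd: Mapping[str, Mapping[str, VpdBranchSet]]

    # -- lookups ----------------------------------------------------------
    def temperature_for(self, stage: GrowthStage,
                        light: LightCondition) -> TrapezoidParams:
        stage = GrowthStage(stage)
        if stage is GrowthStage.GS3_5:
            stage = GrowthStage.GS2  # "same as stage 2"
        table = self.temperature[stage.value]
        if _ALL in table:
            return table[_ALL]
        return table[LightCondition(light).value]

    def humidity_for(self, stage: GrowthStage) -> TrapezoidParams:
        return self.humidity[GrowthStage(stage).value]

    def vpd_for(self, stage: GrowthStage,
                light: LightCondition) -> VpdBranchSet:
        table = self.vpd[GrowthStage(stage).value]
        if _ALL in table:
            return table[_ALL]
        return table[LightCondition(light).value]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "temperature": {s: {l: p.to_dict() for l, p in t.items()}
                            for s, t in self.temperature.items()},
            "humidity": {s: p.to_dict() for s, p in self.humidity.items()},
            "vpd": {s: {l: b.to_dict() for l, b in t.items()}
                    for s, t in self.vpd.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MembershipParams":
        return cls(
            temperature={s: {l: TrapezoidParams.from_dict(p)
                             for l, p in t.items()}
                         for s, t in d["temperature"].items()},
            humidity={s: TrapezoidParams.from_dict(p)
                      for s, p in d["humidity"].items()},
            vpd={s: {l: VpdBranchSet.from_dict(b) for l, b in t.items()}
                 for s, t in d["vpd"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MembershipParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Default tables (corrected transcription of the published tomato references)
# --------------------------------------------------------------------------

def default_params() -> MembershipParams:
    """The shipped anchor/coefficient table with sign-normalized branches."""
    temperature = {
        "GS1": {_ALL: TrapezoidParams(9.0, 24.0, 26.1, 35.0)},
        "GS2": {
            "sun": TrapezoidParams(10.0, 24.0, 27.0, 40.0),
            "cloud": TrapezoidParams(10.0, 22.0, 24.0, 40.0),
            "night": TrapezoidParams(10.0, 18.0, 20.0, 40.0, g0_5=17.0),
        },
        # GS3_5: delegated to GS2 at lookup time
    }
    humidity = {
        "GS1": TrapezoidParams(60.0, 75.0, 99.0, math.inf, one_sided=True),
        "GS2": TrapezoidParams(40.0, 70.0, 80.0, 99.0),
        "GS3_5": TrapezoidParams(30.0, 60.0, 80.0, 99.0),
    }
    vpd = {
        "GS1": {_ALL: VpdBranchSet(
            0.011, 0.030, 0.845, 2.248,
            rising=Quadratic(-1220.0, 103.6, -1.015),
            falling=ExpPair(-0.1046, 0.5763, 2.296, -0.799))},
        "GS2": {
            # rising branch sign-normalized (published first term is -0.626)
            "sun": VpdBranchSet(
                0.012, 0.596, 1.069, 4.422,
                rising=ExpPair(0.626, 0.8509, -0.6655, -4.974),
                falling=ExpPair(-0.0339, 0.4326, 1.711, -0.4562)),
            "cloud": VpdBranchSet(
                0.012, 0.528, 0.895, 4.422,
                rising=ExpPair(-0.6922, -4.889, 0.6492, 0.9212),
                falling=ExpPair(-0.01505, 0.5616, 1.591, -0.4981)),
            "night": VpdBranchSet(
                0.012, 0.412, 0.701, 4.422,
                rising=ExpPair(0.3573, 2.577, -0.3947, -7.396),
                falling=ExpPair(-0.004572, 0.7733, 1.459, -0.5429)),
        },
        "GS3_5": {
            "sun": VpdBranchSet(
                0.012, 0.596, 1.425, 5.160,
                rising=ExpPair(0.626, 0.8509, -0.6655, -4.974),
                falling=ExpPair(-0.03852, 0.3585, 1.864, -0.3953)),
            # rising branch sign-normalized (published signs are swapped)
            "cloud": VpdBranchSet(
                0.012, 0.528, 1.193, 5.160,
                rising=ExpPair(-0.6922, -4.889, 0.6492, 0.92124),
                falling=ExpPair(-0.01806, 0.4577, 1.711, -0.4284)),
            "night": VpdBranchSet(
                0.012, 0.413, 0.935, 5.160,
                rising=ExpPair(0.3573, 2.577, -0.3947, -7.396),
                falling=ExpPair(-0.005992, 0.6209, 1.546, -0.4643)),
        },
    }
    return MembershipParams(temperature=temperature, humidity=humidity,
                            vpd=vpd)


def literal_printed_params() -> MembershipParams:
    """The table with the VPD branch signs exactly as published.

    Differs from :func:`default_params` only in the stage-2 sun and
    stage-3-5 cloud rising branches, whose published signs make the branch
    evaluate to about -1 where the anchor semantics require +1.  Shipped so
    :func:`audit_membership_table` can demonstrate the defect.
    """
    p = default_params()
    vpd = {s: dict(t) for s, t in p.vpd.items()}
    vpd["GS2"]["sun"] = replace(
        vpd["GS2"]["sun"],
        rising=ExpPair(-0.626, 0.8509, -0.6655, -4.974))
    vpd["GS3_5"]["cloud"] = replace(
        vpd["GS3_5"]["cloud"],
        rising=ExpPair(0.6922, -4.889, -0.6492, 0.92124))
    return replace(p, vpd=vpd)


DEFAULT_PARAMS = default_params()


# --------------------------------------------------------------------------
# Membership evaluation
# --------------------------------------------------------------------------

def _as_array(x, fieldname: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(fieldname, "non-finite value")
    return arr, arr.ndim == 0


def _eval_trapezoid(x: np.ndarray, p: TrapezoidParams) -> np.ndarray:
    """Linear-ramp membership.  Plateau closed, support open (score 0 at
    exactly the failure borders); the stage-2 night two-segment rise hits
    0.5 exactly at ``g0_5``."""
    out = np.zeros_like(x, dtype=float)
    plateau = (x >= p.g1_min) & (x <= p.g1_max) if not p.one_sided \
        else (x >= p.g1_min)
    out[plateau] = 1.0

    rise = (x > p.g0_min) & (x < p.g1_min)
    if p.g0_5 is None:
        out[rise] = (x[rise] - p.g0_min) / (p.g1_min - p.g0_min)
    else:
        lo = rise & (x < p.g0_5)
        hi = rise & (x >= p.g0_5)
        out[lo] = 0.5 * (x[lo] - p.g0_min) / (p.g0_5 - p.g0_min)
        out[hi] = 0.5 + 0.5 * (x[hi] - p.g0_5) / (p.g1_min - p.g0_5)

    if not p.one_sided:
        fall = (x > p.g1_max) & (x < p.g0_max)
        out[fall] = (p.g0_max - x[fall]) / (p.g0_max - p.g1_max)
    return np.clip(out, 0.0, 1.0)


def optdeg_temperature(T, stage: GrowthStage, light: LightCondition,
                       params: MembershipParams = None):
    """OptDeg(T): air-temperature optimality in [0, 1]."""
    params = params or DEFAULT_PARAMS
    x, scalar = _as_array(T, "T")
    out = _eval_trapezoid(np.atleast_1d(x), params.temperature_for(stage, light))
    return float(out[0]) if scalar else out.reshape(x.shape)


def optdeg_humidity(RH, stage: GrowthStage,
                    params: MembershipParams = None):
    """OptDeg(RH): relative-humidity optimality in [0, 1].

    Light-independent.  RH must lie in [0, 100] %.
    """
    params = params or DEFAULT_PARAMS
    x, scalar = _as_array(RH, "RH")
    if np.any((x < 0.0) | (x > 100.0)):
        raise InvalidInputError("RH", "relative humidity outside [0, 100] %")
    out = _eval_trapezoid(np.atleast_1d(x), params.humidity_for(stage))
    return float(out[0]) if scalar else out.reshape(x.shape)


def optdeg_vpd(vpd, stage: GrowthStage, light: LightCondition,
               params: MembershipParams = None):
    """OptDeg(VPD): vapor-pressure-deficit optimality in [0, 1].

    Plateau closed, support open; the fitted quadratic/exponential branches
    slightly over/undershoot their endpoints (residuals <= ~0.02), so the
    result is clamped to [0, 1].
    """
    params = params or DEFAULT_PARAMS
    x, scalar = _as_array(vpd, "vpd")
    if np.any(x < 0.0):
        raise InvalidInputError("vpd", "negative vapor pressure deficit")
    p = params.vpd_for(stage, light)
    xv = np.atleast_1d(x)
    out = np.zeros_like(xv, dtype=float)
    out[(xv >= p.g1_min) & (xv <= p.g1_max)] = 1.0
    rise = (xv > p.g0_min) & (xv < p.g1_min)
    out[rise] = p.rising(xv[rise])
    fall = (xv > p.g1_max) & (xv < p.g0_max)
    out[fall] = p.falling(xv[fall])
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out.reshape(x.shape)


@dataclass(frozen=True)
class OptDegRecord:
    """Per-reading scores: VPD plus the three optimality degrees."""

    vpd: float
    opt_t: float
    opt_rh: float
    opt_vpd: float
    stage: GrowthStage
    light: LightCondition


def optdeg_record(T: float, RH: float, stage: GrowthStage,
                  light: LightCondition,
                  params: MembershipParams = None) -> OptDegRecord:
    """Score one (T, RH) reading: VPD is computed first, then all three
    memberships are evaluated under the given stage/light context."""
    stage = GrowthStage(stage)
    light = LightCondition(light)
    v = compute_vpd(T, RH)
    return OptDegRecord(
        vpd=v,
        opt_t=optdeg_temperature(T, stage, light, params),
        opt_rh=optdeg_humidity(RH, stage, params),
        opt_vpd=optdeg_vpd(v, stage, light, params),
        stage=stage, light=light)


# --------------------------------------------------------------------------
# Endpoint audit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditEntry:
    stage: str
    light: str
    branch: str     # "rising" | "falling"
    anchor: str     # "G0_min" | "G1_min" | "G1_max" | "G0_max"
    value: float    # raw branch value at the anchor (pre-clamp)
    residual: float
    flagged: bool


def audit_membership_table(params: MembershipParams = None,
                           tol: float = 0.02) -> list[AuditEntry]:
    """Endpoint quality gate for the fitted VPD branches.

    Every rising branch must give ~0 at G0_min and ~1 at G1_min; every
    falling branch ~1 at G1_max and ~0 at G0_max.  Entries whose residual
    exceeds ``tol`` are flagged; with the shipped sign-normalized defaults
    nothing is flagged at tol = 0.05.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    params = params or DEFAULT_PARAMS
    report: list[AuditEntry] = []
    for stage, table in params.vpd.items():
        for light, p in table.items():
            checks = [
                ("rising", "G0_min", p.g0_min, 0.0),
                ("rising", "G1_min", p.g1_min, 1.0),
                ("falling", "G1_max", p.g1_max, 1.0),
                ("falling", "G0_max", p.g0_max, 0.0),
            ]
            for branch, anchor, x, target in checks:
                f = p.rising if branch == "rising" else p.falling
                val = float(f(x))
                res = abs(val - target)
                report.append(AuditEntry(stage, light, branch, anchor,
                                         val, res, res > tol))
    return report
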