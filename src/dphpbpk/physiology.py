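"""Virtual-individual physiology: organ volumes, blood flows, ontogeny.

Constructs age- and sex-parameterized individuals from packaged
literature-informed reference tables (growth, organ volume fractions,
regional flow fractions, albumin-vs-age, CYP ontogeny). Supported age
range is 2-100 years; neonates and infants are outside the model's domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

ORGANS = (
    "lung", "brain", "heart", "kidney", "liver", "gut", "spleen", "stomach",
    "muscle", "skin", "adipose", "bone", "gonads", "rest",
    "arterial_blood", "venous_blood",
)
#: tissues perfused in parallel from the arterial pool (everything except
#: lung, liver and the blood pools; liver also receives the portal outflow)
PERFUSED = (
    "brain", "heart", "kidney", "gut", "spleen", "stomach", "muscle",
    "skin", "adipose", "bone", "gonads", "rest",
)
PORTAL = ("gut", "spleen", "stomach")
ENZYMES = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6")

MIN_AGE = 2.0
MAX_AGE = 100.0

# reference cardiac output (L/h) for the 30-y reference adult of each sex;
# scaled allometrically with body weight (exponent 0.75) and reduced by
# 0.45 %/year past age 35
_CO_REF = {"male": 390.0, "female": 330.0}
_CO_REF_WEIGHT = {"male": 73.0, "female": 60.0}
_CO_AGE_DECLINE = 0.0045
_HEMATOCRIT = {"male": 0.45, "female": 0.40}


def _data_path(name: str):
    return resources.files("dphpbpk.data").joinpath(name)


@lru_cache(maxsize=None)
def _load_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, comment="#")


@dataclass(frozen=True)
class OntogenyCurve:
    """Hill-type maturation of one hepatic enzyme's expression with age."""

    enzyme: str
    half_maturation_age: float  # years
    hill_coefficient: float
    birth_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.birth_fraction < 1.0:
            raise ValueError("birth_fraction must be in [0, 1)")
        if self.half_maturation_age <= 0 or self.hill_coefficient <= 0:
            raise ValueError("TM50 and Hill coefficient must be positive")


@dataclass
class PhysiologyState:
    """One virtual individual.

    Volumes in L, flows in L/h, weight in kg, height in cm. Enzyme
    expression is a multiplier relative to the adult reference (ontogeny
    times any inter-individual or scenario multiplier).
    """

    age: float
    sex: str
    body_weight: float
    height: float
    organ_volumes: dict[str, float]
    organ_blood_flows: dict[str, float]
    cardiac_output: float
    hematocrit: float
    gfr_fraction_of_adult: float
    albumin_ratio_to_adult: float
    enzyme_expression: dict[str, float]
    mppgl: float = 40.0  # mg microsomal protein per g liver
    portosystemic_shunt_fraction: float = 0.0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        for organ in ORGANS:
            if organ not in self.organ_volumes or self.organ_volumes[organ] <= 0:
                raise ValueError(f"missing or nonpositive volume for {organ}")
        for k, v in self.organ_blood_flows.items():
            if v <= 0:
                raise ValueError(f"nonpositive blood flow for {k}")
        for e, x in self.enzyme_expression.items():
            if x < 0:
                raise ValueError(f"negative expression for {e}")
        q_sum = sum(self.organ_blood_flows[o] for o in PERFUSED)
        q_sum += self.organ_blood_flows["liver"]  # hepatic arterial
        if abs(q_sum - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValueError("organ flows do not sum to cardiac output")

    @property
    def liver_blood_flow_total(self) -> float:
        """Total liver inflow: hepatic artery plus portal vein (L/h)."""
        return self.organ_blood_flows["liver"] + sum(
            self.organ_blood_flows[o] for o in PORTAL
        )

    def with_expression(self, multipliers: dict[str, float]) -> "PhysiologyState":
        expr = dict(self.enzyme_expression)
        for e, m in multipliers.items():
            if e not in expr:
                raise KeyError(f"unknown enzyme {e!r}")
            expr[e] = expr[e] * m
        return replace(self, enzyme_expression=expr)


def load_ontogeny_curves() -> dict[str, OntogenyCurve]:
    df = _load_csv("ontogeny.csv")
    return {
        r.enzyme: OntogenyCurve(r.enzyme, r.tm50_years, r.hill, r.birth_fraction)
        for r in df.itertuples()
    }


def ontogeny_fraction(curve: OntogenyCurve, age: float) -> float:
    """Fraction of adult enzyme expression at a given age (years)."""
    if age < 0:
        raise ValueError("age must be nonnegative")
    h = curve.hill_coefficient
    t = curve.half_maturation_age
    sat = age**h / (age**h + t**h) if age > 0 else 0.0
    return curve.birth_fraction + (1.0 - curve.birth_fraction) * sat


def scale_fraction_unbound(fu_adult: float, albumin_ratio: float) -> float:
    """Scale plasma fraction unbound for altered binding-protein levels.

    Assumes binding capacity proportional to albumin: the bound:free ratio
    scales with the albumin concentration ratio.
    """
    if not 0 < fu_adult <= 1:
        raise ValueError("fu_adult must be in (0, 1]")
    if albumin_ratio < 0:
        raise ValueError("albumin_ratio must be nonnegative")
    return 1.0 / (1.0 + albumin_ratio * (1.0 - fu_adult) / fu_adult)


def mppgl_for_age(age: float) -> float:
    """Microsomal protein per gram liver (mg/g), cubic-in-age log10 form."""
    a = min(age, 60.0)  # published fit covers to ~60 y; hold flat beyond
    return 10.0 ** (1.407 + 0.0158 * a - 0.00038 * a**2 + 2.3e-6 * a**3)


def gfr_fraction_for_age(age: float) -> float:
    """Glomerular filtration relative to adult; ~1 for ages >= 2 y."""
    return age**2.2 / (age**2.2 + 0.65**2.2)


def _interp(df: pd.DataFrame, xcol: str, ycol: str, x: float) -> float:
    return float(np.interp(x, df[xcol].to_numpy(), df[ycol].to_numpy()))


def default_body_size(age: float, sex: str) -> tuple[float, float]:
    """Growth-table median (weight kg, height cm) for an (age, sex)."""
    g = _load_csv("growth.csv")
    g = g[g.sex == sex]
    return (_interp(g, "age_years", "weight_kg", age),
            _interp(g, "age_years", "height_cm", age))


def _organ_fractions(age: float, sex: str) -> dict[str, float]:
    df = _load_csv("organ_fractions.csv")
    col = "frac_male" if sex == "male" else "frac_female"
    out = {}
    for organ, sub in df.groupby("organ"):
        sub = sub.sort_values("age_years")
        out[organ] = _interp(sub, "age_years", col, age)
    return out


def build_reference_individual(
    age: float,
    sex: str,
    body_weight: float | None = None,
    height: float | None = None,
) -> PhysiologyState:
    """Construct a fully parameterized virtual individual.

    Organ volumes come from the packaged age-resolved volume-fraction table
    applied to body weight; flows partition cardiac output with the lumped
    'rest' tissue taking the exact remainder, so flow conservation holds by
    construction. Enzyme expression is the ontogeny fraction at this age
    (adult reference = 1).
    """
    if age < MIN_AGE:
        raise ValueError(
            f"age {age} y is below the supported range: neonate and infant "
            f"(< {MIN_AGE} y) physiologies are excluded from this model"
        )
    if age > MAX_AGE:
        raise ValueError(f"age {age} y exceeds the supported range")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    default_w, default_h = default_body_size(age, sex)
    bw = default_w if body_weight is None else float(body_weight)
    ht = default_h if height is None else float(height)
    if bw <= 0:
        raise ValueError("body weight must be positive")

    fracs = _organ_fractions(age, sex)
    volumes = {organ: fracs[organ] * bw for organ in ORGANS}

    co = _CO_REF[sex] * (bw / _CO_REF_WEIGHT[sex]) ** 0.75
    if age > 35.0:
        co *= max(0.5, 1.0 - _CO_AGE_DECLINE * (age - 35.0))
    flows_df = _load_csv("flow_fractions.csv")
    frac_co = dict(zip(flows_df.organ, flows_df.frac_co))
    named = [o for o in frac_co if o != "rest"]
    flows = {o: frac_co[o] * co for o in named}
    flows["rest"] = co - sum(flows.values())  # exact remainder
    flows["lung"] = co

    alb = _interp(_load_csv("albumin.csv"), "age_years", "ratio_to_adult", age)
    curves = load_ontogeny_curves()
    expression = {e: ontogeny_fraction(curves[e], age) for e in ENZYMES}

    return PhysiologyState(
        age=age,
        sex=sex,
        body_weight=bw,
        height=ht,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        cardiac_output=co,
        hematocrit=_HEMATOCRIT[sex],
        gfr_fraction_of_adult=gfr_fraction_for_age(age),
        albumin_ratio_to_adult=alb,
        enzyme_expression=expression,
        mppgl=mppgl_for_age(age),
    )
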