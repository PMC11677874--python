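"""Drug parameters and derived distribution quantities.

Houses the diphenhydramine parameter set (physicochemistry, binding,
permeability, CYP kinetics, renal clearance) and computes ionization,
Rodgers-Rowland tissue:plasma partition coefficients, and the Caco-2
derived first-order absorption rate constant.

The compound is a moderate-to-strong monoprotic base (pKa 8.98), which
selects the acidic-phospholipid branch of the Rodgers-Rowland scheme: the
erythrocyte partition implied by the blood:plasma ratio calibrates the
acidic-phospholipid association constant, which then drives partitioning
into lean tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import pandas as pd
import yaml

from .physiology import _load_csv

PLASMA_PH = 7.4
TISSUE_CELL_PH = 7.0
ERYTHROCYTE_PH = 7.22

# smooth-cylinder small-intestine geometry: surface-to-volume ratio 2/r with
# the reference human jejunal radius; converts Caco-2 permeability (cm/s)
# to a first-order ka (1/h), timed qualitatively to the adult oral profile
GUT_RADIUS_CM = 1.75
GUT_SURFACE_TO_VOLUME_CM = 2.0 / GUT_RADIUS_CM


@dataclass(frozen=True)
class EnzymeKinetics:
    enzyme: str
    vmax: float       # pmol/min/pmol recombinant enzyme
    km: float         # µM
    abundance: float  # pmol/mg microsomal protein (packaged default)

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0 or self.abundance < 0:
            raise ValueError("invalid enzyme kinetics")


@dataclass(frozen=True)
class DrugParameters:
    name: str
    molecular_weight: float       # g/mol
    log_p: float
    pka: float                    # monoprotic base
    water_solubility: float       # mg/mL
    fu_plasma_adult: float
    binding_protein: str
    caco2_permeability: float     # cm/s
    specific_organ_permeability: float  # cm/min, informational
    renal_clearance_per_kg: float       # L/h/kg
    blood_to_plasma_ratio: float
    calibration_factor: float
    enzyme_kinetics: tuple[EnzymeKinetics, ...]

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if not 0 < self.fu_plasma_adult <= 1:
            raise ValueError("fu must be in (0, 1]")
        if not 0 < self.pka < 14:
            raise ValueError("pKa out of range")
        if self.renal_clearance_per_kg < 0:
            raise ValueError("renal clearance must be nonnegative")


def load_drug(path=None) -> DrugParameters:
    """Load a drug config; defaults to the packaged diphenhydramine fixture."""
    if path is None:
        src = resources.files("dphpbpk.data").joinpath("diphenhydramine.yaml")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    kinetics = tuple(
        EnzymeKinetics(
            enzyme=e["enzyme"],
            vmax=float(e["vmax_pmol_min_pmol"]),
            km=float(e["km_um"]),
            abundance=float(e["abundance_pmol_mg"]),
        )
        for e in cfg["enzyme_kinetics"]
    )
    return DrugParameters(
        name=cfg["name"],
        molecular_weight=float(cfg["molecular_weight"]),
        log_p=float(cfg["log_p"]),
        pka=float(cfg["pka"]),
        water_solubility=float(cfg["water_solubility_mg_ml"]),
        fu_plasma_adult=float(cfg["fu_plasma_adult"]),
        binding_protein=cfg["binding_protein"],
        caco2_permeability=float(cfg["caco2_permeability_cm_s"]),
        specific_organ_permeability=float(cfg["specific_organ_permeability_cm_min"]),
        renal_clearance_per_kg=float(cfg["renal_clearance_l_h_kg"]),
        blood_to_plasma_ratio=float(cfg["blood_to_plasma_ratio"]),
        calibration_factor=float(cfg["calibration_factor"]),
        enzyme_kinetics=kinetics,
    )


def dump_drug(drug: DrugParameters, path) -> None:
    """Write a drug config that round-trips through :func:`load_drug`."""
    cfg = {
        "name": drug.name,
        "molecular_weight": drug.molecular_weight,
        "log_p": drug.log_p,
        "pka": drug.pka,
        "water_solubility_mg_ml": drug.water_solubility,
        "fu_plasma_adult": drug.fu_plasma_adult,
        "binding_protein": drug.binding_protein,
        "caco2_permeability_cm_s": drug.caco2_permeability,
        "specific_organ_permeability_cm_min": drug.specific_organ_permeability,
        "renal_clearance_l_h_kg": drug.renal_clearance_per_kg,
        "blood_to_plasma_ratio": drug.blood_to_plasma_ratio,
        "calibration_factor": drug.calibration_factor,
        "enzyme_kinetics": [
            {
                "enzyme": k.enzyme,
                "vmax_pmol_min_pmol": k.vmax,
                "km_um": k.km,
                "abundance_pmol_mg": k.abundance,
            }
            for k in drug.enzyme_kinetics
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass(frozen=True)
class TissueComposition:
    tissue: str
    f_extracellular_water: float
    f_intracellular_water: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    acidic_phospholipid: float  # mg/g tissue

    def __post_init__(self):
        for f in (self.f_extracellular_water, self.f_intracellular_water,
                  self.f_neutral_lipid, self.f_neutral_phospholipid):
            if not 0 <= f <= 1:
                raise ValueError("fractional volumes must be in [0, 1]")
        if self.acidic_phospholipid < 0:
            raise ValueError("acidic phospholipid must be nonnegative")


def load_tissue_compositions() -> dict[str, TissueComposition]:
    df = _load_csv("tissue_composition.csv")
    return {
        r.tissue: TissueComposition(
            r.tissue, r.f_ew, r.f_iw, r.f_nl, r.f_np, r.ap_mg_g
        )
        for r in df.itertuples()
    }


def ionized_fraction(pka: float, ph: float) -> float:
    """Henderson-Hasselbalch ionized fraction for a monoprotic base."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def acidic_phospholipid_association(
    drug: DrugParameters,
    blood_cells: TissueComposition,
    hematocrit: float = 0.45,
    fu: float | None = None,
) -> float:
    """Association constant to acidic phospholipid, from the B:P ratio.

    The erythrocyte:plasma-water partition implied by the measured
    blood:plasma ratio, less its water and neutral-lipid terms, is
    attributed to acidic-phospholipid binding of the ionized base.
    """
    fu = drug.fu_plasma_adult if fu is None else fu
    p = 10.0 ** drug.log_p
    y = 1.0 + 10.0 ** (drug.pka - PLASMA_PH)
    x_bc = 1.0 + 10.0 ** (drug.pka - ERYTHROCYTE_PH)
    kpu_bc = (drug.blood_to_plasma_ratio - (1.0 - hematocrit)) / (hematocrit * fu)
    water_term = (x_bc / y) * blood_cells.f_intracellular_water
    lipid_term = (
        p * blood_cells.f_neutral_lipid
        + (0.3 * p + 0.7) * blood_cells.f_neutral_phospholipid
    ) / y
    residual = kpu_bc - water_term - lipid_term
    if residual <= 0:
        raise ValueError(
            "blood:plasma ratio leaves no residual erythrocyte binding to "
            "attribute to acidic phospholipid; check B:P, Hct and fu"
        )
    return residual * y / (blood_cells.acidic_phospholipid * 10.0 ** (drug.pka - ERYTHROCYTE_PH))


def partition_coefficients(
    drug: DrugParameters,
    compositions: dict[str, TissueComposition] | None = None,
    tissues: tuple[str, ...] | None = None,
    fu: float | None = None,
    hematocrit: float = 0.45,
) -> dict[str, float]:
    """Total tissue:plasma partition coefficients (Rodgers-Rowland, base form).

    Kp = fu * Kpu with
    Kpu = f_EW + X/Y * f_IW + Ka_AP * [AP] * 10^(pKa - pH_iw) / Y
          + (P * f_NL + (0.3 P + 0.7) * f_NP) / Y
    where X = 1 + 10^(pKa - pH_iw), Y = 1 + 10^(pKa - pH_p). Adipose uses the
    vegetable-oil:water convention for the neutral-lipid partition
    (log P_vo = 1.115 log P - 1.35).
    """
    if drug.pka <= 7.0:
        raise ValueError("acidic-phospholipid scheme requires a base with pKa > 7")
    comps = load_tissue_compositions() if compositions is None else compositions
    fu = drug.fu_plasma_adult if fu is None else fu
    if "blood_cells" not in comps:
        raise ValueError("composition set must include a blood_cells row")
    ka_ap = acidic_phospholipid_association(
        drug, comps["blood_cells"], hematocrit=hematocrit, fu=fu
    )
    p = 10.0 ** drug.log_p
    p_adipose = 10.0 ** (1.115 * drug.log_p - 1.35)
    x = 1.0 + 10.0 ** (drug.pka - TISSUE_CELL_PH)
    y = 1.0 + 10.0 ** (drug.pka - PLASMA_PH)
    wanted = tuple(t for t in comps if t != "blood_cells") if tissues is None else tissues
    out = {}
    for t in wanted:
        if t not in comps:
            raise ValueError(f"no tissue composition available for {t!r}")
        c = comps[t]
        p_eff = p_adipose if t == "adipose" else p
        kpu = (
            c.f_extracellular_water
            + (x / y) * c.f_intracellular_water
            + ka_ap * c.acidic_phospholipid * 10.0 ** (drug.pka - TISSUE_CELL_PH) / y
            + (p_eff * c.f_neutral_lipid + (0.3 * p_eff + 0.7) * c.f_neutral_phospholipid) / y
        )
        out[t] = kpu * fu
    return out


def absorption_rate_constant(drug: DrugParameters) -> float:
    """First-order absorption rate constant ka (1/h) from Caco-2 permeability.

    ka = Papp (cm/s) * 3600 * (surface/volume of the absorbing lumen, 1/cm).
    """
    if drug.caco2_permeability < 0:
        raise ValueError("permeability must be nonnegative")
    return drug.caco2_permeability * 3600.0 * GUT_SURFACE_TO_VOLUME_CM
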