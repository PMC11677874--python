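"""Synthetic observed data and transcribed NCA summary fixtures.

The source concentration-time datasets behind the observed NCA summaries
are digitized literature figures that are not redistributable; this module
(a) generates synthetic observed datasets with the same study designs and
multiplicative residual noise so the evaluation pipeline is testable end
to end, and (b) ships the transcribed predicted/observed NCA summary
fixture with an integrity checksum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .physiology import PhysiologyState, build_reference_individual, ENZYMES
from .drug import DrugParameters
from .engine import DoseRegimen, simulate
from .evaluation import PredObsPair
from .population import PopulationSpec, sample_population

#: default sampling schedule (h) for synthetic observed curves
DEFAULT_SAMPLING_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)

# sha256 of the packaged table3_observed.csv fixture
_TABLE3_SHA256 = "bf78727ac703dc963189326eee89a3282d658d6006812dea6ff33d2770c0b0e6"


@dataclass(frozen=True)
class StudyDesign:
    label: str
    cohort: str
    route: str
    formulation: str
    dose: float
    per_kg: bool
    age_range: tuple[float, float]
    age_ref: float
    sex_ref: str
    weight_ref: float | None
    female_fraction: float
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    def regimen(self) -> DoseRegimen:
        return DoseRegimen(
            route=self.route, amount=self.dose, per_kg=self.per_kg,
            formulation=self.formulation,
        )

    def reference_individual(self) -> PhysiologyState:
        return build_reference_individual(
            self.age_ref, self.sex_ref, body_weight=self.weight_ref
        )


@dataclass
class SyntheticObservation:
    design: StudyDesign
    data: pd.DataFrame      # subject_id, time_h, conc_ng_ml
    noise_cv: float
    seed: int
    true_states: list = field(default_factory=list)


def load_study_designs() -> dict[str, StudyDesign]:
    """The twelve observed-profile study designs (packaged fixture)."""
    src = resources.files("dphpbpk.data").joinpath("study_designs.csv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p, comment="#")
    out = {}
    for r in df.itertuples():
        out[r.label] = StudyDesign(
            label=r.label,
            cohort=r.cohort,
            route=r.route,
            formulation=r.formulation,
            dose=float(r.dose),
            per_kg=bool(r.per_kg),
            age_range=(float(r.age_min), float(r.age_max)),
            age_ref=float(r.age_ref),
            sex_ref=r.sex_ref,
            weight_ref=None if pd.isna(r.weight_ref) else float(r.weight_ref),
            female_fraction=float(r.female_fraction),
        )
    return out


def generate_observed(
    design: StudyDesign,
    truth_drug: DrugParameters,
    noise_cv: float = 0.15,
    n_subjects: int = 12,
    seed: int = 0,
    variability: dict | None = None,
) -> SyntheticObservation:
    """Simulate a virtual study and overlay multiplicative residual noise.

    Each subject is sampled from the design's demographic range, simulated
    with the truth model, sampled at the design's schedule, and each
    concentration is multiplied by an independent lognormal deviate with
    natural-scale mean 1 and the stated CV. Fully reproducible per seed.
    """
    if noise_cv < 0:
        raise ValueError("noise CV must be nonnegative")
    rng = np.random.default_rng(seed)
    spec = PopulationSpec(
        label=design.label,
        age_range=design.age_range,
        dose=design.regimen(),
        n=n_subjects,
        female_fraction=design.female_fraction,
        **({"variability": variability} if variability is not None else {}),
    )
    cohort = sample_population(spec, seed=seed)
    times = np.asarray(design.sampling_times)
    t_end = float(times[-1])
    rows = []
    for sid, ind in enumerate(cohort):
        res = simulate(ind, truth_drug, design.regimen(), t_end=t_end, t_step=0.05)
        conc = np.interp(times, res.time_grid, res.plasma_concentration)
        if noise_cv > 0:
            sigma2 = np.log(1.0 + noise_cv**2)
            noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(times))
            conc = conc * noise
        conc = np.maximum(conc, 0.0)
        for t, c in zip(times, conc):
            rows.append({"subject_id": sid, "time_h": t, "conc_ng_ml": c})
    return SyntheticObservation(
        design=design,
        data=pd.DataFrame(rows),
        noise_cv=noise_cv,
        seed=seed,
        true_states=cohort,
    )


def load_table3_fixtures(verify_checksum: bool = True):
    """All 12 scenarios x 3 parameters as transcribed pred/obs pairs."""
    src = resources.files("dphpbpk.data").joinpath("table3_observed.csv")
    raw = src.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE3_SHA256:
            raise ValueError(
                "packaged NCA summary fixture failed its integrity checksum"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), comment="#")
    pairs = [
        PredObsPair(
            parameter=r.parameter,
            predicted=float(r.predicted),
            observed=float(r.observed),
            cohort=r.cohort,
            dose_label=r.label,
        )
        for r in df.itertuples()
    ]
    return pairs


def table3_frame() -> pd.DataFrame:
    """The raw transcribed fixture table (with printed ratios)."""
    src = resources.files("dphpbpk.data").joinpath("table3_observed.csv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, comment="#")
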