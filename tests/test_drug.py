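import math
from dataclasses import replace

import pytest

from dphpbpk.drug import (
    GUT_SURFACE_TO_VOLUME_CM,
    DrugParameters,
    TissueComposition,
    absorption_rate_constant,
    dump_drug,
    ionized_fraction,
    load_drug,
    load_tissue_compositions,
    partition_coefficients,
)


def rodgers_rowland_oracle(drug, comp, comp_bc, fu, hct=0.45):
    """Independent step-by-step transcription of the published base-form
    equations, deliberately structured differently from the implementation."""
    ph_p, ph_iw, ph_bc = 7.4, 7.0, 7.22
    P = 10.0 ** drug.log_p
    ion_p = 10.0 ** (drug.pka - ph_p)
    ion_iw = 10.0 ** (drug.pka - ph_iw)
    ion_bc = 10.0 ** (drug.pka - ph_bc)
    # erythrocyte unbound partition from the blood:plasma ratio
    kpu_bc = (drug.blood_to_plasma_ratio - (1 - hct)) / (hct * fu)
    # subtract water and lipid contributions inside the red cell
    kpu_bc_water = comp_bc.f_intracellular_water * (1 + ion_bc) / (1 + ion_p)
    kpu_bc_lipid = (P * comp_bc.f_neutral_lipid
                    + (0.3 * P + 0.7) * comp_bc.f_neutral_phospholipid) / (1 + ion_p)
    ka_ap = ((kpu_bc - kpu_bc_water - kpu_bc_lipid)
             * (1 + ion_p) / (comp_bc.acidic_phospholipid * ion_bc))
    P_t = 10.0 ** (1.115 * drug.log_p - 1.35) if comp.tissue == "adipose" else P
    kpu = (comp.f_extracellular_water
           + comp.f_intracellular_water * (1 + ion_iw) / (1 + ion_p)
           + ka_ap * comp.acidic_phospholipid * ion_iw / (1 + ion_p)
           + (P_t * comp.f_neutral_lipid
              + (0.3 * P_t + 0.7) * comp.f_neutral_phospholipid) / (1 + ion_p))
    return kpu * fu


class TestIonization:
    @pytest.mark.parametrize(
        "pka,ph,expected",
        [(8.98, 8.98, 0.5), (8.98, 7.4, 0.974), (8.98, 14.0, 0.001)],
    )
    def test_henderson_hasselbalch(self, pka, ph, expected):
        got = ionized_fraction(pka, ph)
        if expected in (0.5, 0.974):
            assert got == pytest.approx(expected, abs=5e-4)
        else:
            assert got < expected


class TestPartitionCoefficients:
    def test_oracle_equivalence_all_tissues(self, drug):
        comps = load_tissue_compositions()
        kp = partition_coefficients(drug, comps)
        for tissue, comp in comps.items():
            if tissue == "blood_cells":
                continue
            expected = rodgers_rowland_oracle(
                drug, comp, comps["blood_cells"], drug.fu_plasma_adult
            )
            assert kp[tissue] == pytest.approx(expected, rel=1e-4), tissue

    def test_adipose_below_muscle_for_strong_base(self, drug):
        kp = partition_coefficients(drug)
        assert kp["adipose"] < kp["muscle"]

    def test_all_positive(self, drug):
        assert all(v > 0 for v in partition_coefficients(drug).values())

    def test_pure_water_composition_gives_unit_partition(self, drug):
        comps = dict(load_tissue_compositions())
        comps["water"] = TissueComposition("water", 1.0, 0.0, 0.0, 0.0, 0.0)
        kp = partition_coefficients(drug, comps, tissues=("water",), fu=1.0)
        assert kp["water"] == pytest.approx(1.0)

    def test_missing_tissue_named_in_error(self, drug):
        with pytest.raises(ValueError, match="pancreas"):
            partition_coefficients(drug, tissues=("pancreas",))

    def test_acid_rejected(self, drug):
        weak = replace(drug, pka=4.5)
        with pytest.raises(ValueError, match="base"):
            partition_coefficients(weak)


class TestAbsorption:
    def test_linearity_in_permeability(self, drug):
        ka = absorption_rate_constant(drug)
        doubled = replace(drug, caco2_permeability=2 * drug.caco2_permeability)
        assert absorption_rate_constant(doubled) == pytest.approx(2 * ka)

    def test_default_in_plausible_range(self, drug):
        assert 0.5 <= absorption_rate_constant(drug) <= 5.0

    def test_zero_permeability(self, drug):
        assert absorption_rate_constant(
            replace(drug, caco2_permeability=0.0)) == 0.0


class TestConfigRoundTrip:
    def test_dump_load_identity(self, drug, tmp_path):
        path = tmp_path / "drug.yaml"
        dump_drug(drug, path)
        again = load_drug(path)
        assert again == drug

    def test_solubility_guard_headroom(self, drug):
        # largest studied dose dissolves in well under 250 mL
        assert 87.9 / drug.water_solubility < 250.0
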