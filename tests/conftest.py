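import pytest

from dphpbpk import build_reference_individual, load_drug
from dphpbpk.engine import DoseRegimen, simulate


@pytest.fixture(scope="session")
def drug():
    return load_drug()


@pytest.fixture(scope="session")
def adult(drug):
    return build_reference_individual(33.5, "male")


@pytest.fixture(scope="session")
def iv_result(adult, drug):
    """Shared adult IV 50 mg run (48 h, fine grid)."""
    return simulate(
        adult, drug, DoseRegimen(route="iv_bolus", amount=50.0),
        t_end=48.0, t_step=0.05,
    )


@pytest.fixture(scope="session")
def po_result(adult, drug):
    """Shared adult PO 50 mg Lint80 run."""
    return simulate(
        adult, drug,
        DoseRegimen(route="po", amount=50.0, formulation="lint80"),
        t_end=48.0, t_step=0.05,
    )
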