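"""Model-verification statistics: predicted/observed ratios, average fold
error, and the 0.5-2-fold acceptance screen.

The fold-error statistics follow the standard PBPK verification convention:
R = predicted/observed per parameter, AFE = 10^(mean log10 R) (the
geometric mean of the ratios, sign-preserving), and a screen that flags
every ratio outside [1/fold, fold].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARAMETERS = ("cmax", "auc_0_inf", "clearance")


@dataclass(frozen=True)
class PredObsPair:
    parameter: str
    predicted: float
    observed: float
    cohort: str = ""
    dose_label: str = ""

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError("predicted and observed must be positive")


def r_ratio(pair: PredObsPair) -> float:
    """Predicted-over-observed ratio for one PK parameter."""
    return pair.predicted / pair.observed


def average_fold_error(pairs) -> float:
    """AFE = 10^(sum(log10 predicted/observed)/N), the geometric mean ratio."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("AFE requires at least one pair")
    params = {p.parameter for p in pairs}
    if len(params) > 1:
        raise ValueError(f"AFE mixes parameters: {sorted(params)}")
    logs = [np.log10(r_ratio(p)) for p in pairs]
    return float(10.0 ** np.mean(logs))


def absolute_average_fold_error(pairs) -> float:
    """AAFE variant using absolute logs (always >= 1); optional output."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("AAFE requires at least one pair")
    logs = [abs(np.log10(r_ratio(p))) for p in pairs]
    return float(10.0 ** np.mean(logs))


def two_fold_screen(pairs, fold: float = 2.0):
    """Flag each pair as within [1/fold, fold]; verdict is all-pass."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    pairs = list(pairs)
    flags = [1.0 / fold <= r_ratio(p) <= fold for p in pairs]
    return flags, all(flags)


def evaluation_report(pairs, fold: float = 2.0) -> pd.DataFrame:
    """Per-pair ratio table with fold flags (full precision retained)."""
    rows = []
    for p in pairs:
        r = r_ratio(p)
        rows.append(
            {
                "cohort": p.cohort,
                "dose_label": p.dose_label,
                "parameter": p.parameter,
                "predicted": p.predicted,
                "observed": p.observed,
                "ratio": r,
                "within_fold": 1.0 / fold <= r <= fold,
            }
        )
    return pd.DataFrame(rows)


def afe_by_population(pairs, printed_afe: dict | None = None) -> pd.DataFrame:
    """Per-(cohort, parameter) AFE summary, optionally with a deviation
    column against externally printed AFE values (keyed by
    (cohort, parameter)); recomputed values are reported, never forced."""
    df = evaluation_report(pairs)
    rows = []
    for (cohort, parameter), sub in df.groupby(["cohort", "parameter"]):
        afe = float(10.0 ** np.mean(np.log10(sub["ratio"])))
        row = {"cohort": cohort, "parameter": parameter, "afe": afe,
               "n_pairs": len(sub)}
        if printed_afe is not None:
            printed = printed_afe.get((cohort, parameter))
            row["printed_afe"] = printed
            row["deviation"] = None if printed is None else afe - printed
        rows.append(row)
    return pd.DataFrame(rows)
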