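"""Non-compartmental analysis of concentration-time curves.

Cmax/Tmax, AUC0-t by the linear-up/log-down trapezoid, terminal slope by
best adjusted-R² log-linear regression over the last 3-6 points after Tmax,
AUC0-inf extrapolation, and clearance as dose/AUC0-inf (per-kg when the
dose was given per kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NCAResult:
    cmax: float                 # ng/mL
    tmax: float                 # h
    auc_0_t: float              # ng*h/mL
    auc_0_inf: float | None     # ng*h/mL, None when no terminal phase
    lambda_z: float | None      # 1/h
    half_life: float | None     # h
    clearance: float | None     # L/h (or L/h/kg for per-kg doses)
    extrapolated_fraction: float | None
    n_lambda_points: int | None
    lambda_reason: str | None = None


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def _terminal_slope(t: np.ndarray, c: np.ndarray, i_tmax: int):
    """Best adjusted-R² log-linear fit over the last 3-6 points after Tmax."""
    pos = (c > 0) & (np.arange(len(t)) > i_tmax)
    tt, cc = t[pos], np.log(c[pos])
    best = None
    for n in range(3, 7):
        if n > len(tt):
            break
        x, y = tt[-n:], cc[-n:]
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0]:
            best = (adj, -slope, n)
    return best  # (adj_r2, lambda_z, n) or None


def run_nca(
    times,
    concentrations,
    dose: float,
    per_kg: bool = False,
    iv_c0_extrapolation: bool = False,
) -> NCAResult:
    """Run NCA on one curve.

    `dose` is in mg (or mg/kg with per_kg=True); concentrations in ng/mL;
    times in h, strictly increasing, at least 4 points. For IV-bolus curves
    whose first sample is post-dose, `iv_c0_extrapolation` back-extrapolates
    C0 log-linearly from the first two samples and prepends it at t=0.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 4:
        raise ValueError("NCA requires at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")

    if iv_c0_extrapolation and t[0] > 0 and c[0] > 0 and c[1] > 0 and c[1] < c[0]:
        slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
        c0 = float(np.exp(np.log(c[0]) - slope * t[0]))
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([c0], c))

    i_tmax = int(np.argmax(c))
    cmax, tmax = float(c[i_tmax]), float(t[i_tmax])
    auc_t = _auc_lin_up_log_down(t, c)
    if auc_t <= 0:
        raise ValueError("AUC0-t is nonpositive")

    fit = _terminal_slope(t, c, i_tmax)
    if fit is None:
        return NCAResult(
            cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=None,
            lambda_z=None, half_life=None, clearance=None,
            extrapolated_fraction=None, n_lambda_points=None,
            lambda_reason="no positive terminal decline after Tmax",
        )
    _, lam, n = fit
    c_last = float(c[c > 0][-1])
    auc_inf = auc_t + c_last / lam
    dose_ug = dose * 1000.0
    clearance = dose_ug / auc_inf  # (µg)/(µg*h/L) = L/h; per-kg dose -> L/h/kg
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=lam,
        half_life=float(np.log(2.0) / lam),
        clearance=clearance,
        extrapolated_fraction=(auc_inf - auc_t) / auc_inf,
        n_lambda_points=n,
    )
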