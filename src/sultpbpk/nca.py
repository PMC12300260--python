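"""Non-compartmental analysis and fold-error verification.

Exposure metrics are computed model-free from concentration-time grids:
Cmax/Tmax from the grid maximum, AUC by linear-up/log-down trapezoid, the
terminal slope (lambda_z) from a log-linear regression on the last declining
points, and AUC(0-inf) = AUC(0-last) + C_last/lambda_z.  For multiple-dose
profiles AUC(0-tau) is taken over the final complete dosing interval.

Predictions are verified against observed clinical summaries with the
conventional PBPK fold-error rule: predicted/observed within [0.5, 2.0].
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConcTimeProfile, PopulationResult

__all__ = [
    "ExposureSummary",
    "nca",
    "fold_error",
    "verification_report",
    "population_exposure",
    "observed_exposure_table",
    "FOLD_ERROR_BOUNDS",
]

FOLD_ERROR_BOUNDS = (0.5, 2.0)


@dataclass
class ExposureSummary:
    """NCA exposure metrics for one profile.  Concentrations in ug/mL,
    AUC in ug*h/mL, lambda_z in 1/h."""

    cmax: float
    tmax: float
    auc_0_last: float
    auc_0_inf: float | None = None
    auc_0_tau: float | None = None
    lambda_z: float | None = None
    lambda_z_reliable: bool = False
    statistic: str = "individual"


def _trapezoid_linear_up_log_down(time: np.ndarray, conc: np.ndarray) -> float:
    """Linear trapezoid on rising/flat segments, log trapezoid on declining
    segments with positive endpoints."""
    dt = np.diff(time)
    c1, c2 = conc[:-1], conc[1:]
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    seg = np.where(
        down,
        (c1 - c2) * dt / np.where(down, np.log(np.where(down, c1 / np.where(c2 > 0, c2, 1.0), 1.0)), 1.0),
        0.5 * (c1 + c2) * dt,
    )
    return float(seg.sum())


def _terminal_slope(time: np.ndarray, conc: np.ndarray, min_points: int = 3,
                    max_points: int = 10) -> tuple[float | None, bool]:
    """lambda_z from a log-linear fit on the last declining points after Tmax.

    Returns (lambda_z, reliable); flagged unreliable when fewer than
    ``min_points`` usable points exist, the terminal phase is non-monotone,
    or the fitted slope is non-negative."""
    i_max = int(np.argmax(conc))
    t, c = time[i_max:], conc[i_max:]
    mask = c > 0
    t, c = t[mask], c[mask]
    if len(c) < min_points + 1:
        return None, False
    t, c = t[1:], c[1:]  # exclude Cmax itself
    t, c = t[-max_points:], c[-max_points:]
    if len(c) < min_points:
        return None, False
    monotone = bool(np.all(np.diff(c) < 0))
    slope = np.polyfit(t, np.log(c), 1)[0]
    lam = -float(slope)
    return (lam if lam > 0 else None), (monotone and lam > 0)


def nca(profile: ConcTimeProfile, tau: float | None = None) -> ExposureSummary:
    """Exposure metrics for one concentration-time profile.

    When ``tau`` is given, AUC(0-tau) is computed over the final complete
    interval ``[t_end - tau, t_end]`` (the steady-state interval for a
    regimen simulated to its horizon)."""
    time, conc = profile.time, profile.conc
    if np.any(np.diff(time) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if not np.any(conc > 0):
        return ExposureSummary(cmax=0.0, tmax=0.0, auc_0_last=0.0, auc_0_tau=0.0)
    i_max = int(np.argmax(conc))
    cmax, tmax = float(conc[i_max]), float(time[i_max])
    auc_last = _trapezoid_linear_up_log_down(time, conc)
    lam, reliable = _terminal_slope(time, conc)
    auc_inf = None
    if lam is not None and conc[-1] > 0:
        auc_inf = auc_last + float(conc[-1]) / lam
    auc_tau = None
    if tau is not None:
        t0 = time[-1] - tau
        if t0 < -1e-9:
            raise ValueError("tau longer than the simulated span")
        mask = time >= t0 - 1e-9
        auc_tau = _trapezoid_linear_up_log_down(time[mask], conc[mask])
    return ExposureSummary(
        cmax=cmax, tmax=tmax, auc_0_last=auc_last, auc_0_inf=auc_inf,
        auc_0_tau=auc_tau, lambda_z=lam, lambda_z_reliable=reliable,
    )


def fold_error(predicted: float, observed: float) -> float:
    """Predicted/observed ratio; the conventional acceptance band is
    [0.5, 2.0]."""
    if observed <= 0:
        raise ValueError("observed value must be > 0")
    if predicted <= 0:
        raise ValueError("predicted value must be > 0")
    return predicted / observed


def population_exposure(pop: PopulationResult, tau: float | None = None,
                        statistic: str = "median") -> pd.DataFrame:
    """Per-population exposure summary across all simulated subjects.

    ``statistic='mean'`` reports mean +/- SD (adult convention);
    ``'median'`` reports median (min-max range) (pediatric convention).
    For single-dose profiles the AUC column is AUC(0-inf); with ``tau`` it is
    AUC(0-tau) over the final interval.
    """
    metrics: dict[str, list[float]] = {"cmax": [], "auc": []}
    for prof in pop.profiles:
        summ = nca(prof, tau=tau)
        metrics["cmax"].append(summ.cmax)
        auc = summ.auc_0_tau if tau is not None else summ.auc_0_inf
        metrics["auc"].append(auc if auc is not None else np.nan)
    rows = []
    for name, values in metrics.items():
        v = np.asarray(values, dtype=float)
        if statistic == "mean":
            rows.append((name, float(np.nanmean(v)), float(np.nanstd(v, ddof=1)),
                         float(np.nanmin(v)), float(np.nanmax(v))))
        else:
            rows.append((name, float(np.nanmedian(v)), float(np.nanstd(v, ddof=1)),
                         float(np.nanmin(v)), float(np.nanmax(v))))
    out = pd.DataFrame(rows, columns=["parameter", "value", "sd", "low", "high"])
    out.insert(0, "population", pop.group)
    out["statistic"] = "mean" if statistic == "mean" else "median"
    return out


def observed_exposure_table() -> pd.DataFrame:
    """Shipped observed clinical exposure summaries (adult infusion data from
    Clements 1984; pediatric multiple-dose data from Zuppa 2011)."""
    ref = importlib.resources.files("sultpbpk.data").joinpath("observed_exposure.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def verification_report(predicted: pd.DataFrame, observed: pd.DataFrame,
                        bounds: tuple[float, float] = FOLD_ERROR_BOUNDS) -> pd.DataFrame:
    """Join predicted and observed exposure values and apply the fold-error
    acceptance rule.

    Both frames need columns ``population``, ``parameter``, plus ``value``
    (predicted) and ``observed``.  An empty observed table yields an empty
    report."""
    if observed.empty:
        return pd.DataFrame(columns=[
            "population", "parameter", "predicted", "observed",
            "fold_error", "within_bounds",
        ])
    keys = ["population", "parameter"]
    if "dose_mg_per_kg" in predicted.columns and "dose_mg_per_kg" in observed.columns:
        keys.append("dose_mg_per_kg")
    merged = predicted.merge(observed, on=keys, how="inner", suffixes=("", "_obs"))
    merged["fold_error"] = [
        fold_error(p, o) for p, o in zip(merged["value"], merged["observed"])
    ]
    lo, hi = bounds
    merged["within_bounds"] = (merged["fold_error"] >= lo) & (merged["fold_error"] <= hi)
    cols = keys + ["value", "observed", "fold_error", "within_bounds"]
    out = merged[cols].rename(columns={"value": "predicted"})
    return out
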