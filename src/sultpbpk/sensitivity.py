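"""Km/Vmax perturbation sweeps: drug-drug-interaction sensitivity analysis.

Potential metabolic DDIs on a victim pathway are emulated by scaling its
Michaelis-Menten parameters: raising Km imitates competitive inhibition,
lowering Vmax imitates mechanism-based inhibition, and raising Vmax imitates
induction.  For each age group a deterministic representative subject
(group-midpoint age, no inter-individual variability) is simulated to steady
state and the exposure ratios AUC(perturbed)/AUC(baseline) and the analogous
Cmax ratio are reported per perturbation factor.

The IVIVE calibration factor is frozen at its baseline value: the
perturbation represents an interaction on top of the verified model, not a
re-anchored model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import PBPKModel, pediatric_regimen
from .nca import nca

__all__ = [
    "SweepSpec",
    "SweepResult",
    "km_factors",
    "vmax_factors",
    "run_sweep",
    "classify_direction",
]


def km_factors(n_steps: int = 10, max_fold: float = 10.0) -> np.ndarray:
    """Km multipliers: log-distributed over [1, max_fold], baseline included."""
    return np.unique(np.concatenate([[1.0], np.logspace(0.0, np.log10(max_fold), n_steps)]))


def vmax_factors(n_steps: int = 20, fold: float = 10.0) -> np.ndarray:
    """Vmax multipliers: log-distributed over [1/fold, fold] with the baseline
    factor 1 included."""
    return np.unique(np.concatenate([[1.0], np.logspace(-np.log10(fold), np.log10(fold), n_steps)]))


@dataclass
class SweepSpec:
    """One sensitivity sweep: which pathway/parameter to perturb, which
    multipliers to apply, and which age groups to evaluate."""

    pathway: str
    parameter: str                      # 'km' | 'vmax'
    factors: np.ndarray | None = None
    age_groups: tuple = ("neonate", "infant", "child")
    regimen_convention: str = "table"

    def __post_init__(self) -> None:
        if self.parameter not in ("km", "vmax"):
            raise ValueError("parameter must be 'km' or 'vmax'")
        if self.factors is None:
            self.factors = km_factors() if self.parameter == "km" else vmax_factors()
        self.factors = np.sort(np.asarray(self.factors, dtype=float))
        if not np.any(np.isclose(self.factors, 1.0)):
            raise ValueError("factor grid must include the baseline factor 1")
        if np.any(self.factors <= 0):
            raise ValueError("factors must be > 0")


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame = field(repr=False)  # group, factor, auc_ratio, cmax_ratio

    def ratios(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def max_abs_deviation(self, group: str | None = None) -> float:
        """max |AUC ratio - 1| over the factor grid (optionally one group)."""
        t = self.table if group is None else self.ratios(group)
        return float(np.max(np.abs(t["auc_ratio"] - 1.0)))


def _steady_state_exposure(model: PBPKModel, group: str, convention: str,
                           dose_scale: float = 1.0):
    subject = model.representative_subject(group)
    regimen = pediatric_regimen(group, convention=convention)
    if dose_scale != 1.0:
        from dataclasses import replace

        regimen = replace(regimen, dose_per_kg=regimen.dose_per_kg * dose_scale)
    prof = model.simulate_subject(subject, regimen)
    summ = nca(prof, tau=regimen.interval)
    # Cmax over the final (steady-state) interval
    mask = prof.time >= prof.time[-1] - regimen.interval - 1e-9
    cmax_ss = float(prof.conc[mask].max())
    return summ.auc_0_tau, cmax_ss


def run_sweep(spec: SweepSpec, model: PBPKModel, dose_scale: float = 1.0) -> SweepResult:
    """Evaluate AUC and Cmax ratios on the factor grid for every age group.

    ``dose_scale`` rescales the regimen dose (used to probe the linear
    regime); ratios at factor 1 are exactly 1 by construction.
    """
    if spec.pathway not in model.profile.kinetics:
        raise KeyError(f"pathway {spec.pathway!r} not in compound profile")
    base_kin = model.profile.kinetics[spec.pathway]
    rows = []
    for group in spec.age_groups:
        auc0, cmax0 = _steady_state_exposure(model, group, spec.regimen_convention, dose_scale)
        for factor in spec.factors:
            if np.isclose(factor, 1.0):
                rows.append((group, 1.0, 1.0, 1.0))
                continue
            if spec.parameter == "km":
                perturbed = model.profile.with_kinetics(spec.pathway, km=base_kin.km * factor)
            else:
                perturbed = model.profile.with_kinetics(spec.pathway, vmax=base_kin.vmax * factor)
            pmodel = PBPKModel(perturbed, model.physiology,
                               model.clearance.ontogeny, calibrate=False)
            pmodel.clearance.calibration = model.clearance.calibration
            auc, cmax = _steady_state_exposure(pmodel, group, spec.regimen_convention, dose_scale)
            rows.append((group, float(factor), auc / auc0, cmax / cmax0))
    table = pd.DataFrame(rows, columns=["group", "factor", "auc_ratio", "cmax_ratio"])
    return SweepResult(spec=spec, table=table)


def classify_direction(spec: SweepSpec, factor: float) -> str:
    """DDI scenario label for one perturbation.

    Km increases imitate competitive inhibition (exposure up); Vmax decreases
    imitate mechanism-based inhibition (exposure up); Vmax increases imitate
    induction (exposure down)."""
    if np.isclose(factor, 1.0):
        return "baseline"
    if spec.parameter == "km":
        if factor > 1:
            return "competitive inhibition"
        raise ValueError("Km sweeps only increase Km (factors >= 1)")
    return "mechanism-based inhibition" if factor < 1 else "induction"
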