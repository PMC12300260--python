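"""In vitro-in vivo extrapolation: Table-level Michaelis-Menten kinetics to
age- and concentration-dependent organ clearances and pathway fractions.

Per-pathway intrinsic clearance is scaled bottom-up::

    CLint_i(age, Cu) = Vmax_i * rel_i(age) / (Km_i + Cu)        [uL/min/mg pool]
                       * PPGL(pool, age) * liver_weight(age)
                       * active_hepatic_scalar * calibration
                       * 60e-6                                  [-> L/h]

with Cu the unbound plasma concentration (converted to uM), PPGL the
microsomal or cytosolic protein content, and ``rel_i`` the pathway's
relative-to-adult ontogeny multiplier.  Hepatic clearance follows the
well-stirred liver model; renal clearance scales the adult value by the GFR
maturation fraction.

``calibration`` is a single global middle-out factor solved once so that the
adult linear-range systemic clearance (CLh + CLr) equals the compound's
reference IV clearance; see docs/methods.md.  Pass ``calibrate=False`` to use
the raw bottom-up scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compound import CompoundProfile, EnzymeKinetics
from .physiology import EnzymeOntogenyTable, Physiology, SystemParameters

__all__ = [
    "ClearanceBreakdown",
    "ClearanceModel",
    "pathway_clint",
    "hepatic_clearance",
    "fm_breakdown",
]

_UL_MIN_TO_L_H = 60.0 / 1.0e6

# Fig-5 style reporting categories.
_CATEGORY_OF = {"SULT": "SULT", "UGT": "UGT", "CYP": "CYP"}


def _category(pathway: str) -> str:
    for prefix, cat in _CATEGORY_OF.items():
        if pathway.startswith(prefix):
            return cat
    return "other"


@dataclass
class ClearanceBreakdown:
    """Per-pathway clearance decomposition at one age.

    ``fm`` fractions (hepatic pathways plus ``renal``) are fractions of total
    systemic clearance and sum to 1.
    """

    age: float
    clint: dict[str, float]         # L/h per hepatic pathway
    total_clint: float              # L/h
    clh: float                      # L/h, well-stirred hepatic clearance
    clr: float                      # L/h, GFR-scaled renal clearance
    fm: dict[str, float]            # pathway -> fraction (includes 'renal')

    @property
    def systemic_clearance(self) -> float:
        return self.clh + self.clr

    def fm_by_category(self) -> dict[str, float]:
        """Aggregate fractions into SULT / UGT / CYP / renal."""
        out: dict[str, float] = {"SULT": 0.0, "UGT": 0.0, "CYP": 0.0, "renal": 0.0}
        for pathway, f in self.fm.items():
            key = "renal" if pathway == "renal" else _category(pathway)
            out[key] = out.get(key, 0.0) + f
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, self.clint.get(p, np.nan), f) for p, f in self.fm.items()]
        return pd.DataFrame(rows, columns=["pathway", "clint_l_per_h", "fm"])


def hepatic_clearance(total_clint: float, sys: SystemParameters,
                      fu: float | None = None, bp: float | None = None) -> float:
    """Well-stirred liver model: CLh = Qh * fu_B * CLint / (Qh + fu_B * CLint)."""
    if total_clint < 0:
        raise ValueError("CLint must be >= 0")
    fu = sys.fu_plasma if fu is None else fu
    bp = sys.blood_plasma_ratio if bp is None else bp
    fub = fu / bp
    q = sys.hepatic_blood_flow
    x = fub * total_clint
    return q * x / (q + x) if x > 0 else 0.0


def pathway_clint(kin: EnzymeKinetics, age: float, unbound_conc: float,
                  sys: SystemParameters, ont: EnzymeOntogenyTable,
                  molecular_weight: float, active_hepatic_scalar: float = 1.0,
                  calibration: float = 1.0, multiplier: float = 1.0) -> float:
    """Whole-liver intrinsic clearance (L/h) of one pathway at ``age`` and
    unbound plasma concentration ``unbound_conc`` (mg/L)."""
    if unbound_conc < 0:
        raise ValueError("unbound concentration must be >= 0")
    cu_um = unbound_conc * 1000.0 / molecular_weight
    rel = ont.relative_activity(kin.pathway, age)
    per_mg = kin.vmax * rel * multiplier / (kin.km + cu_um)  # uL/min/mg
    ppgl = sys.cppgl if kin.pool == "cytosolic" else sys.mppgl
    return per_mg * ppgl * sys.liver_weight * active_hepatic_scalar * calibration * _UL_MIN_TO_L_H


class ClearanceModel:
    """Age- and concentration-dependent clearance of a compound under a given
    physiology and ontogeny table.

    Parameters
    ----------
    profile : CompoundProfile
    physiology : Physiology
    ontogeny : EnzymeOntogenyTable, optional
        Defaults to the physiology's table over the built-in SULT library.
    calibrate : bool
        Solve the global intrinsic-clearance calibration factor so that the
        adult linear-range CLh + CLr equals ``profile.cl_iv_reference``.
    """

    def __init__(self, profile: CompoundProfile, physiology: Physiology | None = None,
                 ontogeny: EnzymeOntogenyTable | None = None, calibrate: bool = True):
        self.profile = profile
        self.physiology = physiology if physiology is not None else Physiology(
            fu_plasma=profile.fu_plasma, blood_plasma_ratio=profile.blood_plasma_ratio
        )
        self.ontogeny = ontogeny if ontogeny is not None else self.physiology.ontogeny_table()
        for pathway in profile.pathways:
            if pathway not in self.ontogeny:
                raise KeyError(f"ontogeny table lacks a profile for {pathway!r}")
        self.calibration = 1.0
        if calibrate:
            self.calibration = self._solve_calibration()

    # -- calibration --------------------------------------------------------

    def _solve_calibration(self) -> float:
        """Middle-out anchor: CLh(adult, Cu=0) + CLr(adult) = reference CL_IV."""
        age = self.physiology.adult_age
        sys = self.physiology.system_parameters(age)
        clr = self.renal_clearance(age)
        target_clh = self.profile.cl_iv_reference - clr
        q = sys.hepatic_blood_flow
        if not 0 < target_clh < q:
            raise ValueError(
                "reference CL_IV incompatible with the well-stirred model "
                f"(target hepatic clearance {target_clh:.3g}, liver flow {q:.3g})"
            )
        fub = sys.fu_plasma / sys.blood_plasma_ratio
        needed_clint = q * target_clh / (q - target_clh) / fub
        raw = self._total_clint(age, 0.0, calibration=1.0)
        return needed_clint / raw

    # -- clearances ---------------------------------------------------------

    def _clint_map(self, age: float, unbound_conc: float,
                   multipliers: dict[str, float] | None = None,
                   calibration: float | None = None) -> dict[str, float]:
        sys = self.physiology.system_parameters(age)
        cal = self.calibration if calibration is None else calibration
        mults = multipliers or {}
        return {
            p: pathway_clint(
                kin, age, unbound_conc, sys, self.ontogeny,
                self.profile.molecular_weight, self.profile.active_hepatic_scalar,
                cal, mults.get(p, 1.0),
            )
            for p, kin in self.profile.kinetics.items()
        }

    def _total_clint(self, age, cu, multipliers=None, calibration=None) -> float:
        return float(sum(self._clint_map(age, cu, multipliers, calibration).values()))

    def total_clint(self, age: float, unbound_conc: float = 0.0,
                    multipliers: dict[str, float] | None = None) -> float:
        return self._total_clint(age, unbound_conc, multipliers)

    def pathway_clint(self, pathway: str, age: float, unbound_conc: float = 0.0) -> float:
        return self._clint_map(age, unbound_conc)[pathway]

    def hepatic_clearance(self, age: float, unbound_conc: float = 0.0,
                          multipliers: dict[str, float] | None = None) -> float:
        sys = self.physiology.system_parameters(age)
        return hepatic_clearance(self._total_clint(age, unbound_conc, multipliers), sys)

    def renal_clearance(self, age: float) -> float:
        return self.profile.cl_renal_adult * self.physiology.gfr_fraction(age)

    def systemic_clearance(self, age: float, unbound_conc: float = 0.0,
                           multipliers: dict[str, float] | None = None) -> float:
        return self.hepatic_clearance(age, unbound_conc, multipliers) + self.renal_clearance(age)

    # -- fraction metabolised -----------------------------------------------

    def fm_breakdown(self, age: float, conc: float = 0.0,
                     multipliers: dict[str, float] | None = None) -> ClearanceBreakdown:
        """Fraction of total systemic clearance per pathway at ``age``.

        Evaluated in the linear range (Cu = 0) unless a plasma concentration
        (mg/L) is supplied; saturation is assessed at the unbound plasma
        concentration fu*C.  Each hepatic pathway's share of CLh is its share
        of total CLint; renal fm = CLr / (CLh + CLr)."""
        sys = self.physiology.system_parameters(age)
        cu = sys.fu_plasma * conc
        clint = self._clint_map(age, cu, multipliers)
        total = float(sum(clint.values()))
        clh = hepatic_clearance(total, sys)
        clr = self.renal_clearance(age)
        cl = clh + clr
        fm = {p: (v / total) * (clh / cl) for p, v in clint.items()}
        fm["renal"] = clr / cl
        return ClearanceBreakdown(age=age, clint=clint, total_clint=total,
                                  clh=clh, clr=clr, fm=fm)

    def fm_report(self, ages, labels=None) -> pd.DataFrame:
        """Pathway-fraction table (one row per age x pathway), Fig-5 style."""
        rows = []
        labels = labels or [f"{a:g}y" for a in ages]
        for label, age in zip(labels, ages):
            breakdown = self.fm_breakdown(age)
            for pathway, f in breakdown.fm.items():
                rows.append((label, age, pathway, f))
        return pd.DataFrame(rows, columns=["age_group", "age_years", "pathway", "fm"])


def fm_breakdown(age: float, profile: CompoundProfile,
                 physiology: Physiology | None = None,
                 ontogeny: EnzymeOntogenyTable | None = None,
                 calibrate: bool = True) -> ClearanceBreakdown:
    """One-shot pathway-fraction decomposition at ``age`` (linear range)."""
    return ClearanceModel(profile, physiology, ontogeny, calibrate).fm_breakdown(age)
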