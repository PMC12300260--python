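"""Age-resolved system parameters and enzyme maturation profiles.

Provides the physiological scaffolding a pediatric PBPK model needs: body and
liver growth, hepatic blood flow, microsomal/cytosolic protein per gram of
liver (MPPGL/CPPGL), a GFR maturation fraction for renal-clearance scaling,
and relative-activity ontogeny profiles for every elimination pathway (SULTs
delegate to :mod:`sultpbpk.ontogeny`; UGT/CYP pathways use configurable
exponential maturation defaults).

All constants live in ``data/physiology_defaults.yaml`` and can be overridden
by passing a custom config mapping or YAML path to :class:`Physiology`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import ontogeny as _ontogeny

__all__ = [
    "SystemParameters",
    "ExponentialMaturation",
    "EnzymeOntogenyTable",
    "Physiology",
    "default_physiology",
    "system_parameters",
    "pathway_relative_activity",
]


@dataclass(frozen=True)
class SystemParameters:
    """Physiology snapshot at one age."""

    age: float
    body_weight: float          # kg
    liver_weight: float         # g
    hepatic_blood_flow: float   # L/h
    mppgl: float                # mg microsomal protein / g liver
    cppgl: float                # mg cytosolic protein / g liver
    gfr_fraction: float         # dimensionless, relative to adult
    fu_plasma: float
    blood_plasma_ratio: float


@dataclass(frozen=True)
class ExponentialMaturation:
    """First-order maturation: rel(age) = b + (1-b)(1 - exp(-age/tau)).

    ``birth_fraction`` b is the fraction of adult activity at birth; ``tau``
    (years) sets the maturation half-time (t1/2 = tau*ln 2).  Monotone
    non-decreasing, bounded in [b, 1)."""

    birth_fraction: float
    tau_years: float

    def relative_activity(self, age, reference_age: float | None = None):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        b = self.birth_fraction
        out = b + (1.0 - b) * (1.0 - np.exp(-age / self.tau_years))
        return float(out) if out.ndim == 0 else out


class EnzymeOntogenyTable:
    """Pathway -> relative-activity profile map.

    SULT pathways wrap the fitted abundance curves (ratio to the adult
    reference age); UGT/CYP pathways use the configured maturation profiles.
    """

    def __init__(self, profiles: dict, reference_age: float = _ontogeny.ADULT_REFERENCE_AGE):
        self.profiles = dict(profiles)
        self.reference_age = reference_age

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.profiles

    def pathways(self) -> list[str]:
        return list(self.profiles)

    def relative_activity(self, pathway: str, age):
        if pathway not in self.profiles:
            raise KeyError(f"no ontogeny profile for pathway {pathway!r}")
        prof = self.profiles[pathway]
        if isinstance(prof, ExponentialMaturation):
            return prof.relative_activity(age)
        return prof.relative_activity(age, self.reference_age)


def pathway_relative_activity(table: EnzymeOntogenyTable, pathway: str, age):
    """Relative (to adult) activity of ``pathway`` at ``age`` years."""
    return table.relative_activity(pathway, age)


def _load_config(config) -> dict:
    if config is None:
        ref = importlib.resources.files("sultpbpk.data").joinpath("physiology_defaults.yaml")
        return yaml.safe_load(ref.read_text())
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


class Physiology:
    """Age-dependent system-parameter model built from a config mapping.

    The default configuration uses published growth, liver-allometry, MPPGL
    and GFR-maturation equations (see ``data/physiology_defaults.yaml``);
    adult values are anchored at the reference age (20 years) and constant
    beyond it.
    """

    def __init__(self, config=None, fu_plasma: float = 0.82, blood_plasma_ratio: float = 1.0):
        cfg = _load_config(config)
        self.config = cfg
        self.adult_age = float(cfg["adult_reference_age"])
        self.adult_weight = float(cfg["adult_body_weight_kg"])
        self.adult_flow = float(cfg["adult_hepatic_blood_flow_l_per_h"])
        self.flow_exponent = float(cfg["flow_allometric_exponent"])
        self._wt_ages = np.asarray(cfg["body_weight_table"]["age_years"], dtype=float)
        self._wt_kg = np.asarray(cfg["body_weight_table"]["weight_kg"], dtype=float)
        self._bsa = cfg["bsa"]
        self._liver = cfg["liver"]
        self._mppgl = cfg["mppgl_log10_poly"]
        self.cppgl = float(cfg["cppgl_mg_per_g"])
        self._gfr = cfg["gfr_maturation"]
        self.fu_plasma = fu_plasma
        self.blood_plasma_ratio = blood_plasma_ratio
        self.fu_ontogeny = bool(cfg.get("fu_plasma_ontogeny", False))
        self.enzyme_config = cfg["enzyme_ontogeny"]

    # -- individual quantities ---------------------------------------------

    def _clip_age(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        return np.minimum(age, self.adult_age)

    def body_weight(self, age):
        a = self._clip_age(age)
        out = np.interp(a, self._wt_ages, self._wt_kg)
        return float(out) if out.ndim == 0 else out

    def body_surface_area(self, age):
        bw = self.body_weight(age)
        return self._bsa["coefficient"] * np.power(bw, self._bsa["exponent"])

    def liver_weight(self, age):
        bsa = self.body_surface_area(age)
        return self._liver["bsa_coefficient"] * np.power(bsa, self._liver["bsa_exponent"])

    def hepatic_blood_flow(self, age):
        bw = self.body_weight(age)
        return self.adult_flow * np.power(bw / self.adult_weight, self.flow_exponent)

    def mppgl(self, age):
        a = self._clip_age(age)
        p = self._mppgl
        exponent = p["a0"] + p["a1"] * a + p["a2"] * a**2 + p["a3"] * a**3
        out = np.power(10.0, exponent)
        return float(out) if np.ndim(out) == 0 else out

    def gfr_fraction(self, age):
        """GFR relative to the adult anchor: BSA-normalised size scaling times
        a postmenstrual-age maturation Hill function."""
        a = self._clip_age(age)
        g = self._gfr
        pma_weeks = g["gestation_weeks"] + a * 52.1786
        x = np.power(pma_weeks / g["pma50_weeks"], g["hill"])
        maturation = x / (1.0 + x)
        adult_pma = g["gestation_weeks"] + self.adult_age * 52.1786
        xa = np.power(adult_pma / g["pma50_weeks"], g["hill"])
        maturation_adult = xa / (1.0 + xa)
        size = self.body_surface_area(a) / self.body_surface_area(self.adult_age)
        out = size * maturation / maturation_adult
        return float(out) if np.ndim(out) == 0 else out

    def fu(self, age):
        """Plasma unbound fraction; optionally scaled for reduced neonatal
        albumin when ``fu_plasma_ontogeny`` is enabled (off by default)."""
        if not self.fu_ontogeny:
            return self.fu_plasma
        # Albumin rises from ~75% of adult at birth to adult by ~1 year.
        alb = 0.75 + 0.25 * (1.0 - np.exp(-np.asarray(age, dtype=float) / 0.3))
        fu = 1.0 / (1.0 + alb * (1.0 / self.fu_plasma - 1.0))
        return float(fu) if np.ndim(fu) == 0 else fu

    # -- aggregates ---------------------------------------------------------

    def system_parameters(self, age: float) -> SystemParameters:
        if age < 0:
            raise ValueError("age must be >= 0")
        if age > 100:
            raise ValueError("age must be <= 100")
        return SystemParameters(
            age=float(age),
            body_weight=float(self.body_weight(age)),
            liver_weight=float(self.liver_weight(age)),
            hepatic_blood_flow=float(self.hepatic_blood_flow(age)),
            mppgl=float(self.mppgl(age)),
            cppgl=self.cppgl,
            gfr_fraction=float(self.gfr_fraction(age)),
            fu_plasma=float(self.fu(age)),
            blood_plasma_ratio=self.blood_plasma_ratio,
        )

    def ontogeny_table(self, sult_library: dict | None = None) -> EnzymeOntogenyTable:
        """Build the pathway -> profile table: fitted SULT curves plus the
        configured UGT/CYP maturation profiles."""
        profiles: dict = {}
        lib = sult_library if sult_library is not None else _ontogeny.builtin_ontogeny_library()
        for enzyme, model in lib.items():
            profiles[enzyme] = model
        for pathway, entry in self.enzyme_config.items():
            profiles[pathway] = ExponentialMaturation(
                float(entry["birth_fraction"]), float(entry["tau_years"])
            )
        return EnzymeOntogenyTable(profiles)


def default_physiology() -> Physiology:
    return Physiology()


def system_parameters(age: float, physiology: Physiology | None = None) -> SystemParameters:
    """Module-level convenience: system parameters at ``age`` under the
    default (or supplied) physiology."""
    phys = physiology if physiology is not None else default_physiology()
    return phys.system_parameters(age)
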