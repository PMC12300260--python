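"""Compound profiles: physicochemistry, binding, distribution and multi-pathway
Michaelis-Menten metabolism parameters.

The shipped acetaminophen profile (``data/apap.yaml``) carries the 13 hepatic
elimination pathways (3 UGT, 4 SULT, 6 CYP), the adult renal clearance, and
the reference adult systemic clearance used to anchor IVIVE.  Vmax values are
expressed per mg of the pathway's protein pool — microsomal protein for
CYP/UGT, cytosolic protein for SULT — and are converted to whole-organ
clearances in :mod:`sultpbpk.ivive`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "EnzymeKinetics",
    "CompoundProfile",
    "load_compound",
    "apap",
    "km_mass_units",
]

_POOLS = ("microsomal", "cytosolic")

#: Pathways acetaminophen is cleared by (Table-driven; validation enforces
#: the pool assignment SULT -> cytosolic, CYP/UGT -> microsomal).
KNOWN_PATHWAYS = frozenset(
    {
        "UGT1A1", "UGT1A9", "UGT2B15",
        "SULT1A1", "SULT1A3", "SULT1E1", "SULT2A1",
        "CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP2E1", "CYP3A4",
    }
)


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten parameters for one elimination pathway.

    vmax : pmol/min/mg pool protein; km : uM; pool : 'microsomal'|'cytosolic'.
    """

    pathway: str
    vmax: float
    km: float
    pool: str

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ValueError(f"{self.pathway}: vmax must be > 0")
        if self.km <= 0:
            raise ValueError(f"{self.pathway}: km must be > 0")
        if self.pool not in _POOLS:
            raise ValueError(f"{self.pathway}: pool must be one of {_POOLS}")
        family_pool = "cytosolic" if self.pathway.startswith("SULT") else "microsomal"
        if self.pool != family_pool:
            raise ValueError(
                f"{self.pathway}: expected {family_pool} pool, got {self.pool}"
            )


def km_mass_units(kinetics: EnzymeKinetics, molecular_weight: float) -> float:
    """Convert a Km in uM to mg/L for a compound of the given molecular weight."""
    return kinetics.km * molecular_weight / 1000.0


@dataclass(frozen=True)
class CompoundProfile:
    name: str
    molecular_weight: float
    logp: float
    pka: float
    fu_plasma: float
    blood_plasma_ratio: float
    vss_l_per_kg: float
    cl_iv_reference: float
    cl_renal_adult: float
    active_hepatic_scalar: float
    kinetics: dict[str, EnzymeKinetics]
    kp_scalar: float | None = None  # metadata: unused with a user-input Vss
    absorption: dict = field(default_factory=dict)  # metadata: IV-only model

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.vss_l_per_kg <= 0:
            raise ValueError("vss must be > 0")
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood/plasma ratio must be > 0")
        for key, kin in self.kinetics.items():
            if key != kin.pathway:
                raise ValueError(f"kinetics key {key!r} != pathway {kin.pathway!r}")
            if key not in KNOWN_PATHWAYS:
                raise ValueError(f"unknown pathway {key!r}")

    @property
    def pathways(self) -> list[str]:
        return list(self.kinetics)

    def km_mass(self, pathway: str) -> float:
        """Km of ``pathway`` in mg/L (plasma mass-concentration units)."""
        return km_mass_units(self.kinetics[pathway], self.molecular_weight)

    def with_kinetics(self, pathway: str, *, vmax: float | None = None, km: float | None = None) -> "CompoundProfile":
        """Copy of the profile with one pathway's Vmax and/or Km replaced
        (used by the DDI sensitivity sweeps)."""
        kin = self.kinetics[pathway]
        new = EnzymeKinetics(
            pathway,
            vmax if vmax is not None else kin.vmax,
            km if km is not None else kin.km,
            kin.pool,
        )
        kinetics = dict(self.kinetics)
        kinetics[pathway] = new
        return replace(self, kinetics=kinetics)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "molecular_weight": self.molecular_weight,
            "logp": self.logp,
            "pka": self.pka,
            "fu_plasma": self.fu_plasma,
            "blood_plasma_ratio": self.blood_plasma_ratio,
            "vss_l_per_kg": self.vss_l_per_kg,
            "kp_scalar": self.kp_scalar,
            "cl_iv_reference": self.cl_iv_reference,
            "cl_renal_adult": self.cl_renal_adult,
            "active_hepatic_scalar": self.active_hepatic_scalar,
            "absorption": dict(self.absorption),
            "kinetics": {
                p: {"vmax": k.vmax, "km": k.km, "pool": k.pool}
                for p, k in self.kinetics.items()
            },
        }


_REQUIRED = (
    "name",
    "molecular_weight",
    "fu_plasma",
    "blood_plasma_ratio",
    "vss_l_per_kg",
    "cl_iv_reference",
    "cl_renal_adult",
    "active_hepatic_scalar",
    "kinetics",
)


def load_compound(config) -> CompoundProfile:
    """Build a validated :class:`CompoundProfile` from a YAML/JSON path or a
    mapping mirroring the compound schema."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    missing = [k for k in _REQUIRED if k not in config]
    if missing:
        raise ValueError(f"compound config missing fields: {missing}")
    kinetics = {
        name: EnzymeKinetics(name, float(entry["vmax"]), float(entry["km"]), entry["pool"])
        for name, entry in config["kinetics"].items()
    }
    return CompoundProfile(
        name=config["name"],
        molecular_weight=float(config["molecular_weight"]),
        logp=float(config.get("logp", 0.0)),
        pka=float(config.get("pka", 7.0)),
        fu_plasma=float(config["fu_plasma"]),
        blood_plasma_ratio=float(config["blood_plasma_ratio"]),
        vss_l_per_kg=float(config["vss_l_per_kg"]),
        kp_scalar=float(config["kp_scalar"]) if config.get("kp_scalar") is not None else None,
        cl_iv_reference=float(config["cl_iv_reference"]),
        cl_renal_adult=float(config["cl_renal_adult"]),
        active_hepatic_scalar=float(config["active_hepatic_scalar"]),
        absorption=dict(config.get("absorption", {})),
        kinetics=kinetics,
    )


def apap() -> CompoundProfile:
    """The shipped acetaminophen profile (13 elimination pathways)."""
    ref = importlib.resources.files("sultpbpk.data").joinpath("apap.yaml")
    return load_compound(yaml.safe_load(ref.read_text()))
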