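"""Drug-specific parameters and the small derived quantities built from them.

A :class:`CompoundParams` record carries the physicochemical, binding,
absorption, distribution, elimination and CYP3A4-interaction constants of a
compound.  The module also houses the elementary conversions these records
feed into: Henderson-Hasselbalch ionization, the blood unbound fraction
fu_b = fu_plasma / (B/P), the blood-cell unbound partition coefficient,
the permeability-to-absorption-rate mapping ka = 2*Peff/R for a cylindrical
intestinal tube, and the hybrid Qgut flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidInputError

COMPOUND_TYPES = ("monoprotic base", "monoprotic acid", "neutral")


@dataclass
class CompoundParams:
    """All drug-specific model inputs.

    Units: mw g/mol; papp_caco2 1e-6 cm/s; peff_man 1e-4 cm/s; solubility
    mg/mL; qgut L/h; vss L/kg; clint_hlm uL/min/mg microsomal protein;
    clint_u_liver L/h (whole-liver unbound intrinsic clearance, used for
    victim drugs whose clearance is not microsome-derived); kapp uM;
    kinact 1/h; clint_gut uL/min (whole-gut unbound CYP3A4 intrinsic
    clearance); renal_cl L/h; dose_mg mg.
    """

    name: str
    mw: float
    logp: float = 0.0
    compound_type: str = "neutral"
    pka: Optional[float] = None
    bp_ratio: float = 1.0
    fu_plasma: float = 1.0
    papp_caco2: Optional[float] = None
    peff_man: Optional[float] = None
    solubility: Optional[float] = None
    fu_gut: float = 1.0
    qgut: Optional[float] = None
    vss: Optional[float] = None
    clint_hlm: Optional[float] = None
    clint_u_liver: Optional[float] = None
    kapp: Optional[float] = None
    kinact: float = 0.0
    fu_mic: float = 1.0
    fm_cyp3a4: Optional[float] = None
    clint_gut: float = 0.0
    renal_cl: float = 0.0
    dose_mg: Optional[float] = None
    ka: Optional[float] = None  # 1/h, overrides the Peff-derived value
    source_note: str = field(default="", repr=False)

    def __post_init__(self):
        if self.mw <= 0:
            raise InvalidInputError("mw must be positive")
        if self.compound_type not in COMPOUND_TYPES:
            raise InvalidInputError(
                f"compound_type must be one of {COMPOUND_TYPES}")
        if self.compound_type != "neutral" and self.pka is None:
            raise InvalidInputError("ionizable compounds need a pKa")
        for name in ("fu_plasma", "fu_gut", "fu_mic"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidInputError(f"{name} must lie in (0, 1]")
        if self.bp_ratio <= 0:
            raise InvalidInputError("bp_ratio must be positive")
        if self.fm_cyp3a4 is not None and not 0 <= self.fm_cyp3a4 <= 1:
            raise InvalidInputError("fm_cyp3a4 must lie in [0, 1]")
        if self.kinact > 0 and (self.kapp is None or self.kapp <= 0):
            raise InvalidInputError("kapp must be positive when kinact > 0")
        for name in ("peff_man", "qgut", "clint_gut", "clint_hlm",
                     "clint_u_liver", "renal_cl", "kinact"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "CompoundParams":
        return replace(self, **kwargs)


def fraction_ionized(pka: float, ph: float, compound_type: str) -> float:
    """Henderson-Hasselbalch ionized fraction at the given pH."""
    if compound_type == "monoprotic base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if compound_type == "monoprotic acid":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if compound_type == "neutral":
        return 0.0
    raise InvalidInputError(f"unsupported compound type: {compound_type!r}")


def blood_unbound_fraction(fu_plasma: float, bp_ratio: float) -> float:
    """fu_b = fu_plasma / (B/P); values above 1 are clamped with a warning."""
    if bp_ratio <= 0:
        raise InvalidInputError("bp_ratio must be positive")
    fu_b = fu_plasma / bp_ratio
    if fu_b > 1.0:
        warnings.warn("fu_blood exceeds 1; clamping", stacklevel=2)
        fu_b = 1.0
    return fu_b


def kpu_blood_cells(bp_ratio: float, fu_plasma: float,
                    hematocrit: float) -> float:
    """Unbound blood-cell:plasma partition coefficient implied by B/P.

    Kpu_BC = (B/P - (1 - Hct)) / (Hct * fu_plasma).  When B/P does not
    exceed the plasma fraction there is no measurable cell partitioning and
    0 is returned with a warning.
    """
    if not 0 < hematocrit < 1:
        raise InvalidInputError("hematocrit must lie in (0, 1)")
    if fu_plasma <= 0:
        raise InvalidInputError("fu_plasma must be positive")
    if bp_ratio <= 1.0 - hematocrit:
        warnings.warn("B/P <= 1 - Hct: no blood-cell partitioning",
                      stacklevel=2)
        return 0.0
    return (bp_ratio - (1.0 - hematocrit)) / (hematocrit * fu_plasma)


def ka_from_peff(peff_1e4_cm_s: float, radius_cm: float) -> float:
    """First-order absorption rate from human jejunal permeability.

    Treats the small intestine as a cylinder of radius R:
    ka = 2 * Peff / R, with Peff given in 1e-4 cm/s and converted to cm/h.
    """
    if peff_1e4_cm_s <= 0 or radius_cm <= 0:
        raise InvalidInputError("peff and radius must be positive")
    peff_cm_h = peff_1e4_cm_s * 1e-4 * 3600.0
    return 2.0 * peff_cm_h / radius_cm


def qgut_hybrid(clperm: float, qvilli: float) -> float:
    """Hybrid flow Qgut = Qvilli * CLperm / (Qvilli + CLperm), L/h."""
    if qvilli <= 0:
        raise InvalidInputError("qvilli must be positive")
    if clperm < 0:
        raise InvalidInputError("clperm must be non-negative")
    if clperm == 0:
        return 0.0
    return qvilli * clperm / (qvilli + clperm)


# ---------------------------------------------------------------------------
# Parameter-file IO

_IO_FIELDS = [f.name for f in fields(CompoundParams) if f.name != "source_note"]


def load_compound(path: str | Path) -> CompoundParams:
    """Read a structured compound-parameter file (YAML, snake_case keys).

    Unknown keys are rejected with an error listing the accepted ones.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: expected a key/value mapping")
    unknown = sorted(set(raw) - set(_IO_FIELDS) - {"source_note"})
    if unknown:
        raise InvalidInputError(
            f"unknown keys {unknown}; accepted keys: {sorted(_IO_FIELDS)}")
    return CompoundParams(**raw)


def save_compound(compound: CompoundParams, path: str | Path) -> None:
    """Write a compound record back to YAML (round-trips every field)."""
    data = {}
    for name in _IO_FIELDS:
        value = getattr(compound, name)
        if value is not None:
            data[name] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def piperine() -> CompoundParams:
    """The packaged piperine parameter set (model input values)."""
    return load_compound(Path(__file__).parent / "data" / "piperine.yaml")
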