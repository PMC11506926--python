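"""Mechanistic tissue:plasma partitioning and steady-state volume of
distribution (Rodgers-Rowland "method 2").

The method splits tissue water into extra- and intra-cellular fractions,
lets the ionized species of a base associate with tissue acidic
phospholipids (association constant KaAP back-calculated from blood-cell
partitioning), and adds neutral-lipid/phospholipid partitioning of the
un-ionized species.  For a monoprotic base at tissue pH below plasma pH,
ion trapping and the acidic-phospholipid term dominate.

All partition coefficients are unbound (Kpu, tissue:plasma-water); the
plasma-referenced steady-state volume is

    Vss = V_plasma + sum_t V_t * Kpu_t * fu_plasma

with blood cells included as a tissue via the hematocrit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import InvalidInputError
from .params import CompoundParams, kpu_blood_cells
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

REQUIRED_TISSUES = ("adipose", "bone", "brain", "gut", "heart", "kidney",
                    "liver", "lung", "muscle", "skin", "spleen",
                    "blood_cells", "plasma")


@dataclass(frozen=True)
class TissueComposition:
    tissue: str
    f_ew: float          # fractional extracellular water
    f_iw: float          # fractional intracellular water
    f_nl: float          # fractional neutral lipid
    f_np: float          # fractional neutral phospholipid
    ap: float            # acidic phospholipid, mg/g
    volume_frac: float   # L tissue / kg body weight

    def __post_init__(self):
        for name in ("f_ew", "f_iw", "f_nl", "f_np", "ap", "volume_frac"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.f_ew + self.f_iw > 1.0 + 1e-12:
            raise InvalidInputError("f_ew + f_iw must not exceed 1")


@dataclass(frozen=True)
class PartitionResult:
    kpu_by_tissue: dict
    ka_ap: float
    vss: float           # L/kg


def load_tissue_table(path: str | Path | None = None) -> list[TissueComposition]:
    """Read the delimited tissue table (defaults to the packaged dataset)."""
    if path is None:
        path = Path(__file__).parent / "data" / "tissue_composition.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    return [TissueComposition(**row) for row in df.to_dict("records")]


def _base_ion_ratio(pka: float, ph: float) -> float:
    return 10.0 ** (pka - ph)


def _lipid_term(compound: CompoundParams, comp: TissueComposition) -> float:
    """Neutral-lipid/phospholipid partitioning of the un-ionized species.

    Adipose uses a vegetable-oil:water scale (logD_vo = 1.115 logP - 1.35);
    other tissues use the octanol:water P.
    """
    if comp.tissue == "adipose":
        p = 10.0 ** (1.115 * compound.logp - 1.35)
    else:
        p = 10.0 ** compound.logp
    return p * comp.f_nl + (0.3 * p + 0.7) * comp.f_np


def ka_ap_from_blood(compound: CompoundParams,
                     blood_cells: TissueComposition,
                     hematocrit: float,
                     physiology: Physiology = DEFAULT_PHYSIOLOGY) -> float:
    """Acidic-phospholipid association constant from blood-cell partitioning.

    The measured B/P and fu_plasma give the unbound blood-cell coefficient
    Kpu_BC; subtracting the water and neutral-lipid contributions and
    dividing by the ionized-species phospholipid exposure yields KaAP.
    Negative values (no residual association) are clamped to 0 with a
    warning.
    """
    if compound.compound_type != "monoprotic base" or compound.pka is None:
        raise InvalidInputError("KaAP derivation needs an ionizable base")
    if blood_cells.ap <= 0:
        raise InvalidInputError("blood-cell acidic phospholipid must be > 0")
    kpu_bc = kpu_blood_cells(compound.bp_ratio, compound.fu_plasma, hematocrit)
    y = 1.0 + _base_ion_ratio(compound.pka, physiology.ph_plasma)
    x_bc = 1.0 + _base_ion_ratio(compound.pka, physiology.ph_blood_cells)
    water = blood_cells.f_ew + (x_bc / y) * blood_cells.f_iw
    lipid = _lipid_term(compound, blood_cells) / y
    denom = blood_cells.ap * _base_ion_ratio(
        compound.pka, physiology.ph_blood_cells) / y
    ka_ap = (kpu_bc - water - lipid) / denom
    if ka_ap < 0:
        warnings.warn("negative KaAP back-calculated; clamping to 0",
                      stacklevel=2)
        ka_ap = 0.0
    return ka_ap


def kpu_tissue(compound: CompoundParams, comp: TissueComposition,
               ka_ap: float,
               physiology: Physiology = DEFAULT_PHYSIOLOGY) -> float:
    """Unbound tissue:plasma partition coefficient for one tissue."""
    if ka_ap < 0:
        raise InvalidInputError("ka_ap must be non-negative")
    ph_iw = (physiology.ph_blood_cells if comp.tissue == "blood_cells"
             else physiology.ph_intracellular)
    if compound.compound_type == "monoprotic base" and compound.pka is not None:
        y = 1.0 + _base_ion_ratio(compound.pka, physiology.ph_plasma)
        x = 1.0 + _base_ion_ratio(compound.pka, ph_iw)
        ap_term = ka_ap * comp.ap * _base_ion_ratio(compound.pka, ph_iw) / y
        return (comp.f_ew + (x / y) * comp.f_iw + ap_term
                + _lipid_term(compound, comp) / y)
    # neutral compounds (and the inactive acid path): water plus neutral
    # lipid, no phospholipid association
    return comp.f_ew + comp.f_iw + _lipid_term(compound, comp)


def vss_method2(compound: CompoundParams,
                table: Optional[Sequence[TissueComposition]] = None,
                physiology: Physiology = DEFAULT_PHYSIOLOGY) -> PartitionResult:
    """Plasma-referenced steady-state volume of distribution, L/kg."""
    if table is None:
        table = load_tissue_table()
    by_name = {c.tissue: c for c in table}
    missing = [t for t in REQUIRED_TISSUES if t not in by_name]
    if missing:
        raise InvalidInputError(f"tissue table missing: {missing}")

    hct = physiology.hematocrit
    blood_vf = by_name["blood_cells"].volume_frac + by_name["plasma"].volume_frac
    v_plasma = (1.0 - hct) * blood_vf
    v_cells = hct * blood_vf

    if compound.compound_type == "monoprotic base":
        ka_ap = ka_ap_from_blood(compound, by_name["blood_cells"], hct,
                                 physiology)
    else:
        ka_ap = 0.0

    kpu = {}
    vss = v_plasma
    for comp in table:
        if comp.tissue == "plasma":
            continue
        k = kpu_tissue(compound, comp, ka_ap, physiology)
        kpu[comp.tissue] = k
        vf = v_cells if comp.tissue == "blood_cells" else comp.volume_frac
        vss += vf * k * compound.fu_plasma
    return PartitionResult(kpu_by_tissue=kpu, ka_ap=ka_ap, vss=float(vss))
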