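"""In vitro to in vivo extrapolation of metabolic clearance.

Microsomal CLint (uL/min/mg protein) scales to a whole-liver intrinsic
clearance through the microsomal protein yield (MPPGL, mg/g) and liver
weight; hepatic plasma-flow-limited clearance then follows from the
well-stirred organ model

    CLh = Qh * fu_b * CLint_u / (Qh + fu_b * CLint_u).

Elimination is hepatic and (optionally) renal; renal clearance is
filtration-only, fu_b * GFR.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError


def whole_liver_clint(clint_hlm: float, mppgl: float,
                      liver_weight: float) -> float:
    """Whole-liver intrinsic clearance in L/h from microsomal CLint."""
    if clint_hlm < 0:
        raise InvalidInputError("clint_hlm must be non-negative")
    if mppgl <= 0 or liver_weight <= 0:
        raise InvalidInputError("mppgl and liver_weight must be positive")
    return clint_hlm * mppgl * liver_weight * 60.0 / 1e6


@dataclass(frozen=True)
class HepaticClearance:
    clh: float            # blood clearance, L/h
    extraction: float     # E_h
    availability: float   # F_h = 1 - E_h


def well_stirred_clh(q_h: float, fu_b: float, clint_u: float) -> HepaticClearance:
    """Well-stirred hepatic clearance, extraction and availability."""
    if q_h <= 0:
        raise InvalidInputError("hepatic blood flow must be positive")
    if fu_b < 0 or clint_u < 0:
        raise InvalidInputError("fu_b and clint_u must be non-negative")
    num = fu_b * clint_u
    extraction = num / (q_h + num)
    return HepaticClearance(clh=q_h * extraction, extraction=extraction,
                            availability=1.0 - extraction)


def renal_clearance(fu_b: float, gfr: float = 7.2,
                    enabled: bool = True) -> float:
    """Filtration-only renal clearance fu_b * GFR; exactly 0 when disabled."""
    if fu_b < 0 or gfr < 0:
        raise InvalidInputError("inputs must be non-negative")
    if not enabled:
        return 0.0
    return fu_b * gfr
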