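"""System (drug-independent) parameters of the virtual human.

Standard adult reference values used throughout IVIVE/PBPK work: 70 kg body
weight, hematocrit 0.45, hepatic blood flow 90 L/h, 1650 g liver with
40 mg microsomal protein per gram, a 1.75 cm small-intestinal radius and
18 L/h villous blood flow. Enzyme-turnover rates refer to CYP3A4
(degradation half-lives of roughly 36 h in liver and 23 h in gut).
Population CVs describe log-normal between-subject variability of CYP3A4
abundance (41%) and turnover (68%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidInputError


@dataclass(frozen=True)
class Physiology:
    body_weight: float = 70.0        # kg
    hematocrit: float = 0.45         # fraction of blood volume
    q_h: float = 90.0                # hepatic blood flow, L/h
    liver_weight: float = 1650.0     # g
    mppgl: float = 40.0              # mg microsomal protein / g liver
    q_villi: float = 18.0            # villous blood flow, L/h
    intestinal_radius: float = 1.75  # cm
    gfr: float = 7.2                 # glomerular filtration rate, L/h
    enterocyte_volume: float = 1.0   # effective enterocyte distribution space, L
    blood_volume_frac: float = 0.0771  # L blood / kg body weight
    kdeg_liver: float = 0.0193       # CYP3A4 hepatic degradation rate, 1/h
    kdeg_gut: float = 0.03           # CYP3A4 enterocyte degradation rate, 1/h
    cv_abundance: float = 0.41       # population CV of CYP3A4 abundance
    cv_kdeg: float = 0.68            # population CV of CYP3A4 turnover
    ph_plasma: float = 7.4
    ph_intracellular: float = 7.0
    ph_blood_cells: float = 7.22
    cyp3a4_abundance: float = 1.0    # subject-level multiplier (population module)

    def __post_init__(self):
        for name in ("body_weight", "q_h", "liver_weight", "mppgl", "q_villi",
                     "intestinal_radius", "enterocyte_volume", "kdeg_liver",
                     "kdeg_gut", "blood_volume_frac"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0 < self.hematocrit < 1:
            raise InvalidInputError("hematocrit must lie in (0, 1)")
        for name in ("cv_abundance", "cv_kdeg"):
            cv = getattr(self, name)
            if not 0 <= cv <= 2:
                raise InvalidInputError(f"{name} must lie in [0, 2]")

    def with_(self, **kwargs) -> "Physiology":
        return replace(self, **kwargs)


DEFAULT_PHYSIOLOGY = Physiology()
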