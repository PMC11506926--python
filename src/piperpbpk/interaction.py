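"""Mechanism-based CYP3A4 inactivation and victim co-simulation.

A mechanism-based inactivator removes active enzyme at rate

    lambda(I_u) = kinact * I_u / (Kapp_u + I_u),

opposed by zero-order resynthesis, so the active fraction E (baseline 1)
follows dE/dt = kdeg * (1 - E) - lambda(I_u(t)) * E at each expression
site.  Kapp is unbound-corrected by the microsomal unbound fraction
(Kapp_u = Kapp * fu_mic).  The hepatic driver is the unbound liver-inflow
blood concentration of the perpetrator (systemic blood plus the portal
absorption flux over hepatic blood flow); the gut driver is the unbound
enterocyte concentration.

A victim drug is co-simulated twice - alone and on day 7 of the
perpetrator regimen - and its exposure change is summarised as AUC and
Cmax ratios.  A closed-form static ratio for a low-extraction victim is
provided as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .engine import (LUMEN, N_STATES, SYSTEMIC, CompoundDynamics, ConcProfile,
                     DoseSchedule, ModelOptions, PKMetrics,
                     integrate_with_doses, nca)
from .errors import InvalidInputError
from .params import CompoundParams
from .physiology import DEFAULT_PHYSIOLOGY, Physiology


@dataclass
class EnzymeState:
    site: str            # "liver" | "gut"
    kdeg: float          # 1/h
    e_active: float = 1.0

    def __post_init__(self):
        if self.site not in ("liver", "gut"):
            raise InvalidInputError("site must be 'liver' or 'gut'")
        if self.kdeg <= 0:
            raise InvalidInputError("kdeg must be positive")
        if not 0 <= self.e_active <= 1:
            raise InvalidInputError("e_active must lie in [0, 1]")


@dataclass(frozen=True)
class InteractionResult:
    victim: str
    auc_alone: float
    auc_with: float
    cmax_alone: float
    cmax_with: float
    auc_ratio: float
    cmax_ratio: float
    e_liver_at_victim_dose: float
    e_gut_at_victim_dose: float


def inactivation_rate(i_u: float, kinact: float, kapp_u: float) -> float:
    """lambda = kinact * I_u / (Kapp_u + I_u); saturates at kinact."""
    if i_u < 0 or kinact < 0 or kapp_u < 0:
        raise InvalidInputError("inputs must be non-negative")
    if i_u == 0.0:
        return 0.0
    return kinact * i_u / (kapp_u + i_u)


def enzyme_steady_state(kdeg: float, lam: float) -> float:
    """E at steady state under constant inactivation rate: kdeg/(kdeg+lam)."""
    return kdeg / (kdeg + lam)


def solve_enzyme(i_u_of_t: Callable[[float], float], kdeg: float,
                 kinact: float, kapp_u: float, t_end: float,
                 step: float = 0.05, e0: float = 1.0):
    """Integrate dE/dt = kdeg(1-E) - lambda(I_u(t)) E; returns (t, E)."""
    if kdeg <= 0:
        raise InvalidInputError("kdeg must be positive")

    def rhs(t, y):
        lam = inactivation_rate(i_u_of_t(t), kinact, kapp_u)
        return [kdeg * (1.0 - y[0]) - lam * y[0]]

    t, states = integrate_with_doses(rhs, np.array([e0]), [], t_end, step)
    return t, states[:, 0]


def static_auc_ratio(fm: float, e_liver_ss: float, fg_alone: float,
                     fg_inhibited: float) -> float:
    """Static mechanistic AUC ratio for a low-extraction oral victim."""
    if not 0 <= fm <= 1:
        raise InvalidInputError("fm must lie in [0, 1]")
    for name, v in (("e_liver_ss", e_liver_ss), ("fg_alone", fg_alone),
                    ("fg_inhibited", fg_inhibited)):
        if not 0 < v <= 1:
            raise InvalidInputError(f"{name} must lie in (0, 1]")
    return (fg_inhibited / fg_alone) / (fm * e_liver_ss + (1.0 - fm))


@dataclass(frozen=True)
class DDIOptions:
    washout_h: float = 72.0          # victim AUC window after its dose
    output_step_h: float = 0.05
    auto_inhibition: bool = False    # perpetrator inhibits its own CYP3A4 share
    rtol: float = 1e-8
    atol: float = 1e-12


def cosimulate_ddi(perpetrator: CompoundParams,
                   victim: CompoundParams,
                   physiology: Physiology = DEFAULT_PHYSIOLOGY,
                   perp_schedule: Optional[DoseSchedule] = None,
                   victim_schedule: Optional[DoseSchedule] = None,
                   options: DDIOptions = DDIOptions(),
                   perp_options: ModelOptions = ModelOptions(),
                   victim_options: ModelOptions = ModelOptions(
                       renal_enabled=True)) -> InteractionResult:
    """Victim exposure with and without the perpetrator regimen.

    Defaults follow the studied scenario: perpetrator 20 mg/day for 7 days,
    victim given as a single dose simultaneously with the 7th perpetrator
    dose, exposure read over the following washout window.
    """
    if victim.fm_cyp3a4 is None:
        raise InvalidInputError(f"{victim.name}: fm_cyp3a4 is required")
    if perpetrator.kinact > 0 and perpetrator.kapp is None:
        raise InvalidInputError("perpetrator lacks TDI constants")

    if perp_schedule is None:
        perp_schedule = DoseSchedule(dose_mg=perpetrator.dose_mg or 20.0,
                                     interval_h=24.0, n_doses=7)
    victim_dose_time = (perp_schedule.start_h
                        + (perp_schedule.n_doses - 1) * perp_schedule.interval_h)
    if victim_schedule is None:
        if victim.dose_mg is None:
            raise InvalidInputError(f"{victim.name}: no dose given")
        victim_schedule = DoseSchedule(dose_mg=victim.dose_mg, n_doses=1,
                                       start_h=victim_dose_time)
    t_end = max(victim_schedule.dose_times) + options.washout_h

    alone = _run_joint(perpetrator, victim, physiology,
                       perp_schedule.dose_mg * 0.0, perp_schedule,
                       victim_schedule, t_end, options, perp_options,
                       victim_options)
    combo = _run_joint(perpetrator, victim, physiology,
                       perp_schedule.dose_mg, perp_schedule,
                       victim_schedule, t_end, options, perp_options,
                       victim_options)

    window = (victim_schedule.dose_times[0], t_end)
    m_alone = nca(alone["victim_profile"], window)
    m_combo = nca(combo["victim_profile"], window)
    return InteractionResult(
        victim=victim.name,
        auc_alone=m_alone.auc_last, auc_with=m_combo.auc_last,
        cmax_alone=m_alone.cmax, cmax_with=m_combo.cmax,
        auc_ratio=m_combo.auc_last / m_alone.auc_last,
        cmax_ratio=m_combo.cmax / m_alone.cmax,
        e_liver_at_victim_dose=combo["e_liver_at_victim_dose"],
        e_gut_at_victim_dose=combo["e_gut_at_victim_dose"],
    )


def _run_joint(perpetrator, victim, physiology, perp_dose, perp_schedule,
               victim_schedule, t_end, options, perp_options, victim_options):
    """One joint perpetrator + enzyme + victim integration."""
    p_dyn = CompoundDynamics(perpetrator, physiology, perp_options)
    v_dyn = CompoundDynamics(victim, physiology, victim_options)
    kapp_u = (perpetrator.kapp or 0.0) * perpetrator.fu_mic
    kinact = perpetrator.kinact
    mw = perpetrator.mw
    i_el, i_eg = 2 * N_STATES, 2 * N_STATES + 1  # enzyme state indices

    def rhs(t, y):
        e_l, e_g = y[i_el], y[i_eg]
        if options.auto_inhibition:
            dp, c_ent, c_in = p_dyn.derivatives(y[:N_STATES], e_l, e_g)
        else:
            dp, c_ent, c_in = p_dyn.derivatives(y[:N_STATES])
        dv, _, _ = v_dyn.derivatives(y[N_STATES:2 * N_STATES], e_l, e_g)
        # unbound drivers, mg/L -> uM via 1000/MW; clamp tiny negative
        # integrator excursions
        iu_liver = max(0.0, p_dyn.fu_b * c_in * 1000.0 / mw)
        iu_gut = max(0.0, perpetrator.fu_gut * c_ent * 1000.0 / mw)
        lam_l = inactivation_rate(iu_liver, kinact, kapp_u)
        lam_g = inactivation_rate(iu_gut, kinact, kapp_u)
        de_l = physiology.kdeg_liver * (1.0 - e_l) - lam_l * e_l
        de_g = physiology.kdeg_gut * (1.0 - e_g) - lam_g * e_g
        return np.concatenate([dp, dv, [de_l, de_g]])

    events = [(t, LUMEN, perp_dose) for t in perp_schedule.dose_times]
    events += [(t, N_STATES + LUMEN, victim_schedule.dose_mg)
               for t in victim_schedule.dose_times]
    y0 = np.zeros(2 * N_STATES + 2)
    y0[i_el] = y0[i_eg] = 1.0
    t, states = integrate_with_doses(rhs, y0, events, t_end,
                                     options.output_step_h,
                                     rtol=options.rtol, atol=options.atol)
    v_profile = ConcProfile(
        t, v_dyn.plasma_ng_ml(states[:, N_STATES + SYSTEMIC]))
    idx_dose = int(np.argmin(np.abs(t - victim_schedule.dose_times[0])))
    return {
        "time_h": t,
        "victim_profile": v_profile,
        "perp_profile": ConcProfile(t, p_dyn.plasma_ng_ml(states[:, SYSTEMIC])),
        "e_liver": states[:, i_el],
        "e_gut": states[:, i_eg],
        "e_liver_at_victim_dose": float(states[idx_dose, i_el]),
        "e_gut_at_victim_dose": float(states[idx_dose, i_eg]),
    }
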