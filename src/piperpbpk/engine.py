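"""Reduced oral PBPK engine.

Structure: a gut-lumen depot absorbed first order (ka from jejunal
permeability), an enterocyte stage handled quasi-steady-state (its washout
rate Qgut/V_ent of ~15 1/h is much faster than absorption, so the absorbed
flux is split instantaneously between the Qgut outflow to the portal vein
and gut-wall CYP3A4 metabolism), an instantaneous well-stirred liver
first pass, and a single systemic compartment of volume Vss x body weight
eliminated by time-varying hepatic (plus optional renal) clearance.

With both first-pass sites enabled the systemic input on each dose is
Fg(t) * Fh(t) * ka * A_lumen; with gut and liver CYP3A4 activity states
E(t) attached (interaction module), gut CLint scales with E_gut and the
CYP3A4 share of hepatic CLint with E_liver, so Fg, Fh and CLh all become
time dependent.  The model is linear in dose for fixed enzyme activity.

Amounts are integrated in mg; concentrations are reported in plasma units
of ng/mL via the blood:plasma ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InvalidInputError, SimulationError
from .ivive import well_stirred_clh, whole_liver_clint
from .params import CompoundParams, blood_unbound_fraction, ka_from_peff
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

# state-vector layout per compound
LUMEN, SYSTEMIC, GUT_MET, FIRST_PASS, ELIMINATED = range(5)
N_STATES = 5


@dataclass(frozen=True)
class DoseSchedule:
    """Oral dosing regimen: n_doses of dose_mg every interval_h from start_h."""

    dose_mg: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_h: float = 0.0
    route: str = "oral"

    def __post_init__(self):
        if self.dose_mg < 0:
            raise InvalidInputError("dose_mg must be non-negative")
        if self.n_doses < 0:
            raise InvalidInputError("n_doses must be non-negative")
        if self.n_doses > 1 and self.interval_h <= 0:
            raise InvalidInputError("interval_h must be positive")
        if self.route != "oral":
            raise InvalidInputError("only oral dosing is supported")

    @property
    def dose_times(self) -> tuple:
        return tuple(self.start_h + i * self.interval_h
                     for i in range(self.n_doses))


@dataclass(frozen=True)
class ConcProfile:
    time_h: np.ndarray
    conc_ng_ml: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time_h,
                             "conc_ng_ml": self.conc_ng_ml})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PKMetrics:
    cmax: float          # ng/mL
    tmax: float          # h
    auc_last: float      # ng/mL*h
    auc_window: tuple    # (t0, t1) h


@dataclass(frozen=True)
class ModelOptions:
    first_pass_gut: bool = True
    first_pass_hepatic: bool = True
    fu_mic_correction: bool = True   # unbind measured CLint by fu_mic
    renal_enabled: bool = False
    elimination_enabled: bool = True


class CompoundDynamics:
    """Precomputed rate constants and the per-compound derivative kernel."""

    def __init__(self, compound: CompoundParams,
                 physiology: Physiology = DEFAULT_PHYSIOLOGY,
                 options: ModelOptions = ModelOptions()):
        if compound.vss is None:
            raise InvalidInputError(
                f"{compound.name}: Vss missing; supply it or predict it "
                "from the tissue-composition table first")
        self.compound = compound
        self.physiology = physiology
        self.options = options

        self.ka = compound.ka if compound.ka is not None else ka_from_peff(
            compound.peff_man, physiology.intestinal_radius)
        self.volume_l = compound.vss * physiology.body_weight
        self.fu_b = blood_unbound_fraction(compound.fu_plasma,
                                           compound.bp_ratio)
        # whole-liver unbound intrinsic clearance, L/h
        if compound.clint_u_liver is not None:
            clint_u = compound.clint_u_liver
        elif compound.clint_hlm is not None:
            clint_u = whole_liver_clint(compound.clint_hlm, physiology.mppgl,
                                        physiology.liver_weight)
            if options.fu_mic_correction:
                clint_u /= compound.fu_mic
        else:
            clint_u = 0.0
        if not options.elimination_enabled:
            clint_u = 0.0
        self.clint_u_liver = clint_u
        self.fm = compound.fm_cyp3a4 if compound.fm_cyp3a4 is not None else 0.0
        # whole-gut unbound CYP3A4 CLint, uL/min -> L/h, times fu_gut
        self.qgut = compound.qgut if compound.qgut else physiology.q_villi
        self.clg_u = compound.fu_gut * compound.clint_gut * 60.0 / 1e6
        if not options.elimination_enabled:
            self.clg_u = 0.0
        self.clr = (compound.renal_cl
                    if options.renal_enabled and options.elimination_enabled
                    else 0.0)

    # -- time-varying clearances -------------------------------------------
    def hepatic_clint_scaled(self, e_liver: float) -> float:
        """CYP3A4 share scaled by active enzyme (abundance x activity)."""
        abundance = self.physiology.cyp3a4_abundance
        return self.clint_u_liver * (self.fm * abundance * e_liver
                                     + (1.0 - self.fm))

    def gut_availability(self, e_gut: float) -> float:
        clg = self.clg_u * self.physiology.cyp3a4_abundance * e_gut
        if not self.options.first_pass_gut or clg == 0.0:
            return 1.0
        return self.qgut / (self.qgut + clg)

    def derivatives(self, y: np.ndarray, e_liver: float = 1.0,
                    e_gut: float = 1.0):
        """Return (dy, c_enterocyte mg/L, c_liver_inflow_blood mg/L).

        ``y`` is the 5-state slice for this compound.
        """
        phys = self.physiology
        abs_flux = self.ka * y[LUMEN]                      # mg/h
        fg = self.gut_availability(e_gut)
        hep = well_stirred_clh(phys.q_h, self.fu_b,
                               self.hepatic_clint_scaled(e_liver))
        fh = hep.availability if self.options.first_pass_hepatic else 1.0

        c_plasma = y[SYSTEMIC] / self.volume_l             # mg/L
        c_blood = c_plasma * self.compound.bp_ratio
        elim = (hep.clh + self.clr) * c_blood              # mg/h

        dy = np.empty(N_STATES)
        dy[LUMEN] = -abs_flux
        dy[SYSTEMIC] = fg * fh * abs_flux - elim
        dy[GUT_MET] = (1.0 - fg) * abs_flux
        dy[FIRST_PASS] = fg * (1.0 - fh) * abs_flux
        dy[ELIMINATED] = elim

        c_ent = fg * abs_flux / self.qgut                  # QSS outflow conc
        c_inflow = c_blood + fg * abs_flux / phys.q_h
        return dy, c_ent, c_inflow

    def plasma_ng_ml(self, a_systemic) -> np.ndarray:
        return np.asarray(a_systemic) / self.volume_l * 1000.0  # mg/L -> ng/mL


@dataclass
class PBPKModel:
    """A single-compound oral model ready for simulation."""

    dynamics: CompoundDynamics
    schedule: DoseSchedule
    rtol: float = 1e-8
    atol: float = 1e-12
    enzyme_activity: Optional[Callable[[float], tuple]] = None
    # bookkeeping populated by simulate()
    last_states: Optional[pd.DataFrame] = field(default=None, repr=False)

    def simulate(self, t_end_h: float, output_step_h: float = 0.05
                 ) -> ConcProfile:
        if self.schedule.n_doses and t_end_h < max(self.schedule.dose_times):
            raise InvalidInputError("t_end does not cover the dose schedule")

        def rhs(t, y):
            if self.enzyme_activity is None:
                e_l, e_g = 1.0, 1.0
            else:
                e_l, e_g = self.enzyme_activity(t)
            dy, _, _ = self.dynamics.derivatives(y, e_l, e_g)
            return dy

        events = [(t, LUMEN, self.schedule.dose_mg)
                  for t in self.schedule.dose_times]
        t, states = integrate_with_doses(rhs, np.zeros(N_STATES), events,
                                         t_end_h, output_step_h,
                                         rtol=self.rtol, atol=self.atol)
        self.last_states = pd.DataFrame(
            states, columns=["lumen", "systemic", "gut_met", "first_pass",
                             "eliminated"]).assign(time_h=t)
        return ConcProfile(t, self.dynamics.plasma_ng_ml(states[:, SYSTEMIC]))


def build_model(compound: CompoundParams,
                physiology: Physiology = DEFAULT_PHYSIOLOGY,
                schedule: DoseSchedule | None = None,
                options: ModelOptions = ModelOptions()) -> PBPKModel:
    if schedule is None:
        if compound.dose_mg is None:
            raise InvalidInputError("no dose given")
        schedule = DoseSchedule(dose_mg=compound.dose_mg)
    return PBPKModel(CompoundDynamics(compound, physiology, options), schedule)


def integrate_with_doses(rhs, y0: np.ndarray, dose_events: Sequence[tuple],
                         t_end: float, step: float,
                         rtol: float = 1e-8, atol: float = 1e-12):
    """Piecewise stiff-capable integration with dose impulses.

    ``dose_events`` is a list of (time, state_index, amount); each event is
    applied as an exact state discontinuity, and the solver restarts there.
    Output lands on the fixed grid arange(0, t_end, step); grid points that
    coincide with a dose time report the pre-dose state.
    """
    grid = np.arange(0.0, t_end + step / 2, step)
    y = np.array(y0, dtype=float)
    out = np.empty((grid.size, y.size))
    out[0] = y

    breaks = sorted({t for t, _, _ in dose_events if 0.0 <= t < t_end})
    edges = [0.0] + [b for b in breaks if b > 0.0] + [t_end]
    # doses at t=0 apply before integration starts
    for t_d, idx, amount in dose_events:
        if t_d == 0.0:
            y[idx] += amount
            out[0] = y

    filled = 1
    for seg_start, seg_end in zip(edges[:-1], edges[1:]):
        mask = (grid > seg_start + 1e-12) & (grid <= seg_end + 1e-12)
        t_eval = list(grid[mask])
        n_grid = len(t_eval)
        if not n_grid or abs(t_eval[-1] - seg_end) > 1e-9:
            t_eval.append(seg_end)  # always land on the segment end
        sol = solve_ivp(rhs, (seg_start, seg_end), y, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}",
                                  t=seg_start, state=y.copy())
        if n_grid:
            out[filled:filled + n_grid] = sol.y.T[:n_grid]
            filled += n_grid
        y = sol.y[:, -1].copy()
        for t_d, idx, amount in dose_events:
            if abs(t_d - seg_end) < 1e-9 and t_d < t_end:
                y[idx] += amount
    return grid, out


def nca(profile: ConcProfile, window: tuple | None = None) -> PKMetrics:
    """Non-compartmental summary: grid Cmax/Tmax, linear-trapezoid AUC."""
    t = np.asarray(profile.time_h, dtype=float)
    c = np.asarray(profile.conc_ng_ml, dtype=float)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if not np.any(mask):
        raise InvalidInputError("empty NCA window")
    tw, cw = t[mask], c[mask]
    imax = int(np.argmax(cw))
    auc = float(np.trapezoid(cw, tw)) if tw.size > 1 else 0.0
    return PKMetrics(cmax=float(cw[imax]), tmax=float(tw[imax]),
                     auc_last=auc, auc_window=(float(t0), float(t1)))
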