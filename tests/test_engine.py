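"""Reduced PBPK engine: conservation, closed forms, linearity, NCA."""

import numpy as np
import pytest

from piperpbpk import (DEFAULT_PHYSIOLOGY, ConcProfile, DoseSchedule,
                       InvalidInputError, ModelOptions, build_model, nca,
                       well_stirred_clh)
from piperpbpk.engine import CompoundDynamics

NO_FIRST_PASS = ModelOptions(first_pass_gut=False, first_pass_hepatic=False)


def _bateman(t, dose_mg, ka, ke, volume_l):
    amounts = dose_mg * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    return amounts / volume_l * 1000.0  # ng/mL


def _elimination_rate(compound, options=ModelOptions()):
    dyn = CompoundDynamics(compound, DEFAULT_PHYSIOLOGY, options)
    clh = well_stirred_clh(DEFAULT_PHYSIOLOGY.q_h, dyn.fu_b,
                           dyn.clint_u_liver).clh
    return (clh + dyn.clr) * compound.bp_ratio / dyn.volume_l, dyn


def test_mass_conservation_without_clearance(piperine_params):
    model = build_model(piperine_params,
                        schedule=DoseSchedule(20.0, 24.0, n_doses=3),
                        options=ModelOptions(elimination_enabled=False,
                                             first_pass_gut=False,
                                             first_pass_hepatic=False))
    model.simulate(72.0)
    states = model.last_states
    # grid points at a dose time report the pre-dose state
    dosed = 20.0 * (1 + (states.time_h > 24.0) + (states.time_h > 48.0))
    total = states.lumen + states.systemic
    np.testing.assert_allclose(total, dosed, rtol=1e-7)


def test_mass_balance_with_elimination(piperine_params):
    """Dose = remaining + gut-extracted + first-pass + eliminated to 0.1%."""
    model = build_model(piperine_params, schedule=DoseSchedule(20.0))
    model.simulate(48.0)
    s = model.last_states
    total = s.lumen + s.systemic + s.gut_met + s.first_pass + s.eliminated
    np.testing.assert_allclose(total, 20.0, rtol=1e-3)
    np.testing.assert_allclose(total, 20.0, rtol=1e-6)  # in fact much tighter


def test_extraction_disabled_matches_bateman_closed_form(piperine_params):
    """First-pass off reduces the engine to one-compartment oral kinetics."""
    ke, dyn = _elimination_rate(piperine_params, NO_FIRST_PASS)
    model = build_model(piperine_params, schedule=DoseSchedule(20.0),
                        options=NO_FIRST_PASS)
    profile = model.simulate(48.0)
    expected = _bateman(profile.time_h, 20.0, dyn.ka, ke, dyn.volume_l)
    scale = np.maximum(expected, 1e-9)
    assert np.max(np.abs(profile.conc_ng_ml - expected) / scale) < 1e-3


def test_model_is_linear_in_dose(piperine_params):
    p1 = build_model(piperine_params,
                     schedule=DoseSchedule(20.0)).simulate(48.0)
    p2 = build_model(piperine_params,
                     schedule=DoseSchedule(40.0)).simulate(48.0)
    np.testing.assert_allclose(p2.conc_ng_ml, 2 * p1.conc_ng_ml, rtol=1e-6,
                               atol=1e-9)


def test_multiple_dose_superposition(piperine_params):
    """Seven daily doses equal the sum of seven shifted single doses."""
    t_end = 216.0
    single = build_model(piperine_params,
                         schedule=DoseSchedule(20.0)).simulate(t_end)
    multi = build_model(
        piperine_params,
        schedule=DoseSchedule(20.0, 24.0, n_doses=7)).simulate(t_end)
    t = single.time_h
    combined = np.zeros_like(t)
    for i in range(7):
        shift = 24.0 * i
        combined += np.interp(t - shift, t, single.conc_ng_ml,
                              left=0.0, right=np.nan)
    mask = multi.conc_ng_ml > 1e-3 * multi.conc_ng_ml.max()
    rel = np.abs(combined[mask] - multi.conc_ng_ml[mask]) \
        / multi.conc_ng_ml[mask]
    assert np.nanmax(rel) < 5e-3


def test_steady_state_accumulation_ratio(piperine_params):
    """Trough accumulation approaches 1/(1-exp(-ke*tau)) for fast absorption."""
    fast = piperine_params.with_(ka=30.0)
    ke, _ = _elimination_rate(fast)
    n = 20
    multi = build_model(fast, schedule=DoseSchedule(20.0, 24.0, n_doses=n)
                        ).simulate(n * 24.0, output_step_h=0.1)
    single = build_model(fast, schedule=DoseSchedule(20.0)
                         ).simulate(48.0, output_step_h=0.1)
    trough_ss = multi.conc_ng_ml[np.searchsorted(multi.time_h, n * 24.0)]
    trough_1 = single.conc_ng_ml[np.searchsorted(single.time_h, 24.0)]
    expected = 1.0 / (1.0 - np.exp(-ke * 24.0))
    assert trough_ss / trough_1 == pytest.approx(expected, rel=0.01)


def test_zero_dose_gives_zero_profile(piperine_params):
    profile = build_model(piperine_params,
                          schedule=DoseSchedule(0.0)).simulate(24.0)
    assert np.all(profile.conc_ng_ml == 0.0)


def test_grid_convergence_of_nca(piperine_params):
    model = build_model(piperine_params, schedule=DoseSchedule(20.0))
    coarse = nca(model.simulate(48.0, output_step_h=0.05), (0.0, 24.0))
    fine = nca(model.simulate(48.0, output_step_h=0.025), (0.0, 24.0))
    assert fine.cmax == pytest.approx(coarse.cmax, rel=1e-3)
    assert fine.auc_last == pytest.approx(coarse.auc_last, rel=1e-3)


def test_trapezoid_auc_matches_analytic_exposure(piperine_params):
    """AUC(0-inf) approaches F*D/CL for the extraction-free model."""
    ke, dyn = _elimination_rate(piperine_params, NO_FIRST_PASS)
    model = build_model(piperine_params, schedule=DoseSchedule(20.0),
                        options=NO_FIRST_PASS)
    profile = model.simulate(240.0)
    analytic = 20.0 / (ke * dyn.volume_l) * 1000.0  # ng/mL*h
    assert nca(profile).auc_last == pytest.approx(analytic, rel=5e-3)


def test_nca_degenerate_windows():
    profile = ConcProfile(np.linspace(0, 10, 101), np.full(101, 7.0))
    assert nca(profile, (0.0, 10.0)).auc_last == pytest.approx(70.0,
                                                               rel=1e-12)
    assert nca(profile, (5.0, 5.0)).auc_last == 0.0
    with pytest.raises(InvalidInputError):
        nca(profile, (20.0, 30.0))


def test_schedule_validation(piperine_params):
    with pytest.raises(InvalidInputError):
        DoseSchedule(-1.0)
    with pytest.raises(InvalidInputError):
        DoseSchedule(20.0, interval_h=0.0, n_doses=3)
    model = build_model(piperine_params,
                        schedule=DoseSchedule(20.0, 24.0, n_doses=7))
    with pytest.raises(InvalidInputError):
        model.simulate(48.0)  # does not cover the schedule
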