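"""Mechanism-based inactivation dynamics and DDI co-simulation."""

import numpy as np
import pytest

from piperpbpk import (DEFAULT_PHYSIOLOGY, DDIOptions, DoseSchedule,
                       InvalidInputError, build_model, cosimulate_ddi,
                       inactivation_rate, nca, solve_enzyme, static_auc_ratio)
from piperpbpk.engine import ModelOptions
from piperpbpk.interaction import EnzymeState, enzyme_steady_state

KAPP_U = 6.74 * 0.863  # unbound-corrected inactivation constant, uM


def test_inactivation_rate_limits():
    assert inactivation_rate(0.0, 0.558, KAPP_U) == 0.0
    assert inactivation_rate(1e9, 0.558, KAPP_U) == pytest.approx(0.558,
                                                                  rel=1e-6)
    assert inactivation_rate(KAPP_U, 0.558, KAPP_U) == pytest.approx(
        0.558 / 2, rel=1e-12)
    with pytest.raises(InvalidInputError):
        inactivation_rate(-1.0, 0.558, KAPP_U)


def test_enzyme_reaches_closed_form_steady_state():
    """Constant 1 uM unbound inhibitor: E_ss = kdeg/(kdeg+lambda) = 0.191."""
    kdeg = 0.0193
    lam = inactivation_rate(1.0, 0.558, KAPP_U)
    assert lam == pytest.approx(0.0819, abs=0.0001)
    expected = enzyme_steady_state(kdeg, lam)
    assert expected == pytest.approx(0.191, abs=0.001)
    _, e = solve_enzyme(lambda t: 1.0, kdeg, 0.558, KAPP_U, t_end=200.0)
    assert e[-1] == pytest.approx(expected, rel=1e-3)


def test_enzyme_identity_without_inhibitor_and_washout_recovery():
    t, e = solve_enzyme(lambda t: 0.0, 0.0193, 0.558, KAPP_U, t_end=50.0)
    np.testing.assert_allclose(e, 1.0, atol=1e-9)
    # washout from a depleted state recovers exponentially at kdeg
    t, e = solve_enzyme(lambda t: 0.0, 0.0193, 0.558, KAPP_U, t_end=100.0,
                        e0=0.5)
    np.testing.assert_allclose(e, 1.0 - 0.5 * np.exp(-0.0193 * t), rtol=1e-6)


def test_static_auc_ratio_formula():
    assert static_auc_ratio(0.9, 0.5, 1.0, 1.0) == pytest.approx(1.818,
                                                                 abs=0.001)
    assert static_auc_ratio(0.0, 0.5, 0.6, 0.9) == pytest.approx(1.5,
                                                                 rel=1e-12)
    assert static_auc_ratio(0.5, 1.0, 0.7, 0.7) == 1.0
    with pytest.raises(InvalidInputError):
        static_auc_ratio(1.5, 0.5, 1.0, 1.0)


def test_no_inactivation_means_no_interaction(piperine_params, victims):
    """kinact = 0 and zero perpetrator dose both give a unit AUC ratio."""
    mid = victims["midazolam"]
    inert = piperine_params.with_(kinact=0.0)
    res = cosimulate_ddi(inert, mid)
    assert res.auc_ratio == pytest.approx(1.0, abs=1e-6)
    res0 = cosimulate_ddi(piperine_params, mid,
                          perp_schedule=DoseSchedule(0.0, 24.0, n_doses=7))
    assert res0.auc_ratio == pytest.approx(1.0, abs=1e-6)


def test_dynamic_ratio_matches_static_oracle_at_fixed_enzyme(victims):
    """A victim run under frozen enzyme activity reproduces the static ratio."""
    alf = victims["alfentanil"]
    e_liver, e_gut = 0.6, 0.8
    schedule = DoseSchedule(alf.dose_mg)
    opts = ModelOptions(renal_enabled=True)

    def run(activity):
        model = build_model(alf, schedule=schedule, options=opts)
        model.enzyme_activity = activity
        return nca(model.simulate(72.0), (0.0, 72.0)).auc_last

    auc_base = run(lambda t: (1.0, 1.0))
    auc_inh = run(lambda t: (e_liver, e_gut))
    dyn = build_model(alf, schedule=schedule, options=opts).dynamics
    fg_alone = dyn.gut_availability(1.0)
    fg_inh = dyn.gut_availability(e_gut)
    expected = static_auc_ratio(alf.fm_cyp3a4, e_liver, fg_alone, fg_inh)
    assert auc_inh / auc_base == pytest.approx(expected, rel=0.01)


def test_auc_ratio_monotone_in_inactivation_and_dose(piperine_params,
                                                     victims):
    mid = victims["midazolam"]
    ratios_kinact = [
        cosimulate_ddi(piperine_params.with_(kinact=k), mid).auc_ratio
        for k in (0.0, 0.28, 0.558)]
    assert ratios_kinact == sorted(ratios_kinact)
    ratios_dose = [
        cosimulate_ddi(piperine_params, mid,
                       perp_schedule=DoseSchedule(d, 24.0, n_doses=7)
                       ).auc_ratio
        for d in (10.0, 20.0, 40.0)]
    assert ratios_dose == sorted(ratios_dose)


def test_interaction_result_consistency(ddi_results):
    """Ratios are with/alone and >= 1 for a pure inactivator."""
    table = ddi_results
    np.testing.assert_allclose(table.auc_with / table.auc_alone,
                               table.auc_ratio, rtol=1e-12)
    assert (table.auc_ratio >= 1.0).all()
    assert (table.cmax_ratio >= 1.0).all()


def test_enzyme_state_validation():
    EnzymeState("liver", kdeg=0.0193)
    with pytest.raises(InvalidInputError):
        EnzymeState("plasma", kdeg=0.0193)
    with pytest.raises(InvalidInputError):
        EnzymeState("gut", kdeg=0.0)
    with pytest.raises(InvalidInputError):
        EnzymeState("gut", kdeg=0.03, e_active=1.2)


def test_victim_without_fm_is_rejected(piperine_params, victims):
    broken = victims["midazolam"].with_(fm_cyp3a4=None)
    with pytest.raises(InvalidInputError, match="fm_cyp3a4"):
        cosimulate_ddi(piperine_params, broken)


def test_washout_window_is_configurable(piperine_params, victims):
    res = cosimulate_ddi(piperine_params, victims["midazolam"],
                         options=DDIOptions(washout_h=24.0))
    assert res.auc_ratio > 1.0
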