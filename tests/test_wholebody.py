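"""Whole-body model: balance-equation structure, mass conservation,
calibration self-consistency, steady states and flux bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from gutchol import (BodyState, CalibrationLedger, calibrate, rhs,
                     simulate_to_steady_state, compute_flux_table,
                     steady_state_vector, integrate, closed_configuration,
                     total_mass, STATE_NAMES)
from gutchol.wholebody import CalibrationError, _switch_on, _switch_release

IDX = {n: i for i, n in enumerate(STATE_NAMES)}


def literal_fluxes(x, p):
    """Independent literal transcription of every named edge flux of the
    balance equations (mg/day), used as the double-implementation oracle."""
    ccc, pbsd, lpbs, lc, ipbs, ic, hbs, hc, hce, hdl, ldl, pc = x[:12]
    monod = ccc / (p.K_ccc + ccc)
    k_bs = p.k_lca if p.k_lpbsa is None else p.k_lpbsa
    if p.hbs_feedback == "saturating":
        hbss = p.V_H * p.k_hbss * hc / (1.0 + (hbs / p.HBS_t) ** p.HBS_sens)
    else:
        hbss = p.V_H * p.k_hbss * hc * hbs
    return {
        "ss_k_in": p.f_meal,
        "ss_BCRmax": p.V_H * p.BCR_max / (1 + (p.BCR_t / hc) ** p.BS_sens),
        "ss_kLCe": p.V_L * p.k_lce * lc,
        "ss_kCC": p.V_L * p.k_cc * lc * monod,
        "ss_kLCa": p.V_L * p.k_lca * lc * lpbs,
        "ss_kLCo": p.V_I * p.k_lco * ic * lpbs,
        "ss_ICSmax": p.V_I * p.ICS_max / (1 + (ic / p.IC_t) ** p.IS),
        "ss_thetaI_kICo": p.V_I * p.theta_i * p.k_ico * ic,
        "ss_1thetaI_kICo": p.V_I * (1 - p.theta_i) * p.k_ico * ic,
        "ss_HCSmax": p.V_H * p.HCS_max / (1 + (hc / p.HC_t) ** p.HS),
        "ss_kHCest": p.V_H * p.k_hcest * hc,
        "ss_kHCunest": p.V_H * p.k_hcunest * hce,
        "ss_thetaH_kHCo": p.V_H * p.theta_h * p.k_hco * hc,
        "ss_1thetaH_kHCo": p.V_H * (1 - p.theta_h) * p.k_hco * hc,
        "ss_kLDLha": p.V_B * p.k_ldlha * ldl,
        "ss_kHDLha": p.V_B * p.k_hdlha * hdl,
        "ss_kLDLpa": p.V_B * p.k_ldlpa * ldl,
        "ss_PCSmax": p.V_P * p.PCS_max / (1 + (pc / p.PC_t) ** p.PS),
        "ss_kPCo": p.V_P * p.k_pco * pc,
        "ss_kPloss": p.V_P * p.k_ploss * pc,
        "ss_kHBSs": hbss,
        "ss_kHBSo": p.V_H * p.k_hbso * hbs,
        "ss_kLPBSa": p.V_L * k_bs * lc * lpbs,
        "ss_kLPBSe": p.V_L * p.k_lpbse * lpbs,
        "ss_kLPBSD": p.V_L * p.k_lpbsd * lpbs * pbsd ** 2,
        "ss_kIPBSa": p.V_I * p.k_ipbsa * ipbs,
    }


class TestCalibration:
    def test_designed_state_is_exact_fixed_point(self, calib):
        x = steady_state_vector(calib.params)
        d = rhs(0.0, x, calib.params)
        flux_scale = calib.ledger_final["ss_kHBSo"]
        assert np.max(np.abs(d[:12])) < 1e-6 * flux_scale

    def test_esterification_symmetry(self, calib):
        assert calib.ledger_final["ss_kHCest"] == pytest.approx(0.9705)
        assert calib.ledger_final["ss_kHCunest"] == pytest.approx(0.9705)

    def test_conversion_excretion_ratio(self, calib):
        p = calib.params
        assert p.k_cc / p.k_lce == pytest.approx(0.1, rel=1e-12)

    def test_printed_ledger_conflicts_reported_not_fixed(self, calib):
        joined = "\n".join(calib.discrepancies)
        assert "ss_kLCe" in joined and "ss_kCC" in joined
        # the printed downstream value is what the calibrator uses
        assert calib.ledger_final["ss_kLCe"] == pytest.approx(1.2352)

    def test_mc_identities_of_the_final_ledger(self, calib):
        f = calib.ledger_final
        assert f["ss_kLCa"] == pytest.approx(
            f["ss_k_in"] + f["ss_BCRmax"] + f["ss_kLCo"]
            - f["ss_kLCe"] - f["ss_kCC"], rel=1e-10)
        assert f["ss_thetaI_kICo"] == pytest.approx(
            f["ss_kLCa"] + f["ss_ICSmax"] - f["ss_1thetaI_kICo"]
            - f["ss_kLCo"], rel=1e-10)
        assert f["ss_BH"] == pytest.approx(
            f["ss_kLDLha"] + f["ss_kHDLha"], rel=1e-12)

    def test_blood_to_liver_periphery_split_conserved(self, calib):
        f = calib.ledger_final
        assert f["ss_kLDLha"] / f["ss_kLDLpa"] == pytest.approx(
            1.1646 / 0.0970, rel=1e-10)

    def test_unstable_repression_rejected(self):
        ledger = CalibrationLedger()
        ledger.microbial = dict(ledger.microbial, mu_pbsd=1.0)
        with pytest.raises(CalibrationError):
            calibrate(ledger)

    def test_round_trip_reproduces_ledger_fluxes(self, calib):
        """Simulating the calibrated model to steady state reproduces every
        ledger flux within 1% relative error."""
        res = simulate_to_steady_state(calib.params, tol=1e-9)
        assert res.converged
        for name, want in calib.ledger_final.items():
            if name not in res.flux_table.names():
                continue
            got = res.flux_table[name]
            assert got == pytest.approx(want, rel=0.01), name

    def test_round_trip_from_perturbed_start(self, calib):
        x0 = steady_state_vector(calib.params)
        x0[2:12] *= 1.15
        res = simulate_to_steady_state(calib.params,
                                       init=BodyState.from_vector(x0),
                                       tol=1e-9, t_max=3000.0)
        assert res.converged
        x_ss = steady_state_vector(calib.params)
        live = res.state.to_vector()[2:12]
        assert np.allclose(live, x_ss[2:12], rtol=1e-4)


class TestRhsStructure:
    def test_closed_configuration_conserves_total_sterol(self, calib):
        p = closed_configuration(calib.params)
        x0 = steady_state_vector(calib.params)
        times = np.linspace(0, 5.0, 11)
        sol = integrate(p, x0, times, rtol=1e-10, atol=1e-12)
        masses = [total_mass(x, p) for x in sol]
        assert np.allclose(masses, masses[0], rtol=1e-8)

    def test_flux_decomposition_equals_volume_weighted_rhs(self, calib, rng):
        """Signed sums of the named edge fluxes reproduce V*d[x]/dt for
        every non-cumulative compartment (bookkeeping identity)."""
        p = calib.params
        x = steady_state_vector(p) * rng.uniform(0.6, 1.4, 16)
        fl = compute_flux_table(x, p)
        get = lambda n: fl[n]  # noqa: E731
        expected = {
            "lpbs": get("ss_kHBSo") - get("ss_kLPBSD") - get("ss_kLPBSa")
                    - get("ss_kLPBSe"),
            "lc": get("ss_k_in") + get("ss_BCRmax") - get("ss_kLCa")
                  + get("ss_kLCo") - get("ss_kLCe") - get("ss_kCC"),
            "ipbs": get("ss_kLPBSa") - get("ss_kIPBSa"),
            "ic": get("ss_kLCa") - get("ss_kLCo") + get("ss_ICSmax")
                  - get("ss_thetaI_kICo") - get("ss_1thetaI_kICo"),
            "hbs": get("ss_kHBSs") - get("ss_kHBSo") + get("ss_kIPBSa"),
            "hc": get("ss_kLDLha") + get("ss_kHDLha") - get("ss_thetaH_kHCo")
                  - get("ss_1thetaH_kHCo") + get("ss_HCSmax")
                  - get("ss_kHCest") + get("ss_kHCunest") - get("ss_kHBSs")
                  - get("ss_BCRmax"),
            "hce": get("ss_kHCest") - get("ss_kHCunest"),
            "hdl": get("ss_1thetaI_kICo") + get("ss_1thetaH_kHCo")
                   + get("ss_kPCo") - get("ss_kHDLha"),
            "ldl": get("ss_thetaI_kICo") + get("ss_thetaH_kHCo")
                   - get("ss_kLDLha") - get("ss_kLDLpa"),
            "pc": get("ss_kLDLpa") - get("ss_kPCo") + get("ss_PCSmax")
                  - get("ss_kPloss"),
        }
        balances = fl.net_balances(p, x)
        for comp, want in expected.items():
            assert balances[comp] == pytest.approx(want, abs=1e-9), comp

    def test_flux_table_matches_literal_transcription(self, calib, rng):
        p = calib.params
        x = steady_state_vector(p) * rng.uniform(0.5, 1.5, 16)
        fl = compute_flux_table(x, p)
        oracle = literal_fluxes(x, p)
        seen = set()
        for e in fl.edges:
            if e.name in seen:
                continue
            seen.add(e.name)
            assert e.value == pytest.approx(oracle[e.name], rel=1e-12), e.name
        assert seen == set(oracle)

    def test_bs_synthesis_edge_equal_in_both_cycles(self, calib):
        fl = compute_flux_table(steady_state_vector(calib.params),
                                calib.params)
        chol = fl.cycle("cholesterol")["ss_kHBSs"]
        bs = fl.cycle("bs")["ss_kHBSs"]
        assert chol == bs

    def test_zero_state_fluxes(self, calib):
        p = calib.params
        fl = compute_flux_table(np.zeros(16), p)
        for e in fl.edges:
            if e.name == "ss_k_in":
                assert e.value == p.f_meal
            elif e.name in ("ss_ICSmax", "ss_HCSmax", "ss_PCSmax"):
                assert e.value > 0  # synthesis switches fully on
            else:
                assert e.value == 0.0

    def test_cumulative_pools_non_decreasing(self, calib):
        x0 = steady_state_vector(calib.params)
        x0[2:12] *= 1.3
        times = np.linspace(0, 20, 60)
        sol = integrate(calib.params, x0, times)
        for i in range(12, 16):
            assert np.all(np.diff(sol[:, i]) >= -1e-9)

    def test_doubling_diet_increases_excretion_rate(self, calib):
        p = calib.params
        base = simulate_to_steady_state(p, tol=1e-9)
        rich = simulate_to_steady_state(replace(p, f_meal=2 * p.f_meal),
                                        tol=1e-9, t_max=3000.0)
        assert rich.flux_table["ss_kLCe"] > base.flux_table["ss_kLCe"]

    def test_nonnegativity_under_parameter_perturbations(self, calib, rng):
        """Trajectories started non-negative stay non-negative under random
        +/-20% perturbations of every rate parameter."""
        p0 = calib.params
        rate_names = [k for k, v in p0.as_dict().items()
                      if isinstance(v, float) and k not in
                      ("theta_i", "theta_h", "hbs_feedback")]
        x0 = steady_state_vector(p0)
        times = np.linspace(0.0, 2.0, 9)
        for _ in range(150):
            changes = {k: getattr(p0, k) * rng.uniform(0.8, 1.2)
                       for k in rate_names
                       if k not in ("IS", "HS", "PS", "BS_sens", "HBS_sens")}
            p = replace(p0, steady_state=None, **changes)
            sol = integrate(p, x0, times, rtol=1e-7, atol=1e-9)
            assert sol.min() > -1e-6

    def test_steady_state_from_known_point_returns_immediately(self, calib):
        res = simulate_to_steady_state(calib.params, tol=1e-8)
        assert res.converged and res.t_used == 0.0

    def test_nonconvergence_flagged_not_raised(self, calib):
        res = simulate_to_steady_state(
            calib.params,
            init=BodyState.from_vector(steady_state_vector(calib.params) * 3),
            tol=1e-14, t_max=1.0, chunk=1.0, polish=False)
        assert not res.converged
        assert res.residual > 0

    def test_bacterial_conversion_negligible_against_circulation(self, calib):
        fl = simulate_to_steady_state(calib.params).flux_table
        assert fl["ss_kLPBSD"] < 0.05 * fl["ss_kHBSo"]

    def test_coprostanol_ratio_approaches_monod_scaled_q(self, calib):
        """The excreted coprostanol:cholesterol flux ratio equals
        (k_cc/k_lce) times the Monod factor at carrying capacity."""
        p = calib.params
        fl = simulate_to_steady_state(p).flux_table
        monod = p.ccc_max / (p.K_ccc + p.ccc_max)
        assert fl["ss_kCC"] / fl["ss_kLCe"] == pytest.approx(
            p.k_cc / p.k_lce * monod, rel=1e-6)


class TestStateHelpers:
    def test_excreted_concentration_undefined_at_t0(self):
        s = BodyState(ec=3.0)
        assert s.excreted_concentration("ec", 0.0, 0.001) is None
        assert s.excreted_concentration("ec", 2.0, 0.001) == pytest.approx(
            3.0 / 0.002)

    def test_vector_round_trip(self, rng):
        x = rng.uniform(0, 2, 16)
        assert np.allclose(BodyState.from_vector(x).to_vector(), x)

    def test_switches_are_complementary_limits(self):
        assert _switch_on(0.0, 1.0, 5.0) == 1.0
        assert _switch_release(0.0, 1.0, 5.0) == 0.0
        assert _switch_on(1.0, 1.0, 5.0) == pytest.approx(0.5)
        assert _switch_release(1.0, 1.0, 5.0) == pytest.approx(0.5)
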