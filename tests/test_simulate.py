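"""Generator correctness: closed forms vs ODE oracles, seeds, design guards."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

import receptorpharm as rp
from receptorpharm.simulate import (
    association_expectation,
    competition_expectation,
    dose_response_expectation,
)


def ode_association(bmax, kon, koff, L, times):
    """Numeric mass-action oracle: d[RL]/dt = kon*L*(Bmax-[RL]) - koff*[RL]."""
    sol = solve_ivp(
        lambda t, y: [kon * L * (bmax - y[0]) - koff * y[0]],
        (0, times[-1]), [0.0], t_eval=times, rtol=1e-10, atol=1e-12,
    )
    return sol.y[0]


def ode_chase(bmax, kon, koff, L, chase_nM, rl0, times):
    """Two-ligand oracle: tracer + excess unlabeled competitor (same rates)."""
    def rhs(t, y):
        rl, rc = y
        free = bmax - rl - rc
        return [kon * L * free - koff * rl, kon * chase_nM * free - koff * rc]
    sol = solve_ivp(rhs, (0, times[-1]), [rl0, 0.0], t_eval=times,
                    rtol=1e-10, atol=1e-12)
    return sol.y[0]


class TestAssociation:
    def test_zero_time_zero_binding(self, kinetic_system):
        assert association_expectation(kinetic_system, 0.2, [0.0])[0] == 0.0

    def test_closed_form_matches_ode_oracle(self):
        sysp = rp.SystemParams(bmax_cpm=3000.0, kon=0.1, koff=0.01, noise_cv=0.0)
        times = np.linspace(0.5, 120, 60)
        expected = association_expectation(sysp, 0.2, times)
        oracle = ode_association(3000.0, 0.1, 0.01, 0.2, times)
        assert np.allclose(expected, oracle, rtol=1e-3)
        # and the curve really is Beq*(1-exp(-0.03 t))
        beq = 3000.0 * 0.2 / (0.2 + 0.1)
        assert np.allclose(expected, beq * (1 - np.exp(-0.03 * times)), rtol=1e-12)

    def test_minute_sampling_design_has_101_points_per_replicate(self, kinetic_system):
        trace = rp.simulate_association(kinetic_system, L=0.21, times=np.arange(0, 101.0), n_rep=3)
        counts = trace.data.groupby("replicate")["time_min"].count()
        assert (counts == 101).all()

    def test_seed_determinism(self):
        sysp = rp.SystemParams(bmax_cpm=2000.0, kon=0.3, koff=0.01, noise_cv=0.05, seed=42)
        t = np.arange(0, 50.0)
        a = rp.simulate_association(sysp, 0.2, t, n_rep=2)
        b = rp.simulate_association(sysp, 0.2, t, n_rep=2)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = rp.simulate_association(sysp, 0.2, t, n_rep=2, seed=43)
        assert not np.allclose(a.data["total_cpm"], c.data["total_cpm"])

    def test_depletion_guard_warns(self):
        sysp = rp.SystemParams(bmax_cpm=2e6, kon=0.3, koff=0.01, noise_cv=0.0)
        with pytest.warns(rp.TracerDepletionWarning):
            rp.simulate_association(sysp, 0.2, np.arange(0, 20.0))

    @pytest.mark.parametrize("bad", [
        dict(L=-0.1, times=np.arange(0, 20.0)),
        dict(L=0.2, times=np.array([5.0, 1.0, 10.0])),
        dict(L=0.2, times=np.array([-1.0, 1.0])),
    ])
    def test_invalid_designs_rejected(self, kinetic_system, bad):
        with pytest.raises(ValueError):
            rp.simulate_association(kinetic_system, **bad)


class TestDissociation:
    def test_halflife_matches_two_ligand_ode_oracle(self):
        bmax, kon, koff, L = 2000.0, 0.3, 0.01, 0.2
        sysp = rp.SystemParams(bmax_cpm=bmax, kon=kon, koff=koff, noise_cv=0.0)
        # chase >> 100*KD so the two-ligand oracle runs in the
        # rebinding-negligible regime the closed form assumes
        preinc, chase = 60.0, 1.0e4
        times = np.linspace(1, 200, 100)
        trace = rp.simulate_dissociation(sysp, L, preinc, chase, times)
        mean = trace.data.groupby("time_min")["specific_cpm"].mean()
        rl0 = association_expectation(sysp, L, [preinc])[0]
        oracle = ode_chase(bmax, kon, koff, L, chase, rl0, times)
        assert np.allclose(mean.to_numpy(), oracle, rtol=1e-3)
        # noise-free half-life equals ln2/koff
        expected = rl0 * np.exp(-koff * times)
        t_half = np.interp(rl0 / 2, expected[::-1], times[::-1])
        assert t_half == pytest.approx(np.log(2) / koff, rel=1e-3)

    def test_time_zero_equals_preincubation_plateau(self):
        sysp = rp.SystemParams(bmax_cpm=2000.0, kon=0.2, koff=0.010, noise_cv=0.0)
        trace = rp.simulate_dissociation(sysp, 0.2, 60.0, 500.0, np.arange(0, 30.0))
        b0 = association_expectation(sysp, 0.2, [60.0])[0]
        assert trace.data["specific_cpm"].iloc[0] == pytest.approx(b0, rel=1e-6)

    def test_expectation_non_increasing(self, kinetic_system):
        trace = rp.simulate_dissociation(kinetic_system, 0.21, 60.0, 1000.0, np.arange(1, 100.0))
        spec = trace.data["specific_cpm"].to_numpy()
        assert (np.diff(spec) <= 0).all()

    def test_insufficient_chase_rejected(self):
        sysp = rp.SystemParams(bmax_cpm=2000.0, kd_nM=40.0, noise_cv=0.0)
        sysp = rp.SystemParams(bmax_cpm=2000.0, kon=0.01, koff=0.4, noise_cv=0.0)  # kd 40 nM
        with pytest.raises(ValueError, match="chase"):
            rp.simulate_dissociation(sysp, 0.2, 60.0, 1000.0, np.arange(1, 30.0))

    def test_micromolar_chase_design_valid(self, kinetic_system):
        # 1 uM chase vs kd ~0.032 nM: ratio >> 100
        trace = rp.simulate_dissociation(kinetic_system, 0.21, 60.0, 1000.0, np.arange(1, 20.0))
        assert trace.phase == "dissociation"


class TestCompetition:
    def test_zero_competitor_equals_association_plateau(self, kinetic_system):
        L = 0.21
        spec = competition_expectation(kinetic_system, L, [0.0])[0]
        beq = kinetic_system.bmax_cpm * L / (L + kinetic_system.kd_nM)
        assert spec == pytest.approx(beq, rel=1e-12)

    def test_homologous_ic50_is_L_plus_kd_by_bisection(self):
        sysp = rp.SystemParams(bmax_cpm=1000.0, kd_nM=40.0, noise_cv=0.0)
        L = 0.05
        b0 = competition_expectation(sysp, L, [0.0])[0]
        lo, hi = 0.0, 1.0  # molar bounds for bisection on the closed form
        for _ in range(200):
            mid = (lo + hi) / 2
            if competition_expectation(sysp, L, [mid])[0] > b0 / 2:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 * 1e9 == pytest.approx(L + 40.0, rel=1e-6)

    def test_full_displacement_limit(self):
        sysp = rp.SystemParams(bmax_cpm=1000.0, kd_nM=40.0, ns_fraction=0.02, noise_cv=0.0)
        curve = rp.simulate_competition(sysp, 0.05, [0.0, 1e-2], added_cpm=25000.0)
        bound = curve.data["bound_cpm"].to_numpy()
        ns = 0.02 * 25000.0
        assert bound[1] == pytest.approx(ns, rel=1e-4)  # only nonspecific remains
        assert bound[0] > bound[1]

    def test_heterologous_requires_ki(self, kinetic_system):
        with pytest.raises(ValueError):
            rp.simulate_competition(kinetic_system, 0.05, [0.0, 1e-9], homologous=False)


class TestDoseResponse:
    def test_half_max_at_ec50(self):
        fp = rp.FunctionalParams(ec50_nM=1.0, emax_frac=0.8, basal=5.0, noise_cv=0.0)
        resp = dose_response_expectation(fp, [1e-9])
        assert resp[0] == pytest.approx(5.0 + 100 * 0.8 / 2)

    def test_partial_agonist_profile(self, agonist_concs):
        # weak partial agonist: ~11% of reference efficacy
        fp = rp.FunctionalParams(ec50_nM=27.5, emax_frac=0.11, noise_cv=0.0)
        curve = rp.simulate_dose_response(fp, agonist_concs)
        assert curve.data["response"].max() < 12.0

    def test_antagonist_without_kb_rejected(self, agonist_concs):
        fp = rp.FunctionalParams(ec50_nM=1.0, noise_cv=0.0)
        with pytest.raises(ValueError, match="kb_nM"):
            rp.simulate_dose_response(fp, agonist_concs, antagonist_nM=100.0)

    def test_gaddum_shift_refit_dose_ratio(self, functional_noise_free, agonist_concs):
        control = rp.fit_logistic(rp.simulate_dose_response(functional_noise_free, agonist_concs))
        shifted = rp.fit_logistic(
            rp.simulate_dose_response(functional_noise_free, agonist_concs, antagonist_nM=100.0)
        )
        assert shifted.ec50_nM / control.ec50_nM == pytest.approx(3.0, rel=1e-4)


class TestBret:
    def test_zero_efficacy_constant_ratio(self, agonist_concs):
        fp = rp.FunctionalParams(ec50_nM=1.0, emax_frac=0.0, basal=0.1, noise_cv=0.0)
        table = rp.simulate_bret(fp, agonist_concs, donor_level=1e5)
        ratio = rp.bret_ratio(table.data["acceptor"], table.data["donor"])
        assert np.allclose(ratio, 0.1, rtol=1e-9)

    def test_half_max_ratio_at_ec50(self):
        fp = rp.FunctionalParams(ec50_nM=2.0, emax_frac=0.4, basal=0.1, noise_cv=0.0)
        table = rp.simulate_bret(fp, [2e-9], donor_level=1e5)
        ratio = rp.bret_ratio(table.data["acceptor"], table.data["donor"])[0]
        assert ratio == pytest.approx(0.1 + 0.4 / 2)

    def test_refit_recovers_pec50(self, agonist_concs):
        fp = rp.FunctionalParams(ec50_nM=2.6, emax_frac=0.5, basal=0.05, noise_cv=0.0)
        table = rp.simulate_bret(fp, agonist_concs, donor_level=1e5)
        fit = rp.fit_logistic(rp.bret_to_curve(table), "activation")
        assert fit.pec50 == pytest.approx(9 - np.log10(2.6), abs=0.02)

    def test_nonpositive_donor_rejected(self, agonist_concs):
        fp = rp.FunctionalParams(ec50_nM=1.0, noise_cv=0.0)
        with pytest.raises(ValueError):
            rp.simulate_bret(fp, agonist_concs, donor_level=0.0)


class TestSystemParams:
    def test_kd_derived_from_rates(self):
        assert rp.SystemParams(bmax_cpm=1.0, kon=0.308, koff=0.010).kd_nM == pytest.approx(0.010 / 0.308)

    def test_inconsistent_kd_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            rp.SystemParams(bmax_cpm=1.0, kon=0.1, koff=0.01, kd_nM=0.5)

    @pytest.mark.parametrize("kw", [
        dict(bmax_cpm=-1.0, kd_nM=1.0),
        dict(bmax_cpm=1.0, kd_nM=1.0, ns_fraction=1.5),
        dict(bmax_cpm=1.0, kon=0.1),
        dict(bmax_cpm=1.0),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            rp.SystemParams(**kw)
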