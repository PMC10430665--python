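"""Occupancy, competition, cascade integration, dose-response, Hill fits."""

from dataclasses import replace

import numpy as np
import pytest

from gpcrscreen.cascade import (Affinity, CascadeParameters, DoseGrid,
                                affinity_gate, agonist_ec80_uM,
                                competitive_occupancy, dose_response,
                                fit_hill, hill, linear_cascade_camp,
                                occupancy, simulate_cascade,
                                DoseResponseCurve)


class TestOccupancy:
    def test_half_occupancy_at_kd(self):
        # the reference antagonist affinity: Kd 310 nM
        aff = Affinity.from_Kd_nM(310.0)
        assert occupancy(aff, 0.310) == pytest.approx(0.5, abs=1e-9)

    def test_zero_dose_zero_occupancy(self):
        assert occupancy(Affinity(6.0), 0.0) == 0.0

    def test_saturation(self):
        aff = Affinity(6.0)
        assert occupancy(aff, 1000 * aff.Kd_uM) >= 0.999

    def test_negative_concentration_is_error(self):
        with pytest.raises(ValueError):
            occupancy(Affinity(6.0), -1.0)

    def test_monotone_in_L_and_Kd(self, rng):
        for _ in range(50):
            pkd = rng.uniform(4, 9)
            L = np.sort(rng.uniform(0.001, 100, 5))
            occ = [occupancy(Affinity(pkd), x) for x in L]
            assert all(np.diff(occ) > 0)
            occ_weak = occupancy(Affinity(pkd - 1), L[0])
            assert occ_weak < occ[0]

    def test_pkd_unit_conversion(self):
        assert Affinity(5.5).Kd_uM == pytest.approx(10 ** -5.5 * 1e6)
        assert Affinity(5.5).Kd_uM == pytest.approx(3.162, rel=1e-3)


class TestCompetition:
    def test_zero_competitor_reduces_to_occupancy(self):
        lig, ago = Affinity(7.0), Affinity(6.5)
        _, f_ag = competitive_occupancy(lig, ago, 0.0, 1.0)
        assert f_ag == pytest.approx(occupancy(ago, 1.0))

    def test_infinite_ligand_displaces_agonist(self):
        lig, ago = Affinity(7.0), Affinity(6.5)
        _, f_ag = competitive_occupancy(lig, ago, 1e9, 1.0)
        assert f_ag < 1e-6

    def test_symmetry_at_equal_kd_and_dose(self):
        a = Affinity(6.0)
        f_l, f_a = competitive_occupancy(a, a, 2.0, 2.0)
        assert f_l == pytest.approx(f_a)

    def test_fraction_conservation(self, rng):
        """Bound + free receptor fractions sum to one at every dose."""
        for _ in range(50):
            lig = Affinity(rng.uniform(4, 9))
            ago = Affinity(rng.uniform(4, 9))
            L, A = rng.uniform(0, 50, 2)
            f_l, f_a = competitive_occupancy(lig, ago, L, A)
            free = 1.0 / (1.0 + L / lig.Kd_uM + A / ago.Kd_uM)
            assert f_l + f_a + free == pytest.approx(1.0, abs=1e-12)


class TestCascade:
    def test_zero_occupancy_holds_basal_fixed_point(self):
        p = CascadeParameters()
        _, camp = simulate_cascade(p, 0.0)
        np.testing.assert_allclose(camp, p.camp_basal_uM, rtol=1e-6)

    def test_linear_regime_matches_analytic_solution(self):
        """With negligible ATP consumption the system is linear; the
        integrator must match the closed form within 0.1%."""
        p = replace(CascadeParameters(), k_AC_cat=1e-6)
        for frac in (0.2, 0.7, 1.0):
            t, camp = simulate_cascade(p, frac)
            expected = linear_cascade_camp(p, frac, t)
            np.testing.assert_allclose(camp, expected, rtol=1e-3)

    def test_no_pde_linear_growth_regime(self):
        """With degradation off and G* saturated, cAMP grows ~linearly
        until ATP depletion bends the curve."""
        p = replace(CascadeParameters(), k_PDE=0.0, k_G_hyd=0.0,
                    k_G_act=100.0)  # G* jumps to its ceiling immediately
        t, camp = simulate_cascade(p, 1.0, t_end=5.0)
        # early-time growth rate ~ k_AC_cat * G_total * ATP
        rate = np.gradient(camp, t)
        expected = p.k_AC_cat * p.g_total_uM * p.atp_uM
        assert rate[len(rate) // 2] == pytest.approx(expected, rel=0.05)

    def test_trajectories_nonnegative_and_steady_state_independent_of_init(self):
        p = CascadeParameters()
        finals = []
        for camp0 in (0.0, 0.1, 2.0):
            _, camp = simulate_cascade(p, 0.5, camp0_uM=camp0, t_end=200.0)
            assert (camp >= 0).all()
            finals.append(camp[-1])
        assert max(finals) - min(finals) < 1e-4 * max(finals)

    def test_step_refinement_stability(self):
        """Halving/quartering the reporting step changes the end cAMP by
        < 0.1% (the adaptive integrator controls true error)."""
        p = CascadeParameters()
        ends = []
        for n in (1000, 2000, 4000):
            _, camp = simulate_cascade(p, 0.6, n_steps=n)
            ends.append(camp[-1])
        for e in ends[1:]:
            assert abs(e - ends[0]) / ends[0] < 1e-3

    def test_invalid_occupancy_is_error(self):
        with pytest.raises(ValueError):
            simulate_cascade(CascadeParameters(), 1.5)


class TestDoseResponse:
    def test_agonist_mode_monotone_and_small_at_low_dose(self):
        p = CascadeParameters()
        curve = dose_response(p, Affinity(6.0), fit=False)
        r = curve.responses_uM
        assert abs(r[0]) < 0.01 * abs(r[-1])  # dose << Kd: no response
        assert (np.diff(r) >= -1e-9).all()

    def test_antagonist_mode_suppresses_tone(self):
        tone_aff = Affinity(7.0)
        p = replace(CascadeParameters(),
                    agonist_tone=(agonist_ec80_uM(CascadeParameters(),
                                                  tone_aff), 7.0))
        curve = dose_response(p, Affinity(7.0), mode="antagonist", fit=False)
        r = curve.responses_uM
        assert (np.diff(r) <= 1e-9).all()
        # top doses approach full suppression of the tone response
        baseline_rise = -r[-1]
        _, camp_tone = simulate_cascade(p, occupancy(tone_aff,
                                                     p.agonist_tone[0]))
        _, camp_0 = simulate_cascade(p, 0.0)
        full = camp_tone[-1] - camp_0[-1]
        assert baseline_rise == pytest.approx(full, rel=0.05)

    def test_antagonist_mode_requires_tone(self):
        with pytest.raises(ValueError):
            dose_response(CascadeParameters(), Affinity(6.0),
                          mode="antagonist")

    def test_monotone_by_mode_over_random_parameters(self, rng):
        """Agonist curves never fall, antagonist curves never rise, across
        50 random rate/pool draws."""
        grid = DoseGrid.make(n=10)
        for i in range(50):
            p = CascadeParameters(
                g_total_uM=float(rng.uniform(2, 20)),
                atp_uM=float(rng.uniform(500, 2000)),
                camp_basal_uM=float(rng.uniform(0.01, 0.5)),
                k_G_act=float(rng.uniform(0.02, 0.5)),
                k_G_hyd=float(rng.uniform(0.1, 2.0)),
                k_AC_cat=float(10 ** rng.uniform(-5, -3.3)),
                k_PDE=float(rng.uniform(0.2, 3.0)))
            aff = Affinity(float(rng.uniform(5, 8)))
            if i % 2 == 0:
                curve = dose_response(p, aff, grid=grid, fit=False,
                                      t_end=60.0, n_steps=200)
                assert (np.diff(curve.responses_uM) >= -1e-8).all()
            else:
                tone = Affinity(float(rng.uniform(6, 8)))
                pa = replace(p, agonist_tone=(4.0 * tone.Kd_uM, tone.pKd))
                curve = dose_response(pa, aff, grid=grid, mode="antagonist",
                                      fit=False, t_end=60.0, n_steps=200)
                assert (np.diff(curve.responses_uM) <= 1e-8).all()

    def test_hundredfold_x50_shift_between_pkd_6_and_8(self):
        p = CascadeParameters()
        c6 = dose_response(p, Affinity(6.0))
        c8 = dose_response(p, Affinity(8.0))
        ratio = c6.hill_fit.x50_uM / c8.hill_fit.x50_uM
        assert ratio == pytest.approx(100.0, rel=0.15)


class TestHillFit:
    @staticmethod
    def _curve(doses, responses):
        return DoseResponseCurve(molecule_id="x", doses_uM=np.asarray(doses),
                                 responses_uM=np.asarray(responses),
                                 t_end=100.0, mode="agonist")

    def test_noiseless_recovery_within_one_percent(self):
        doses = np.logspace(-3, 3, 24)
        y = hill(doses, top=1.0, bottom=0.0, x50=1.0, n=1.0)
        f = fit_hill(self._curve(doses, y))
        assert f.x50_uM == pytest.approx(1.0, rel=0.01)
        assert f.hill_n == pytest.approx(1.0, rel=0.01)

    def test_noisy_recovery_within_five_percent_over_20_seeds(self):
        doses = np.logspace(-3, 3, 24)
        clean = hill(doses, top=1.0, bottom=0.0, x50=1.0, n=1.0)
        x50s, ns = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 0.02, clean.shape)
            f = fit_hill(self._curve(doses, y))
            x50s.append(f.x50_uM)
            ns.append(f.hill_n)
        assert np.mean(np.abs(np.array(x50s) - 1.0)) < 0.05
        assert np.mean(np.abs(np.array(ns) - 1.0)) < 0.05

    def test_flat_curve_degenerate(self):
        doses = np.logspace(-3, 3, 10)
        f = fit_hill(self._curve(doses, np.zeros(10)))
        assert f.degenerate and f.x50_uM is None

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_hill(self._curve([0.1, 1, 10], [0, 0.5, 1]))


class TestAffinityGate:
    def test_boundary_inclusive(self):
        assert affinity_gate([5.4, 5.5, 7.0]) == [1, 2]

    def test_all_below_warns_and_empties(self):
        with pytest.warns(RuntimeWarning):
            assert affinity_gate([4.0, 5.0]) == []

    def test_missing_pkd_is_error(self):
        with pytest.raises(ValueError, match="index 1"):
            affinity_gate([6.0, None, 7.0])
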