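"""Compensatory control: fold-changes, taus, transients, Pareto front."""

import numpy as np
import pytest

from coldshift import (
    ControlPoint,
    RATES_14C,
    RATES_24C,
    RateConstants,
    combined_control,
    control_report,
    degradation_stop_response,
    mrna_side_effect,
    pareto_front,
    required_fold_change,
    response_simulation,
    steady_state,
    transition_time,
)

F1, F2, F3, F4 = (ControlPoint.F1, ControlPoint.F2, ControlPoint.F3,
                  ControlPoint.F4)


class TestRequiredFoldChange:
    @pytest.mark.parametrize("point, expected_factor", [
        (F1, 25.0),        # transcription up 25-fold
        (F3, 25.0),        # translation up 25-fold
        (F2, 1.0 / 25.0),  # mRNA degradation down 25-fold
        (F4, 1.0 / 25.0),  # protein degradation down 25-fold
    ])
    def test_single_point_protein_compensation(self, warm_ss, point,
                                               expected_factor):
        sol = required_fold_change(point, RATES_14C, warm_ss)
        assert sol.fold_changes[point] == pytest.approx(expected_factor,
                                                        rel=1e-12)
        assert sol.achieved_ss.protein_ss == pytest.approx(
            warm_ss.protein_ss, rel=1e-12)

    def test_mrna_only_stabilization_needs_fivefold_k2_cut(self, warm_ss):
        sol = required_fold_change(F2, RATES_14C, warm_ss, species="mrna")
        assert sol.fold_changes[F2] == pytest.approx(0.2, rel=1e-12)
        assert sol.achieved_ss.mrna_ss == pytest.approx(warm_ss.mrna_ss,
                                                        rel=1e-12)

    def test_translation_cannot_target_mrna(self, warm_ss):
        with pytest.raises(ValueError):
            required_fold_change(F3, RATES_14C, warm_ss, species="mrna")

    def test_solution_steady_state_is_consistent(self, warm_ss):
        sol = required_fold_change(F1, RATES_14C, warm_ss)
        recomputed = steady_state(sol.adjusted_rates)
        assert sol.achieved_ss == recomputed


class TestMrnaSideEffect:
    def test_transcription_control_quintuples_mrna(self, warm_ss):
        sol = required_fold_change(F1, RATES_14C, warm_ss)
        ratio = mrna_side_effect(sol, warm_ss)
        assert ratio == pytest.approx(5.0, rel=1e-12)
        assert ratio > 4.0  # the published bound

    def test_mrna_degradation_control_also_quintuples_mrna(self, warm_ss):
        sol = required_fold_change(F2, RATES_14C, warm_ss)  # protein target
        assert sol.adjusted_rates.k2 == pytest.approx(0.02, rel=1e-12)
        assert mrna_side_effect(sol, warm_ss) == pytest.approx(5.0, rel=1e-12)

    def test_translation_control_leaves_mrna_at_cold_level(self, warm_ss,
                                                           cold_ss):
        # k3 does not enter the mRNA steady state, so the F3 solution
        # keeps mRNA at the uncompensated post-shift steady state
        sol = required_fold_change(F3, RATES_14C, warm_ss)
        assert sol.achieved_ss.mrna_ss == pytest.approx(cold_ss.mrna_ss,
                                                        rel=1e-12)
        assert mrna_side_effect(sol, warm_ss) == pytest.approx(0.2, rel=1e-12)


class TestCombinedControl:
    def test_production_pair_splits_into_fivefold_each(self, warm_ss):
        sol = combined_control({F1, F3}, RATES_14C, warm_ss)
        assert sol.fold_changes[F1] == pytest.approx(5.0, rel=1e-12)
        assert sol.fold_changes[F3] == pytest.approx(5.0, rel=1e-12)
        assert sol.achieved_ss.protein_ss == pytest.approx(6.25, rel=1e-12)

    def test_degradation_pair_splits_into_fivefold_cuts(self, warm_ss):
        sol = combined_control({F2, F4}, RATES_14C, warm_ss)
        assert sol.fold_changes[F2] == pytest.approx(0.2, rel=1e-12)
        assert sol.fold_changes[F4] == pytest.approx(0.2, rel=1e-12)
        assert sol.achieved_ss.protein_ss == pytest.approx(6.25, rel=1e-12)

    def test_fold_change_magnitudes_multiply_to_required_total(self, warm_ss):
        for pts in ({F1, F3}, {F2, F4}, {F1, F2}, {F1, F2, F3, F4}):
            sol = combined_control(pts, RATES_14C, warm_ss)
            product = np.prod([sol.fold_magnitude(p) for p in pts])
            assert product == pytest.approx(25.0, rel=1e-9)

    def test_singleton_matches_single_point_solver(self, warm_ss):
        a = combined_control({F1}, RATES_14C, warm_ss)
        b = required_fold_change(F1, RATES_14C, warm_ss)
        assert a.fold_changes[F1] == pytest.approx(b.fold_changes[F1],
                                                   rel=1e-12)

    def test_explicit_split_validated_against_total(self, warm_ss):
        ok = combined_control({F1, F3}, RATES_14C, warm_ss,
                              split={F1: 12.5, F3: 2.0})
        assert ok.achieved_ss.protein_ss == pytest.approx(6.25, rel=1e-12)
        with pytest.raises(ValueError, match="split"):
            combined_control({F1, F3}, RATES_14C, warm_ss,
                             split={F1: 3.0, F3: 3.0})


class TestTransitionTime:
    def test_published_formulas_on_warm_rates(self, warm_rates):
        assert transition_time(warm_rates, "mrna") == pytest.approx(1 / 3.5)
        assert transition_time(warm_rates, "protein") == pytest.approx(1 / 7.0)

    def test_homogeneous_in_rate_scaling(self, warm_rates):
        c = 3.0
        for level in ("mrna", "protein"):
            assert transition_time(warm_rates.scaled(c), level) == \
                pytest.approx(transition_time(warm_rates, level) / c, rel=1e-12)

    def test_relaxation_method_gives_textbook_times(self):
        r = RateConstants(2.5, 1.0, 2.5, 0.4)
        assert transition_time(r, "mrna", method="relaxation") == 1.0
        assert transition_time(r, "protein", method="relaxation") == 2.5


class TestResponseSimulation:
    @pytest.mark.parametrize("point", [F3, F4])
    def test_immediate_protein_side_control_overshoots(self, warm_ss, point):
        sol = required_fold_change(point, RATES_14C, warm_ss)
        traj = response_simulation(RATES_14C, sol, "immediate", warm_ss)
        assert traj.protein.max() > warm_ss.protein_ss * 1.01

    @pytest.mark.parametrize("point", [F1, F2])
    def test_immediate_mrna_side_control_dips(self, warm_ss, point):
        sol = required_fold_change(point, RATES_14C, warm_ss)
        traj = response_simulation(RATES_14C, sol, "immediate", warm_ss)
        assert traj.protein.min() < warm_ss.protein_ss * 0.99

    @pytest.mark.parametrize("point", [F1, F2, F3, F4])
    def test_settled_mode_restores_warm_protein_level(self, warm_ss, point):
        # F2/F4 solutions relax on a 1/0.02 = 50 a.u. timescale, so the
        # horizon must cover many of those
        sol = required_fold_change(point, RATES_14C, warm_ss)
        traj = response_simulation(RATES_14C, sol, "settled", warm_ss,
                                   duration=700.0)
        assert traj.protein[-1] == pytest.approx(6.25, rel=1e-4)

    def test_production_control_settles_faster_than_degradation(self, warm_ss):
        # published ordering: F1/F3 return the system quickly, F2/F4 slowly
        def settle_time(point):
            sol = required_fold_change(point, RATES_14C, warm_ss)
            traj = response_simulation(RATES_14C, sol, "settled", warm_ss,
                                       duration=400.0, n_points=4001)
            gap = np.abs(traj.protein - warm_ss.protein_ss)
            within = gap < 0.05 * warm_ss.protein_ss
            idx = len(within) - np.argmin(within[::-1])  # last exit + 1
            return traj.times[min(idx, len(within) - 1)]

        assert settle_time(F1) < settle_time(F4)
        assert settle_time(F3) < settle_time(F2)


class TestParetoFront:
    def test_boundaries_and_monotonicity(self, warm_ss):
        front = pareto_front(RATES_14C, warm_ss, "mrna", n_grid=50)
        assert front[0].up_factor == pytest.approx(1.0)
        assert front[0].down_factor == pytest.approx(25.0)
        assert front[-1].up_factor == pytest.approx(25.0)
        assert front[-1].down_factor == pytest.approx(1.0)
        taus = [p.tau for p in front]
        assert all(b < a for a, b in zip(taus, taus[1:]))

    def test_interior_point_matches_hand_calculation(self, warm_ss):
        front = pareto_front(RATES_14C, warm_ss, "mrna", n_grid=3)
        mid = front[1]  # log-midpoint of [1, 25] is u = 5
        assert mid.up_factor == pytest.approx(5.0, rel=1e-12)
        assert mid.tau == pytest.approx(1.0 / 1.35, rel=1e-12)

    def test_every_point_restores_protein_target(self, warm_ss):
        for p in pareto_front(RATES_14C, warm_ss, "protein", n_grid=20):
            assert p.up_factor * p.down_factor == pytest.approx(25.0,
                                                                rel=1e-9)

    def test_pure_production_endpoint_tau(self, warm_ss):
        front = pareto_front(RATES_14C, warm_ss, "mrna", n_grid=50)
        assert front[-1].tau == pytest.approx(1.0 / 6.75, rel=1e-12)


class TestDegradationStop:
    def test_transient_stop_beats_steady_reduction(self, warm_ss):
        traj = degradation_stop_response(RATES_14C, warm_ss,
                                         stop_duration=8.0, duration=60.0)
        # protein rises from the cold steady state toward the target and
        # ends pinned at the compensating steady state
        assert traj.protein[0] == pytest.approx(0.25, rel=1e-6)
        assert traj.protein.max() > 0.25
        sol = required_fold_change(F4, RATES_14C, warm_ss)
        slow = response_simulation(RATES_14C, sol, "settled", warm_ss,
                                   duration=60.0)
        # at mid-course, the stop strategy is ahead of the steady 25-fold cut
        i = np.searchsorted(traj.times, 8.0)
        assert traj.protein[i] > slow.protein[np.searchsorted(slow.times, 8.0)]


class TestControlReport:
    def test_report_covers_all_points_and_pairs(self, warm_ss):
        rep = control_report(RATES_14C, warm_ss, warm_ss)
        assert set(rep["single"]) == {"F1", "F2", "F3", "F4"}
        assert set(rep["combined"]) == {"F1+F3", "F2+F4"}
        assert rep["single"]["F1"]["fold_changes"]["F1"] == pytest.approx(25.0)
        assert rep["single"]["F1"]["mrna_side_effect"] == pytest.approx(5.0)
        for entry in rep["single"].values():
            assert entry["achieved_steady_state"]["protein"] == \
                pytest.approx(6.25, rel=1e-12)
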