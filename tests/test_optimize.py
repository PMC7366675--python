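import itertools
import math

import numpy as np
import pytest

from beatfield.envelope import TIPattern, ti_envelope
from beatfield.errors import ValidationError
from beatfield.leadfield import LeadFieldSet, montage_field
from beatfield.mesh import ROISpec
from beatfield.optimize import (
    MontageCandidate,
    SearchConfig,
    baseline_tacs,
    baseline_unoptimized_ti,
    current_grid,
    enumerate_montages,
    evaluate_montage,
    icosphere_directions,
    optimize_ti,
    optimized_tacs,
    peak_ratio,
)


def brute_force_search(lf, roi, config):
    """Independent nested-loop reference for the exhaustive search."""
    best, best_key = None, (False, -np.inf)
    ids = lf.candidate_ids
    for montage in enumerate_montages(len(ids), ids=ids):
        for currents in current_grid(config):
            r = evaluate_montage(lf, montage, currents, roi=roi, config=config)
            obj = r.PR if config.objective_mode == "max_pr_with_amplitude_floor" else r.A_target
            key = (r.feasible, obj)
            if key > best_key:
                best_key, best = key, r
    return best


class TestCurrentGrid:
    def test_default_grid_endpoints_and_count(self):
        grid = current_grid(SearchConfig())
        assert len(grid) == 21
        assert grid[0] == (0.5, 1.5)
        assert grid[-1] == (1.5, 0.5)

    def test_every_pair_sums_to_total_exactly(self):
        for a, b in current_grid(SearchConfig()):
            assert a + b == 2.0

    def test_degenerate_single_point_grid(self):
        grid = current_grid(SearchConfig(alpha_min_mA=1.0, alpha_max_mA=1.0))
        assert grid == [(1.0, 1.0)]

    def test_step_larger_than_range_rejected(self):
        with pytest.raises(ValidationError, match="range"):
            SearchConfig(alpha_min_mA=0.9, alpha_max_mA=1.1, alpha_step_mA=0.5)


class TestEnumeration:
    def test_sixty_one_candidates_give_printed_subset_count(self):
        count = sum(1 for _ in enumerate_montages(61))
        assert count // 3 == 521_855
        assert count // 3 == math.comb(61, 4)

    def test_four_candidates_single_subset_three_pairings(self):
        montages = list(enumerate_montages(4))
        assert len(montages) == 3
        assert len({m.electrode_ids for m in montages}) == 1
        assert len({m.pairing for m in montages}) == 3

    def test_five_candidates_match_independent_enumeration(self):
        montages = list(enumerate_montages(5))
        assert len(montages) == 15
        seen = {(m.electrode_ids, m.pairing) for m in montages}
        want = set()
        ids = [f"E{i:02d}" for i in range(5)]
        for quad in itertools.combinations(ids, 4):
            for (i, j), (k, l) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
                want.add((quad, ((quad[i], quad[j]), (quad[k], quad[l]))))
        assert seen == want

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValidationError):
            list(enumerate_montages(3))

    def test_invalid_montage_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            MontageCandidate(("a", "a", "b", "c"), (("a", "a"), ("b", "c")))
        with pytest.raises(ValidationError, match="cover"):
            MontageCandidate(("a", "b", "c", "d"), (("a", "b"), ("a", "c")))


class TestPeakRatio:
    @pytest.mark.parametrize(
        "a_hippo, a_cortex, printed",
        [(0.20, 0.18, 1.1), (0.26, 0.39, 0.67), (0.21, 0.73, 0.29), (0.34, 0.75, 0.45)],
    )
    def test_worked_examples_reproduce_printed_ratios(self, a_hippo, a_cortex, printed):
        pattern = TIPattern(np.array([a_hippo, a_cortex]), 10.0)
        roi = ROISpec(np.array([0]), np.array([1]))
        _, _, pr = peak_ratio(pattern, roi)
        assert pr == pytest.approx(printed, abs=0.02)

    def test_equal_amplitudes_give_unit_ratio(self):
        pattern = TIPattern(np.full(10, 0.5), 10.0)
        roi = ROISpec(np.arange(3), np.arange(3, 10))
        assert peak_ratio(pattern, roi)[2] == 1.0

    def test_zero_cortex_peak_is_an_error(self):
        pattern = TIPattern(np.array([1.0, 0.0]), 10.0)
        roi = ROISpec(np.array([0]), np.array([1]))
        with pytest.raises(ValidationError, match="undefined"):
            peak_ratio(pattern, roi)


class TestEvaluateMontage:
    def test_polarity_swap_leaves_amplitude_unchanged(self, toy_leadfields):
        lf, roi = toy_leadfields
        m1 = MontageCandidate(("E00", "E01", "E02", "E03"), (("E00", "E01"), ("E02", "E03")))
        m2 = MontageCandidate(("E00", "E01", "E02", "E03"), (("E01", "E00"), ("E02", "E03")))
        r1 = evaluate_montage(lf, m1, (1.2, 0.8), roi=roi)
        r2 = evaluate_montage(lf, m2, (1.2, 0.8), roi=roi)
        assert np.allclose(r1.pattern.amplitude, r2.pattern.amplitude)

    def test_pair_frequency_assignment_immaterial_at_mirrored_grid_point(self, toy_leadfields):
        lf, roi = toy_leadfields
        m = MontageCandidate(("E00", "E01", "E02", "E03"), (("E00", "E01"), ("E02", "E03")))
        mirrored = MontageCandidate(("E00", "E01", "E02", "E03"), (("E02", "E03"), ("E00", "E01")))
        r1 = evaluate_montage(lf, m, (1.3, 0.7), roi=roi)
        r2 = evaluate_montage(lf, mirrored, (0.7, 1.3), roi=roi)
        assert np.allclose(r1.pattern.amplitude, r2.pattern.amplitude)

    def test_hand_built_two_node_leadfields_give_peak_ratio_ten(self):
        fields = {
            "E00": np.array([[1.0, 0, 0], [0.1, 0, 0]]),
            "E01": np.zeros((2, 3)),
            "E02": np.array([[0, 1.0, 0], [0, 0.1, 0]]),
            "E03": np.zeros((2, 3)),
        }
        lf = LeadFieldSet(fields=fields, reference_id="REF", mesh_fingerprint="hand")
        roi = ROISpec(np.array([0]), np.array([1]))
        m = MontageCandidate(("E00", "E01", "E02", "E03"), (("E00", "E01"), ("E02", "E03")))
        r = evaluate_montage(lf, m, (1.0, 1.0), roi=roi)
        # orthogonal equal fields: A = sqrt(2)*norm at each node -> ratio 1/0.1
        assert r.A_target == pytest.approx(np.sqrt(2), rel=1e-12)
        assert r.PR == pytest.approx(10.0, rel=1e-9)


class TestOptimizeTi:
    @pytest.mark.parametrize(
        "mode", ["max_pr_with_amplitude_floor", "max_amplitude_with_pr_floor"]
    )
    def test_matches_nested_loop_brute_force(self, toy_leadfields, mode):
        lf, roi = toy_leadfields
        config = SearchConfig(objective_mode=mode)
        got = optimize_ti(lf, roi, config)
        want = brute_force_search(lf, roi, config)
        assert got.montage == want.montage
        assert got.alpha_mA == want.alpha_mA
        assert got.PR == pytest.approx(want.PR, rel=1e-12)
        assert got.A_target == pytest.approx(want.A_target, rel=1e-12)
        assert got.feasible == want.feasible

    def test_feasible_result_honours_amplitude_floor(self, toy_leadfields):
        lf, roi = toy_leadfields
        got = optimize_ti(lf, roi, SearchConfig())
        if got.feasible:
            assert got.A_target > 0.2

    def test_unreachable_threshold_flags_infeasible_with_diagnostic_best(self, toy_leadfields):
        lf, roi = toy_leadfields
        config = SearchConfig(constraint_threshold_V_per_m=1e6)
        got = optimize_ti(lf, roi, config)
        assert not got.feasible
        want = brute_force_search(lf, roi, config)
        assert got.montage == want.montage

    def test_evaluation_counter_covers_full_search_space(self, toy_leadfields):
        lf, roi = toy_leadfields
        got = optimize_ti(lf, roi, SearchConfig())
        assert got.n_evaluations == math.comb(5, 4) * 3 * 21

    def test_peak_ratio_consistent_with_reported_peaks(self, toy_leadfields):
        lf, roi = toy_leadfields
        got = optimize_ti(lf, roi, SearchConfig())
        assert got.PR == pytest.approx(got.A_target / got.A_cortex, abs=1e-12)


class TestBaselines:
    def test_unoptimized_fixes_unit_currents_and_maximizes_target(self, toy_leadfields):
        lf, roi = toy_leadfields
        res = baseline_unoptimized_ti(lf, roi)
        assert res.alpha_mA == 1.0 and res.beta_mA == 1.0
        # brute force: max target amplitude over all montages at 1 mA / 1 mA
        best = -np.inf
        for montage in enumerate_montages(5, ids=lf.candidate_ids):
            r = evaluate_montage(lf, montage, (1.0, 1.0), roi=roi)
            best = max(best, r.A_target)
        assert res.A_target == pytest.approx(best, rel=1e-12)

    def test_tacs_baseline_reports_summed_field_peaks(self, toy_leadfields):
        lf, roi = toy_leadfields
        opt = optimize_ti(lf, roi, SearchConfig())
        rec = baseline_tacs(lf, opt, roi)
        (a1, c1), (a2, c2) = opt.montage.pairing
        amp = np.linalg.norm(
            opt.alpha_mA * (lf[a1] - lf[c1]) + opt.beta_mA * (lf[a2] - lf[c2]), axis=1
        )
        assert rec["A_target"] == pytest.approx(np.max(amp[roi.target_nodes]))
        assert rec["A_cortex"] == pytest.approx(np.max(amp[roi.cortex_nodes]))
        assert rec["PR"] == pytest.approx(rec["A_target"] / rec["A_cortex"])


class TestOptimizedTacs:
    def test_constraints_hold(self, toy_leadfields):
        lf, roi = toy_leadfields
        rec = optimized_tacs(lf, roi)
        I = rec["currents_mA"]
        total = sum(I.values())
        assert total == pytest.approx(0.0, abs=1e-9)
        assert sum(abs(v) for v in I.values()) / 2.0 <= 2.0 + 1e-9
        assert max(abs(v) for v in I.values()) <= 1.0 + 1e-9

    def test_matches_dense_grid_search_on_three_electrodes(self, toy_leadfields):
        lf, roi = toy_leadfields
        sub = LeadFieldSet(
            fields={e: lf[e] for e in ["E00", "E01", "E02"]},
            reference_id="REF",
            mesh_fingerprint="toy",
        )
        rec = optimized_tacs(sub, roi)
        tn = roi.target_nodes[roi.target_nodes.size // 2]
        L = np.stack([sub[e][tn] for e in ["E00", "E01", "E02"]])
        grid = np.arange(-1.0, 1.0 + 1e-9, 0.02)
        best = 0.0
        for i1 in grid:
            for i2 in grid:
                i3s = grid
                iref = -(i1 + i2 + i3s)
                ok = (np.abs(iref) <= 1.0) & (
                    (abs(i1) + abs(i2) + np.abs(i3s) + np.abs(iref)) / 2.0 <= 2.0
                )
                if not ok.any():
                    continue
                vecs = i1 * L[0] + i2 * L[1] + np.outer(i3s, L[2])
                amps = np.linalg.norm(vecs, axis=1)
                amps[~ok] = 0.0
                best = max(best, amps.max())
        achieved = np.linalg.norm(
            sum(rec["currents_mA"][e] * sub[e][tn] for e in ["E00", "E01", "E02"]), axis=0
        )
        assert achieved >= best * 0.99  # LP at least matches the discrete grid

    def test_doubling_limits_doubles_amplitude(self, toy_leadfields):
        lf, roi = toy_leadfields
        one = optimized_tacs(lf, roi, total_current_mA=2.0, max_individual_mA=1.0)
        two = optimized_tacs(lf, roi, total_current_mA=4.0, max_individual_mA=2.0)
        assert two["A_target"] == pytest.approx(2.0 * one["A_target"], rel=1e-6)

    def test_icosphere_direction_fan(self):
        d = icosphere_directions(2)
        assert d.shape == (162, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)


def test_optimum_dominates_any_fixed_candidate(toy_leadfields):
    lf, roi = toy_leadfields
    config = SearchConfig()
    opt = optimize_ti(lf, roi, config)
    fixed = evaluate_montage(
        lf,
        MontageCandidate(("E00", "E01", "E02", "E03"), (("E00", "E01"), ("E02", "E03"))),
        (1.0, 1.0),
        roi=roi,
        config=config,
    )
    if fixed.feasible and opt.feasible:
        assert opt.PR >= fixed.PR
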