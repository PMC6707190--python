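"""Balanced-state mean-field solver against dense linear-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

import rivalsim as rs
from rivalsim import theory
from rivalsim.theory import (
    BalancedSolution,
    MeanFieldSystem,
    meanfield_from_architecture,
    solve_balanced,
    solve_single_pool,
    sweep_mutual_inhibition,
    two_pool_matrix,
    compare_theory_simulation,
)


def case_weights(params=None, k=200):
    p = params or rs.NeuronParams()
    a = rs.DISCRETE_AMPLITUDES
    w = {key: theory.effective_weight(a[key], k, p)
         for key in ("A_ee", "A_ei", "A_ie", "A_ii", "A_ie_long")}
    return w["A_ee"], w["A_ei"], w["A_ie"], w["A_ii"], w["A_ie_long"]


class TestSolveBalanced:
    def test_two_by_two_example(self):
        """W=[[1,-2],[1,-1]], f=[1,0] has the balanced solution r=(1,1);
        verified by substitution."""
        sys2 = MeanFieldSystem(W=[[1.0, -2.0], [1.0, -1.0]], f=[1.0, 0.0],
                               populations=("e", "i"))
        sol = solve_balanced(sys2)
        assert sol.feasible
        assert np.allclose(sol.rates, [1.0, 1.0])
        assert np.allclose(sys2.W @ sol.rates + sys2.f, 0.0, atol=1e-12)

    def test_zero_drive_zero_rates(self):
        sys2 = MeanFieldSystem(W=[[1.0, -2.0], [1.0, -1.0]], f=[0.0, 0.0],
                               populations=("e", "i"))
        sol = solve_balanced(sys2)
        assert sol.feasible
        assert np.allclose(sol.rates, 0.0)

    def test_random_systems_match_dense_oracle(self):
        """10^4 random invertible 4x4 systems: the solver agrees with an
        independent dense solve and the residual of W r + f vanishes."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10_000:
            W = rng.normal(size=(4, 4)) * 10
            if abs(np.linalg.det(W)) < 1e-3:
                continue
            f = rng.normal(size=4)
            sol = solve_balanced(MeanFieldSystem(W=W, f=f))
            oracle = scipy.linalg.solve(W, -f)
            assert np.allclose(sol.rates, oracle, rtol=1e-10, atol=1e-12)
            scale = max(np.linalg.norm(f), 1.0)
            assert sol.residual < 1e-10 * scale
            assert sol.feasible == bool(np.all(oracle >= 0))
            checked += 1

    def test_symmetric_coupling_asymmetric_drive_insoluble(self):
        """With the two pools symmetrically coupled, W is rank deficient and
        an asymmetric drive lies outside its column space: no balanced state
        exists (the unstructured heterogeneous-drive situation)."""
        w_ee, w_ei, w_ie, w_ii = 1.0, 2.0, 3.0, 4.0
        W = np.array([
            [w_ee, -w_ei, w_ee, -w_ei],
            [w_ie, -w_ii, w_ie, -w_ii],
            [w_ee, -w_ei, w_ee, -w_ei],
            [w_ie, -w_ii, w_ie, -w_ii],
        ])
        asym = solve_balanced(MeanFieldSystem(W=W, f=[1.0, 0.0, 2.0, 0.0]))
        assert not asym.feasible
        assert asym.singular
        assert asym.reason == "singular"

    def test_negative_rate_marks_infeasible(self):
        sys2 = MeanFieldSystem(W=[[1.0, -2.0], [1.0, -1.0]], f=[0.0, 1.0],
                               populations=("e", "i"))
        sol = solve_balanced(sys2)
        assert not sol.feasible
        assert sol.reason == "negative_rate"


class TestSinglePool:
    def test_matches_two_by_two(self):
        w_ee, w_ei, w_ie, w_ii, w_long = case_weights()
        sys4 = MeanFieldSystem(W=two_pool_matrix(w_ee, w_ei, w_ie, w_ii, w_long),
                               f=[5.0, 0.0, 5.0, 0.0])
        single = solve_single_pool(sys4, pool=0)
        direct = solve_balanced(MeanFieldSystem(
            W=[[w_ee, -w_ei], [w_ie, -w_ii]], f=[5.0, 0.0],
            populations=("e", "i")))
        assert np.allclose(single.rates, direct.rates)

    def test_zero_drive(self):
        w_ee, w_ei, w_ie, w_ii, w_long = case_weights()
        sys4 = MeanFieldSystem(W=two_pool_matrix(w_ee, w_ei, w_ie, w_ii, w_long),
                               f=np.zeros(4))
        assert np.allclose(solve_single_pool(sys4).rates, 0.0)


class TestMeanFieldFromArchitecture:
    def test_effective_weight_mapping(self):
        p = rs.NeuronParams()
        assert theory.effective_weight(10.5, 200, p) == pytest.approx(
            np.sqrt(200) * 10.5 * 2.0)

    def test_structural_sparsity(self, case_discrete):
        drive = rs.constant_drive(case_discrete.n_neurons,
                                  case_discrete.layout.e_idx, 5.0)
        sys4 = meanfield_from_architecture(case_discrete, drive)
        W = sys4.W
        # cross-pool entries vanish except e -> i (the long-range pathway)
        assert W[0, 2] == 0 and W[0, 3] == 0
        assert W[2, 0] == 0 and W[2, 1] == 0
        assert W[1, 3] == 0 and W[3, 1] == 0
        assert W[1, 2] > 0 and W[3, 0] > 0
        # sign structure: E columns >= 0, I columns <= 0
        assert np.all(W[:, [0, 2]] >= 0) and np.all(W[:, [1, 3]] <= 0)
        assert np.allclose(sys4.f, [5.0, 0.0, 5.0, 0.0])

    def test_pool_swap_equivariance(self, case_discrete):
        """The symmetric system commutes with the pool-swap permutation and
        a pool-swapped drive yields the permuted solution."""
        drive = rs.constant_drive(case_discrete.n_neurons,
                                  case_discrete.layout.e_idx, 5.0)
        sys4 = meanfield_from_architecture(case_discrete, drive)
        P = np.zeros((4, 4))
        P[0, 2] = P[1, 3] = P[2, 0] = P[3, 1] = 1
        assert np.allclose(P @ sys4.W @ P.T, sys4.W)
        f = np.array([4.0, 0.0, 6.0, 0.0])
        a = solve_balanced(MeanFieldSystem(W=sys4.W, f=f))
        b = solve_balanced(MeanFieldSystem(W=sys4.W, f=P @ f))
        assert np.allclose(P @ a.rates, b.rates)

    def test_zero_long_range_block_diagonal(self):
        conn = rs.build_discrete_mutual_inhibition(
            n=400, k=20, amplitudes=dict(rs.DISCRETE_AMPLITUDES, A_ie_long=0.0),
            seed=1)
        drive = rs.constant_drive(conn.n_neurons, conn.layout.e_idx, 5.0)
        sys4 = meanfield_from_architecture(conn, drive)
        assert sys4.W[1, 2] == 0 and sys4.W[3, 0] == 0
        full = solve_balanced(sys4)
        single = solve_single_pool(sys4, pool=0)
        assert np.allclose(full.rates[:2], single.rates)

    def test_continuum_unsupported(self):
        conn = rs.build_continuum(n=100, seed=2)
        drive = rs.constant_drive(conn.n_neurons, conn.layout.e_idx, 5.0)
        with pytest.raises(ValueError, match="continuum"):
            meanfield_from_architecture(conn, drive)


class TestSweep:
    def grid_system(self):
        # inhibition-dominated single pool (w_ei*w_ie > w_ee*w_ii) so the
        # symmetric solution is feasible at w_long = 0
        w_ee, w_ei, w_ie, w_ii = 300.0, 570.0, 850.0, 1270.0
        return MeanFieldSystem(W=two_pool_matrix(w_ee, w_ei, w_ie, w_ii, 0.0),
                               f=[5.0, 0.0, 5.0, 0.0])

    def analytic_singularity(self, base):
        w_ee, w_ei = base.W[0, 0], -base.W[0, 1]
        w_ie, w_ii = base.W[1, 0], -base.W[1, 1]
        # antisymmetric-block determinant w_ei*(w_ie - w_L) - w_ee*w_ii = 0
        return w_ie - w_ee * w_ii / w_ei

    def test_bisection_locates_determinant_root(self):
        base = self.grid_system()
        expected = self.analytic_singularity(base)
        grid = np.linspace(0.0, 400.0, 21)
        frame, singular = sweep_mutual_inhibition(base, grid)
        assert singular == pytest.approx(expected, abs=1e-6)
        dets = [np.linalg.det(two_pool_matrix(
            base.W[0, 0], -base.W[0, 1], base.W[1, 0], -base.W[1, 1], w))
            for w in grid]
        assert np.sign(dets[0]) != np.sign(dets[-1])

    def test_rates_fall_with_mutual_inhibition_e_faster(self):
        """Below the singularity all solutions are feasible, rates decrease
        with the mutual-inhibition weight, and E rates fall faster
        (normalization regime)."""
        base = self.grid_system()
        w_star = self.analytic_singularity(base)
        grid = np.linspace(0.0, 0.9 * w_star, 10)
        frame, _ = sweep_mutual_inhibition(base, grid)
        assert frame["feasible"].all()
        assert np.all(np.diff(frame["r_e1_hz"]) < 0)
        assert np.all(np.diff(frame["r_i1_hz"]) < 0)
        rel_e = frame["r_e1_hz"] / frame["r_e1_hz"].iloc[0]
        rel_i = frame["r_i1_hz"] / frame["r_i1_hz"].iloc[0]
        assert np.all(rel_e.iloc[1:] < rel_i.iloc[1:])

    def test_rates_diverge_near_singularity(self):
        """The singular direction is the antisymmetric pool mode: with any
        drive asymmetry the solution magnitude blows up approaching the
        critical mutual-inhibition weight, while a purely symmetric drive
        passes through smoothly."""
        base = self.grid_system()
        base_asym = MeanFieldSystem(W=base.W.copy(), f=[5.0, 0.0, 5.2, 0.0])
        w_star = self.analytic_singularity(base)
        near = sweep_mutual_inhibition(
            base_asym, np.array([0.999 * w_star, 1.2 * w_star]))[0]
        far = sweep_mutual_inhibition(
            base_asym, np.array([0.5 * w_star, 1.2 * w_star]))[0]
        assert abs(near["r_e1_hz"].iloc[0]) > 10 * abs(far["r_e1_hz"].iloc[0])
        sym_near = sweep_mutual_inhibition(
            base, np.array([0.999 * w_star, 1.2 * w_star]))[0]
        sym_far = sweep_mutual_inhibition(
            base, np.array([0.5 * w_star, 1.2 * w_star]))[0]
        assert abs(sym_near["r_e1_hz"].iloc[0]) < 2 * abs(sym_far["r_e1_hz"].iloc[0])

    def test_zero_long_range_equals_single_pool(self):
        base = self.grid_system()
        frame, _ = sweep_mutual_inhibition(base, np.array([0.0, 10.0]))
        single = solve_single_pool(base)
        assert frame.loc[0, "r_e1_hz"] == pytest.approx(single.rates_hz[0])
        assert frame.loc[0, "r_i1_hz"] == pytest.approx(single.rates_hz[1])

    def test_no_singularity_reported_absent(self):
        base = self.grid_system()
        w_star = self.analytic_singularity(base)
        frame, singular = sweep_mutual_inhibition(
            base, np.linspace(0, 0.5 * w_star, 5))
        assert singular is None


class TestComparison:
    def test_identical_inputs_zero_error(self):
        base = TestSweep().grid_system()
        w_star = TestSweep().analytic_singularity(base)
        grid = np.linspace(0.0, 0.8 * w_star, 6)
        frame, _ = sweep_mutual_inhibition(base, grid)
        sim = frame[["w_long"]].copy()
        for p in ("e1", "i1", "e2", "i2"):
            sim[f"r_{p}_hz"] = frame[f"r_{p}_hz"]
        merged = compare_theory_simulation(frame, sim)
        assert merged["calibration"].iloc[0] == pytest.approx(1.0)
        for p in ("e1", "i1", "e2", "i2"):
            assert np.allclose(merged[f"rel_err_{p}"], 0.0, atol=1e-12)
        assert (merged["regime"] == "symmetric").all()

    def test_calibration_scalar_recovered(self):
        base = TestSweep().grid_system()
        grid = np.linspace(0.0, 100.0, 5)
        frame, _ = sweep_mutual_inhibition(base, grid)
        sim = frame[["w_long"]].copy()
        for p in ("e1", "i1", "e2", "i2"):
            sim[f"r_{p}_hz"] = 0.7 * frame[f"r_{p}_hz"]
        merged = compare_theory_simulation(frame, sim)
        assert merged["calibration"].iloc[0] == pytest.approx(0.7)

    def test_mismatched_grids_rejected(self):
        base = TestSweep().grid_system()
        frame, _ = sweep_mutual_inhibition(base, np.array([0.0, 50.0]))
        sim = pd.DataFrame({"w_long": [0.0, 60.0],
                            **{f"r_{p}_hz": [1.0, 1.0]
                               for p in ("e1", "i1", "e2", "i2")}})
        with pytest.raises(ValueError):
            compare_theory_simulation(frame, sim)
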