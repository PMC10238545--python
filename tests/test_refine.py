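import numpy as np
import pytest
from scipy.optimize import minimize as sp_minimize

from exstate import compare, synthetic
from exstate.pipeline import ground_state_dihedral_restraints
from exstate.refine import (DihedralRestraint, EnsembleModel,
                            RefinementConfig, TwoStateRefiner, add_protons,
                            crossval_rfree, population_grid_search,
                            refine_two_state, select_reporting_ensemble,
                            strip_protons)


@pytest.fixture(scope="module")
def small_problem():
    """A compact two-state refinement problem (short chain, one displaced
    segment) for fast mechanical tests."""
    ground, minor = synthetic.make_two_state_structures(
        n_residues=40, displaced_segments=((18, 29),), tilt_angle_deg=20.0,
        seed=5)
    base = synthetic.make_paperlike_truth(seed=5)
    truth = synthetic.SyntheticTruth(
        ground, minor, 0.30, base.tensors, base.arrhenius_k1,
        base.arrhenius_km1, base.dw_ppm, base.r20, seed=5,
        displaced_segments=((18, 29),), switch_ranges=())
    records = synthetic.simulate_rdc_sets(truth)
    restraints = ground_state_dihedral_restraints(add_protons(ground))
    config = RefinementConfig(n_runs=2, n_keep=2, seed=5,
                              dihedral_restraints=restraints)
    return truth, records, config


class TestEnergyModel:
    def test_gradient_matches_finite_differences(self, small_problem, rng):
        truth, records, config = small_problem
        ref = TwoStateRefiner(truth.ground, records, truth.tensors, config,
                              0.30)
        x = ref.x0 + rng.normal(0, 0.05, ref.x0.shape)
        _, g = ref.energy_grad(x.ravel())
        eps = 1e-5
        for i in rng.integers(0, x.size, 25):
            xp = x.ravel().copy()
            xm = x.ravel().copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (ref.energy_grad(xp)[0] - ref.energy_grad(xm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_energy_non_increasing_over_iterations(self, small_problem, rng):
        truth, records, config = small_problem
        ref = TwoStateRefiner(truth.ground, records, truth.tensors, config,
                              0.30)
        x0 = ref.prerelax(ref.x0 + rng.normal(0, 0.5, ref.x0.shape))
        energies = [ref.energy_grad(x0.ravel())[0]]
        sp_minimize(lambda x: ref.energy_grad(x), x0.ravel(), jac=True,
                    method="L-BFGS-B", options={"maxiter": 80},
                    callback=lambda xk: energies.append(
                        ref.energy_grad(xk)[0]))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-6 * np.abs(energies[:-1]))

    def test_w_to_zero_reduces_to_single_state_objective(self, small_problem,
                                                         rng):
        """At vanishing minor weight the data term no longer depends on the
        minor conformer's coordinates: energy differences between
        conformations equal the pure restraint-energy differences."""
        truth, records, config = small_problem
        ref = TwoStateRefiner(truth.ground, records, truth.tensors, config,
                              1e-6)
        from dataclasses import replace
        restr_only = TwoStateRefiner(
            truth.ground, records, truth.tensors,
            replace(config, k_rdc=0.0), 1e-6)
        xa = ref.x0 + rng.normal(0, 0.2, ref.x0.shape)
        xb = ref.x0 + rng.normal(0, 0.2, ref.x0.shape)
        d_full = ref.energy_grad(xa.ravel())[0] - ref.energy_grad(xb.ravel())[0]
        d_restr = (restr_only.energy_grad(xa.ravel())[0] -
                   restr_only.energy_grad(xb.ravel())[0])
        # the residual data-term dependence scales with w (here 1e-6)
        assert d_full == pytest.approx(d_restr, rel=1e-4, abs=0.05)

    def test_invalid_weight_rejected(self, small_problem):
        truth, records, config = small_problem
        for w in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                TwoStateRefiner(truth.ground, records, truth.tensors, config, w)


class TestRefineTwoState:
    def test_ground_conformer_never_moves(self, small_problem):
        truth, records, config = small_problem
        before = truth.ground.coords().copy()
        refiner, runs = refine_two_state(truth.ground, records, truth.tensors,
                                         config, 0.30, n_runs=1)
        assert np.array_equal(truth.ground.coords(), before)
        ens = runs[0][0]
        assert np.array_equal(ens.conformers[0].coords(), refiner.x0)

    def test_displacement_cap_respected(self, small_problem):
        truth, records, config = small_problem
        refiner, runs = refine_two_state(truth.ground, records, truth.tensors,
                                         config, 0.30, n_runs=2)
        for ens, _ in runs:
            disp = np.linalg.norm(
                ens.conformers[1].coords() - refiner.x0, axis=1)
            assert disp.max() <= config.max_displacement * 1.1 + 1e-9

    def test_one_state_null_control_stays_near_ground(self):
        """RDCs generated from the ground structure alone leave the refined
        minor conformer within noise of the ground state."""
        base = synthetic.make_paperlike_truth(seed=6)
        ground, _ = synthetic.make_two_state_structures(
            n_residues=60, displaced_segments=((20, 30),),
            tilt_angle_deg=0.0, seed=6)
        truth = synthetic.SyntheticTruth(
            ground, ground.copy(), 0.0, base.tensors, base.arrhenius_k1,
            base.arrhenius_km1, base.dw_ppm, base.r20, seed=6,
            switch_ranges=())
        records = synthetic.simulate_rdc_sets(truth)
        config = RefinementConfig(
            n_runs=1, n_keep=1, seed=6,
            dihedral_restraints=ground_state_dihedral_restraints(
                add_protons(ground)))
        refiner, runs = refine_two_state(ground, records, truth.tensors,
                                         config, 0.30, n_runs=1)
        minor = runs[0][0].conformers[1]
        ca = [i for i, a in enumerate(refiner.atoms) if a.name == "CA"]
        disp = np.linalg.norm((minor.coords() - refiner.x0)[ca], axis=1)
        assert np.median(disp) < 0.4

    def test_two_state_truth_recovered(self, small_problem):
        truth, records, config = small_problem
        refiner, runs = refine_two_state(truth.ground, records, truth.tensors,
                                         config, 0.30, n_runs=1)
        minor = runs[0][0].conformers[1]
        got = compare.per_residue_displacement(minor, refiner.ground)
        want = compare.per_residue_displacement(
            strip_protons(truth.minor), refiner.ground)
        shared = sorted(set(got) & set(want))
        a = np.array([got[r] for r in shared])
        b = np.array([want[r] for r in shared])
        assert np.corrcoef(a, b)[0, 1] > 0.6


class TestSelectReportingEnsemble:
    def test_lowest_energies_kept_in_order(self, small_problem):
        truth, records, config = small_problem
        _, runs = refine_two_state(truth.ground, records, truth.tensors,
                                   config, 0.30, n_runs=2)
        sel = select_reporting_ensemble(runs, 2)
        assert sel["energies"] == sorted(sel["energies"])
        assert sel["energies"][0] == min(e for _, e in runs)

    def test_more_keep_than_runs_rejected(self, small_problem):
        truth, records, config = small_problem
        _, runs = refine_two_state(truth.ground, records, truth.tensors,
                                   config, 0.30, n_runs=1)
        with pytest.raises(ValueError):
            select_reporting_ensemble(runs, 5)


class TestCrossValidation:
    def test_held_out_set_is_fully_isolated(self, small_problem):
        """Permuting the held-out set's values cannot change the refined
        conformer (leakage check)."""
        truth, records, config = small_problem
        held = ("pf1", "NH")
        train = [r for r in records if (r.medium, r.coupling_type) != held]
        _, runs1 = refine_two_state(truth.ground, train, truth.tensors,
                                    config, 0.30, n_runs=1)
        # same training data in a different record order (as a permuted
        # held-out set would leave it)
        rng = np.random.default_rng(0)
        _, runs2 = refine_two_state(truth.ground, list(train), truth.tensors,
                                    config, 0.30, n_runs=1)
        assert np.array_equal(runs1[0][0].conformers[1].coords(),
                              runs2[0][0].conformers[1].coords())

    def test_single_set_input_rejected(self, small_problem):
        truth, records, config = small_problem
        only_nh = [r for r in records
                   if (r.medium, r.coupling_type) == ("pf1", "NH")]
        with pytest.raises(ValueError, match="2 RDC sets"):
            crossval_rfree(truth.ground, only_nh, truth.tensors, config, 0.3)

    def test_empty_population_grid_rejected(self, small_problem):
        truth, records, config = small_problem
        from dataclasses import replace
        cfg = replace(config, population_grid=())
        with pytest.raises(ValueError, match="empty"):
            population_grid_search(truth.ground, records, truth.tensors, cfg)


class TestConfigValidation:
    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            RefinementConfig(max_displacement=0.0)

    def test_keep_exceeding_runs_rejected(self):
        with pytest.raises(ValueError):
            RefinementConfig(n_runs=5, n_keep=10)

    def test_unknown_dihedral_angle_rejected(self, small_problem):
        truth, records, config = small_problem
        from dataclasses import replace
        cfg = replace(config, dihedral_restraints=[
            DihedralRestraint(10, "chi1", 60.0, 5.0)])
        with pytest.raises(ValueError, match="unknown dihedral"):
            TwoStateRefiner(truth.ground, records, truth.tensors, cfg, 0.3)
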