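import numpy as np
import pytest

from exstate import geometry, synthetic
from exstate.constants import DMAX_RATIO
from exstate.formats_io import RdcRecord
from exstate.rdc import (AlignmentTensor, back_calc_rdc, build_bond_vectors,
                         correct_tensor_magnitude, ensemble_rdc,
                         quality_factors, svd_fit_tensor, vector_map)
from exstate.refine import EnsembleModel, strip_protons
from exstate.synthetic import _tensor_from


def axial_tensor(da):
    return _tensor_from(da, 0.0, np.eye(3))


class TestBondVectors:
    def test_reconstructed_protons_match_ideal_fixture(self, small_backbone):
        """Stripping protons from an ideal-geometry chain and rebuilding
        them reproduces the original positions."""
        stripped = strip_protons(small_backbone)
        vm_ref = vector_map(build_bond_vectors(small_backbone))
        vm_new = vector_map(build_bond_vectors(stripped))
        n_h = 0
        for key, bv in vm_ref.items():
            if key[1] in ("NH", "CAHA"):
                n_h += 1
                # 0.05 A on a ~1 A bond is ~3 degrees
                assert bv.vector @ vm_new[key].vector > np.cos(np.deg2rad(3))
        assert n_h > 20

    def test_proline_has_no_amide_vectors(self, small_backbone):
        model = small_backbone.copy()
        for a in model.atoms:
            if a.resnum == 10:
                a.resname = "PRO"
        model = strip_protons(model)
        keys = {(v.resnum, v.coupling_type)
                for v in build_bond_vectors(model)}
        assert (10, "NH") not in keys and (10, "HNC") not in keys
        assert (10, "CAHA") in keys and (10, "NC") in keys

    def test_all_vectors_unit_norm(self, small_backbone):
        for v in build_bond_vectors(small_backbone):
            assert np.linalg.norm(v.vector) == pytest.approx(1.0, abs=1e-9)


class TestBackCalc:
    def test_vector_on_tensor_axis(self):
        from exstate.rdc import BondVector
        da = 8.0
        v = BondVector(1, "NH", np.array([0.0, 0.0, 1.0]), 1.0)
        d = back_calc_rdc([v], axial_tensor(da))
        assert d[0] == pytest.approx(2.0 * da, rel=1e-12)

    def test_magic_angle_is_null(self):
        from exstate.rdc import BondVector
        theta = np.deg2rad(54.7356103)
        v = BondVector(1, "NH", np.array([np.sin(theta), 0.0, np.cos(theta)]),
                       1.0)
        d = back_calc_rdc([v], axial_tensor(8.0))
        assert abs(d[0]) < 1e-4

    def test_matches_angle_formula_oracle(self, rng):
        """D = Da[(3 cos^2 th - 1) + 3/2 R sin^2 th cos 2phi] in the tensor
        eigenframe, for random tensors and orientations."""
        from exstate.rdc import BondVector
        for _ in range(20):
            da = rng.uniform(5, 15) * rng.choice([-1, 1])
            rh = rng.uniform(0.0, 2.0 / 3.0)
            rot = geometry.random_rotation(rng)
            tensor = _tensor_from(da, rh, rot)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            v = BondVector(1, "NH", u, 1.0)
            d = back_calc_rdc([v], tensor)[0]
            # express u in the tensor eigenframe (columns x, y, z)
            loc = rot.T @ u
            ct = loc[2]
            st2 = loc[0] ** 2 + loc[1] ** 2
            cos2phi = ((loc[0] ** 2 - loc[1] ** 2) / st2) if st2 > 0 else 1.0
            expected = da * ((3 * ct ** 2 - 1) + 1.5 * rh * st2 * cos2phi)
            assert d == pytest.approx(expected, abs=1e-9)


class TestSvdFit:
    def _dense_problem(self, truth, medium="pf1", noise=0.0, seed=7):
        records = synthetic.simulate_rdc_sets(
            truth, media=[medium], noise=noise > 0, seed=seed)
        vecs = build_bond_vectors(truth.ground)
        return vecs, records

    def test_exact_recovery_on_noise_free_data(self, null_truth):
        vecs, recs = self._dense_problem(null_truth)
        tensor, fq = svd_fit_tensor(vecs, recs)
        true = null_truth.tensors["pf1"]
        assert tensor.da == pytest.approx(true.da, rel=1e-8)
        assert tensor.rhombicity == pytest.approx(true.rhombicity, abs=1e-8)
        assert fq.q_factor < 1e-7

    def test_rotation_invariance_of_da_and_rhombicity(self, null_truth, rng):
        vecs, recs = self._dense_problem(null_truth)
        tensor, _ = svd_fit_tensor(vecs, recs)
        rot = geometry.random_rotation(rng)
        from dataclasses import replace
        rotated = [replace(v, vector=rot @ v.vector) for v in vecs]
        # rotating structure and observations together: observations are
        # regenerated from the rotated tensor, which co-rotates
        m = rot @ null_truth.tensors["pf1"].matrix @ rot.T
        rec2 = []
        vm = vector_map(rotated)
        for r in recs:
            v = vm[(r.resnum, r.coupling_type)]
            rec2.append(RdcRecord(r.resnum, r.coupling_type, r.medium,
                                  float(v.dmax * v.vector @ m @ v.vector),
                                  r.error))
        tensor2, _ = svd_fit_tensor(rotated, rec2)
        assert tensor2.da == pytest.approx(tensor.da, rel=1e-8)
        assert tensor2.rhombicity == pytest.approx(tensor.rhombicity, abs=1e-8)

    def test_saupe_matrix_traceless(self, null_truth):
        vecs, recs = self._dense_problem(null_truth, noise=1.0)
        tensor, _ = svd_fit_tensor(vecs, recs)
        assert abs(np.trace(tensor.matrix)) < 1e-12

    def test_least_squares_optimality(self, null_truth, rng):
        vecs, recs = self._dense_problem(null_truth, noise=1.0)
        tensor, _ = svd_fit_tensor(vecs, recs)
        vm = vector_map(vecs)

        def chi2(saupe):
            t = AlignmentTensor(saupe)
            tot = 0.0
            for r in recs:
                v = vm[(r.resnum, r.coupling_type)]
                pred = v.dmax * (v.vector @ t.matrix @ v.vector)
                tot += ((r.value - pred) / r.error) ** 2
            return tot

        best = chi2(tensor.saupe)
        for _ in range(10):
            assert chi2(tensor.saupe + rng.normal(0, 0.02, 5)) >= best

    def test_rank_deficient_orientations_rejected(self):
        from exstate.rdc import BondVector
        z = np.array([0.0, 0.0, 1.0])
        vecs = [BondVector(i, "NH", z, 1.0) for i in range(1, 9)]
        recs = [RdcRecord(i, "NH", "pf1", 10.0, 0.5) for i in range(1, 9)]
        with pytest.raises(ValueError, match="rank|degenerate"):
            svd_fit_tensor(vecs, recs)


class TestQualityFactors:
    def test_perfect_agreement(self):
        fq = quality_factors([1.0, -2.0, 3.0], [1.0, -2.0, 3.0], 10.0, 0.3)
        assert fq.rmsd == fq.q_factor == fq.r_factor == 0.0

    def test_zero_prediction_gives_q_of_one(self):
        fq = quality_factors([1.0, -2.0, 3.0], [0.0, 0.0, 0.0], 10.0, 0.3)
        assert fq.q_factor == pytest.approx(1.0)

    def test_five_point_hand_example(self):
        obs = np.array([4.0, -6.0, 2.0, 8.0, -3.0])
        calc = np.array([3.0, -5.0, 2.5, 7.0, -4.0])
        da, rh = 9.0, 0.25
        fq = quality_factors(obs, calc, da, rh)
        rmsd = np.sqrt(np.mean((obs - calc) ** 2))
        assert fq.rmsd == pytest.approx(rmsd, rel=1e-12)
        assert fq.q_factor == pytest.approx(
            rmsd / np.sqrt(np.mean(obs ** 2)), rel=1e-12)
        assert fq.r_factor == pytest.approx(
            rmsd / np.sqrt(2 * da ** 2 * (4 + 3 * rh ** 2) / 5), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quality_factors([], [], 10.0, 0.3)


class TestEnsembleRdc:
    def test_degenerate_weights_equal_single_conformer(self, truth):
        recs = synthetic.simulate_rdc_sets(truth, noise=False)[:40]
        ens = EnsembleModel([truth.ground, truth.minor], [1.0, 0.0])
        single = back_calc_rdc(
            [vector_map(build_bond_vectors(truth.ground))[(r.resnum, r.coupling_type)]
             for r in recs],
            truth.tensors["pf1"])
        # restrict to one medium so the single-tensor reference applies
        sub = [r for r in recs if r.medium == "pf1"]
        pred = ensemble_rdc(ens, sub, truth.tensors)
        ref = back_calc_rdc(
            [vector_map(build_bond_vectors(truth.ground))[(r.resnum, r.coupling_type)]
             for r in sub], truth.tensors["pf1"])
        assert np.allclose(pred, ref, atol=1e-12)

    def test_identical_conformers_any_weights(self, truth):
        sub = [r for r in synthetic.simulate_rdc_sets(truth, noise=False)
               if r.medium == "pf1"][:30]
        ens = EnsembleModel([truth.ground, truth.ground.copy()], [0.4, 0.6])
        pred = ensemble_rdc(ens, sub, truth.tensors)
        ref = back_calc_rdc(
            [vector_map(build_bond_vectors(truth.ground))[(r.resnum, r.coupling_type)]
             for r in sub], truth.tensors["pf1"])
        assert np.allclose(pred, ref, atol=1e-12)

    def test_weighted_sum_oracle(self, truth):
        sub = [r for r in synthetic.simulate_rdc_sets(truth, noise=False)
               if r.medium == "bicelles"][:50]
        pred = ensemble_rdc(truth.ensemble(), sub, truth.tensors)
        t = truth.tensors["bicelles"]
        vg = vector_map(build_bond_vectors(truth.ground))
        vm = vector_map(build_bond_vectors(truth.minor))
        for r, p in zip(sub, pred):
            vga = vg[(r.resnum, r.coupling_type)]
            vma = vm[(r.resnum, r.coupling_type)]
            expected = (0.7 * vga.dmax * vga.vector @ t.matrix @ vga.vector +
                        0.3 * vma.dmax * vma.vector @ t.matrix @ vma.vector)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_weights_must_sum_to_one(self, truth):
        sub = [r for r in synthetic.simulate_rdc_sets(truth, noise=False)
               if r.medium == "pf1"][:10]
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleModel([truth.ground, truth.minor], [0.6, 0.3])


class TestTensorMagnitudeCorrection:
    def test_dense_sampling_needs_no_correction(self, null_truth):
        recs = synthetic.simulate_rdc_sets(null_truth, media=["pf1"], seed=11)
        corr = correct_tensor_magnitude(null_truth.ground, recs)
        assert corr.scale == pytest.approx(1.0, abs=0.02)

    def test_sparse_anisotropic_subset_underestimates_and_corrects(self,
                                                                   null_truth):
        """Restricting measurements to one helix makes the single-set SVD
        magnitude collapse along unsampled directions; the all-set
        corrected magnitude lands closer to the truth."""
        subset = set(range(87, 105))
        recs = synthetic.simulate_rdc_sets(null_truth, media=["pf1"],
                                           residue_subset=subset, seed=21)
        corr = correct_tensor_magnitude(null_truth.ground, recs)
        true_da = abs(null_truth.tensors["pf1"].da)
        nh_da = abs(corr.per_set_svd["NH"].da)
        corrected = abs(corr.corrected.da)
        assert nh_da < true_da
        assert abs(corrected - true_da) < abs(nh_da - true_da)

    def test_never_selects_shrinking_scale(self, null_truth):
        recs = synthetic.simulate_rdc_sets(null_truth, media=["pf1"], seed=11)
        corr = correct_tensor_magnitude(null_truth.ground, recs)
        assert corr.scale >= 1.0
        assert min(corr.summed_r) >= 1.0

    def test_requires_two_coupling_types(self, null_truth):
        recs = [r for r in synthetic.simulate_rdc_sets(null_truth,
                                                       media=["pf1"], seed=11)
                if r.coupling_type == "NH"]
        with pytest.raises(ValueError, match="2 coupling types"):
            correct_tensor_magnitude(null_truth.ground, recs)
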