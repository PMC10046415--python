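"""DWBA operator construction, TSVD inversion, and the imaging estimator."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermowave.imaging import (
    DifferentialData,
    TsvdRoiImager,
    build_roi_operator,
    differential_data,
    solution_norm_curve,
    tsvd_invert,
)
from thermowave.phantom import RoiSpec, set_roi_temperatures


class TestDifferentialData:
    def test_identical_inputs_give_zero(self):
        es = np.ones((2, 3, 3), dtype=complex)
        assert np.all(differential_data(es, es).stacked == 0)

    def test_subtraction_contract(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(2, 4, 4)) + 1j * rng.normal(size=(2, 4, 4))
        b = rng.normal(size=(2, 4, 4)) + 1j * rng.normal(size=(2, 4, 4))
        out = differential_data(a + b, a)
        assert np.allclose(out.blocks(), b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            differential_data(np.ones((2, 3, 3)), np.ones((2, 4, 4)))


class TestRoiOperator:
    def test_svd_reconstructs_operator(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        rebuilt = (op.u * op.s) @ op.vh
        assert np.linalg.norm(rebuilt - op.matrix) < 1e-10 * np.linalg.norm(op.matrix)
        assert np.all(op.s >= 0)
        assert np.all(np.diff(op.s) <= 0)

    def test_rank_bounded_by_window_pixels(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        nf = len(small_baseline_fields)
        nm = small_baseline_fields[0].layout.n
        assert op.matrix.shape == (nf * nm * nm, 25)
        assert op.rank <= min(nf * nm * nm, 25)

    def test_kernel_is_bilinear_in_baseline_field(self, small_baseline_fields, small_phantom):
        rec = small_baseline_fields[0]
        scaled = dataclasses.replace(rec, etot=2.0 * rec.etot)
        op1 = build_roi_operator([rec], small_phantom.tumor_roi)
        op2 = build_roi_operator([scaled], small_phantom.tumor_roi)
        assert np.allclose(op2.matrix, 4.0 * op1.matrix)

    def test_single_pixel_roi_matches_scalar_least_squares(self, small_baseline_fields, small_phantom):
        roi = small_phantom.tumor_roi
        one_px = RoiSpec(name="pt", row0=roi.row0 + 2, col0=roi.col0 + 2, size=1)
        op = build_roi_operator(small_baseline_fields, one_px)
        assert op.matrix.shape[1] == 1
        rng = np.random.default_rng(3)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        data = DifferentialData(stacked=y, shape=op.shape)
        img = tsvd_invert(op, data, p_cut=1)
        col = op.matrix[:, 0]
        lsq = (col.conj() @ y) / (col.conj() @ col)
        assert img.dchi.reshape(()) == pytest.approx(lsq, rel=1e-10)


class TestTsvd:
    def test_zero_data_gives_zero_image(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        data = DifferentialData(stacked=np.zeros(op.matrix.shape[0], complex), shape=op.shape)
        assert np.all(tsvd_invert(op, data, 1).dchi == 0)

    def test_full_rank_recovers_consistent_data(self, small_baseline_fields, small_phantom):
        """Oracle: pseudo-inverse solve of noiseless consistent data."""
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        rng = np.random.default_rng(11)
        truth = rng.normal(size=25) + 1j * rng.normal(size=25)
        data = DifferentialData(stacked=op.matrix @ truth, shape=op.shape)
        img = tsvd_invert(op, data, p_cut=op.rank)
        pinv = np.linalg.pinv(op.matrix) @ data.stacked
        assert np.linalg.norm(img.dchi.ravel() - truth) < 1e-8 * np.linalg.norm(truth)
        assert np.allclose(img.dchi.ravel(), pinv, atol=1e-10)

    def test_pcut_one_is_single_triplet(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        rng = np.random.default_rng(4)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        data = DifferentialData(stacked=y, shape=op.shape)
        img = tsvd_invert(op, data, 1)
        expected = op.vh[0].conj() * (op.u[:, 0].conj() @ y) / op.s[0]
        assert np.allclose(img.dchi.ravel(), expected)

    def test_pcut_out_of_range_rejected(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        data = DifferentialData(stacked=np.zeros(op.matrix.shape[0], complex), shape=op.shape)
        with pytest.raises(ValueError):
            tsvd_invert(op, data, 0)
        with pytest.raises(ValueError):
            tsvd_invert(op, data, op.rank + 1)

    def test_online_inversion_uses_only_pcut_triplets(self, cached_operator):
        """Offline/online split: the per-sample solve reads just the first
        Pcut singular triplets (cost O(Pcut * Nf*Nm*Nv)), so truncating the
        cached SVD beyond Pcut cannot change the result."""
        op = cached_operator
        rng = np.random.default_rng(21)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        data = DifferentialData(stacked=y, shape=op.shape)
        p = 2
        truncated = dataclasses.replace(
            op, u=op.u[:, :p].copy(), s=op.s[:p].copy(), vh=op.vh[:p].copy()
        )
        assert np.allclose(
            tsvd_invert(op, data, p).dchi, tsvd_invert(truncated, data, p).dchi
        )

    def test_fitted_norm_grows_with_pcut(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        rng = np.random.default_rng(6)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        data = DifferentialData(stacked=y, shape=op.shape)
        fitted = [
            np.linalg.norm(op.matrix @ tsvd_invert(op, data, p).dchi.ravel())
            for p in range(1, op.rank + 1)
        ]
        assert np.all(np.diff(fitted) >= -1e-12 * fitted[-1])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_solution_norm_curve_monotone(self, seed, cached_operator):
        op = cached_operator
        rng = np.random.default_rng(seed)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        curve = solution_norm_curve(op, DifferentialData(stacked=y, shape=op.shape))
        assert curve.size == op.rank
        assert np.all(np.diff(curve) >= -1e-12 * curve[-1])

    def test_solution_norm_curve_endpoints(self, small_baseline_fields, small_phantom):
        op = build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
        zero = DifferentialData(stacked=np.zeros(op.matrix.shape[0], complex), shape=op.shape)
        assert np.all(solution_norm_curve(op, zero) == 0)
        rng = np.random.default_rng(12)
        truth = rng.normal(size=25) + 1j * rng.normal(size=25)
        data = DifferentialData(stacked=op.matrix @ truth, shape=op.shape)
        curve = solution_norm_curve(op, data)
        pinv_norm = np.linalg.norm(np.linalg.pinv(op.matrix) @ data.stacked)
        assert curve[-1] == pytest.approx(pinv_norm, rel=1e-8)


class TestPhysics:
    def test_linearization_error_shrinks_with_contrast(self, small_phantom, small_solver):
        """DWBA accuracy sweep: imposed |dchi| in {1e-1, 1e-2, 1e-3}."""
        base = small_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            baseline = small_solver.solve(base)
        es0 = np.stack([r.es for r in baseline])
        op = build_roi_operator(baseline, base.tumor_roi)
        # perturb the tumor tissue's permittivity directly via offsets
        eps_b = base.config.background_eps(baseline[0].f)
        errors = []
        for mag in (1e-1, 1e-2, 1e-3):
            delta_eps = mag * eps_b  # dchi = delta_eps / eps_b has magnitude mag
            pert = dataclasses.replace(base, offsets={"tumor": delta_eps})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                heated = small_solver.solve(pert)
            d = (np.stack([r.es for r in heated]) - es0).ravel()
            # predicted by the linear operator: dchi = mag on tumor pixels
            dchi = np.zeros(op.matrix.shape[1], complex)
            roi = base.tumor_roi
            sub = base.labels[roi.rows, roi.cols].ravel() == base.tissue_ids["tumor"]
            dchi[sub] = mag
            pred = op.matrix @ dchi
            errors.append(np.linalg.norm(d - pred) / np.linalg.norm(d))
        assert errors[0] > errors[1] > errors[2]

    def test_roi_separability(self, small_phantom, small_solver):
        """Heating the cord barely leaks into the tumor ROI image."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            baseline = small_solver.solve(small_phantom)
            es0 = np.stack([r.es for r in baseline])
            op_t = build_roi_operator(baseline, small_phantom.tumor_roi)
            hot_tumor = small_solver.solve(set_roi_temperatures(small_phantom, 43.0, 37.0))
            hot_cord = small_solver.solve(set_roi_temperatures(small_phantom, 37.0, 40.0))
        d_tumor = differential_data(np.stack([r.es for r in hot_tumor]), es0)
        d_cord = differential_data(np.stack([r.es for r in hot_cord]), es0)
        img_own = tsvd_invert(op_t, d_tumor, 1).dchi
        img_leak = tsvd_invert(op_t, d_cord, 1).dchi
        assert np.linalg.norm(img_leak) < 0.10 * np.linalg.norm(img_own)


class TestImagerEstimator:
    def test_fit_transform_roundtrip(self, small_baseline_fields, small_phantom):
        imager = TsvdRoiImager(roi=small_phantom.tumor_roi, p_cut=1)
        assert imager.get_params()["p_cut"] == 1
        imager.fit(small_baseline_fields)
        op = imager.operator_
        rng = np.random.default_rng(8)
        y = rng.normal(size=op.matrix.shape[0]) + 1j * rng.normal(size=op.matrix.shape[0])
        data = DifferentialData(stacked=y, shape=op.shape)
        out = imager.transform(data)
        assert out.shape == (1, 5, 5, 2)
        direct = tsvd_invert(op, data, 1)
        assert np.allclose(out[0], direct.channels())

    def test_unfitted_transform_raises(self, small_phantom):
        with pytest.raises(RuntimeError):
            TsvdRoiImager(roi=small_phantom.tumor_roi).transform([])

    def test_set_params_returns_self(self, small_phantom):
        imager = TsvdRoiImager(roi=small_phantom.tumor_roi)
        assert imager.set_params(p_cut=2).p_cut == 2
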