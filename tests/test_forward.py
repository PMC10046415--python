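"""Forward solver: analytic oracle, reciprocity, linearity, noise calibration."""

import dataclasses
import warnings

import numpy as np
import pytest

from thermowave.dielectric import cole_cole
from thermowave.forward import (
    AntennaLayout,
    FrequencySet,
    MomForwardSolver,
    add_awgn,
    analytic_cylinder_reference,
    background_green,
    background_wavenumber,
    incident_field,
    solve_total_field,
)
from thermowave.phantom import PhantomConfig, build_neck_phantom


def _uniform_cylinder_phantom(grid_n=64, radius=0.03, tissue="muscle"):
    """Phantom whose neck is a homogeneous disc of one tissue."""
    cfg = PhantomConfig(
        grid_n=grid_n, domain_size=0.12, neck_semi_axes=(radius, radius),
        skin_thickness=1e-6, fat_thickness=1e-6,
        vertebra_center=(0.0, -0.012), vertebra_radius=0.004, cord_radius=0.003,
        thyroid_centers=((0.0, 0.012),), thyroid_radius=0.006,
        tumor_center=(0.0, 0.012), tumor_radius=0.0045,
    )
    ph = build_neck_phantom(cfg)
    labels = ph.labels.copy()
    labels[labels > 0] = ph.tissue_ids[tissue]
    return dataclasses.replace(ph, labels=labels), cfg


class TestGreenAndIncident:
    def test_magnitude_decays_in_lossy_background(self):
        kb = background_wavenumber(1.0e9, 23 - 10j)
        r0 = np.zeros(2)
        dists = np.linspace(0.02, 0.15, 30)
        mags = [abs(background_green(kb, np.array([d, 0.0]), r0)) for d in dists]
        assert np.all(np.diff(mags) < 0)

    def test_kernel_symmetry(self):
        kb = background_wavenumber(1.3e9, 23 - 13j)
        a, b = np.array([0.01, 0.02]), np.array([-0.03, 0.005])
        assert background_green(kb, a, b) == background_green(kb, b, a)

    def test_outgoing_phase_convention(self):
        # real kb: phase of H0^(2)(kb r) decreases with r (e^{-jkr} outgoing
        # under e^{jwt}), so the unwrapped angle is monotonically decreasing
        kb = 2 * np.pi / 0.05  # purely real
        r0 = np.zeros(2)
        dists = np.linspace(0.05, 0.2, 200)
        phases = np.unwrap([np.angle(background_green(kb, np.array([d, 0]), r0)) for d in dists])
        assert np.all(np.diff(phases) < 0)

    def test_incident_is_source_green(self, ring_layout):
        kb = background_wavenumber(1.0e9, 23 - 13j)
        pts = np.array([[0.0, 0.0], [0.01, -0.02]])
        got = incident_field(ring_layout, kb, 3, pts)
        expected = background_green(kb, pts, ring_layout.positions[3])
        assert np.allclose(got, expected)

    def test_source_index_validated(self, ring_layout):
        kb = background_wavenumber(1.0e9, 23 - 13j)
        with pytest.raises(IndexError):
            incident_field(ring_layout, kb, 12, np.zeros(2))


class TestMomSolver:
    def test_zero_contrast_gives_incident_field_and_zero_data(self):
        from thermowave.dielectric import cole_cole as cc

        ph, cfg = _uniform_cylinder_phantom(grid_n=32)
        f = 1.0e9
        # offset the tissue so its permittivity exactly matches the background
        # at this frequency: chi == 0 everywhere
        delta = cfg.background_eps(f) - cc(ph.tissue_table["muscle"].params, f).to_complex()
        matched = dataclasses.replace(ph, offsets={"muscle": delta})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = solve_total_field(matched, AntennaLayout.default_ring(0.05), f)
        assert np.all(rec.es == 0)
        assert np.array_equal(rec.etot, rec.einc)

    def test_matches_analytic_cylinder_within_two_percent(self):
        ph, cfg = _uniform_cylinder_phantom()
        layout = AntennaLayout.default_ring(0.05)
        f = 1.0e9
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = solve_total_field(ph, layout, f)
        eps_cyl = cole_cole(ph.tissue_table["muscle"].params, f).to_complex()
        es_ref = analytic_cylinder_reference(0.03, eps_cyl, cfg.background_eps(f), layout, f)
        err = np.linalg.norm(rec.es - es_ref) / np.linalg.norm(es_ref)
        assert err < 0.02

    def test_reciprocity(self, small_baseline_fields):
        for rec in small_baseline_fields:
            asym = np.linalg.norm(rec.es - rec.es.T) / np.linalg.norm(rec.es)
            assert asym < 1e-6

    def test_lossier_background_attenuates_data(self):
        layout = AntennaLayout.default_ring(0.05)
        f = 1.0e9
        mags = []
        for sig_b in (0.5, 1.0, 2.0):
            ph, cfg = _uniform_cylinder_phantom(grid_n=32)
            cfg = dataclasses.replace(cfg, background_sigma=sig_b)
            ph = dataclasses.replace(ph, config=cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = solve_total_field(ph, layout, f)
            mags.append(np.abs(rec.es).mean())
        assert mags[0] > mags[1] > mags[2]

    def test_cgfft_agrees_with_dense(self):
        ph, _ = _uniform_cylinder_phantom(grid_n=32)
        layout = AntennaLayout.default_ring(0.05)
        f = 1.0e9
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dense = solve_total_field(ph, layout, f, method="direct")
            iterative = solve_total_field(ph, layout, f, method="cgfft")
        err = np.linalg.norm(dense.es - iterative.es) / np.linalg.norm(dense.es)
        assert err < 1e-4

    def test_grid_refinement_convergence(self):
        layout = AntennaLayout.default_ring(0.05)
        f = 1.0e9
        results = []
        for gn in (32, 64):
            ph, _ = _uniform_cylinder_phantom(grid_n=gn)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(solve_total_field(ph, layout, f).es)
        rel = np.linalg.norm(results[0] - results[1]) / np.linalg.norm(results[1])
        assert rel < 0.05

    def test_antennas_inside_neck_rejected(self, small_phantom):
        layout = AntennaLayout(positions=np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            MomForwardSolver(small_phantom, layout, FrequencySet(np.array([1e9])))


class TestAnalyticCylinder:
    def test_matched_cylinder_scatters_nothing(self):
        layout = AntennaLayout.default_ring(0.05)
        es = analytic_cylinder_reference(0.02, 23 - 13j, 23 - 13j, layout, 1.0e9)
        assert np.all(es == 0)

    def test_vanishing_radius_limit(self):
        layout = AntennaLayout.default_ring(0.05)
        es_small = analytic_cylinder_reference(1e-4, 50 - 10j, 23 - 13j, layout, 1.0e9)
        es_big = analytic_cylinder_reference(0.02, 50 - 10j, 23 - 13j, layout, 1.0e9)
        assert np.abs(es_small).max() < 1e-3 * np.abs(es_big).max()

    def test_series_is_reciprocal(self):
        layout = AntennaLayout.default_ring(0.05)
        es = analytic_cylinder_reference(0.02, 50 - 10j, 23 - 13j, layout, 1.0e9)
        assert np.allclose(es, es.T)


class TestAwgn:
    def test_infinite_snr_is_identity(self):
        data = np.ones((2, 3, 3), dtype=complex)
        out = add_awgn(data, np.inf, 0)
        assert np.array_equal(out, data)

    def test_empirical_snr_within_half_db(self):
        rng = np.random.default_rng(42)
        sig = rng.normal(size=(4, 12, 12)) + 1j * rng.normal(size=(4, 12, 12))
        p_sig = np.mean(np.abs(sig) ** 2)
        noise_powers = []
        for _ in range(1000):
            noisy = add_awgn(sig, 30.0, rng)
            noise_powers.append(np.mean(np.abs(noisy - sig) ** 2))
        snr_db = 10 * np.log10(p_sig / np.mean(noise_powers))
        assert abs(snr_db - 30.0) < 0.5

    def test_seed_reproducibility(self):
        sig = np.ones((1, 4, 4), dtype=complex)
        a, b = add_awgn(sig, 30.0, 9), add_awgn(sig, 30.0, 9)
        c = add_awgn(sig, 30.0, 10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


def test_field_container_round_trip(small_baseline_fields, tmp_path):
    from thermowave.forward import load_fields_h5, save_fields_h5

    path = tmp_path / "fields.h5"
    save_fields_h5(path, small_baseline_fields)
    back = load_fields_h5(path)
    assert len(back) == len(small_baseline_fields)
    for a, b in zip(back, small_baseline_fields):
        assert a.f == b.f and a.kb == b.kb
        assert np.array_equal(a.es, b.es)
        assert np.array_equal(a.etot, b.etot)
        assert np.array_equal(a.support, b.support)


class TestFrequencySet:
    def test_default_band(self):
        fs = FrequencySet.evenly_spaced()
        assert len(fs) == 10
        assert fs.frequencies[0] == 0.9e9 and fs.frequencies[-1] == 1.8e9

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            FrequencySet(np.array([1.0e9, 0.9e9]))
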