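"""Unit tests of the Monte Carlo transport building blocks."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fingersim as fs
from fingersim.mcsim import PhotonPacket, hg_cos_theta, traverse
from fingersim.optics import OpticalProperties
from conftest import slab_volume


class TestLaunch:
    def test_weight_one_and_collimated(self):
        rng = np.random.default_rng(0)
        vol = slab_volume((8, 8, 4))
        p = fs.launch_packet(fs.SimulationConfig(), rng, vol)
        assert p.weight == 1.0
        assert np.allclose(p.direction, [0, 0, 1])
        assert p.position[2] == 0.0
        assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-12)

    def test_positions_uniform_over_entry_face(self):
        rng = np.random.default_rng(1)
        vol = slab_volume((10, 10, 2), pitch=1.0)
        n = 20_000
        xs = np.empty(n)
        ys = np.empty(n)
        for i in range(n):
            p = fs.launch_packet(fs.SimulationConfig(), rng, vol)
            xs[i], ys[i] = p.position[0], p.position[1]
        counts, _, _ = np.histogram2d(xs, ys, bins=5, range=[[0, 10], [0, 10]])
        _, pval = stats.chisquare(counts.ravel())
        assert pval > 0.01


class TestSampleStep:
    def test_closed_form(self):
        assert fs.sample_step(1.0, math.exp(-1.0)) == pytest.approx(1.0)

    def test_zero_attenuation_gives_infinite_path(self):
        assert fs.sample_step(0.0, 0.5) == math.inf

    def test_limit_u_to_one_gives_vanishing_step(self):
        assert fs.sample_step(1.0, 1 - 1e-12) < 1e-9

    def test_sample_mean_matches_mean_free_path(self):
        rng = np.random.default_rng(2)
        u = rng.random(1_000_000)
        s = -np.log(u) / 2.0
        se = s.std() / math.sqrt(s.size)
        assert abs(s.mean() - 0.5) < 3 * se


class TestHenyeyGreenstein:
    def test_isotropic_limit_formula(self):
        u = np.array([0.0, 0.25, 0.5, 1.0])
        assert np.allclose(hg_cos_theta(0.0, u), 2 * u - 1)

    @pytest.mark.parametrize("g", [0.0, 0.75, 0.9])
    def test_sample_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(3)
        ct = hg_cos_theta(g, rng.random(1_000_000))
        se = ct.std() / math.sqrt(ct.size)
        assert abs(ct.mean() - g) < 3 * se

    @given(
        st.floats(-0.95, 0.95),
        st.floats(0.0, 1.0, exclude_max=True),
        st.floats(0.0, 1.0, exclude_max=True),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_direction_is_unit(self, g, u1, u2, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        out = fs.scatter_hg(d, g, u1, u2)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)


class TestFresnel:
    def test_matched_indices_transmit(self):
        R, ct = fs.fresnel(1.4, 1.4, 0.7)
        assert R == 0.0 and ct == 0.7

    def test_normal_incidence_closed_form(self):
        R, _ = fs.fresnel(1.0, 1.5, 1.0)
        assert R == pytest.approx(((1.0 - 1.5) / (1.0 + 1.5)) ** 2)

    def test_total_internal_reflection(self):
        R, _ = fs.fresnel(1.5, 1.0, math.cos(math.radians(60.0)))
        assert R == 1.0

    @given(st.floats(1.0, 2.0), st.floats(1.0, 2.0), st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reflectance_is_probability(self, n1, n2, ci):
        R, _ = fs.fresnel(n1, n2, ci)
        assert 0.0 <= R <= 1.0


class TestRoulette:
    def _packet(self, w):
        return PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=w)

    def test_above_threshold_unchanged(self):
        p = fs.roulette(self._packet(0.5), 1e-4, 10.0, 0.999)
        assert p.weight == 0.5 and p.alive

    def test_survivor_weight_multiplied_by_m(self):
        p = fs.roulette(self._packet(1e-5), 1e-4, 10.0, 0.05)
        assert p.alive and p.weight == pytest.approx(1e-4)

    def test_loser_terminated(self):
        p = fs.roulette(self._packet(1e-5), 1e-4, 10.0, 0.95)
        assert not p.alive

    def test_expected_weight_preserved(self):
        rng = np.random.default_rng(4)
        n = 1_000_000
        w0 = 1e-5
        survived = rng.random(n) * 10.0 < 1.0
        after = survived * w0 * 10.0
        se = after.std() / math.sqrt(n)
        assert abs(after.mean() - w0) < 3 * se


class TestTraverse:
    def _props(self, entries):
        """entries: {label: (mu_a, mu_s, g, n)} -> kernel-style arrays."""
        out = {f: np.zeros(16) for f in ("mu_a", "mu_s", "g", "n")}
        out["n"][:] = 1.0
        for lab, (ma, ms, g, n) in entries.items():
            out["mu_a"][lab] = ma
            out["mu_s"][lab] = ms
            out["g"][lab] = g
            out["n"][lab] = n
        return out

    def test_homogeneous_interaction_at_step_over_mut(self):
        vol = slab_volume((4, 4, 50), pitch=1.0)
        props = self._props({10: (0.5, 1.5, 0.0, 1.0)})  # mu_t = 2
        p = PhotonPacket(np.array([2.0, 2.0, 0.0]), np.array([0.0, 0.0, 1.0]), voxel=(2, 2, 0))
        ev = traverse(p, vol, props, step=3.0)
        assert ev.kind == "interaction"
        assert p.position[2] == pytest.approx(1.5)  # 3.0 / 2

    def test_two_voxel_heterogeneous_arithmetic(self):
        """First voxel costs 1.0 of the step; the remainder (0.5) is spent
        in a voxel with doubled attenuation, i.e. a quarter of the
        first-voxel free path."""
        lab = np.zeros((1, 1, 2), dtype=np.int16)
        lab[0, 0, 0] = 1
        lab[0, 0, 1] = 2
        vol = fs.TissueLabelVolume(lab, 1.0)
        props = self._props({1: (0.0, 1.0, 0.0, 1.0), 2: (0.0, 2.0, 0.0, 1.0)})
        p = PhotonPacket(np.array([0.5, 0.5, 0.0]), np.array([0.0, 0.0, 1.0]), voxel=(0, 0, 0))
        ev = traverse(p, vol, props, step=1.5)
        assert ev.kind == "interaction"
        assert p.position[2] == pytest.approx(1.25)  # 1 mm + 0.5/2 mm
        assert p.voxel == (0, 0, 1)

    def test_mirror_reflection_at_lateral_limit(self):
        vol = slab_volume((4, 4, 4), pitch=1.0)
        d = np.array([0.0, 0.6, 0.8])
        p = PhotonPacket(np.array([2.0, 3.5, 1.0]), d, voxel=(2, 3, 1))
        props = self._props({10: (0.0, 0.0, 0.0, 1.0)})
        ev = traverse(p, vol, props, step=10.0)
        assert ev.kind == "mirror"
        assert np.allclose(p.direction, [0.0, -0.6, 0.8])

    def test_index_mismatch_face_reported(self):
        lab = np.zeros((1, 1, 2), dtype=np.int16)
        lab[0, 0, 0] = 1
        lab[0, 0, 1] = 2
        vol = fs.TissueLabelVolume(lab, 1.0)
        props = self._props({1: (0.0, 0.1, 0.0, 1.3), 2: (0.0, 0.1, 0.0, 1.5)})
        p = PhotonPacket(np.array([0.5, 0.5, 0.0]), np.array([0.0, 0.0, 1.0]), voxel=(0, 0, 0))
        ev = traverse(p, vol, props, step=5.0)
        assert ev.kind == "face"
        assert (ev.n_in, ev.n_out) == (1.3, 1.5)


class TestAbsorbDrop:
    def test_drop_fraction_is_mua_over_mut(self):
        vol = slab_volume((2, 2, 40), pitch=1.0)
        sp = fs.uniform_spectra({10: OpticalProperties(1.0, 1.0, 0.0, 1.0)})
        img = fs.run_simulation(
            vol, sp, fs.SimulationConfig(n_photons=2000, seed=9, record_absorption=True)
        )
        # mu_a = mu_s: exactly half the weight is deposited per interaction;
        # the first interaction alone deposits >= 0.5 * (1 - R - T) of what
        # remains, and the recorded grid must integrate to the scalar total
        assert img.absorbed is not None
        assert img.absorbed.sum() == pytest.approx(img.total_absorbed, rel=1e-12)

    def test_energy_audit_closes(self):
        vol = slab_volume((8, 8, 20))
        sp = fs.uniform_spectra({10: OpticalProperties(0.5, 2.0, 0.8, 1.4)})
        img = fs.run_simulation(
            vol, sp, fs.SimulationConfig(n_photons=50_000, seed=5, record_absorption=True)
        )
        total = img.total_reflectance + img.total_transmittance + img.total_absorbed
        assert total == pytest.approx(1.0, rel=1e-3)


class TestRunSimulation:
    def test_all_ambient_grid_transmits_everything(self):
        vol = fs.TissueLabelVolume(np.zeros((4, 4, 10), dtype=np.int16), 1.0)
        sp = fs.uniform_spectra({10: OpticalProperties(1.0, 0.0, 0.0, 1.0)})
        img = fs.run_simulation(vol, sp, fs.SimulationConfig(n_photons=5000, seed=1))
        assert img.total_transmittance == 1.0
        assert img.total_reflectance == 0.0

    def test_images_non_negative_and_totals_in_unit_interval(self, nir_spectra, small_phantom):
        thin = fs.scale_geometry(small_phantom, (0.5, 0.25, 0.5))
        img = fs.run_simulation(thin, nir_spectra, fs.SimulationConfig(n_photons=5000, seed=3))
        assert (img.reflectance >= 0).all() and (img.transmittance >= 0).all()
        assert 0.0 <= img.total_reflectance <= 1.0
        assert 0.0 <= img.total_transmittance <= 1.0

    def test_seed_determinism_bit_identical(self):
        vol = slab_volume((6, 6, 5))
        sp = fs.uniform_spectra({10: OpticalProperties(0.5, 2.0, 0.8, 1.4)})
        cfg = fs.SimulationConfig(n_photons=20_000, seed=7)
        a = fs.run_simulation(vol, sp, cfg)
        b = fs.run_simulation(vol, sp, cfg)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.transmittance, b.transmittance)

    def test_mirror_boundaries_make_lateral_size_irrelevant(self):
        """A homogeneous slab with mirror sides behaves as laterally
        infinite: totals agree across lateral grid sizes within MC noise."""
        sp = fs.uniform_spectra({10: OpticalProperties(0.5, 5.0, 0.9, 1.4)})
        n = 100_000
        a = fs.run_simulation(slab_volume((4, 4, 10)), sp, fs.SimulationConfig(n_photons=n, seed=11))
        b = fs.run_simulation(slab_volume((16, 16, 10)), sp, fs.SimulationConfig(n_photons=n, seed=12))
        for ta, tb in ((a.total_transmittance, b.total_transmittance), (a.total_reflectance, b.total_reflectance)):
            se = math.sqrt(ta * (1 - ta) / n + tb * (1 - tb) / n)
            assert abs(ta - tb) < 3 * se

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            fs.SimulationConfig(n_photons=0)

    def test_missing_property_rows_rejected(self):
        vol = slab_volume((2, 2, 2), label=10)
        sp = fs.uniform_spectra({1: OpticalProperties(0.1, 1.0, 0.5, 1.4)})
        with pytest.raises(KeyError):
            fs.run_simulation(vol, sp, fs.SimulationConfig(n_photons=10, seed=0))


class TestSpectralSweep:
    def test_degenerate_sweep_matches_single_run(self):
        vol = slab_volume((4, 4, 5))
        sp = fs.uniform_spectra({10: OpticalProperties(0.5, 2.0, 0.8, 1.4)})
        cfg = fs.SimulationConfig(n_photons=5000, seed=13, wavelength_nm=700.0)
        single = fs.run_simulation(vol, sp, cfg)
        stack = fs.spectral_sweep(vol, sp, [700.0], cfg)
        assert np.array_equal(stack.transmittance[0], single.transmittance)
        assert np.array_equal(stack.reflectance[0], single.reflectance)

    def test_default_grid_has_71_wavelengths(self):
        assert fs.default_wavelength_grid().size == 71

    def test_stack_dims(self):
        vol = slab_volume((4, 6, 3))
        sp = fs.uniform_spectra({10: OpticalProperties(0.5, 2.0, 0.8, 1.4)})
        stack = fs.spectral_sweep(vol, sp, [500.0, 600.0, 700.0], fs.SimulationConfig(n_photons=500, seed=2))
        assert stack.transmittance.shape == (3, 4, 6)
        assert stack.wavelengths.shape == (3,)
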