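"""Forward-model unit tests: basis orthonormality, field superposition
against brute-force oracles, power-coupling conservation, dose response,
camera model, and dataset generation protocol."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specklequant import speckle_sim as sim
from specklequant.config import build_render_config, load_config


def brute_force_field(modes, basis):
    """Element-wise loop evaluation of A = sum_m a_m psi_m exp(j phi_m)."""
    h, w = basis.grid.shape
    out = np.zeros((h, w), dtype=complex)
    for m in range(modes.M):
        out += modes.amplitudes[m] * basis.profiles[m] * np.exp(1j * modes.phases[m])
    return out


def brute_force_intensity(modes, basis):
    """Direct double sum: I = sum_m sum_n a_m a_n psi_m psi_n exp(j(phi_m - phi_n))."""
    h, w = basis.grid.shape
    out = np.zeros((h, w), dtype=complex)
    for m in range(modes.M):
        for n in range(modes.M):
            out += (
                modes.amplitudes[m]
                * modes.amplitudes[n]
                * basis.profiles[m]
                * basis.profiles[n]
                * np.exp(1j * (modes.phases[m] - modes.phases[n]))
            )
    assert np.max(np.abs(out.imag)) < 1e-10
    return out.real


class TestModeBasis:
    def test_single_mode_unit_norm(self, small_grid):
        basis = sim.build_mode_basis(1, small_grid, seed=0)
        assert np.isclose(np.sum(basis.profiles[0] ** 2), 1.0, atol=1e-12)

    @pytest.mark.parametrize("kind", ["smooth", "cosine"])
    def test_gram_matrix_is_identity(self, small_grid, kind):
        basis = sim.build_mode_basis(8, small_grid, seed=3, kind=kind)
        gram = basis.gram()
        assert np.max(np.abs(gram - np.eye(8))) < 1e-8

    def test_deterministic_given_seed(self, small_grid):
        a = sim.build_mode_basis(4, small_grid, seed=5)
        b = sim.build_mode_basis(4, small_grid, seed=5)
        np.testing.assert_array_equal(a.profiles, b.profiles)

    def test_infeasible_basis_raises(self):
        grid = sim.SimulationGrid(width=2, height=2)
        with pytest.raises(ValueError, match="infeasible"):
            sim.build_mode_basis(5, grid, seed=0)


class TestSynthesizeField:
    def test_single_mode_returns_profile(self, small_grid):
        basis = sim.build_mode_basis(1, small_grid, seed=1)
        state = sim.ModeState([1.0], [0.0])
        field = sim.synthesize_field(state, basis)
        np.testing.assert_allclose(field.real, basis.profiles[0], atol=1e-15)

    def test_destructive_interference(self, small_grid):
        # two modes sharing a profile, pi out of phase, cancel exactly
        base = sim.build_mode_basis(1, small_grid, seed=1)
        profiles = np.stack([base.profiles[0], base.profiles[0]])
        basis = sim.ModeBasis(profiles=profiles, grid=small_grid)
        state = sim.ModeState([1.0, 1.0], [0.0, np.pi])
        field = sim.synthesize_field(state, basis)
        assert np.max(np.abs(field)) < 1e-12

    def test_matches_bruteforce_loop(self, small_basis, rng):
        basis5 = sim.ModeBasis(profiles=small_basis.profiles[:5], grid=small_basis.grid)
        state = sim.init_mode_state(5, seed=9)
        field = sim.synthesize_field(state, basis5)
        expected = brute_force_field(state, basis5)
        np.testing.assert_allclose(field, expected, rtol=1e-12)

    def test_size_mismatch_raises(self, small_basis):
        with pytest.raises(ValueError, match="does not match"):
            sim.synthesize_field(sim.init_mode_state(3, seed=0), small_basis)


class TestIntensity:
    def test_single_mode_intensity(self, small_grid):
        basis = sim.build_mode_basis(1, small_grid, seed=1)
        state = sim.ModeState([1.0], [0.3])
        inten = sim.field_to_intensity(sim.synthesize_field(state, basis))
        np.testing.assert_allclose(inten, basis.profiles[0] ** 2, atol=1e-15)

    @pytest.mark.parametrize("M", [5, 10])
    def test_equals_double_sum(self, small_grid, M):
        basis = sim.build_mode_basis(M, small_grid, seed=M)
        state = sim.init_mode_state(M, seed=M + 1)
        inten = sim.field_to_intensity(sim.synthesize_field(state, basis))
        expected = brute_force_intensity(state, basis)
        scale = np.max(np.abs(expected))
        np.testing.assert_allclose(inten, expected, rtol=0, atol=1e-10 * scale)

    def test_nonfinite_field_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            sim.field_to_intensity(np.array([[np.nan + 0j]]))


class TestCouplePowers:
    def test_equal_powers_zero_flow(self):
        state = sim.ModeState(np.full(4, 0.5), np.zeros(4))
        h = sim.build_coupling_matrix(4, 0.3, seed=1)
        np.testing.assert_allclose(sim.couple_powers(state, h), 0.0, atol=1e-15)

    def test_zero_coupling_zero_flow(self):
        state = sim.init_mode_state(4, seed=2)
        np.testing.assert_array_equal(
            sim.couple_powers(state, np.zeros((4, 4))), np.zeros(4)
        )

    def test_two_mode_closed_form(self):
        # p=(1,0), h12=0.1: relax convention drains the loaded mode
        state = sim.ModeState([1.0, 0.0], [0.0, 0.0])
        h = np.array([[0.0, 0.1], [0.1, 0.0]])
        dP = sim.couple_powers(state, h, gain=1.0, convention="relax")
        np.testing.assert_allclose(dP, [-0.1, 0.1], atol=1e-15)
        dP_printed = sim.couple_powers(state, h, gain=1.0, convention="printed")
        np.testing.assert_allclose(dP_printed, [0.1, -0.1], atol=1e-15)

    def test_asymmetric_matrix_rejected(self):
        state = sim.init_mode_state(3, seed=0)
        h = np.array([[0, 0.1, 0], [0.2, 0, 0], [0, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            sim.couple_powers(state, h)

    @settings(deadline=None, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        convention=st.sampled_from(["relax", "printed"]),
        m=st.integers(2, 12),
    )
    def test_energy_conservation_property(self, seed, convention, m):
        """sum_m dP_m = 0 under both sign conventions: h symmetric,
        (p_m - p_n) antisymmetric."""
        state = sim.init_mode_state(m, seed=seed)
        h = sim.build_coupling_matrix(m, 0.5, seed=seed + 1)
        dP = sim.couple_powers(state, h, gain=1.3, convention=convention)
        assert abs(dP.sum()) < 1e-12


class TestApplyConcentration:
    @pytest.fixture()
    def dose(self):
        return sim.DoseResponseModel(
            response_max=0.8,
            half_sat_K=100.0,
            hill_h=1.0,
            mode_sensitivities=np.linspace(0.3, 1.5, 6),
            coupling_scale=0.2,
        )

    def test_zero_concentration_is_identity(self, dose):
        state = sim.init_mode_state(6, seed=4)
        h = sim.build_coupling_matrix(6, 0.1, seed=5)
        out = sim.apply_concentration(state, dose, 0.0, h=h)
        np.testing.assert_array_equal(out.amplitudes, state.amplitudes)
        np.testing.assert_array_equal(out.phases, state.phases)

    def test_half_saturation_identity(self, dose):
        assert np.isclose(dose.response(100.0), 0.4)

    def test_monotone_response(self, dose):
        assert dose.response(5.0) < dose.response(50.0)
        c = np.logspace(-2, 4, 200)
        r = dose.response(c)
        assert np.all(np.diff(r) > 0)

    def test_powers_stay_normalized(self, dose):
        state = sim.init_mode_state(6, seed=4)
        h = sim.build_coupling_matrix(6, 0.3, seed=5)
        for c in (1.0, 30.0, 1000.0):
            out = sim.apply_concentration(state, dose, c, h=h)
            assert abs(out.powers.sum() - 1.0) < 1e-12

    def test_negative_concentration_rejected(self, dose):
        with pytest.raises(ValueError, match="non-negative"):
            sim.apply_concentration(sim.init_mode_state(6, seed=0), dose, -1.0)


class TestCameraNoise:
    def test_identity_when_noise_off(self):
        cam = sim.CameraModel(shot_noise=False, read_noise_sd=0.0)
        img = np.arange(12, dtype=float).reshape(3, 4) * 100
        out = sim.add_camera_noise(img, cam, seed=0)
        np.testing.assert_array_equal(out, img.astype(np.uint16))

    def test_output_within_dynamic_range(self):
        cam = sim.CameraModel(bit_depth=12, shot_noise=True, read_noise_sd=50.0)
        img = np.full((32, 32), 6000.0)
        out = sim.add_camera_noise(img, cam, seed=1)
        assert out.min() >= 0 and out.max() <= 2**12 - 1

    def test_read_noise_unbiased(self):
        # Monte-Carlo: sample mean of a constant image stays within 3 SEM
        cam = sim.CameraModel(shot_noise=False, read_noise_sd=2.0)
        const = 500.0
        out = sim.add_camera_noise(np.full((100, 100), const), cam, seed=3)
        sem = 2.0 / np.sqrt(out.size)
        # quantization adds variance but no bias at this amplitude
        assert abs(out.mean() - const) < 3 * np.sqrt(sem**2 + (1 / 12) / out.size) + 0.05


class TestRenderAndDataset:
    def test_render_deterministic(self, tiny_config):
        rc = build_render_config(tiny_config)
        a = sim.render_specklegram(30.0, rc, seed=77)
        b = sim.render_specklegram(30.0, rc, seed=77)
        np.testing.assert_array_equal(a, b)

    def test_noise_free_render_is_pure_composition(self, tiny_config):
        rc = build_render_config(tiny_config)
        img = sim.render_specklegram(10.0, rc, seed=5, noise=False)
        state = sim.apply_concentration(
            rc.baseline, rc.dose, 10.0, h=rc.coupling, convention=rc.convention
        )
        expected = sim.field_to_intensity(sim.synthesize_field(state, rc.basis))
        expected *= rc.grid.npixels * rc.camera.gain_counts
        np.testing.assert_allclose(img, expected, rtol=1e-12)

    def test_concentration_separability(self, tiny_config):
        """Same fiber at 1 vs 1000 ng/mL decorrelates more than two
        independent-noise renders at 1 ng/mL."""
        from specklequant.zncc import zncc

        rc = build_render_config(tiny_config)
        low_a = sim.render_specklegram(1.0, rc, seed=1).astype(float)
        low_b = sim.render_specklegram(1.0, rc, seed=2).astype(float)
        high = sim.render_specklegram(1000.0, rc, seed=1).astype(float)
        assert zncc(low_a, high) < zncc(low_a, low_b)

    def test_dataset_counts_and_split(self, tiny_config):
        manifest, images = sim.generate_dataset(
            build_render_config(tiny_config),
            seed=3,
            panel=(1.0, 10.0, 100.0),
            per_class=8,
            split=(0.5, 0.25, 0.25),
        )
        assert len(manifest) == 24 and len(images) == 24
        counts = manifest.groupby(["concentration_ng_per_ml", "split"]).size()
        for c in (1.0, 10.0, 100.0):
            assert counts[c]["train"] == 4
            assert counts[c]["validation"] == 2
            assert counts[c]["test"] == 2

    def test_dataset_bit_identical_regeneration(self, tiny_config):
        rc = build_render_config(tiny_config)
        hashes = []
        for _ in range(2):
            manifest, images = sim.generate_dataset(
                rc, seed=9, panel=(1.0, 50.0), per_class=4
            )
            digest = hashlib.sha256(images.tobytes())
            digest.update(manifest.to_csv(index=False).encode())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]

    def test_png_roundtrip(self, tiny_config, tmp_path):
        import imageio.v3 as iio

        rc = build_render_config(tiny_config)
        manifest, images = sim.generate_dataset(
            rc, seed=2, panel=(1.0, 100.0), per_class=4, out_dir=tmp_path
        )
        stored = iio.imread(tmp_path / manifest["path"].iloc[0])
        np.testing.assert_array_equal(stored, images[0])
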