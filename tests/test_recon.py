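import numpy as np
import pytest

from epinav.geometry import Grid3D, RigidTransform, resampler_matrix
from epinav.navigator import FieldState
from epinav.phantom import (
    PhantomSpec,
    make_coil_sensitivities,
    make_field_trace,
    make_motion_trace,
    make_phantom,
)
from epinav.recon import (
    EncodingState,
    EPIOperator,
    KSpaceData,
    forward_model,
    nrmse,
    reconstruct_series,
    reconstruct_volume,
    simulate_kspace,
    states_from_traces,
)
from epinav.sampling import build_caipi_pattern


def _centered_dft3(x):
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


@pytest.fixture(scope="module")
def recon_fixture():
    grid = Grid3D.centered((24, 24, 24), (4.0, 4.0, 4.0))
    img, mask = make_phantom(PhantomSpec(grid, 3, seed=1))
    coils = make_coil_sensitivities(grid, 16, seed=2).maps
    pattern = build_caipi_pattern(
        (24, 24, 24), 3, 4, 1, n_interleaves=2, echo_spacing=5e-4, te=0.021, tr=0.039
    )
    return grid, img, mask, coils, pattern


def _random_state(pattern, rng, motion=True, field=True):
    n = pattern.n_shots
    transforms = [
        RigidTransform(*rng.uniform(-2, 2, 3), *rng.uniform(-2, 2, 3))
        if motion
        else RigidTransform.identity()
        for _ in range(n)
    ]
    fields = [
        FieldState(*rng.uniform(-4, 4, 1), *rng.uniform(-0.02, 0.02, 3))
        if field
        else FieldState()
        for _ in range(n)
    ]
    return EncodingState(transforms, fields)


class TestForwardModel:
    def test_identity_full_sampling_is_fft(self, rng):
        grid = Grid3D.centered((12, 10, 8), (4.0, 4.0, 4.0))
        x = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        pattern = build_caipi_pattern((12, 10, 8), 1, 1, 0)
        coils = np.ones((1,) + tuple(grid.shape), complex)
        data = forward_model(x, coils, None, pattern, grid)
        K = _centered_dft3(x)
        full = np.zeros_like(K)
        full[:, pattern.ky_index, pattern.kz_index] = np.moveaxis(
            data.samples[0], 1, 0
        )
        assert np.abs(full - K).max() < 1e-10 * np.abs(K).max()

    def test_translation_is_linear_phase(self, rng):
        # Fourier shift theorem, checked per sample for an integer shift
        grid = Grid3D.centered((12, 10, 8), (2.0, 2.0, 2.0))
        x = np.zeros(grid.shape)
        x[3:7, 2:8, 2:6] = rng.normal(size=(4, 6, 4))  # support clear of edges
        pattern = build_caipi_pattern((12, 10, 8), 1, 1, 0)
        coils = np.ones((1,) + tuple(grid.shape), complex)
        shift_vox = 2
        t = RigidTransform(tx=shift_vox * grid.voxel_size[0])
        state = EncodingState([t] * max(pattern.n_shots, 1), [FieldState()] * max(pattern.n_shots, 1))
        moved = forward_model(x, coils, state, pattern, grid)
        ref = forward_model(x, coils, None, pattern, grid)
        kx = np.arange(12) - 6
        expected_phase = np.exp(-2j * np.pi * kx * shift_vox / 12)
        ratio = moved.samples[0] / np.where(
            np.abs(ref.samples[0]) > 1e-9, ref.samples[0], 1.0
        )
        sel = np.abs(ref.samples[0]) > 1e-6 * np.abs(ref.samples[0]).max()
        err = np.abs(ratio - expected_phase[None, :])[sel]
        assert err.max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjoint_dot_product(self, recon_fixture, seed):
        grid, img, mask, coils, pattern = recon_fixture
        rng = np.random.default_rng(seed)
        state = _random_state(pattern, rng)
        op = EPIOperator(coils[:4], grid, pattern, state)
        x = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        y = rng.normal(size=op.sample_shape) + 1j * rng.normal(size=op.sample_shape)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        denom = np.linalg.norm(op.forward(x)) * np.linalg.norm(y)
        assert abs(lhs - rhs) / denom < 1e-6

    def test_missing_states_rejected(self, recon_fixture):
        grid, img, mask, coils, pattern = recon_fixture
        bad = EncodingState([RigidTransform.identity()], [FieldState()])
        with pytest.raises(ValueError):
            EPIOperator(coils, grid, pattern, bad)


class TestReconstructVolume:
    def test_full_sampling_matches_inverse_fft(self, rng):
        grid = Grid3D.centered((12, 10, 8), (4.0, 4.0, 4.0))
        x = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        pattern = build_caipi_pattern((12, 10, 8), 1, 1, 0)
        coils = np.ones((1,) + tuple(grid.shape), complex)
        data = forward_model(x, coils, None, pattern, grid)
        img, rec = reconstruct_volume(data, coils, None, grid)
        assert nrmse(img, x) < 1e-5

    def test_12fold_caipi_recovery(self, recon_fixture):
        grid, img, mask, coils, pattern = recon_fixture
        data = forward_model(img, coils, None, pattern, grid)
        est, rec = reconstruct_volume(data, coils, None, grid)
        assert nrmse(np.abs(est)[mask], img[mask]) < 0.05

    def test_cost_monotone_nonincreasing(self, recon_fixture, rng):
        grid, img, mask, coils, pattern = recon_fixture
        state = _random_state(pattern, rng)
        data = simulate_kspace(
            img, coils, pattern, state, grid, noise_sd=0.01, rng=rng
        )
        _, rec = reconstruct_volume(data, coils, state, grid, max_iter=25)
        costs = np.asarray(rec.cost)
        assert np.all(np.diff(costs) <= 1e-9 * abs(costs[0]))

    def test_corrected_beats_uncorrected_on_step_motion(self, recon_fixture):
        grid, img, mask, coils, pattern = recon_fixture
        n = pattern.n_shots
        step = RigidTransform(2.0, 0.0, 0.0, 0.0, 0.0, 2.0)
        states = EncodingState(
            [RigidTransform.identity()] * (n // 2) + [step] * (n - n // 2),
            [FieldState()] * n,
        )
        data = forward_model(img, coils, states, pattern, grid)
        corr, _ = reconstruct_volume(data, coils, states, grid)
        unc, _ = reconstruct_volume(data, coils, None, grid)
        e_corr = nrmse(np.abs(corr)[mask], img[mask])
        e_unc = nrmse(np.abs(unc)[mask], img[mask])
        assert e_corr < e_unc

    def test_truth_state_recon_approaches_motion_free(self, recon_fixture, rng):
        grid, img, mask, coils, pattern = recon_fixture
        state = _random_state(pattern, rng, field=False)
        data = forward_model(img, coils, state, pattern, grid)
        data0 = forward_model(img, coils, None, pattern, grid)
        est, _ = reconstruct_volume(data, coils, state, grid)
        est0, _ = reconstruct_volume(data0, coils, None, grid)
        e = nrmse(np.abs(est)[mask], img[mask])
        e0 = nrmse(np.abs(est0)[mask], img[mask])
        assert e < 2 * e0 + 0.02


class TestReconstructSeries:
    def _series_setup(self, n_volumes=2):
        grid = Grid3D.centered((20, 16, 16), (6.0, 6.0, 6.0))
        img, mask = make_phantom(PhantomSpec(grid, 3, seed=4))
        coils = make_coil_sensitivities(grid, 8, seed=5).maps
        pattern = build_caipi_pattern(
            (20, 16, 16), 2, 2, 1, n_interleaves=2,
            echo_spacing=5e-4, te=0.021, tr=0.039,
        )
        volume_tr = pattern.n_shots * 0.039
        motion = make_motion_trace(
            8, 1.5, 1.5, "smooth_drift", seed=6, frame_interval=0.234
        )
        field = make_field_trace(8, 3.0, 0.01, seed=7, frame_interval=0.234)
        run = []
        rng = np.random.default_rng(8)
        for v in range(n_volumes):
            state = states_from_traces(
                pattern, motion, field, 0.234, volume_start_s=v * volume_tr
            )
            run.append(
                simulate_kspace(img, coils, pattern, state, grid, 0.0, rng)
            )
        return grid, img, mask, coils, pattern, motion, field, run, volume_tr

    def test_zero_traces_modes_identical(self):
        grid, img, mask, coils, pattern, *_ = self._series_setup()
        zero_motion = make_motion_trace(8, 0.0, 0.0, seed=0, frame_interval=0.234)
        zero_field = make_field_trace(8, 0.0, 0.0, seed=0, frame_interval=0.234)
        run = [simulate_kspace(img, coils, pattern, None, grid)]
        a = reconstruct_series(
            run, coils, zero_motion, zero_field, "corrected", grid,
            volume_tr=1.0, frame_interval=0.234, max_iter=5,
        )
        b = reconstruct_series(
            run, coils, zero_motion, zero_field, "uncorrected", grid,
            volume_tr=1.0, frame_interval=0.234, max_iter=5,
        )
        assert np.array_equal(a.data, b.data)

    def test_volume_count_preserved_and_corrected_closer(self):
        (grid, img, mask, coils, pattern, motion, field, run, volume_tr) = (
            self._series_setup(2)
        )
        corr = reconstruct_series(
            run, coils, motion, field, "corrected", grid,
            volume_tr=volume_tr, frame_interval=0.234, max_iter=20,
        )
        unc = reconstruct_series(
            run, coils, motion, field, "uncorrected", grid,
            volume_tr=volume_tr, frame_interval=0.234, max_iter=20,
        )
        assert corr.n_volumes == 2 and unc.n_volumes == 2
        e_corr = np.mean([nrmse(v[mask], img[mask]) for v in corr.data])
        e_unc = np.mean([nrmse(v[mask], img[mask]) for v in unc.data])
        assert e_corr < e_unc

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_series([], np.ones((1, 4, 4, 4)), mode="banana")


class TestStatesFromTraces:
    def test_nearest_frame_lookup(self):
        pattern = build_caipi_pattern(
            (8, 8, 8), 1, 2, 0, n_interleaves=1, echo_spacing=1e-4, te=0.02, tr=0.1
        )
        motion = make_motion_trace(4, 1.0, 1.0, "step", seed=1, frame_interval=0.2)
        field = make_field_trace(4, 1.0, 0.01, seed=2, frame_interval=0.2)
        state = states_from_traces(pattern, motion, field, 0.2)
        assert len(state) == pattern.n_shots
        # first shot is near t=0 -> frame 0 (identity by construction)
        assert state.transforms[0].is_identity()

    def test_linear_interpolation_between_frames(self):
        pattern = build_caipi_pattern(
            (8, 8, 8), 1, 2, 0, n_interleaves=1, echo_spacing=1e-4, te=0.0, tr=0.1
        )
        frames = [RigidTransform.identity(), RigidTransform(tx=1.0)]
        from epinav.phantom import FieldTrace

        field = FieldTrace(np.array([0.0, 2.0]), np.zeros(2), np.zeros(2), np.zeros(2))
        state = states_from_traces(
            pattern, frames, field, frame_interval=0.4, interp="linear"
        )
        # shot times are 0.05, 0.15, 0.25, 0.35 -> fractions of 0.4
        t_shot = [np.mean(pattern.time_s[pattern.shot_id == s]) for s in range(4)]
        for s, ts in enumerate(t_shot):
            w = min(ts / 0.4, 1.0)
            assert state.transforms[s].tx == pytest.approx(w * 1.0, abs=1e-9)
            assert state.fields[s].g0 == pytest.approx(w * 2.0, abs=1e-9)
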