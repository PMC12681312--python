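import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epinav import metrics as M


def _series(data):
    return np.asarray(data, float)


class TestTsnr:
    def test_matches_brute_force(self, rng):
        data = rng.normal(10, 2, size=(30, 4, 4, 4))
        result = M.tsnr(data)
        i, j, k = 1, 2, 3
        ts = data[:, i, j, k]
        assert result.values[i, j, k] == pytest.approx(ts.mean() / ts.std())

    def test_constant_series_flagged_zero(self):
        data = np.full((10, 2, 2, 2), 7.0)
        result = M.tsnr(data)
        assert np.all(result.values == 0)
        assert result.flagged.all()

    def test_known_ratio(self):
        t = np.arange(16)
        voxel = 10 + 2 * np.sqrt(2) * np.cos(2 * np.pi * t / 16)  # SD = 2
        data = np.tile(voxel[:, None, None, None], (1, 2, 2, 2))
        result = M.tsnr(data)
        assert result.values[0, 0, 0] == pytest.approx(5.0, rel=1e-12)


class TestFramewiseDisplacement:
    def test_constant_parameters_zero(self):
        fd = M.framewise_displacement(np.ones((5, 6)))
        assert np.allclose(fd, 0)

    def test_translation_step(self):
        p = np.zeros((4, 6))
        p[2:, 0] = 0.3
        fd = M.framewise_displacement(p)
        assert fd[2] == pytest.approx(0.3)
        assert fd[0] == 0.0 and fd[1] == 0.0 and fd[3] == 0.0

    def test_rotation_radius_conversion(self):
        p = np.zeros((3, 6))
        p[1:, 3] = 1.0  # 1 degree about x
        fd = M.framewise_displacement(p, radius_mm=50.0)
        assert fd[1] == pytest.approx(50 * np.pi / 180, rel=1e-9)


class TestDvars:
    def test_constant_series_zero(self):
        data = np.full((8, 3, 3, 3), 5.0)
        mask = np.ones((3, 3, 3), bool)
        assert np.allclose(M.dvars(data, mask, standardize=False), 0)

    def test_uniform_step_equals_amplitude(self):
        data = np.zeros((6, 2, 2, 2))
        data[3:] = 1.7
        mask = np.ones((2, 2, 2), bool)
        raw = M.dvars(data, mask, standardize=False)
        assert raw[3] == pytest.approx(1.7)

    def test_standardized_median_is_one(self, rng):
        data = rng.normal(size=(40, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        std = M.dvars(data, mask, standardize=True)
        assert np.median(std[1:]) == pytest.approx(1.0)


class TestOutlierFlags:
    @pytest.mark.parametrize(
        "fd,dv,expected",
        [(0.6, 1.0, True), (0.4, 1.6, True), (0.4, 1.0, False), (0.5, 1.5, False)],
    )
    def test_thresholds(self, fd, dv, expected):
        flags = M.flag_motion_outliers([0.0, fd], [0.0, dv])
        assert bool(flags[1]) is expected


class TestConfoundExpansion:
    def _base(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 9)), columns=list(M.BASE_9P)
        )

    def test_36_columns(self):
        out = M.expand_confounds_36p(self._base())
        assert out.shape[1] == 36

    def test_24p_from_motion_only(self):
        base = self._base()[list(M.BASE_9P[:6])]
        out = M.expand_confounds(base)
        assert out.shape[1] == 24

    def test_derivative_of_constant_is_zero(self):
        base = self._base()
        base["csf"] = 1.0
        out = M.expand_confounds_36p(base)
        assert np.allclose(out["csf_derivative1"], 0)

    def test_derivative_first_row_zero_and_squares(self):
        base = self._base()
        out = M.expand_confounds_36p(base)
        assert out["trans_x_derivative1"].iloc[0] == 0.0
        assert np.allclose(out["trans_x_power2"], base["trans_x"] ** 2)

    def test_wrong_base_count_rejected(self):
        with pytest.raises(ValueError):
            M.expand_confounds_36p(self._base().iloc[:, :5])


class TestCompCor:
    def test_rank1_data_gives_single_component(self, rng):
        t = rng.normal(size=30)
        spatial = rng.normal(size=27)
        data = (t[:, None] * spatial[None]).reshape(30, 3, 3, 3)
        mask = np.ones((3, 3, 3), bool)
        comps = M.compcor(data, mask, variant="anatomical", highpass_cutoff_s=1e9)
        assert comps.shape[1] == 1

    def test_top_voxel_count(self, rng):
        data = rng.normal(size=(20, 5, 5, 4))
        mask = np.ones((5, 5, 4), bool)
        k = int(np.ceil(0.02 * mask.sum()))
        assert k == 2
        comps = M.compcor(data, mask, variant="temporal", tr_s=2.0)
        assert comps.shape[0] == 20

    def test_variance_fraction_boundary(self, rng):
        data = rng.normal(size=(25, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        comps = M.compcor(
            data, mask, variant="anatomical", variance_fraction=0.5, tr_s=2.0,
            highpass_cutoff_s=1e9,
        )
        ts = data.reshape(25, -1)
        ts = ts - ts.mean(axis=0)
        ts = ts / ts.std(axis=0)
        s = np.linalg.svd(ts, compute_uv=False)
        energy = np.cumsum(s**2) / np.sum(s**2)
        k = comps.shape[1]
        assert energy[k - 1] >= 0.5
        if k > 1:
            assert energy[k - 2] < 0.5


class TestBandpass:
    FS = 1 / 2.34

    def test_dc_removed(self):
        data = np.full((100, 3), 50.0)
        out = M.bandpass_butterworth(data, self.FS)
        assert np.abs(out).max() < 1e-6 * 50.0

    def test_inband_gain_high(self):
        t = np.arange(300) / self.FS
        x = np.sin(2 * np.pi * 0.04 * t)
        y = M.bandpass_butterworth(x[:, None], self.FS)[:, 0]
        gain = y[100:-100].std() / x[100:-100].std()
        assert gain > 0.9

    def test_outofband_gain_low(self):
        t = np.arange(300) / self.FS
        x = np.sin(2 * np.pi * 0.2 * t)
        y = M.bandpass_butterworth(x[:, None], self.FS)[:, 0]
        gain = y[100:-100].std() / x[100:-100].std()
        assert gain < 0.1

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            M.bandpass_butterworth(np.zeros((10, 1)), fs=0.1, high=0.08)


class TestRegression:
    def test_self_regression_zero_residual(self, rng):
        x = rng.normal(size=20)
        data = np.tile(x[:, None, None, None], (1, 2, 2, 2))
        resid = M.regress_confounds(data, x)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_regressors(self, rng):
        data = rng.normal(size=(30, 3, 3, 3))
        conf = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        resid = M.regress_confounds(data, conf)
        R = resid.reshape(30, -1)
        C = conf.to_numpy()
        inner = np.abs(C.T @ R).max()
        assert inner < 1e-8 * np.linalg.norm(R) * np.linalg.norm(C)

    def test_matches_hat_matrix_on_toy(self, rng):
        y = rng.normal(size=(5, 1, 1, 1))
        c = rng.normal(size=(5, 1))
        X = np.column_stack([np.ones(5), c[:, 0]])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        expected = y[:, 0, 0, 0] - H @ y[:, 0, 0, 0]
        resid = M.regress_confounds(y, c)
        assert np.allclose(resid[:, 0, 0, 0], expected, atol=1e-10)


class TestAlff:
    FS = 1 / 2.34

    def test_constant_series_zero(self):
        data = np.full((64, 2, 2, 2), 3.0)
        result = M.alff(data, self.FS)
        assert np.all(result.values == 0)
        assert result.flagged.all()

    def test_linearity_in_amplitude(self):
        t = np.arange(128) / self.FS
        base = np.sin(2 * np.pi * 0.03 * t)
        data = np.stack([base, 2 * base], axis=1).reshape(128, 2, 1, 1)
        result = M.alff(data, self.FS)
        assert result.values[1, 0, 0] == pytest.approx(
            2 * result.values[0, 0, 0], rel=1e-9
        )

    def test_inband_beats_outofband(self):
        t = np.arange(128) / self.FS
        inband = np.sin(2 * np.pi * 0.04 * t)
        outband = np.sin(2 * np.pi * 0.18 * t)
        data = np.stack([inband, outband], axis=1).reshape(128, 2, 1, 1)
        result = M.alff(data, self.FS)
        assert result.values[0, 0, 0] > 3 * result.values[1, 0, 0]


class TestRehoKcc:
    def test_identical_series_give_w_one(self, rng):
        x = rng.normal(size=12)
        data = np.tile(x[:, None, None, None], (1, 3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        result = M.reho_kcc(data, mask)
        assert result.values[1, 1, 1] == pytest.approx(1.0)

    def test_two_reversed_series_give_w_zero(self):
        # KCC of two fully discordant rankings is 0
        x = np.arange(6, dtype=float)
        ranks = np.stack([x + 1, x[::-1] + 1])
        assert M.kcc(ranks) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_toy(self):
        from scipy.stats import rankdata

        series = np.array(
            [[1.0, 3.0, 2.0, 4.0], [2.0, 1.0, 4.0, 3.0], [1.0, 2.0, 3.0, 4.0]]
        )  # m=3 series, n=4 timepoints
        m, n = series.shape
        ranks = np.stack([rankdata(s) for s in series])
        R = ranks.sum(axis=0)
        S = np.sum((R - m * (n + 1) / 2) ** 2)
        W_expected = 12 * S / (m**2 * (n**3 - n))
        assert M.kcc(ranks) == pytest.approx(W_expected, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_kcc_bounded_on_random_input(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 6)
        n = rng.integers(3, 10)
        from scipy.stats import rankdata

        data = rng.integers(0, 5, size=(m, n)).astype(float)
        ranks = np.stack([rankdata(row) for row in data])
        ties = np.array([M._tie_term(row) for row in data])
        w = M.kcc(ranks, ties)
        assert 0.0 <= w <= 1.0 + 1e-12

    def test_scaling_invariance(self, rng):
        data = rng.normal(size=(10, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        a = M.reho_kcc(data, mask).values
        b = M.reho_kcc(5.0 * data + 2.0, mask).values
        assert np.allclose(a, b, atol=1e-12)

    def test_edge_neighbourhoods_use_actual_count(self, rng):
        data = rng.normal(size=(10, 3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        result = M.reho_kcc(data, mask)
        assert 0.0 <= result.values[0, 0, 0] <= 1.0


class TestFcMatrix:
    def test_identical_parcels_fully_correlated(self, rng):
        x = rng.normal(size=20)
        data = np.tile(x[:, None, None, None], (1, 2, 2, 1))
        labels = np.zeros((2, 2, 1), int)
        labels[0] = 1
        labels[1] = 2
        fc = M.fc_matrix(data, labels)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        data = rng.normal(size=(30, 4, 4, 2))
        labels = (rng.integers(1, 4, size=(4, 4, 2))).astype(int)
        fc = M.fc_matrix(data, labels)
        assert np.allclose(fc, fc.T, equal_nan=True)
        assert np.allclose(np.diag(fc), 1.0)

    def test_matches_brute_force_three_parcels(self, rng):
        data = rng.normal(size=(25, 3, 1, 1))
        labels = np.array([1, 2, 3]).reshape(3, 1, 1)
        fc = M.fc_matrix(data, labels)
        a, b = data[:, 0, 0, 0], data[:, 1, 0, 0]
        assert fc[0, 1] == pytest.approx(np.corrcoef(a, b)[0, 1], rel=1e-12)

    def test_compare_fc_mean_absolute_offdiag(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert M.compare_fc(a, b) == pytest.approx(0.4)
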