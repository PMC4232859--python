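"""SAM scalar beamformer: covariance, weights, source measures, virtual sensors."""

import numpy as np
import pytest

from conftest import make_epochs
from samface.beamformer import (
    Covariance,
    compute_covariance,
    evoked_measures,
    induced_measures,
    sam_weights,
    sam_weights_all,
    source_power_image,
    virtual_sensor,
)
from samface.containers import FACE, SCRAMBLED, GridSpec
from samface.forward import Dipole, HeadModel, forward_matrix, leadfield_grid, sphere_field
from samface.simulate import helmet_sensors

SFREQ = 600.0


def _identity_cov(n_ch, band=(1.0, 30.0)):
    return Covariance(
        matrix=np.eye(n_ch), band=band, window=(0.0, 1.0), n_trials=10, mu=0.0
    )


class TestComputeCovariance:
    def test_outer_product_example(self):
        """Two two-sample trials with known values give the hand-computed covariance."""
        # channels x time per trial chosen so the mean-removed outer product is easy
        tr1 = np.array([[1.0, -1.0], [2.0, -2.0]])
        tr2 = np.array([[3.0, -3.0], [-1.0, 1.0]])
        data = np.stack([tr1, tr2])
        ep = make_epochs(data, SFREQ)
        cov = compute_covariance(ep, band=(1.0, 30.0), mu=0.0, filter_data=False)
        stacked = np.concatenate([tr1, tr2], axis=1)
        stacked = stacked - stacked.mean(axis=1, keepdims=True)
        expected = stacked @ stacked.T / (stacked.shape[1] - 1)
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-12)

    def test_white_noise_cov_near_identity(self, rng):
        data = rng.standard_normal((40, 4, 500))
        ep = make_epochs(data, SFREQ)
        cov = compute_covariance(ep, band=(1.0, 30.0), mu=0.0, filter_data=False)
        np.testing.assert_allclose(cov.matrix, np.eye(4), atol=0.05)

    def test_regularization_adds_mu_mean_diag(self, rng):
        data = rng.standard_normal((10, 3, 400))
        ep = make_epochs(data, SFREQ)
        c0 = compute_covariance(ep, band=(1.0, 30.0), mu=0.0, filter_data=False)
        c1 = compute_covariance(ep, band=(1.0, 30.0), mu=0.1, filter_data=False)
        bump = 0.1 * np.mean(np.diag(c0.matrix)) * np.eye(3)
        np.testing.assert_allclose(c1.matrix, c0.matrix + bump, atol=1e-12)

    def test_window_restricts_samples(self, rng):
        data = rng.standard_normal((5, 2, 600))
        ep = make_epochs(data, SFREQ)
        full = compute_covariance(ep, band=(1.0, 30.0), mu=0.0, filter_data=False)
        half = compute_covariance(
            ep, band=(1.0, 30.0), window=(0.0, 0.4), mu=0.0, filter_data=False
        )
        assert not np.allclose(full.matrix, half.matrix)

    def test_too_few_samples_without_regularization_rejected(self, rng):
        data = rng.standard_normal((1, 10, 5))
        ep = make_epochs(data, SFREQ, labels=[FACE])
        with pytest.raises(ValueError):
            compute_covariance(ep, band=(1.0, 30.0), mu=0.0, filter_data=False)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            Covariance(
                matrix=np.array([[1.0, 0.2], [0.1, 1.0]]),
                band=(1, 30), window=(0, 1), n_trials=5, mu=0.0,
            )


class TestSamWeights:
    def test_identity_covariance_closed_form(self, rng):
        """With C = I the optimum is the smallest-eigenvalue direction of L'L
        and w = l / ||l||^2, so w'l = 1 and S = 1/||l||^2."""
        L = rng.standard_normal((12, 2))
        cov = _identity_cov(12)
        w, eta, S = sam_weights(L, cov, method="eig")
        evals, evecs = np.linalg.eigh(L.T @ L)
        expected_eta = evecs[:, 0]
        if np.sign(eta @ expected_eta) < 0:
            expected_eta = -expected_eta
        np.testing.assert_allclose(eta, expected_eta, atol=1e-10)
        l = L @ eta
        np.testing.assert_allclose(w, l / (l @ l), atol=1e-12)
        assert S == pytest.approx(1.0 / evals[0], rel=1e-10)

    def test_unit_gain(self, rng):
        L = rng.standard_normal((20, 2))
        M = rng.standard_normal((20, 20))
        cov = Covariance(
            matrix=M @ M.T + 0.5 * np.eye(20), band=(1, 30), window=(0, 1), n_trials=9, mu=0.0
        )
        for method in ("grid", "eig"):
            w, eta, S = sam_weights(L, cov, method=method)
            assert w @ (L @ eta) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_grid_matches_eigendecomposition(self, seed):
        """Dense 1-degree search agrees with the closed form to within the
        grid resolution, over random SPD covariances (10 instances per seed)."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            L = rng.standard_normal((15, 2))
            M = rng.standard_normal((15, 15))
            cov = Covariance(
                matrix=M @ M.T + 0.1 * np.eye(15),
                band=(1, 30), window=(0, 1), n_trials=9, mu=0.0,
            )
            _, eta_g, S_g = sam_weights(L, cov, method="grid", step_deg=1.0)
            _, eta_e, S_e = sam_weights(L, cov, method="eig")
            cosang = abs(float(eta_g @ eta_e))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 1.0
            assert S_g == pytest.approx(S_e, rel=5e-3)
            assert S_g <= S_e + 1e-15  # grid power cannot exceed the true optimum

    def test_bad_leadfield_shape(self):
        with pytest.raises(ValueError):
            sam_weights(np.ones((5, 3)), _identity_cov(5))

    def test_all_voxels_match_single_voxel_path(self, small_sensors, rng):
        grid = GridSpec.sphere(radius=0.04, spacing=0.02)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        lf = leadfield_grid(grid, small_sensors, head)
        M = rng.standard_normal((small_sensors.n_channels, small_sensors.n_channels))
        cov = Covariance(
            matrix=M @ M.T + np.eye(small_sensors.n_channels),
            band=(1, 30), window=(0, 1), n_trials=9, mu=0.0,
        )
        filters = sam_weights_all(lf, cov)
        for v in range(lf.n_voxels):
            if not lf.valid[v] or np.isnan(filters.power[v]):
                # invalid voxels, and valid ones with a singular (zero)
                # leadfield such as the sphere centre, carry zero weights
                assert np.all(filters.weights[v] == 0)
                assert np.isnan(filters.power[v])
                continue
            w, eta, S = sam_weights(lf.lf[v], cov)
            np.testing.assert_allclose(filters.weights[v], w, atol=1e-12)
            assert filters.power[v] == pytest.approx(S, rel=1e-12)


def _simulated_epochs(rng, sensors, src_pos, moment, signal, n_trials, noise=2e-14,
                      phase_jitter=False, sfreq=SFREQ):
    """Trials = forward-projected source timecourse + white sensor noise."""
    head = HeadModel(centres=np.zeros(3), radius=0.09)
    gain = forward_matrix(src_pos[None, :], moment[None, :], sensors, head)[:, 0]  # (n_ch,)
    n_t = len(signal)
    data = np.zeros((n_trials, sensors.n_channels, n_t))
    for t in range(n_trials):
        s = signal
        if phase_jitter:
            shift = rng.integers(0, n_t)
            s = np.roll(signal, shift)
        data[t] = gain[:, None] * s[None, :] + noise * rng.standard_normal((sensors.n_channels, n_t))
    return make_epochs(data, sfreq, labels=[FACE] * n_trials)


@pytest.fixture(scope="module")
def sensors():
    return helmet_sensors(60)


class TestSourceMeasures:
    def test_evoked_point_source_localized(self, sensors):
        """A single evoked dipole is recovered within one grid step."""
        rng = np.random.default_rng(0)
        n_t = int(1.2 * SFREQ)
        time = (np.arange(n_t) - n_t // 2) / SFREQ  # onset mid-epoch, as in make_epochs
        signal = 20e-9 * np.exp(-0.5 * ((time - 0.15) / 0.02) ** 2)
        src = np.array([0.03, -0.04, 0.01])
        moment = np.array([0.0, 0.5, 1.0])
        moment -= (moment @ src) / (src @ src) * src  # tangential
        moment /= np.linalg.norm(moment)
        ep = _simulated_epochs(rng, sensors, src, moment, signal, n_trials=30)
        grid = GridSpec.sphere(radius=0.06, spacing=0.01)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        lf = leadfield_grid(grid, sensors, head)
        cov = compute_covariance(ep, band=(1.0, 40.0), mu=0.05)
        filters = sam_weights_all(lf, cov)
        X, se = evoked_measures(filters, ep, FACE, window=(0.10, 0.20))
        X = np.where(lf.valid, X, -np.inf)
        best = lf.positions[np.argmax(X)]
        assert np.linalg.norm(best - src) <= 0.0101

    def test_induced_point_source_localized(self, sensors):
        """A non-phase-locked band-limited burst is recovered within 10 mm."""
        rng = np.random.default_rng(1)
        from samface.sensor import bandpass

        n_samp = int(1.6 * SFREQ)
        time = (np.arange(n_samp) - n_samp // 2) / SFREQ
        env = np.exp(-0.5 * ((time - 0.25) / 0.08) ** 2)
        src = np.array([0.035, -0.045, 0.005])
        moment = np.array([1.0, 0.2, 0.0])
        moment -= (moment @ src) / (src @ src) * src
        moment /= np.linalg.norm(moment)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        gain = forward_matrix(src[None, :], moment[None, :], sensors, head)[:, 0]
        n_t = len(time)
        data = np.zeros((40, sensors.n_channels, n_t))
        for t in range(40):
            carrier = bandpass(rng.standard_normal(n_t), SFREQ, 55, 85)
            carrier /= carrier.std()
            s = 10e-9 * env * carrier
            data[t] = gain[:, None] * s[None, :] + 2e-14 * rng.standard_normal(
                (sensors.n_channels, n_t)
            )
        ep = make_epochs(data, SFREQ, labels=[FACE] * 40)
        grid = GridSpec.sphere(radius=0.06, spacing=0.01)
        lf = leadfield_grid(grid, sensors, head)
        filtered = ep  # already band-limited source; filter to the band anyway
        from samface.sensor import filter_epochs

        filtered = filter_epochs(ep, 55, 85, order=4)
        cov = compute_covariance(filtered, band=(55.0, 85.0), mu=0.05, filter_data=False)
        filters = sam_weights_all(lf, cov)
        X, se = induced_measures(filters, filtered, FACE, window=(0.10, 0.40))
        X = np.where(lf.valid, X, -np.inf)
        best = lf.positions[np.argmax(X)]
        assert np.linalg.norm(best - src) <= 0.010
        # the burst is not phase-locked, so the trial average carries almost no
        # power: evoked window power at the source is far below the squared
        # induced amplitude there
        Xe, _ = evoked_measures(filters, filtered, FACE, window=(0.10, 0.40))
        v = int(np.argmax(X))
        assert Xe[v] < 0.1 * X[v] ** 2

    def test_evoked_jackknife_matches_explicit_loop(self, sensors, rng):
        """Closed-form leave-one-out sums equal a literal delete-one recomputation."""
        n_tr, n_t = 7, 240
        data = rng.standard_normal((n_tr, sensors.n_channels, n_t)) * 1e-13
        ep = make_epochs(data, SFREQ, labels=[FACE] * n_tr)
        grid = GridSpec.sphere(radius=0.03, spacing=0.02)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        lf = leadfield_grid(grid, sensors, head)
        cov = compute_covariance(ep, band=(1.0, 40.0), mu=0.1)
        filters = sam_weights_all(lf, cov)
        window, baseline = (0.05, 0.15), (-0.15, 0.0)
        X, se = evoked_measures(filters, ep, FACE, window, baseline=baseline)

        wmask = ep.time_mask(*window)
        bmask = ep.time_mask(*baseline)
        proj = np.einsum("vc,tcs->tvs", filters.weights, data)

        def measure(trials):
            avg = proj[trials].mean(axis=0)
            return (avg[:, wmask] ** 2).mean(axis=1) - (avg[:, bmask] ** 2).mean(axis=1)

        full = measure(np.arange(n_tr))
        np.testing.assert_allclose(X, full, rtol=1e-9, atol=1e-40)
        theta = np.array([
            measure(np.delete(np.arange(n_tr), i)) for i in range(n_tr)
        ])
        se_loop = np.sqrt(
            (n_tr - 1) / n_tr * ((theta - theta.mean(axis=0)) ** 2).sum(axis=0)
        )
        np.testing.assert_allclose(se, se_loop, rtol=1e-7, atol=1e-40)

    def test_source_power_scale_homogeneity(self, sensors, rng):
        """Scaling the data by k scales evoked power by k^2 and induced amplitude by k
        (with weights held fixed)."""
        data = rng.standard_normal((8, sensors.n_channels, 600)) * 1e-13
        ep1 = make_epochs(data, SFREQ, labels=[FACE] * 8)
        ep2 = make_epochs(3.0 * data, SFREQ, labels=[FACE] * 8)
        grid = GridSpec.sphere(radius=0.03, spacing=0.02)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        lf = leadfield_grid(grid, sensors, head)
        cov = compute_covariance(ep1, band=(1.0, 40.0), mu=0.1)
        filters = sam_weights_all(lf, cov)
        a1, b1 = source_power_image(filters, ep1, FACE, (0.1, 0.2), measure="evoked")
        a2, b2 = source_power_image(filters, ep2, FACE, (0.1, 0.2), measure="evoked")
        np.testing.assert_allclose(a2.flat(), 9.0 * a1.flat(), rtol=1e-9)
        i1, _ = source_power_image(filters, ep1, FACE, (0.1, 0.2), measure="induced")
        i2, _ = source_power_image(filters, ep2, FACE, (0.1, 0.2), measure="induced")
        np.testing.assert_allclose(i2.flat(), 3.0 * i1.flat(), rtol=1e-9)

    def test_zero_data_zero_measures(self, sensors):
        data = np.zeros((4, sensors.n_channels, 300))
        ep = make_epochs(data, SFREQ, labels=[FACE] * 4)
        grid = GridSpec.sphere(radius=0.03, spacing=0.02)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        lf = leadfield_grid(grid, sensors, head)
        cov = Covariance(
            matrix=np.eye(sensors.n_channels), band=(1, 30), window=(0, 1), n_trials=4, mu=0.0
        )
        filters = sam_weights_all(lf, cov)
        X, se = evoked_measures(filters, ep, FACE, (0.1, 0.2))
        np.testing.assert_array_equal(X, 0.0)
        np.testing.assert_array_equal(se, 0.0)


class TestVirtualSensor:
    def test_projection_matches_manual(self, rng):
        data = rng.standard_normal((5, 4, 50))
        ep = make_epochs(data, 100.0, labels=[FACE] * 5)
        w = rng.standard_normal(4)
        ts = virtual_sensor(w, ep, FACE)
        expected = np.tensordot(data, w, axes=([1], [0]))
        np.testing.assert_allclose(ts, expected, atol=1e-12)

    def test_polarity_flip(self):
        time = np.arange(100) / 100.0 - 0.3
        sig = -np.exp(-0.5 * ((time - 0.2) / 0.05) ** 2)
        data = np.tile(sig, (3, 1, 1))
        ep = make_epochs(data, 100.0, labels=[FACE] * 3)
        ts = virtual_sensor(np.array([1.0]), ep, FACE, twoi=(0.1, 0.3), flip_polarity=True)
        avg = ts.mean(axis=0)
        assert avg[np.argmax(np.abs(avg))] > 0

    def test_flip_requires_twoi(self, rng):
        ep = make_epochs(rng.standard_normal((2, 3, 50)), 100.0)
        with pytest.raises(ValueError):
            virtual_sensor(np.ones(3), ep, flip_polarity=True)

    def test_recovers_source_timecourse(self, rng):
        """At the true source, the virtual sensor correlates >0.95 with the truth."""
        sensors = helmet_sensors(60)
        time = np.arange(int(1.2 * SFREQ)) / SFREQ - 0.4
        signal = 20e-9 * np.exp(-0.5 * ((time - 0.15) / 0.02) ** 2) * np.sin(
            2 * np.pi * 8 * time
        )
        src = np.array([0.03, -0.04, 0.01])
        moment = np.array([0.0, 0.5, 1.0])
        moment -= (moment @ src) / (src @ src) * src
        moment /= np.linalg.norm(moment)
        ep = _simulated_epochs(rng, sensors, src, moment, signal, n_trials=20)
        head = HeadModel(centres=np.zeros(3), radius=0.09)
        L = np.stack(
            [
                forward_matrix(src[None], e[None], sensors, head)[:, 0]
                for e in np.linalg.qr(
                    np.column_stack([moment, rng.standard_normal(3)])
                )[0].T
            ],
            axis=1,
        )
        cov = compute_covariance(ep, band=(1.0, 40.0), mu=0.05)
        w, eta, S = sam_weights(L, cov)
        ts = virtual_sensor(w, ep, FACE).mean(axis=0)
        r = np.corrcoef(ts, signal)[0, 1]
        assert abs(r) > 0.95
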