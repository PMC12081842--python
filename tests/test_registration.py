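import itertools

import numpy as np
import pytest

from elastigate.errors import InputError
from elastigate.imaging import DensityImage
from elastigate.model import PlotSpec
from elastigate.registration import (
    RegistrationConfig,
    register,
    register_1d,
    resampled_ssd,
)

from conftest import gaussian_blob_image, gaussian_peak_hist


def _grid_points(size, step=8.0):
    jj, ii = np.meshgrid(np.arange(0, size, step), np.arange(0, size, step))
    return np.stack([jj.ravel(), ii.ravel()], axis=1)


def _support_points(img, thresh=0.5):
    ys, xs = np.nonzero(img.as_float() > thresh)
    return np.stack([xs.astype(float), ys.astype(float)], axis=1)


class TestRegister2D:
    def test_self_registration_is_identity(self, blob_256):
        res = register(blob_256, blob_256)
        d = res.field.displacement(_grid_points(256))
        assert np.abs(d).max() < 0.5
        assert res.final_ssd <= res.initial_ssd + 1e-12

    def test_translation_recovered(self, blob_256, shift_registration):
        res = shift_registration
        d = res.field.displacement(_support_points(blob_256))
        mean = d.mean(axis=0)
        assert mean[0] == pytest.approx(5.0, abs=1.0)
        assert mean[1] == pytest.approx(0.0, abs=1.0)
        assert res.converged

    def test_isotropic_expansion_recovered(self):
        src = gaussian_blob_image(256, 128.0, 128.0, 10.0)
        tgt = gaussian_blob_image(256, 128.0, 128.0, 14.0)
        res = register(src, tgt)
        centre = np.array([[127.5, 127.5]])
        assert np.linalg.norm(res.field.displacement(centre)) < 1.0
        # numerical Jacobian determinant at the centre must indicate expansion
        e = 1.0
        dx = (res.field.evaluate(centre + [e, 0]) - res.field.evaluate(centre - [e, 0])) / (2 * e)
        dy = (res.field.evaluate(centre + [0, e]) - res.field.evaluate(centre - [0, e])) / (2 * e)
        J = np.array([[dx[0, 0], dy[0, 0]], [dx[0, 1], dy[0, 1]]])
        assert np.linalg.det(J) > 1.0

    def test_similarity_never_worsens_without_regularization(self, blob_256, blob_256_shifted):
        cfg = RegistrationConfig(regularization_weight=0.0, consistency_weight=0.1)
        res = register(blob_256, blob_256_shifted, cfg)
        assert res.final_ssd <= res.initial_ssd

    def test_energy_trace_non_increasing_within_levels(self, shift_registration):
        res = shift_registration
        for trace in res.energy_trace:
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_inverse_consistency(self, shift_registration):
        res = shift_registration
        pts = _grid_points(256, 16.0)
        back = res.inverse_field.evaluate(res.field.evaluate(pts))
        err = np.linalg.norm(back - pts, axis=1)
        assert err.mean() <= 1.0

    def test_dimension_mismatch_rejected(self, blob_256):
        small = gaussian_blob_image(128, 64.0, 64.0, 8.0)
        with pytest.raises(InputError):
            register(blob_256, small)

    def test_deterministic(self):
        src = gaussian_blob_image(64, 30.0, 34.0, 6.0)
        tgt = gaussian_blob_image(64, 33.0, 32.0, 6.0)
        cfg = RegistrationConfig(min_intervals=4, max_intervals=8)
        r1 = register(src, tgt, cfg)
        r2 = register(src, tgt, cfg)
        assert np.array_equal(r1.field.coeff_x, r2.field.coeff_x)
        assert r1.final_ssd == r2.final_ssd

    def test_small_instance_matches_bruteforce_oracle(self):
        """On 16x16 images with a 2x2-interval grid, the optimized SSD must be
        within 5% of the best SSD over a coarse sweep of the 2 central
        backward-field coefficients (others held at the solution)."""
        src = gaussian_blob_image(16, 7.0, 8.0, 2.5)
        tgt = gaussian_blob_image(16, 9.0, 8.0, 2.5)
        cfg = RegistrationConfig(
            min_intervals=2, max_intervals=2,
            regularization_weight=0.0, consistency_weight=0.0,
        )
        res = register(src, tgt, cfg)
        S, T = src.as_float(), tgt.as_float()
        bwd = res.inverse_field
        centre = (bwd.coeff_x.shape[0] // 2, bwd.coeff_x.shape[1] // 2)
        best = np.inf
        sweep = np.arange(-4.0, 4.01, 0.5)
        cx0, cy0 = bwd.coeff_x[centre], bwd.coeff_y[centre]
        for ax, ay in itertools.product(sweep, sweep):
            bwd.coeff_x[centre] = cx0 + ax
            bwd.coeff_y[centre] = cy0 + ay
            best = min(best, resampled_ssd(S, T, bwd))
        bwd.coeff_x[centre], bwd.coeff_y[centre] = cx0, cy0
        assert res.final_ssd <= 1.05 * best + 1e-9


class TestRegister1D:
    def test_identity(self):
        h = gaussian_peak_hist(256, 100.0, 8.0)
        res = register_1d(h, h)
        d = res.field.displacement(np.arange(0.0, 256.0, 4.0))
        assert np.abs(d).max() < 0.5

    def test_shift_recovered_at_peak(self):
        src = gaussian_peak_hist(256, 100.0, 8.0)
        tgt = gaussian_peak_hist(256, 110.0, 8.0)
        res = register_1d(src, tgt)
        d = res.field.displacement(np.array([100.0]))
        assert d[0] == pytest.approx(10.0, abs=1.0)

    def test_opposite_local_shifts_recovered(self):
        x = np.arange(256)
        def two_peaks(c1, c2):
            g = np.exp(-((x - c1) ** 2) / (2 * 8.0 ** 2)) + np.exp(
                -((x - c2) ** 2) / (2 * 8.0 ** 2)
            )
            return DensityImage(
                np.rint(255 * g / g.max()).astype(np.uint8),
                PlotSpec("x", None, 256, 16), 0, 256,
            )
        src = two_peaks(70.0, 180.0)
        tgt = two_peaks(76.0, 174.0)
        res = register_1d(src, tgt)
        assert res.field.displacement(np.array([70.0]))[0] == pytest.approx(6.0, abs=2.0)
        assert res.field.displacement(np.array([180.0]))[0] == pytest.approx(-6.0, abs=2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            register_1d(gaussian_peak_hist(256, 100, 8), gaussian_peak_hist(128, 50, 8))
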