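"""Global envelope PCA, canonical HRF, design assembly and GLM fitting."""

import numpy as np
import pytest

from nvcpipe.eeg import BandDefinition, BandEnvelopes
from nvcpipe.errors import DataError, NumericalError, ParameterError
from nvcpipe.fnirs import HemoglobinTimecourses, default_geometry
from nvcpipe.nc import (
    ChannelBetas,
    DesignMatrix,
    GlobalEnvelope,
    block_resample,
    build_design,
    canonical_hrf,
    estimate_subject_nc,
    fit_glm_channel,
    global_envelope_pca,
    prepare_target,
    subject_nc_metrics,
    unimodal_powers,
)

ALPHA = BandDefinition("alpha", 7.4, 13.0)


def _env(data, fs=250.0):
    return BandEnvelopes(np.asarray(data, dtype=float), fs, ALPHA)


class TestGlobalEnvelopePCA:
    def test_identical_channels_are_rank_one(self, rng):
        series = np.abs(rng.standard_normal(2000)) + 0.1
        g = global_envelope_pca(_env(np.tile(series, (5, 1))))
        assert g.variance_fraction == pytest.approx(1.0, abs=1e-9)
        assert abs(np.corrcoef(g.timecourse, series)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_channels_split_variance(self):
        n = 4000
        t = np.arange(n)
        a = np.sin(2 * np.pi * t / 100)
        b = np.cos(2 * np.pi * t / 100)
        g = global_envelope_pca(_env(np.stack([a, b])))
        assert g.variance_fraction == pytest.approx(0.5, abs=1e-6)

    def test_planted_factor_recovered(self, rng):
        latent = rng.standard_normal(20000)
        weights = rng.uniform(0.2, 1.0, size=(128, 1))
        env = weights * latent + 0.1 * rng.standard_normal((128, 20000))
        g = global_envelope_pca(_env(env))
        assert abs(np.corrcoef(g.timecourse, latent)[0, 1]) > 0.99

    def test_sign_convention_positive_mean_loading(self, rng):
        latent = rng.standard_normal(5000)
        env = rng.uniform(0.5, 1.0, size=(8, 1)) * latent
        g = global_envelope_pca(_env(env))
        # flipping every channel must not flip the returned component
        g2 = global_envelope_pca(_env(-env))
        assert np.corrcoef(g.timecourse, g2.timecourse)[0, 1] < -0.99 or np.corrcoef(
            g.timecourse, g2.timecourse
        )[0, 1] > 0.99

    def test_zero_variance_channel_excluded(self, rng):
        env = rng.standard_normal((4, 1000))
        env[2] = 5.0
        with pytest.warns(UserWarning):
            g = global_envelope_pca(_env(env))
        assert np.isfinite(g.timecourse).all()

    def test_all_zero_input_rejected(self):
        with pytest.raises(DataError):
            global_envelope_pca(_env(np.zeros((4, 100))))


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf(10.0).kernel[0] == 0.0

    def test_peak_time_physiological(self):
        h = canonical_hrf(25.0)
        assert 4.5 <= h.peak_time_s <= 6.5

    def test_peak_normalized_single_positive_lobe(self):
        h = canonical_hrf(10.0)
        assert h.kernel.max() == pytest.approx(1.0)
        assert h.kernel.min() > -0.5  # undershoot smaller than the main lobe

    def test_impulse_convolution_is_identity(self):
        h = canonical_hrf(5.0)
        impulse = np.zeros(len(h.kernel) * 2)
        impulse[0] = 1.0
        out = np.convolve(impulse, h.kernel)[: len(h.kernel)]
        assert np.allclose(out, h.kernel)


class TestBlockResample:
    def test_integer_ratio_equals_reshape_mean(self, rng):
        x = rng.standard_normal(1000)
        out = block_resample(x, fs=250.0, target_fs=1.0)
        assert np.allclose(out, x.reshape(4, 250).mean(axis=1))

    def test_non_integer_ratio_preserves_mean(self, rng):
        x = rng.standard_normal(3125) + 3.0
        out = block_resample(x, fs=10.42, target_fs=1.0)
        assert len(out) == int(np.floor(3125 / 10.42))
        assert out.mean() == pytest.approx(3.0, abs=0.1)


def _globals(rng, n=75000, fs=250.0, k=3):
    names = ["theta", "alpha", "beta"]
    return {
        names[i]: GlobalEnvelope(rng.standard_normal(n), fs, 0.5, BandDefinition(names[i], 1 + i, 2 + i))
        for i in range(k)
    }


class TestBuildDesign:
    def test_hrf_makes_band_columns_slow(self, rng):
        design = build_design(_globals(rng), short_hb=None, short_fs=10.42, include_short=False)
        from scipy.signal import periodogram

        for j in range(3):
            f, p = periodogram(design.X[:, j], fs=1.0)
            assert p[f <= 0.2].sum() / p.sum() > 0.95

    def test_columns_standardized_full_rank(self, rng):
        short = rng.standard_normal((4, 3125))
        design = build_design(_globals(rng), short, 10.42)
        assert design.X.shape[1] == 8
        assert np.allclose(design.X[:, :-1].mean(axis=0), 0, atol=1e-12)
        assert np.allclose(design.X[:, :-1].std(axis=0), 1, atol=1e-12)
        assert np.linalg.matrix_rank(design.X) == 8

    def test_duplicated_short_channel_rejected(self, rng):
        s = rng.standard_normal(3125)
        with pytest.raises(NumericalError, match="short"):
            build_design(_globals(rng), np.stack([s, s]), 10.42)

    def test_constant_envelope_flagged_degenerate(self, rng):
        g = _globals(rng)
        g["theta"] = GlobalEnvelope(np.full(75000, 2.0), 250.0, 0.5, BandDefinition("theta", 3.5, 8.2))
        with pytest.raises(DataError, match="theta"):
            build_design(g, None, 10.42, include_short=False)


def _design_from_matrix(X, labels):
    return DesignMatrix(X=X, column_labels=labels, fs=1.0, trim_rows=0, n_rows_total=len(X))


class TestGLM:
    def test_perfect_fit_on_theta_column(self, rng):
        X = rng.standard_normal((100, 3))
        X = (X - X.mean(0)) / X.std(0)
        X = np.column_stack([X, np.ones(100)])
        design = _design_from_matrix(X, ["theta", "alpha", "beta", "intercept"])
        betas, _, _ = fit_glm_channel(design, X[:, 0])
        assert betas["theta"] == pytest.approx(1.0, abs=1e-10)
        assert abs(betas["alpha"]) < 1e-10 and abs(betas["beta"]) < 1e-10

    def test_white_noise_betas_bounded(self, rng):
        n = 200
        X = np.column_stack([rng.standard_normal((n, 3)), np.ones(n)])
        design = _design_from_matrix(X, ["theta", "alpha", "beta", "intercept"])
        for _ in range(10):
            betas, _, _ = fit_glm_channel(design, rng.standard_normal(n))
            assert all(abs(b) < 3 / np.sqrt(n) for b in betas.values())

    def test_matches_pseudoinverse_oracle(self, rng):
        n, p = 50, 7
        X = np.column_stack([rng.standard_normal((n, p)), np.ones(n)])
        labels = ["theta", "alpha", "beta", "s1", "s2", "s3", "s4", "intercept"]
        design = _design_from_matrix(X, labels)
        y = rng.standard_normal(n)
        _, by_label, _ = fit_glm_channel(design, y)
        oracle = np.linalg.pinv(X) @ y
        got = np.array([by_label[lab] for lab in labels])
        assert np.abs(got - oracle).max() < 1e-8

    def test_too_few_rows_rejected(self, rng):
        X = np.column_stack([rng.standard_normal((3, 3)), np.ones(3)])
        design = _design_from_matrix(X, ["theta", "alpha", "beta", "intercept"])
        with pytest.raises(ParameterError):
            fit_glm_channel(design, np.zeros(3))


class TestSubjectMetrics:
    def test_mean_of_constant_betas(self):
        betas = ChannelBetas(
            beta={("theta", "hbo"): np.full(16, 0.3)}, residual_sd={}, channel_ids=list(range(16))
        )
        assert subject_nc_metrics(betas).nc[("theta", "hbo")] == pytest.approx(0.3)

    def test_arithmetic_mean(self):
        betas = ChannelBetas(beta={("alpha", "hbr"): np.array([0.2, 0.4])}, residual_sd={}, channel_ids=[0, 1])
        assert subject_nc_metrics(betas).nc[("alpha", "hbr")] == pytest.approx(0.3)

    def test_qc_excluded_channel_left_out(self, coupled_subject, small_config):
        from nvcpipe.pipeline import preprocess_subject

        pre = preprocess_subject(
            coupled_subject.eeg, coupled_subject.intensities, coupled_subject.age,
            coupled_subject.label, small_config,
        )
        _, full_betas, _ = estimate_subject_nc(pre.envelopes, pre.hb)
        _, reduced_betas, _ = estimate_subject_nc(pre.envelopes, pre.hb, excluded_channels=[0])
        assert len(reduced_betas.channel_ids) == len(full_betas.channel_ids) - 1
        key = ("theta", "hbo")
        expected = full_betas.beta[key][1:].mean()
        got = subject_nc_metrics(reduced_betas).nc[key]
        assert got == pytest.approx(expected, abs=1e-9)


class TestUnimodalPowers:
    def test_constant_envelope_power(self):
        env = {"theta": _env(np.full((4, 100), 3.0))}
        hb = HemoglobinTimecourses(
            hbo=np.ones((2, 100)), hbr=np.ones((2, 100)), fs=10.42, geometry=default_geometry(1, 1)
        )
        powers = unimodal_powers(env, hb)
        assert powers.eeg_power["theta"] == pytest.approx(9.0)

    def test_unit_variance_noise_power(self, rng):
        hbo = rng.standard_normal((17, 5000))
        hb = HemoglobinTimecourses(hbo=hbo, hbr=hbo * 0, fs=10.42, geometry=default_geometry(16, 1))
        powers = unimodal_powers({"theta": _env(np.zeros((4, 10)) + 1)}, hb)
        assert powers.fnirs_power["hbo"] == pytest.approx(1.0, abs=0.05)
        assert powers.fnirs_power["hbr"] == 0.0


class TestShortChannelRegression:
    def test_nuisance_regressors_shrink_null_couplings(self):
        """With scalp leakage and no neural coupling, short-channel
        regressors reduce the magnitude of the estimated couplings
        (paired over replicates)."""
        from nvcpipe.pipeline import PipelineConfig, preprocess_subject
        from nvcpipe.synthetic import CouplingSpec, generate_subject

        cfg = PipelineConfig()
        spec = CouplingSpec(scalp_gain_long=0.6)
        diffs = []
        for seed in range(20):
            subj = generate_subject(spec, 70, 0, duration_s=120, seed=seed, n_eeg_channels=16)
            pre = preprocess_subject(subj.eeg, subj.intensities, subj.age, subj.label, cfg)
            with_short, _, _ = estimate_subject_nc(pre.envelopes, pre.hb, include_short=True)
            without, _, _ = estimate_subject_nc(pre.envelopes, pre.hb, include_short=False)
            m_with = np.mean(np.abs(with_short.as_vector()))
            m_without = np.mean(np.abs(without.as_vector()))
            diffs.append(m_without - m_with)
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() >= 0.7


def test_prepare_target_alignment(rng):
    X = np.column_stack([rng.standard_normal((50, 2)), np.ones(50)])
    design = DesignMatrix(X=X, column_labels=["a", "b", "intercept"], fs=1.0, trim_rows=10, n_rows_total=60)
    y = rng.standard_normal(int(60 * 10.42) + 5)
    out = prepare_target(y, 10.42, design)
    assert len(out) == 50
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    assert out.std() == pytest.approx(1.0, abs=1e-12)
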