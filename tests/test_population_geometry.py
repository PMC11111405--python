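import numpy as np
import pytest

import facegeom as fg
from facegeom.population_geometry import (
    _zscore_cells,
    centroid_distance_trace,
    condition_contrast,
    decode_familiarity,
    decode_features,
    dprime_from_matrix,
    familiarity_axis_orthogonality,
    fit_familiarity_classifier,
    rate_shift_distribution,
    reconstruct_features,
    rsa_matrix,
)
from facegeom.response_core import window_response
from tests.conftest import make_faces


def simulate(seed=0, **kw):
    defaults = dict(n_cells=80, n_unfamiliar=300, n_familiar=36, n_trials=10,
                    shift_magnitude=0.0, rotation_angle_deg=0.0)
    defaults.update(kw)
    cfg = fg.SimConfig(seed=seed, **defaults)
    faces = make_faces(cfg.n_familiar, cfg.n_unfamiliar, seed=seed + 700)
    tensor = fg.simulate_responses(fg.make_population(cfg), faces, cfg)
    return cfg, faces, tensor


class TestRsaMatrix:
    def test_identical_categories_look_alike(self):
        rng = np.random.default_rng(0)
        proto = rng.normal(size=(30, 1))
        resp = proto + rng.normal(0, 0.05, size=(30, 8))
        cats = np.array(["a"] * 4 + ["b"] * 4)
        mat, labels, diag = rsa_matrix(resp, cats)
        assert abs(mat[0, 1] - mat[0, 0]) < 0.05
        assert np.allclose(diag, 1.0)

    def test_orthogonal_categories_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(200, 4))
        b = rng.normal(size=(200, 4))
        mat, labels, _ = rsa_matrix(np.hstack([a, b]),
                                    np.array(["a"] * 4 + ["b"] * 4))
        assert abs(mat[0, 1]) < 0.1
        assert mat[0, 0] < 0.1  # independent exemplars within category too

    def test_single_exemplar_within_category_masked(self):
        resp = np.random.default_rng(2).normal(size=(10, 3))
        mat, labels, _ = rsa_matrix(resp, np.array(["a", "a", "b"]))
        i_b = list(labels).index("b")
        assert np.isnan(mat[i_b, i_b])

    def test_familiar_block_structure_stronger_late(self):
        # familiar recoding at long latency sharpens the familiar/unfamiliar
        # block structure of the similarity matrix
        _, faces, tensor = simulate(seed=3, rotation_angle_deg=60.0,
                                    familiar_gain=0.6, shift_magnitude=2.0)
        cats = np.where(faces.familiar, "familiar", "unfamiliar")
        short = rsa_matrix(window_response(tensor, 50, 125), cats)[0]
        full = rsa_matrix(window_response(tensor, 200, 300), cats)[0]

        def block_contrast(m):
            return 0.5 * (m[0, 0] + m[1, 1]) - m[0, 1]

        assert block_contrast(full) > block_contrast(short)


class TestFeatureDecoding:
    def test_noiseless_duality_mse_zero_and_inversion(
            self, noiseless_linear_experiment):
        cfg, pop, faces, tensor = noiseless_linear_experiment
        mask = ~faces.familiar
        test = faces.familiar
        fd = decode_features(tensor, faces, mask, test, width_ms=50, step_ms=250,
                             ridge_alpha=1e-8, shuffle_repeats=2, seed=0)
        post = fd.trace.times_ms >= 150
        assert np.all(fd.trace.value[post] < 1e-8)
        # decoder composed with the encoder is the identity on feature space
        model = fd.models[250]
        rates = window_response(tensor, 200, 250).T
        pred = model.predict(rates[test])
        assert np.max(np.abs(pred - faces.features[test, :20])) < 1e-6

    def test_orthogonal_shift_causes_no_leakage(self):
        # noiseless, high-offset population: the familiar-face shift is
        # orthogonal to the feature code, so familiar decoding error equals
        # the unfamiliar level exactly
        cfg = fg.SimConfig(n_cells=80, n_unfamiliar=150, n_familiar=20,
                           n_trials=1, seed=6, shift_magnitude=1.0,
                           shift_onset_ms=90, rotation_angle_deg=0.0,
                           baseline_hz=200.0, peak_hz=260.0, noise_model="none")
        faces = make_faces(20, 150, seed=16)
        tensor = fg.simulate_responses(fg.make_population(cfg), faces, cfg)
        rng = np.random.default_rng(0)
        unfam = np.flatnonzero(~faces.familiar)
        test_unfam = np.zeros(faces.n_faces, bool)
        test_unfam[rng.choice(unfam, 30, replace=False)] = True
        train = ~faces.familiar & ~test_unfam
        # modest ridge keeps the linear system well conditioned; the shift is
        # exactly in the decoder's null space by construction
        fd_fam = decode_features(tensor, faces, train, faces.familiar,
                                 width_ms=50, step_ms=250, ridge_alpha=1.0,
                                 shuffle_repeats=1, seed=0,
                                 normalize_cells=False)
        fd_unf = decode_features(tensor, faces, train, test_unfam,
                                 width_ms=50, step_ms=250, ridge_alpha=1.0,
                                 shuffle_repeats=1, seed=0,
                                 normalize_cells=False)
        post = fd_fam.trace.times_ms >= 150
        assert np.all(np.abs(fd_fam.trace.value[post]
                             - fd_unf.trace.value[post]) < 1e-10)

    def test_identity_shuffle_null_equals_feature_variance(self):
        _, faces, tensor = simulate(seed=7, n_cells=60)
        unfam = ~faces.familiar
        # heavy shrinkage makes the shuffled decoder predict the training mean,
        # so the null is exactly the information-free floor var(feature) = 1
        fd = decode_features(tensor, faces, unfam, faces.familiar, width_ms=100,
                             step_ms=300, ridge_alpha=1e6, shuffle_repeats=5,
                             seed=0)
        assert abs(fd.null_trace.value[-1] - 1.0) < 0.15

    def test_long_latency_decoder_failure_for_familiar(self):
        _, faces, tensor = simulate(seed=8, n_cells=120, n_unfamiliar=1000,
                                    rotation_angle_deg=60.0,
                                    rotation_onset_ms=200)
        rng = np.random.default_rng(1)
        unfam = np.flatnonzero(~faces.familiar)
        test_unfam = np.zeros(faces.n_faces, bool)
        test_unfam[rng.choice(unfam, 200, replace=False)] = True
        train = ~faces.familiar & ~test_unfam
        fd_fam = decode_features(tensor, faces, train, faces.familiar, seed=0,
                                 shuffle_repeats=2)
        fd_unf = decode_features(tensor, faces, train, test_unfam, seed=0,
                                 shuffle_repeats=2)
        t = fd_fam.trace.times_ms
        i_short, i_long = np.flatnonzero(t == 170)[0], np.flatnonzero(t == 270)[0]
        jump = fd_fam.trace.value[i_long] - fd_fam.trace.value[i_short]
        assert jump > 3 * fd_fam.trace.sem[i_long]
        unf_change = abs(fd_unf.trace.value[i_long] - fd_unf.trace.value[i_short])
        assert unf_change < 3 * fd_unf.trace.sem[i_long]

    def test_reconstruct_features_roundtrip(self, noiseless_linear_experiment):
        cfg, pop, faces, tensor = noiseless_linear_experiment
        mask = ~faces.familiar
        fd = decode_features(tensor, faces, mask, faces.familiar, width_ms=50,
                             step_ms=250, ridge_alpha=1e-8, shuffle_repeats=1,
                             seed=0)
        model = fd.models[250]
        rates = window_response(tensor, 200, 250).T
        pred, metrics = reconstruct_features(model, rates[mask],
                                             faces.features[mask, :20])
        assert np.all(metrics["mse_per_face"] < 1e-12)
        assert np.all(metrics["corr_per_face"] > 1 - 1e-9)

    def test_overlapping_masks_rejected(self, plain_experiment):
        _, _, faces, tensor = plain_experiment
        mask = ~faces.familiar
        with pytest.raises(ValueError):
            decode_features(tensor, faces, mask, mask)


class TestFamiliarityDecoding:
    def test_null_generator_stays_at_chance(self):
        _, faces, tensor = simulate(seed=9, n_cells=50)
        trace, _ = decode_familiarity(tensor, faces.familiar, n_perm=30,
                                      n_balance=5, seed=0)
        assert trace.latency_ms is None
        post = trace.times_ms >= 150
        assert abs(np.nanmean(trace.value[post]) - 0.5) < 0.1

    def test_shift_recovery_latency_and_plateau(self):
        _, faces, tensor = simulate(seed=10, n_cells=100, n_unfamiliar=500,
                                    shift_magnitude=2.0, shift_onset_ms=100)
        trace, model = decode_familiarity(tensor, faces.familiar, n_perm=50,
                                          seed=0)
        assert trace.latency_ms is not None and 100 <= trace.latency_ms <= 120
        assert np.nanmean(trace.value[trace.times_ms >= 200]) > 0.9
        assert model.kind == "familiarity_classifier"

    def test_rotation_only_familiarity_is_late(self):
        _, faces, tensor = simulate(seed=11, n_cells=100, n_unfamiliar=500,
                                    shift_magnitude=0.0,
                                    rotation_angle_deg=60.0, familiar_gain=0.7,
                                    rotation_onset_ms=200)
        trace, _ = decode_familiarity(tensor, faces.familiar, n_perm=50, seed=0)
        assert trace.latency_ms is not None and trace.latency_ms >= 200

    def test_too_few_identities_rejected(self):
        _, faces, tensor = simulate(seed=12, n_cells=25, n_familiar=3,
                                    n_unfamiliar=40)
        with pytest.raises(fg.InsufficientDataError):
            decode_familiarity(tensor, faces.familiar)


class TestCentroidAndDPrime:
    def test_gaussian_oracle_dprime_of_one(self):
        # closed form: two unit-variance Gaussians, unit mean separation
        rng = np.random.default_rng(0)
        n = 500
        X = rng.normal(size=(n, 10))
        labels = np.arange(n) < n // 2
        X[labels, 0] += 1.0
        res = dprime_from_matrix(X, labels, n_shuffles=200, seed=1)
        assert abs(res.dprime - 1.0) < 0.1
        assert res.p_value < 0.01

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 30))
        labels = np.arange(300) < 150
        res = dprime_from_matrix(X, labels, n_shuffles=200, seed=3)
        assert res.dprime < res.null_quantiles[0.99]
        assert res.p_value > 0.05

    def test_centroid_trace_null_case(self):
        _, faces, tensor = simulate(seed=13, n_cells=50)
        tr = centroid_distance_trace(tensor, faces.familiar, n_control=8,
                                     n_boot=4, seed=0)
        post = tr.times_ms >= 150
        rel = np.abs(tr.value[post] - np.asarray(tr.null_level)[post])
        assert np.all(rel < 4 * tr.extras["control_sem"][post] * np.sqrt(8) + 0.5)

    def test_centroid_trace_recovers_achieved_shift(self):
        cfg, faces, tensor = simulate(seed=14, n_cells=100, n_unfamiliar=500,
                                      n_trials=50, shift_magnitude=2.0)
        tr = centroid_distance_trace(tensor, faces.familiar, n_control=10,
                                     n_boot=4, seed=0)
        late = tr.times_ms >= 200
        debiased = tr.extras["debiased"][late].mean()
        # oracle: achieved shift from a noiseless twin, z-scaled like the data
        twin = fg.simulate_responses(fg.make_population(cfg), faces,
                                     cfg.replace(noise_model="none"))
        exp_rates = window_response(twin, 200, 300)
        d_hz = (exp_rates[:, faces.familiar].mean(1)
                - exp_rates[:, ~faces.familiar].mean(1))
        sd = window_response(tensor, 200, 300).T.std(0)
        truth = np.linalg.norm(d_hz / np.where(sd > 0, sd, 1.0))
        assert abs(debiased - truth) / truth < 0.15

    def test_distance_scales_with_population_size(self):
        # doubling an i.i.d. population scales distances by sqrt(2)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 60))
        labels = np.arange(100) < 36
        X[labels] += 0.3

        def dist(Xs):
            Z, _, _ = _zscore_cells(Xs)
            return np.linalg.norm(Z[labels].mean(0) - Z[~labels].mean(0))

        d1 = dist(X[:, :30])
        d2 = dist(np.hstack([X[:, :30], X[:, 30:]]))
        assert abs(d2 / d1 - np.sqrt(2)) < 0.15

    def test_dprime_and_decoding_latencies_agree(self):
        _, faces, tensor = simulate(seed=15, n_cells=100, n_unfamiliar=500,
                                    shift_magnitude=2.0, shift_onset_ms=100)
        trace, _ = decode_familiarity(tensor, faces.familiar, n_perm=50, seed=0)
        dtr = fg.dprime_trace(tensor, faces.familiar, n_shuffles=300, seed=0)
        assert dtr.latency_ms is not None and trace.latency_ms is not None
        assert abs(dtr.latency_ms - trace.latency_ms) <= 10

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(fg.InsufficientDataError):
            dprime_from_matrix(X, np.ones(10, bool))


class TestRateShiftDistribution:
    def test_null_centered_with_nominal_false_positives(self):
        _, faces, tensor = simulate(seed=16, n_cells=150)
        res = rate_shift_distribution(tensor, faces.familiar, [(100, 300)],
                                      alpha=0.01)
        assert abs(res.diffs[0].mean()) < 1.0
        assert res.significant[0].mean() < 0.05
        assert res.population_p[0] > 0.01

    def test_shift_creates_mixed_signs_with_zero_mean(self):
        _, faces, tensor = simulate(seed=17, n_cells=150, shift_magnitude=2.0)
        res = rate_shift_distribution(tensor, faces.familiar, [(150, 300)],
                                      alpha=0.01)
        d = res.diffs[0]
        assert (d > 1).sum() > 10 and (d < -1).sum() > 10
        assert abs(d.mean()) < 0.15 * d.std()
        assert res.significant[0].mean() > 0.3

    def test_suppression_shifts_distribution_negative(self):
        _, faces, tensor = simulate(seed=18, n_cells=100, familiar_gain=0.7,
                                    rotation_onset_ms=200)
        res = rate_shift_distribution(tensor, faces.familiar,
                                      [(100, 200), (200, 300)])
        assert abs(res.diffs[0].mean()) < 2.0       # pre-suppression window
        assert res.diffs[1].mean() < -3.0           # suppressed window
        assert res.population_p[1] < 1e-6


class TestOrthogonality:
    @staticmethod
    def cosines(shift_mode, seed):
        cfg = fg.SimConfig(n_cells=200, n_unfamiliar=600, n_familiar=36,
                           n_trials=10, seed=seed, shift_magnitude=2.0,
                           rotation_angle_deg=0.0, shift_mode=shift_mode)
        faces = make_faces(36, 600, seed=seed + 70)
        tensor = fg.simulate_responses(fg.make_population(cfg), faces, cfg)
        fd = decode_features(tensor, faces, ~faces.familiar, faces.familiar,
                             width_ms=50, step_ms=50, shuffle_repeats=1, seed=0)
        clf = fit_familiarity_classifier(tensor, faces.familiar, (100, 150),
                                         seed=0, ridge_alpha=100.0)
        return familiarity_axis_orthogonality(clf, fd.models[150])

    def test_constructed_shift_orthogonal_to_feature_axes(self):
        cos = self.cosines("orthogonal", seed=19)
        assert np.abs(cos).mean() < 0.1
        assert np.abs(cos).max() < 0.25

    def test_in_subspace_shift_detected(self):
        cos = self.cosines("in_subspace", seed=20)
        assert np.abs(cos).max() > 0.5

    def test_random_vectors_concentrate_at_inverse_sqrt_n(self):
        # analytic null in R^200
        rng = np.random.default_rng(5)
        v = rng.normal(size=200); v /= np.linalg.norm(v)
        W = rng.normal(size=(20, 200))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        cos = np.abs(W @ v)
        assert abs(cos.mean() - np.sqrt(2 / np.pi) / np.sqrt(200)) < 0.03

    def test_mismatched_populations_rejected(self):
        from facegeom.population_geometry import DecoderModel
        a = DecoderModel("familiarity_classifier", np.ones((1, 5)), np.zeros(1),
                         np.zeros(5), np.ones(5), (0, 50))
        b = DecoderModel("feature_regressor", np.ones((3, 6)), np.zeros(3),
                         np.zeros(6), np.ones(6), (0, 50))
        with pytest.raises(ValueError):
            familiarity_axis_orthogonality(a, b)


class TestConditionContrast:
    def test_identical_conditions_give_zero_change(self, plain_experiment):
        _, _, faces, tensor = plain_experiment
        res = condition_contrast(tensor, tensor, faces.familiar)
        assert np.allclose(res.change_familiar, 0.0)
        assert np.allclose(res.change_unfamiliar, 0.0)

    def test_global_gain_gives_analytic_change(self, plain_experiment):
        _, _, faces, tensor = plain_experiment
        scaled = fg.ResponseTensor(tensor.counts * 1.5, tensor.bin_ms,
                                   tensor.t_start_ms, tensor.t_end_ms,
                                   tensor.cell_ids, tensor.face_ids,
                                   mask=tensor.mask, normalized=True)
        res = condition_contrast(tensor, scaled, faces.familiar)
        assert np.allclose(res.change_familiar, 0.2, atol=1e-10)
        assert np.allclose(res.change_unfamiliar, 0.2, atol=1e-10)
        assert res.paired_p > 0.05 or np.isnan(res.paired_p)

    def test_gain_rescale_preserves_axis_deficit_in_both_conditions(self):
        _, faces, tensor = simulate(seed=21, n_cells=100, n_unfamiliar=500,
                                    rotation_angle_deg=60.0,
                                    rotation_onset_ms=90, shift_onset_ms=90)
        scaled = fg.ResponseTensor(tensor.counts * 1.4, tensor.bin_ms,
                                   tensor.t_start_ms, tensor.t_end_ms,
                                   tensor.cell_ids, tensor.face_ids,
                                   mask=tensor.mask, normalized=True)
        res = condition_contrast(tensor, scaled, faces.familiar, (100, 300),
                                 faces=faces, axis_window=(100, 300), seed=0)
        assert res.comparison_a.p_value < 0.001
        assert res.comparison_b.p_value < 0.001
        assert res.paired_p > 0.05  # both classes modulated alike
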