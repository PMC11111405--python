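"""Population-level coding analyses.

Representational similarity, linear feature decoding and reconstruction,
familiarity decoding with identity-generalizing cross-validation, centroid
distances and d-prime with shuffle nulls, per-cell rate-shift distributions,
orthogonality of the familiarity axis to the feature-coding subspace, and
two-condition (inactivation-style) contrasts.

Geometry operations work in per-cell z-scored population space so that
high-rate cells do not dominate Euclidean structure.  Euclidean distances grow
like sqrt(n_cells) for i.i.d. populations and are therefore only comparable
within a fixed population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.model_selection import StratifiedKFold

from .axis_dynamics import uu_uf_comparison
from .response_core import (
    GeometryTrace,
    InsufficientDataError,
    ResponseTensor,
    latency_from_pvalues,
    rolling_windows,
    window_response,
    window_response_per_trial,
)
from .synthetic_data import FaceSet

__all__ = [
    "DecoderModel",
    "rsa_matrix",
    "decode_features",
    "FeatureDecoding",
    "reconstruct_features",
    "fit_familiarity_classifier",
    "decode_familiarity",
    "centroid_distance_trace",
    "dprime_from_matrix",
    "DPrimeResult",
    "dprime_along_centroid",
    "dprime_trace",
    "rate_shift_distribution",
    "RateShiftResult",
    "familiarity_axis_orthogonality",
    "condition_contrast",
    "ConditionContrast",
]


@dataclass
class DecoderModel:
    """A linear readout of population activity (feature regressor or classifier).

    ``weights`` is targets x cells, applied to per-cell z-scored rates
    (``cell_center``/``cell_scale`` from the training set).
    """

    kind: str  # "feature_regressor" | "familiarity_classifier"
    weights: np.ndarray
    intercepts: np.ndarray
    cell_center: np.ndarray
    cell_scale: np.ndarray
    window: tuple[float, float]
    training_tag: str = ""
    cv_tag: str = ""
    training_score: float = np.nan

    def transform_inputs(self, rates: np.ndarray) -> np.ndarray:
        return (rates - self.cell_center) / self.cell_scale

    def predict(self, rates: np.ndarray) -> np.ndarray:
        """Apply the readout to raw rates (faces x cells, or a single vector)."""
        one = rates.ndim == 1
        X = self.transform_inputs(np.atleast_2d(rates))
        out = X @ self.weights.T + self.intercepts
        return out[0] if one else out

    @property
    def unit_weights(self) -> np.ndarray:
        return self.weights / np.linalg.norm(self.weights, axis=1, keepdims=True)


def _zscore_cells(rates_faces_by_cells: np.ndarray):
    center = rates_faces_by_cells.mean(axis=0)
    scale = rates_faces_by_cells.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (rates_faces_by_cells - center) / scale, center, scale


# ---------------------------------------------------------------------------
# representational similarity


def rsa_matrix(
    window_matrix: np.ndarray, categories: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category-level Pearson similarity of population response vectors.

    window_matrix: cells x stimuli.  Entry (a, b) is the mean correlation between
    population vectors over exemplar pairs of categories a and b; within-category
    entries use distinct-exemplar pairs only.  Returns (matrix, unique category
    labels, diagonal of self-correlations -- always 1 -- reported separately).
    Within-category entries with fewer than 2 exemplars are NaN.
    """
    categories = np.asarray(categories)
    cats = np.unique(categories)
    corr = np.corrcoef(np.asarray(window_matrix, dtype=float).T)  # stimuli pairs
    k = len(cats)
    out = np.full((k, k), np.nan)
    for i, a in enumerate(cats):
        ia = np.flatnonzero(categories == a)
        for j, b in enumerate(cats):
            ib = np.flatnonzero(categories == b)
            block = corr[np.ix_(ia, ib)]
            if i == j:
                if len(ia) < 2:
                    continue
                vals = block[np.triu_indices(len(ia), k=1)]
            else:
                vals = block.ravel()
            out[i, j] = float(np.mean(vals))
    return out, cats, np.ones(k)


# ---------------------------------------------------------------------------
# feature decoding and reconstruction


@dataclass
class FeatureDecoding:
    """Time-resolved feature-decoding error with its identity-shuffle null."""

    trace: GeometryTrace          # test MSE (mean over features and test faces)
    null_trace: GeometryTrace     # identity-shuffled training, same evaluation
    models: dict = field(default_factory=dict)  # window label -> DecoderModel


def _fit_feature_decoder(
    X_rates: np.ndarray, features: np.ndarray, window, ridge_alpha: float,
    tag: str = "",
    normalize_cells: bool = True,
) -> DecoderModel:
    if normalize_cells:
        Xz, center, scale = _zscore_cells(X_rates)
    else:
        Xz = X_rates
        center = np.zeros(X_rates.shape[1])
        scale = np.ones(X_rates.shape[1])
    model = Ridge(alpha=ridge_alpha).fit(Xz, features)
    score = float(model.score(Xz, features))
    return DecoderModel(
        kind="feature_regressor", weights=model.coef_.copy(),
        intercepts=np.atleast_1d(model.intercept_).astype(float),
        cell_center=center, cell_scale=scale, window=window,
        training_tag=tag, training_score=score,
    )


def decode_features(
    tensor: ResponseTensor,
    faces: FaceSet,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    width_ms: int = 50,
    step_ms: int = 10,
    ridge_alpha: float = 1.0,
    shuffle_repeats: int = 10,
    seed: int = 0,
    normalize_cells: bool = True,
) -> FeatureDecoding:
    """Ridge-decode face features from population rates over rolling windows.

    The decoder is trained on ``train_mask`` faces and evaluated (mean squared
    error per feature) on ``test_mask`` faces; the null repeats the training with
    stimulus-identity-shuffled feature rows (``shuffle_repeats`` draws averaged).
    ``normalize_cells=False`` fits in raw rate space, where an orthogonally
    constructed familiarity shift is exactly invisible to the decoder.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    test_mask = np.asarray(test_mask, dtype=bool)
    if train_mask.sum() < 2 * faces.d:
        raise InsufficientDataError("need at least 2*d training faces")
    if np.any(train_mask & test_mask):
        raise ValueError("train and test sets overlap")
    rng = np.random.default_rng(seed)
    F = faces.features
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, mses, sems, null_m, null_s = [], [], [], [], []
    models = {}
    shuffles = [rng.permutation(train_mask.sum()) for _ in range(shuffle_repeats)]
    for label, t0, t1 in wins:
        rates = window_response(tensor, t0, t1).T  # faces x cells
        model = _fit_feature_decoder(rates[train_mask], F[train_mask], (t0, t1),
                                     ridge_alpha, normalize_cells=normalize_cells)
        pred = model.predict(rates[test_mask])
        per_face = np.mean((pred - F[test_mask]) ** 2, axis=1)
        times.append(label)
        mses.append(per_face.mean())
        sems.append(stats.sem(per_face))
        models[label] = model

        null_vals = []
        for perm in shuffles:
            nm = _fit_feature_decoder(rates[train_mask], F[train_mask][perm],
                                      (t0, t1), ridge_alpha,
                                      normalize_cells=normalize_cells)
            npred = nm.predict(rates[test_mask])
            null_vals.append(float(np.mean((npred - F[test_mask]) ** 2)))
        null_m.append(np.mean(null_vals))
        null_s.append(np.std(null_vals) / np.sqrt(max(len(null_vals), 1)))

    times = np.array(times)
    trace = GeometryTrace(times, np.array(mses), np.array(sems),
                          null_level=np.array(null_m),
                          method_tag="feature_decoding_mse")
    null_trace = GeometryTrace(times, np.array(null_m), np.array(null_s),
                               method_tag="feature_decoding_mse_null")
    return FeatureDecoding(trace=trace, null_trace=null_trace, models=models)


def reconstruct_features(
    model: DecoderModel,
    rates: np.ndarray,
    true_features: np.ndarray | None = None,
):
    """Apply a stored feature decoder; optionally score against true features.

    Returns (predicted features, metrics) where metrics holds per-face MSE and
    per-face Pearson correlation when true features are given.
    """
    pred = model.predict(rates)
    metrics: dict = {}
    if true_features is not None:
        true = np.atleast_2d(true_features)
        p = np.atleast_2d(pred)
        metrics["mse_per_face"] = np.mean((p - true) ** 2, axis=1)
        corr = [
            float(np.corrcoef(p[i], true[i])[0, 1]) if np.std(p[i]) > 0 else np.nan
            for i in range(len(p))
        ]
        metrics["corr_per_face"] = np.array(corr)
    return pred, metrics


# ---------------------------------------------------------------------------
# familiarity decoding


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = [np.mean(y_pred[y_true == c] == c) for c in (False, True)
            if np.any(y_true == c)]
    return float(np.mean(accs))


def _window_classify(
    rates: np.ndarray, labels: np.ndarray, n_folds: int, n_balance: int,
    rng: np.random.Generator, ridge_alpha: float,
) -> float:
    """Leave-identities-out, class-balanced linear classification accuracy."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    votes = np.zeros(len(labels))
    counted = np.zeros(len(labels), dtype=bool)
    for tr, te in skf.split(rates, labels):
        y_tr = labels[tr]
        if y_tr.all() or not y_tr.any():
            warnings.warn("single-class training fold skipped")
            continue
        pos = tr[y_tr]
        neg = tr[~y_tr]
        k = min(len(pos), len(neg))
        for _ in range(n_balance):
            sub = np.concatenate([
                rng.choice(pos, size=k, replace=False),
                rng.choice(neg, size=k, replace=False),
            ])
            Xz, center, scale = _zscore_cells(rates[sub])
            clf = RidgeClassifier(alpha=ridge_alpha).fit(Xz, labels[sub])
            dec = clf.decision_function((rates[te] - center) / scale)
            votes[te] += np.sign(dec)
        counted[te] = True
    if not counted.any():
        return np.nan
    pred = votes[counted] > 0
    return _balanced_accuracy(labels[counted], pred)


def fit_familiarity_classifier(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    window: tuple[float, float],
    n_balance: int = 20,
    seed: int = 0,
    ridge_alpha: float = 1.0,
) -> DecoderModel:
    """Train the familiarity readout on one window (balanced, averaged weights)."""
    labels = np.asarray(familiar, dtype=bool)
    rates = window_response(tensor, *window).T  # faces x cells
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    k = min(len(pos), len(neg))
    Xz, center, scale = _zscore_cells(rates)
    w_sum = np.zeros(rates.shape[1])
    b_sum = 0.0
    for _ in range(n_balance):
        sub = np.concatenate([rng.choice(pos, size=k, replace=False),
                              rng.choice(neg, size=k, replace=False)])
        clf = RidgeClassifier(alpha=ridge_alpha).fit(Xz[sub], labels[sub])
        w_sum += np.ravel(clf.coef_)
        b_sum += float(np.ravel(clf.intercept_)[0])
    w = w_sum / n_balance
    b = b_sum / n_balance
    acc = _balanced_accuracy(labels, (Xz @ w + b) > 0)
    return DecoderModel(
        kind="familiarity_classifier", weights=w[None, :],
        intercepts=np.array([b]), cell_center=center, cell_scale=scale,
        window=window, cv_tag="balanced-subsample", training_score=acc,
    )


def decode_familiarity(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    width_ms: int = 50,
    step_ms: int = 10,
    n_folds: int = 5,
    n_balance: int = 10,
    n_perm: int = 50,
    null_quantile: float = 0.99,
    consecutive: int = 2,
    seed: int = 0,
    ridge_alpha: float = 1.0,
    model_window: tuple[float, float] | None = None,
) -> tuple[GeometryTrace, DecoderModel]:
    """Time course of familiarity decoding accuracy with a permutation null.

    Folds split by face identity (no identity in both train and test); class
    balance is enforced by repeated majority-class subsampling.  The latency is
    the first window whose balanced accuracy exceeds the permutation null's
    ``null_quantile`` for ``consecutive`` consecutive windows.
    """
    labels = np.asarray(familiar, dtype=bool)
    if labels.sum() < 4 or (~labels).sum() < 4:
        raise InsufficientDataError("need >= 4 identities of each class")
    rng = np.random.default_rng(seed)
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, accs, thresholds = [], [], []
    null_accs_all = []
    for label, t0, t1 in wins:
        rates = window_response(tensor, t0, t1).T
        acc = _window_classify(rates, labels, n_folds, n_balance, rng, ridge_alpha)
        null = [
            _window_classify(rates, rng.permutation(labels), n_folds, 1, rng,
                             ridge_alpha)
            for _ in range(n_perm)
        ]
        times.append(label)
        accs.append(acc)
        null = np.asarray(null, dtype=float)
        ok = np.isfinite(null)
        # normal-theory estimate of the permutation null's upper quantile:
        # stabler than the empirical order statistic at moderate n_perm
        thresholds.append(float(null[ok].mean()
                                + stats.norm.ppf(null_quantile) * null[ok].std()))
        null_accs_all.append(null)

    times = np.array(times)
    accs = np.array(accs)
    thresholds = np.array(thresholds)
    above = accs > thresholds
    latency = None
    run = 0
    for i, s in enumerate(above):
        run = run + 1 if s else 0
        if run >= consecutive:
            latency = int(times[i - consecutive + 1])
            break
    null_sd = np.array([np.nanstd(n) for n in null_accs_all])
    trace = GeometryTrace(
        times, accs, sem=null_sd, null_level=thresholds, latency_ms=latency,
        method_tag="familiarity_decoding",
        extras={"null_accuracies": np.array(null_accs_all), "chance": 0.5},
    )
    mw = model_window if model_window is not None else (wins[-1][1], wins[-1][2])
    model = fit_familiarity_classifier(
        tensor, labels, mw, n_balance=max(n_balance, 10),
        seed=int(rng.integers(2**31)), ridge_alpha=ridge_alpha,
    )
    return trace, model


# ---------------------------------------------------------------------------
# centroid geometry and d-prime


def centroid_distance_trace(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    width_ms: int = 50,
    step_ms: int = 10,
    n_control: int = 20,
    n_boot: int = 20,
    seed: int = 0,
) -> GeometryTrace:
    """Distance between familiar and unfamiliar response centroids over time.

    Computed in per-cell z-scored population space on trial-averaged per-face
    responses.  ``null_level`` carries the matched-size unfamiliar-subset control
    (averaged over draws); ``extras['debiased']`` holds
    sqrt(max(0, value^2 - control^2)), an estimate of the true shift norm with
    the centroid sampling noise (shared by both curves) removed.
    """
    labels = np.asarray(familiar, dtype=bool)
    n_fam = int(labels.sum())
    unfam_idx = np.flatnonzero(~labels)
    if n_fam == 0 or len(unfam_idx) <= n_fam:
        raise InsufficientDataError("need familiar faces and a larger unfamiliar pool")
    rng = np.random.default_rng(seed)
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, values, sems, controls, control_sems, debiased = [], [], [], [], [], []
    for label, t0, t1 in wins:
        rates = window_response(tensor, t0, t1).T  # faces x cells
        Xz, _, _ = _zscore_cells(rates)
        d_fam = float(np.linalg.norm(Xz[labels].mean(0) - Xz[~labels].mean(0)))
        ctrl = []
        for _ in range(n_control):
            sub = rng.choice(unfam_idx, size=n_fam, replace=False)
            rest = np.setdiff1d(unfam_idx, sub)
            ctrl.append(float(np.linalg.norm(Xz[sub].mean(0) - Xz[rest].mean(0))))
        boot = []
        for _ in range(n_boot):
            bf = rng.choice(np.flatnonzero(labels), size=n_fam, replace=True)
            bu = rng.choice(unfam_idx, size=len(unfam_idx), replace=True)
            boot.append(float(np.linalg.norm(Xz[bf].mean(0) - Xz[bu].mean(0))))
        times.append(label)
        values.append(d_fam)
        sems.append(float(np.std(boot)))
        c = float(np.mean(ctrl))
        controls.append(c)
        control_sems.append(float(np.std(ctrl) / np.sqrt(n_control)))
        debiased.append(float(np.sqrt(max(0.0, d_fam**2 - c**2))))
    return GeometryTrace(
        np.array(times), np.array(values), np.array(sems),
        null_level=np.array(controls), method_tag="centroid_distance",
        extras={"control_sem": np.array(control_sems),
                "debiased": np.array(debiased)},
    )


@dataclass
class DPrimeResult:
    """Cross-validated d-prime along the centroid-difference axis."""

    dprime: float
    p_value: float
    null_quantiles: dict
    n: int


def dprime_from_matrix(
    X: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> DPrimeResult:
    """Cross-validated d' along the class-centroid axis.

    For every sample, the centroid-difference direction is estimated with that
    sample left out (leave-one-out training split) and the held-out sample is
    projected onto the unit axis; d' = |mu_F - mu_U| / sqrt((var_F + var_U) / 2)
    over the held-out projections.  Leave-one-out keeps the axis independent of
    the projected sample (no selection bias) without split randomness.  The null
    distribution repeats the identical procedure with shuffled labels.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InsufficientDataError("both classes required")
    rng = np.random.default_rng(seed)

    def one(lbl: np.ndarray) -> float:
        pos = X[lbl]
        neg = X[~lbl]
        nf, nu = len(pos), len(neg)
        if nf < 4 or nu < 4:
            raise InsufficientDataError("need >= 4 samples per class")
        mu_f = pos.mean(0)
        mu_u = neg.mean(0)
        a = mu_f - mu_u
        # leaving out familiar face i: axis_i = a + (mu_f - x_i)/(nf - 1)
        axes_f = a[None, :] + (mu_f[None, :] - pos) / (nf - 1)
        # leaving out unfamiliar face j: axis_j = a + (x_j - mu_u)/(nu - 1)
        axes_u = a[None, :] + (neg - mu_u[None, :]) / (nu - 1)
        norm_f = np.linalg.norm(axes_f, axis=1)
        norm_u = np.linalg.norm(axes_u, axis=1)
        if np.any(norm_f == 0) or np.any(norm_u == 0):
            return 0.0
        proj_f = np.sum(pos * axes_f, axis=1) / norm_f
        proj_u = np.sum(neg * axes_u, axis=1) / norm_u
        pooled = 0.5 * (proj_f.var(ddof=1) + proj_u.var(ddof=1))
        if pooled <= 0:
            return 0.0
        return float(abs(proj_f.mean() - proj_u.mean()) / np.sqrt(pooled))

    obs = one(labels)
    null = np.array([one(rng.permutation(labels)) for _ in range(n_shuffles)])
    p = float((1 + np.sum(null >= obs)) / (1 + n_shuffles))
    qs = {q: float(np.quantile(null, q)) for q in (0.5, 0.95, 0.99)}
    return DPrimeResult(dprime=obs, p_value=p, null_quantiles=qs, n=len(labels))


def dprime_along_centroid(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    window: tuple[float, float],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> DPrimeResult:
    """d' between familiar and unfamiliar per-face responses in one window."""
    rates = window_response(tensor, *window).T
    Xz, _, _ = _zscore_cells(rates)
    return dprime_from_matrix(Xz, familiar, n_shuffles=n_shuffles, seed=seed)


def dprime_trace(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    width_ms: int = 50,
    step_ms: int = 10,
    n_shuffles: int = 200,
    alpha: float = 0.01,
    consecutive: int = 2,
    seed: int = 0,
) -> GeometryTrace:
    """Time-resolved d' with its shuffle null; latency = first significant window."""
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, values, nulls, pvals = [], [], [], []
    for i, (label, t0, t1) in enumerate(wins):
        res = dprime_along_centroid(tensor, familiar, (t0, t1),
                                    n_shuffles=n_shuffles, seed=seed + i)
        times.append(label)
        values.append(res.dprime)
        nulls.append(res.null_quantiles[0.99])
        pvals.append(res.p_value)
    times = np.array(times)
    pvals = np.array(pvals)
    latency = latency_from_pvalues(times, pvals, alpha, consecutive)
    return GeometryTrace(
        times, np.array(values), np.zeros(len(times)),
        null_level=np.array(nulls), latency_ms=latency, pvalues=pvals,
        method_tag="dprime_along_centroid",
    )


# ---------------------------------------------------------------------------
# per-cell rate shifts and axis orthogonality


@dataclass
class RateShiftResult:
    """Per-cell familiar-minus-unfamiliar mean-rate differences per window."""

    windows: list
    diffs: np.ndarray        # windows x cells (Hz)
    pvalues: np.ndarray      # windows x cells, per-cell two-tailed test
    significant: np.ndarray  # windows x cells bool
    population_p: np.ndarray  # signed-rank test per window
    alpha: float


def rate_shift_distribution(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    windows: list[tuple[float, float]],
    alpha: float = 0.01,
) -> RateShiftResult:
    """Distribution of per-cell familiar-unfamiliar rate differences per window."""
    labels = np.asarray(familiar, dtype=bool)
    diffs, pvals, pops = [], [], []
    for t0, t1 in windows:
        rates = window_response(tensor, t0, t1)
        fam = rates[:, labels]
        unf = rates[:, ~labels]
        diff = np.nanmean(fam, axis=1) - np.nanmean(unf, axis=1)
        _, p = stats.ttest_ind(fam, unf, axis=1, equal_var=False,
                               nan_policy="omit")
        finite = diff[np.isfinite(diff)]
        nonzero = finite[finite != 0]
        pop = (stats.wilcoxon(nonzero)[1] if len(nonzero) >= 10 else np.nan)
        diffs.append(diff)
        pvals.append(np.asarray(p))
        pops.append(pop)
    diffs = np.array(diffs)
    pvals = np.array(pvals)
    return RateShiftResult(
        windows=list(windows), diffs=diffs, pvalues=pvals,
        significant=pvals < alpha, population_p=np.array(pops), alpha=alpha,
    )


def familiarity_axis_orthogonality(
    classifier: DecoderModel, feature_decoder: DecoderModel
) -> np.ndarray:
    """Cosine, in cell space, of the familiarity axis with each feature axis."""
    if classifier.weights.shape[1] != feature_decoder.weights.shape[1]:
        raise ValueError("decoders must share the cell population")
    w = classifier.unit_weights[0]
    return feature_decoder.unit_weights @ w


# ---------------------------------------------------------------------------
# two-condition contrasts


@dataclass
class ConditionContrast:
    """Normalized rate changes between two conditions, per cell and class."""

    change_familiar: np.ndarray    # per cell, (B - A) / (B + A)
    change_unfamiliar: np.ndarray
    paired_t: float
    paired_p: float
    comparison_a: object | None = None  # AxisComparison per condition, if faces given
    comparison_b: object | None = None


def condition_contrast(
    tensor_a: ResponseTensor,
    tensor_b: ResponseTensor,
    familiar: np.ndarray,
    window: tuple[float, float] = (50, 300),
    faces: FaceSet | None = None,
    axis_window: tuple[float, float] | None = None,
    seed: int = 0,
) -> ConditionContrast:
    """Per-cell normalized rate change (B - A)/(B + A) for each familiarity class.

    The paired test asks whether familiar and unfamiliar responses changed
    differently.  When ``faces`` is given, the UU/UF axis comparison is re-run in
    both conditions (``axis_window`` defaults to ``window``).
    """
    labels = np.asarray(familiar, dtype=bool)

    def class_rates(tensor):
        r = window_response(tensor, *window)
        return np.nanmean(r[:, labels], axis=1), np.nanmean(r[:, ~labels], axis=1)

    fam_a, unf_a = class_rates(tensor_a)
    fam_b, unf_b = class_rates(tensor_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ch_f = (fam_b - fam_a) / (fam_b + fam_a)
        ch_u = (unf_b - unf_a) / (unf_b + unf_a)
    ok = np.isfinite(ch_f) & np.isfinite(ch_u)
    t, p = stats.ttest_rel(ch_f[ok], ch_u[ok])
    cmp_a = cmp_b = None
    if faces is not None:
        aw = axis_window if axis_window is not None else window
        cmp_a = uu_uf_comparison(tensor_a, faces, aw, seed=seed, corrected=False)
        cmp_b = uu_uf_comparison(tensor_b, faces, aw, seed=seed + 1, corrected=False)
    return ConditionContrast(
        change_familiar=ch_f, change_unfamiliar=ch_u,
        paired_t=float(t), paired_p=float(p),
        comparison_a=cmp_a, comparison_b=cmp_b,
    )
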