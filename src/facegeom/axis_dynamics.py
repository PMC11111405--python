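"""Comparing preferred axes across stimulus sets and time.

The central statistic contrasts, per cell, the cosine similarity between axes fit
on disjoint unfamiliar face sets (UU, the noise ceiling) with the similarity
between an unfamiliar-fit axis and a familiar-fit axis (UF).  A UF deficit that
emerges at long latency is the signature of memory-driven axis rotation.

Two flavors of the per-cell similarity are computed:

* raw cosines (matched-n, resampled) — the primary statistic; and
* reliability-corrected cosines (split-half, Spearman attenuation-corrected) —
  used by the gain/contrast and nonlinearity controls, where the probe set's
  fits have a different SNR by construction and raw cosines would conflate
  reliability with axis direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .axis_model import AxisFit, fit_axes_matrix
from .response_core import (
    GeometryTrace,
    InsufficientDataError,
    ResponseTensor,
    latency_from_pvalues,
    rolling_windows,
    window_response_per_trial,
)
from .synthetic_data import FaceSet

__all__ = [
    "AxisComparison",
    "axis_similarity",
    "uu_uf_comparison",
    "time_resolved_axis_similarity",
    "contrast_control",
    "cross_context_axis_stability",
    "ContextStability",
    "fit_gain_model",
    "fit_subset_model",
    "fit_nonlinearity_model",
    "fit_refit_model",
    "model_comparison",
    "ModelComparison",
    "MODEL_ORDER",
]


def axis_similarity(fit_a: AxisFit, fit_b: AxisFit) -> float:
    """Cosine similarity of two unit-normalized preferred axes."""
    if fit_a.coefficients.shape != fit_b.coefficients.shape:
        raise ValueError("axes must share feature dimensionality")
    return float(fit_a.unit_axis @ fit_b.unit_axis)


MIN_RELIABILITY_PRODUCT = 0.05


@dataclass
class AxisComparison:
    """Per-cell UU and UF cosine similarities plus the population test.

    ``p_value`` is the one-tailed paired t-test of UU > UF on raw cosines;
    ``p_corrected`` the same test on reliability-corrected cosines (cells
    below the reliability floor excluded).  Raw cosines carry the noise
    ceiling and the cos(angle) relation; the corrected test is the calibrated
    significance decision, because a fixed probe design's conditioning shifts
    raw attenuation identically across cells and the paired raw test mistakes
    that for an axis change.
    """

    uu: np.ndarray
    uf: np.ndarray
    t_stat: float
    p_value: float
    n_cells: int
    window: tuple[float, float]
    uu_corrected: np.ndarray | None = None
    uf_corrected: np.ndarray | None = None
    t_corrected: float = np.nan
    p_corrected: float = np.nan

    @property
    def uu_mean(self) -> float:
        return float(np.nanmean(self.uu))

    @property
    def uf_mean(self) -> float:
        return float(np.nanmean(self.uf))

    @property
    def test_pvalue(self) -> float:
        """Headline UU > UF significance: corrected when available, else raw."""
        return self.p_corrected if np.isfinite(self.p_corrected) else self.p_value


def _row_cosines(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.sum(a * b, axis=1)
    den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _fit_axes_on(per_trial, features, face_idx, trial_idx, ridge):
    """Trial-average the chosen trials, then fit all cells' axes at once."""
    sub = per_trial[:, face_idx][:, :, trial_idx]
    with np.errstate(invalid="ignore"):
        rates = np.nanmean(sub, axis=2)
    rates = np.nan_to_num(rates)
    coefs, *_ = fit_axes_matrix(rates, features[face_idx], ridge)
    return coefs


def _paired_onetail(uu: np.ndarray, uf: np.ndarray) -> tuple[float, float]:
    diff = uu - uf
    diff = diff[np.isfinite(diff)]
    if len(diff) < 3:
        return np.nan, np.nan
    t, p = stats.ttest_1samp(diff, 0.0, alternative="greater")
    return float(t), float(p)


def uu_uf_comparison(
    tensor: ResponseTensor,
    faces: FaceSet,
    window: tuple[float, float],
    n_heldout: int = 36,
    n_resamples: int = 20,
    seed: int = 0,
    ridge: float | None = None,
    probe_mask: np.ndarray | None = None,
    corrected: bool = True,
) -> AxisComparison:
    """Compare noise-ceiling (UU) and cross-set (UF) axis similarities.

    Per resample: hold out ``n_heldout`` unfamiliar faces; fit each cell's
    reference axis on the remaining unfamiliar pool, and probe axes on (a) the
    held-out unfamiliar faces and (b) a matched-size draw of the probe set
    (familiar faces by default, or ``probe_mask``).  Cosines are averaged over
    resamples per cell; the population test is a one-tailed paired t-test of
    UU > UF across cells.
    """
    probe = (np.asarray(probe_mask, dtype=bool) if probe_mask is not None
             else faces.familiar)
    unfam_idx = np.flatnonzero(~faces.familiar & ~probe)
    probe_idx = np.flatnonzero(probe)
    if len(probe_idx) < n_heldout or len(unfam_idx) < 2 * n_heldout:
        raise InsufficientDataError(
            f"need >= {n_heldout} probe and >= {2 * n_heldout} unfamiliar faces"
        )
    rng = np.random.default_rng(seed)
    per_trial = window_response_per_trial(tensor, *window)
    n_trials = per_trial.shape[2]
    feats = faces.features

    uu = np.zeros((tensor.n_cells, n_resamples))
    uf = np.zeros_like(uu)
    can_correct = corrected and n_trials >= 2
    if can_correct:
        uu_c = np.zeros_like(uu)
        uf_c = np.zeros_like(uu)
    for r in range(n_resamples):
        held = rng.choice(unfam_idx, size=n_heldout, replace=False)
        ref_idx = np.setdiff1d(unfam_idx, held)
        p_idx = (probe_idx if len(probe_idx) == n_heldout
                 else rng.choice(probe_idx, size=n_heldout, replace=False))
        all_trials = np.arange(n_trials)
        ref = _fit_axes_on(per_trial, feats, ref_idx, all_trials, ridge)
        ax_h = _fit_axes_on(per_trial, feats, held, all_trials, ridge)
        ax_p = _fit_axes_on(per_trial, feats, p_idx, all_trials, ridge)
        uu[:, r] = _row_cosines(ref, ax_h)
        uf[:, r] = _row_cosines(ref, ax_p)
        if can_correct:
            perm = rng.permutation(n_trials)
            h1, h2 = perm[: n_trials // 2], perm[n_trials // 2:]
            ref1 = _fit_axes_on(per_trial, feats, ref_idx, h1, ridge)
            ref2 = _fit_axes_on(per_trial, feats, ref_idx, h2, ridge)
            held1 = _fit_axes_on(per_trial, feats, held, h1, ridge)
            held2 = _fit_axes_on(per_trial, feats, held, h2, ridge)
            p1 = _fit_axes_on(per_trial, feats, p_idx, h1, ridge)
            p2 = _fit_axes_on(per_trial, feats, p_idx, h2, ridge)
            rel_ref = _row_cosines(ref1, ref2)
            rel_h = _row_cosines(held1, held2)
            rel_p = _row_cosines(p1, p2)
            num_uu = 0.5 * (_row_cosines(ref1, held2) + _row_cosines(ref2, held1))
            num_uf = 0.5 * (_row_cosines(ref1, p2) + _row_cosines(ref2, p1))
            # reliability floor: ratio estimates are meaningless for cells whose
            # split-half axes are essentially noise
            with np.errstate(invalid="ignore"):
                prod_uu = rel_ref * rel_h
                prod_uf = rel_ref * rel_p
                den_uu = np.sqrt(np.where(prod_uu > MIN_RELIABILITY_PRODUCT,
                                          prod_uu, np.nan))
                den_uf = np.sqrt(np.where(prod_uf > MIN_RELIABILITY_PRODUCT,
                                          prod_uf, np.nan))
            uu_c[:, r] = np.clip(num_uu / den_uu, -3.0, 3.0)
            uf_c[:, r] = np.clip(num_uf / den_uf, -3.0, 3.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        uu_cell = np.nanmean(uu, axis=1)
        uf_cell = np.nanmean(uf, axis=1)
    t, p = _paired_onetail(uu_cell, uf_cell)
    out = AxisComparison(
        uu=uu_cell, uf=uf_cell, t_stat=t, p_value=p,
        n_cells=tensor.n_cells, window=window,
    )
    if can_correct:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            out.uu_corrected = np.nanmean(uu_c, axis=1)
            out.uf_corrected = np.nanmean(uf_c, axis=1)
        out.t_corrected, out.p_corrected = _paired_onetail(
            out.uu_corrected, out.uf_corrected
        )
    return out


def time_resolved_axis_similarity(
    tensor: ResponseTensor,
    faces: FaceSet,
    step_ms: int = 10,
    width_ms: int = 50,
    alpha: float = 0.001,
    n_heldout: int = 36,
    n_resamples: int = 10,
    seed: int = 0,
    ridge: float | None = None,
    consecutive: int = 2,
) -> tuple[GeometryTrace, GeometryTrace, int | None]:
    """UU and UF cosine-similarity traces over causal rolling windows.

    The divergence latency is the first window (trailing-edge label) whose
    one-tailed UU > UF p-value is below ``alpha`` for ``consecutive`` windows.
    Significance uses the reliability-corrected comparison (the raw paired test
    confounds a fixed probe design's attenuation with an axis change); the
    traces report the raw cosines.
    """
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, uu_m, uu_s, uf_m, uf_s, pvals, pvals_raw = [], [], [], [], [], [], []
    for i, (label, t0, t1) in enumerate(wins):
        cmp_ = uu_uf_comparison(
            tensor, faces, (t0, t1), n_heldout=n_heldout,
            n_resamples=n_resamples, seed=seed + 7919 * i, ridge=ridge,
            corrected=True,
        )
        times.append(label)
        uu_m.append(np.nanmean(cmp_.uu))
        uu_s.append(stats.sem(cmp_.uu, nan_policy="omit"))
        uf_m.append(np.nanmean(cmp_.uf))
        uf_s.append(stats.sem(cmp_.uf, nan_policy="omit"))
        pvals.append(cmp_.test_pvalue)
        pvals_raw.append(cmp_.p_value)
    times = np.array(times)
    pvals = np.array(pvals)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    latency = latency_from_pvalues(times, pvals, alpha, consecutive)
    uu_trace = GeometryTrace(times, np.array(uu_m), np.array(uu_s),
                             method_tag="axis_similarity_uu")
    uf_trace = GeometryTrace(times, np.array(uf_m), np.array(uf_s),
                             latency_ms=latency, pvalues=pvals,
                             method_tag="axis_similarity_uf",
                             extras={"pvalues_raw": np.array(pvals_raw)})
    return uu_trace, uf_trace, latency


def contrast_control(
    tensor: ResponseTensor,
    faces: FaceSet,
    probe_mask: np.ndarray,
    window: tuple[float, float],
    n_heldout: int = 36,
    n_resamples: int = 20,
    seed: int = 0,
    ridge: float | None = None,
) -> AxisComparison:
    """UU-vs-probe axis comparison for a gain/contrast control set.

    Same machinery as :func:`uu_uf_comparison` with the probe set (for example
    low-contrast faces) in place of the familiar set.  The decision statistic for
    this control is the reliability-corrected comparison (``p_corrected``): a
    pure response-gain change alters the probe fits' SNR, and only the corrected
    cosines isolate a change of axis *direction*.
    """
    return uu_uf_comparison(
        tensor, faces, window, n_heldout=n_heldout, n_resamples=n_resamples,
        seed=seed, ridge=ridge, probe_mask=probe_mask, corrected=True,
    )


@dataclass
class ContextStability:
    """UF-deficit and mean-rate statistics replicated across two contexts."""

    comparison_a: AxisComparison
    comparison_b: AxisComparison
    rate_diff_a: float  # mean familiar - unfamiliar rate (Hz), context A
    rate_diff_b: float
    rate_p_a: float
    rate_p_b: float

    @property
    def sign_flip(self) -> bool:
        return self.rate_diff_a * self.rate_diff_b < 0

    def uf_deficit_in_both(self, alpha: float = 0.05) -> bool:
        return self.comparison_a.p_value < alpha and self.comparison_b.p_value < alpha


def _mean_rate_difference(tensor, faces, window):
    from .response_core import window_response

    rates = window_response(tensor, *window)
    fam = faces.familiar
    diff = np.nanmean(rates[:, fam], axis=1) - np.nanmean(rates[:, ~fam], axis=1)
    t, p = stats.ttest_1samp(diff[np.isfinite(diff)], 0.0)
    return float(np.nanmean(diff)), float(p)


def cross_context_axis_stability(
    tensor_a: ResponseTensor,
    faces_a: FaceSet,
    tensor_b: ResponseTensor,
    faces_b: FaceSet,
    axis_window: tuple[float, float],
    rate_window: tuple[float, float] = (50, 300),
    n_heldout: int = 36,
    n_resamples: int = 20,
    seed: int = 0,
    ridge: float | None = None,
) -> ContextStability:
    """Test whether the UF axis deficit replicates across two presentation
    contexts while the familiar-unfamiliar mean-rate difference may flip sign."""
    cmp_a = uu_uf_comparison(tensor_a, faces_a, axis_window, n_heldout=n_heldout,
                             n_resamples=n_resamples, seed=seed, ridge=ridge,
                             corrected=False)
    cmp_b = uu_uf_comparison(tensor_b, faces_b, axis_window, n_heldout=n_heldout,
                             n_resamples=n_resamples, seed=seed + 1, ridge=ridge,
                             corrected=False)
    diff_a, p_a = _mean_rate_difference(tensor_a, faces_a, rate_window)
    diff_b, p_b = _mean_rate_difference(tensor_b, faces_b, rate_window)
    return ContextStability(cmp_a, cmp_b, diff_a, diff_b, p_a, p_b)


# ---------------------------------------------------------------------------
# alternative single-cell models for the familiar-face response change


MODEL_ORDER = ("gain", "nonlinearity", "subset", "refit")  # simplest first


def _cv_r2(x_fit, predict, y: np.ndarray, n_folds: int, seed: int) -> tuple[float, float]:
    """Cross-validated R^2 (per-fold mean and SE) for a fit/predict pair."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(y):
        model = x_fit(tr)
        pred = predict(model, te)
        ss_res = np.sum((y[te] - pred) ** 2)
        ss_tot = np.sum((y[te] - np.mean(y[tr])) ** 2)
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(n_folds))


def fit_gain_model(
    responses: np.ndarray, features_std: np.ndarray, ref_axis: np.ndarray,
    n_folds: int = 5, seed: int = 0,
) -> dict:
    """r_fam = alpha * (c.f) + beta along the fixed reference axis."""
    x = features_std @ (ref_axis / np.linalg.norm(ref_axis))
    y = np.asarray(responses, dtype=float)
    if len(y) < n_folds:
        raise InsufficientDataError("fewer familiar faces than folds")

    def fit(tr):
        return np.polyfit(x[tr], y[tr], 1)

    def predict(m, te):
        return np.polyval(m, x[te])

    r2, se = _cv_r2(fit, predict, y, n_folds, seed)
    coef = np.polyfit(x, y, 1)
    return {"model": "gain", "cv_r2": r2, "cv_se": se,
            "alpha": float(coef[0]), "beta": float(coef[1])}


def fit_nonlinearity_model(
    responses: np.ndarray, features_std: np.ndarray, ref_axis: np.ndarray,
    n_folds: int = 5, seed: int = 0,
) -> dict:
    """r_fam = h(c.f) with h monotone (isotonic), direction set by the data."""
    x = features_std @ (ref_axis / np.linalg.norm(ref_axis))
    y = np.asarray(responses, dtype=float)
    if len(y) < n_folds:
        raise InsufficientDataError("fewer familiar faces than folds")
    increasing = bool(np.corrcoef(x, y)[0, 1] >= 0)

    def fit(tr):
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        iso.fit(x[tr], y[tr])
        return iso

    def predict(m, te):
        return m.predict(x[te])

    r2, se = _cv_r2(fit, predict, y, n_folds, seed)
    return {"model": "nonlinearity", "cv_r2": r2, "cv_se": se,
            "increasing": increasing}


def fit_subset_model(
    responses: np.ndarray, features_std: np.ndarray, ref_axis: np.ndarray,
    n_folds: int = 5, seed: int = 0, l1: float = 0.05,
) -> dict:
    """r_fam = (c (.) m).f + beta with m >= 0 a sparse per-feature sensitivity."""
    unit = ref_axis / np.linalg.norm(ref_axis)
    Z = features_std * unit[None, :]
    y = np.asarray(responses, dtype=float)
    if len(y) < n_folds:
        raise InsufficientDataError("fewer familiar faces than folds")
    scale = np.std(y) if np.std(y) > 0 else 1.0

    def fit(tr):
        las = Lasso(alpha=l1 * scale, positive=True, max_iter=10000)
        las.fit(Z[tr], y[tr])
        return las

    def predict(m, te):
        return m.predict(Z[te])

    r2, se = _cv_r2(fit, predict, y, n_folds, seed)
    final = Lasso(alpha=l1 * scale, positive=True, max_iter=10000).fit(Z, y)
    return {"model": "subset", "cv_r2": r2, "cv_se": se,
            "sensitivity": final.coef_.copy()}


def fit_refit_model(
    responses: np.ndarray, features_std: np.ndarray, ref_axis: np.ndarray,
    n_folds: int = 5, seed: int = 0, ridge: float = 1e-2,
) -> dict:
    """Free re-fit of the full axis on the familiar set (most flexible model)."""
    y = np.asarray(responses, dtype=float)
    d = features_std.shape[1]
    if len(y) < n_folds:
        raise InsufficientDataError("fewer familiar faces than folds")

    def fit(tr):
        X = features_std[tr]
        lam = ridge * np.trace(X.T @ X) / d
        yc = y[tr] - y[tr].mean()
        c = np.linalg.solve(X.T @ X + lam * np.eye(d), X.T @ yc)
        return c, y[tr].mean()

    def predict(m, te):
        c, b = m
        return features_std[te] @ c + b

    r2, se = _cv_r2(fit, predict, y, n_folds, seed)
    return {"model": "refit", "cv_r2": r2, "cv_se": se}


@dataclass
class ModelComparison:
    """Per-cell model-selection outcome across the four candidate families."""

    per_cell: list = field(default_factory=list)
    selected: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def counts(self) -> dict:
        vals, cnts = np.unique(self.selected, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


def model_comparison(
    responses_fam: np.ndarray,
    features_fam: np.ndarray,
    ref_axes: np.ndarray,
    feature_center: np.ndarray,
    feature_scale: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> ModelComparison:
    """Fit all four models per cell and select by the one-standard-error rule.

    The simplest model (gain < nonlinearity < subset < refit) whose CV R^2 is
    within one SE of the best model's CV R^2 is selected.
    """
    feats_std = (features_fam - feature_center) / feature_scale
    fitters = {
        "gain": fit_gain_model, "nonlinearity": fit_nonlinearity_model,
        "subset": fit_subset_model, "refit": fit_refit_model,
    }
    out = ModelComparison()
    selected = []
    for i in range(responses_fam.shape[0]):
        fits = {
            name: fn(responses_fam[i], feats_std, ref_axes[i], n_folds, seed)
            for name, fn in fitters.items()
        }
        best = max(fits.values(), key=lambda f: f["cv_r2"])
        threshold = best["cv_r2"] - best["cv_se"]
        pick = next(n for n in MODEL_ORDER if fits[n]["cv_r2"] >= threshold)
        fits["selected"] = pick
        out.per_cell.append(fits)
        selected.append(pick)
    out.selected = np.array(selected)
    return out
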