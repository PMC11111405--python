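"""Per-cell preferred-axis estimation for the linear face code r = c.f + c0.

Axes are fit by (optionally ridge-regularized) least squares of trial-averaged
window rates on column-standardized face features.  The standardization is
computed on the fitting set only and retained, so coefficients from different
fits live in comparable per-s.d. feature units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .response_core import (
    InsufficientDataError,
    ResponseTensor,
    window_response,
    window_response_per_trial,
)
from .synthetic_data import FaceSet

__all__ = [
    "AxisFit",
    "fit_axis",
    "fit_axes_matrix",
    "split_half_axis_consistency",
    "tuning_curve",
    "TuningCurve",
]


@dataclass
class AxisFit:
    """A fitted preferred axis for one cell."""

    cell_id: str
    coefficients: np.ndarray  # Hz per feature s.d.
    offset: float             # Hz; intercept on the raw feature scale
    window: tuple[float, float] | None
    r_squared: float
    n_faces_fit: int
    split_half: float | None = None
    feature_center: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    @property
    def unit_axis(self) -> np.ndarray:
        norm = np.linalg.norm(self.coefficients)
        if norm == 0:
            raise ValueError("zero coefficient vector has no direction")
        return self.coefficients / norm

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.feature_center is not None:
            # offset is the raw-feature intercept; undo the standardization
            return ((features / self.feature_scale) @ self.coefficients
                    + self.offset)
        return features @ self.coefficients + self.offset


def _standardize(features: np.ndarray):
    center = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (features - center) / scale, center, scale


def fit_axes_matrix(
    rates: np.ndarray,
    features: np.ndarray,
    ridge: float | None = None,
):
    """Fit preferred axes for many cells at once.

    rates: cells x faces trial-averaged responses; features: faces x d.
    ridge is an absolute penalty added as ``ridge * mean diag(X'X)`` per
    coefficient (trace-scaled); None uses the 1e-6 default, 0 requests plain OLS
    and raises on rank deficiency.

    Returns (coefs cells x d, offsets, r_squared, center, scale).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    X, center, scale = _standardize(np.asarray(features, dtype=float))
    n, d = X.shape
    if n < d + 2:
        raise InsufficientDataError(f"need at least d + 2 = {d + 2} faces, got {n}")
    if ridge is None:
        ridge = 1e-6
    gram = X.T @ X
    if ridge == 0 and np.linalg.matrix_rank(gram) < d:
        raise np.linalg.LinAlgError(
            "rank-deficient design; pass ridge > 0 to regularize"
        )
    lam = ridge * np.trace(gram) / d
    means = rates.mean(axis=1)
    yc = rates - means[:, None]
    coefs = np.linalg.solve(gram + lam * np.eye(d), X.T @ yc.T).T
    pred = coefs @ X.T
    ss_res = np.sum((yc - pred) ** 2, axis=1)
    ss_tot = np.sum(yc ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    # report the intercept on the raw feature scale (coefficients stay in
    # per-s.d. units): c0 = mean rate - c . (center / scale)
    offsets = means - coefs @ (center / scale)
    return coefs, offsets, np.clip(r2, 0.0, 1.0), center, scale


def fit_axis(
    responses: np.ndarray,
    faces: FaceSet,
    ridge: float | None = None,
    cell_id: str = "cell",
    window: tuple[float, float] | None = None,
) -> AxisFit:
    """Fit one cell's preferred axis from per-face mean rates."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (faces.n_faces,):
        raise ValueError("responses must be one mean rate per face")
    coefs, offsets, r2, center, scale = fit_axes_matrix(
        responses[None, :], faces.features, ridge
    )
    return AxisFit(
        cell_id=cell_id, coefficients=coefs[0], offset=float(offsets[0]),
        window=window, r_squared=float(r2[0]), n_faces_fit=faces.n_faces,
        feature_center=center, feature_scale=scale,
    )


def split_half_axis_consistency(
    tensor: ResponseTensor,
    faces: FaceSet,
    window: tuple[float, float],
    n_splits: int = 10,
    seed: int = 0,
    ridge: float | None = None,
) -> dict:
    """Cosine similarity of axes fit on random trial split halves, per cell.

    Returns per-cell per-split cosines plus mean and a normal-theory 95% CI.
    """
    per_trial = window_response_per_trial(tensor, *window)  # cells x faces x trials
    n_valid = np.sum(np.isfinite(per_trial[0]), axis=1)
    if np.any(n_valid < 2):
        raise InsufficientDataError("every face needs >= 2 trials for split halves")
    rng = np.random.default_rng(seed)
    n_trials = per_trial.shape[2]
    cosines = np.empty((tensor.n_cells, n_splits))
    for s in range(n_splits):
        halves = []
        perm = rng.permutation(n_trials)
        split_sets = (perm[: n_trials // 2], perm[n_trials // 2:])
        for idx in split_sets:
            with np.errstate(invalid="ignore"):
                rates = np.nanmean(per_trial[:, :, idx], axis=2)
            coefs, *_ = fit_axes_matrix(rates, faces.features, ridge)
            halves.append(coefs)
        a, b = halves
        num = np.sum(a * b, axis=1)
        den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        cosines[:, s] = num / den
    mean = cosines.mean(axis=1)
    half_ci = 1.96 * cosines.std(axis=1, ddof=1) / np.sqrt(n_splits)
    return {
        "cosines": cosines,
        "mean": mean,
        "ci_low": mean - half_ci,
        "ci_high": mean + half_ci,
    }


@dataclass
class TuningCurve:
    """Binned ramp summary along a preferred axis."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray
    slope: float
    projections: np.ndarray
    orth_projections: np.ndarray
    responses: np.ndarray


def tuning_curve(
    fit: AxisFit,
    faces: FaceSet,
    responses: np.ndarray,
    n_points: int = 10,
) -> TuningCurve:
    """Mean response vs. projection on the preferred axis, in quantile bins.

    Also returns each face's coordinate on the principal orthogonal axis: the
    first principal direction of the features after removing the preferred-axis
    component.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    responses = np.asarray(responses, dtype=float)
    z = faces.features
    if fit.feature_center is not None:
        z = (z - fit.feature_center) / fit.feature_scale
    axis = fit.unit_axis
    proj = z @ axis
    resid = z - np.outer(proj, axis)
    _, _, vt = np.linalg.svd(resid - resid.mean(axis=0), full_matrices=False)
    orth = resid @ vt[0]

    edges = np.quantile(proj, np.linspace(0, 1, n_points + 1))
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, proj, side="right") - 1, 0, n_points - 1)
    centers, means, sems = [], [], []
    for b in range(n_points):
        sel = which == b
        if not sel.any():
            continue
        centers.append(proj[sel].mean())
        means.append(responses[sel].mean())
        sems.append(responses[sel].std(ddof=1) / np.sqrt(sel.sum())
                    if sel.sum() > 1 else 0.0)
    slope = float(np.polyfit(proj, responses, 1)[0])
    return TuningCurve(
        bin_centers=np.array(centers), bin_means=np.array(means),
        bin_sems=np.array(sems), slope=slope, projections=proj,
        orth_projections=orth, responses=responses,
    )
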