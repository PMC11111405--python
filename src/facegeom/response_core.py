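"""Spike-count tensors, binning, window averages, normalization, and latency statistics.

The central container is :class:`ResponseTensor`, a cells x faces x trials x bins
spike-count array with explicit binning metadata and a trial mask (absent trials are
masked, never encoded as zeros).  Time is in milliseconds relative to stimulus onset
at 0; bins are half-open ``[t, t + bin_ms)``.

Latency statistics use causal rolling windows ``[t - width, t)`` labeled by their
trailing edge ``t``, so a detected latency is an upper bound on the true onset of the
underlying effect rather than pre-dating it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseTensor",
    "GeometryTrace",
    "Normalized",
    "InsufficientDataError",
    "bin_spikes",
    "read_spike_table",
    "write_spike_table",
    "window_response",
    "window_response_per_trial",
    "normalize_per_cell",
    "rolling_windows",
    "latency_from_pvalues",
    "response_latency",
    "divergence_latency",
    "save_tensor",
    "load_tensor",
]


class InsufficientDataError(ValueError):
    """Raised when an analysis has too few cells, trials or faces to proceed."""


@dataclass
class ResponseTensor:
    """Spike counts for a population: cells x faces x trials x time bins.

    ``mask[face, trial]`` is True where the trial was actually recorded; all
    per-trial averages respect the mask.  ``normalized`` flags real-valued
    (post-normalization) content.
    """

    counts: np.ndarray
    bin_ms: int
    t_start_ms: int
    t_end_ms: int
    cell_ids: np.ndarray
    face_ids: np.ndarray
    mask: np.ndarray | None = None
    region_tag: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-d (cells, faces, trials, bins)")
        span = self.t_end_ms - self.t_start_ms
        if span <= 0 or span % self.bin_ms != 0:
            raise ValueError("bin_ms must evenly divide the time span")
        if span // self.bin_ms != self.counts.shape[3]:
            raise ValueError(
                f"expected {span // self.bin_ms} bins, got {self.counts.shape[3]}"
            )
        self.cell_ids = np.asarray(self.cell_ids)
        self.face_ids = np.asarray(self.face_ids)
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length mismatch")
        if len(self.face_ids) != self.counts.shape[1]:
            raise ValueError("face_ids length mismatch")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape[1:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape[1:3]:
                raise ValueError("mask must be (faces, trials)")
        if not self.normalized and np.any(self.counts < 0):
            raise ValueError("raw spike counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_faces(self) -> int:
        return self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[3]

    @property
    def bin_edges_ms(self) -> np.ndarray:
        return np.arange(self.t_start_ms, self.t_end_ms + self.bin_ms, self.bin_ms)

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.bin_edges_ms[:-1]


@dataclass
class GeometryTrace:
    """A time-resolved statistic with uncertainty, a null level, and a latency.

    ``times_ms`` are trailing edges of the causal rolling windows.  ``latency_ms``
    is None when the statistic never reached significance.
    """

    times_ms: np.ndarray
    value: np.ndarray
    sem: np.ndarray
    null_level: np.ndarray | float | None = None
    latency_ms: int | None = None
    method_tag: str = ""
    pvalues: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms)
        self.value = np.asarray(self.value, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError("sem must be nonnegative")
        if self.latency_ms is not None and self.latency_ms not in self.times_ms:
            raise ValueError("latency_ms must be a member of times_ms")


# ---------------------------------------------------------------------------
# binning and I/O


def bin_spikes(
    spike_table: pd.DataFrame,
    bin_ms: int,
    t_start_ms: int,
    t_end_ms: int,
    cell_ids: Sequence | None = None,
    face_ids: Sequence | None = None,
    n_trials: int | None = None,
) -> ResponseTensor:
    """Bin a long-format spike table into a ResponseTensor.

    The table needs columns cell_id, trial_id, face_id, spike_time_ms, where
    trial_id is a global presentation identifier (each trial_id shows exactly one
    face).  Spikes outside ``[t_start_ms, t_end_ms)`` are dropped.  Trials are
    mapped to per-face repetition slots in order of trial_id.
    """
    required = {"cell_id", "trial_id", "face_id", "spike_time_ms"}
    if not required.issubset(spike_table.columns):
        raise ValueError(f"spike table needs columns {sorted(required)}")
    times = pd.to_numeric(spike_table["spike_time_ms"], errors="coerce")
    if times.isna().any():
        raise ValueError("non-numeric spike times")
    span = t_end_ms - t_start_ms
    if span <= 0 or span % bin_ms != 0:
        raise ValueError("bin_ms must evenly divide the time span")

    trial_face = spike_table.groupby("trial_id")["face_id"].nunique()
    if (trial_face > 1).any():
        bad = trial_face[trial_face > 1].index.tolist()
        raise ValueError(f"trial_id(s) {bad} map to multiple face_ids")

    cells = np.asarray(cell_ids if cell_ids is not None
                       else sorted(spike_table["cell_id"].unique()))
    faces = np.asarray(face_ids if face_ids is not None
                       else sorted(spike_table["face_id"].unique()))
    cell_pos = {c: i for i, c in enumerate(cells)}
    face_pos = {f: i for i, f in enumerate(faces)}

    # per-face repetition slot, in trial_id order
    trial_to_face = spike_table.drop_duplicates("trial_id").set_index("trial_id")["face_id"]
    rep_of_trial: dict = {}
    per_face_count: dict = {}
    for tid in sorted(trial_to_face.index):
        f = trial_to_face.loc[tid]
        rep_of_trial[tid] = per_face_count.get(f, 0)
        per_face_count[f] = rep_of_trial[tid] + 1
    max_reps = n_trials if n_trials is not None else max(per_face_count.values(), default=1)

    n_bins = span // bin_ms
    counts = np.zeros((len(cells), len(faces), max_reps, n_bins), dtype=np.int32)
    mask = np.zeros((len(faces), max_reps), dtype=bool)
    for f, n in per_face_count.items():
        if f in face_pos:
            mask[face_pos[f], :min(n, max_reps)] = True

    t = times.to_numpy(dtype=float)
    keep = (t >= t_start_ms) & (t < t_end_ms)
    sub = spike_table.loc[keep]
    tb = ((t[keep] - t_start_ms) // bin_ms).astype(int)
    ci = sub["cell_id"].map(cell_pos).to_numpy()
    fi = sub["face_id"].map(face_pos).to_numpy()
    ri = sub["trial_id"].map(rep_of_trial).to_numpy()
    ok = ~(pd.isna(ci) | pd.isna(fi)) & (ri < max_reps)
    np.add.at(
        counts,
        (ci[ok].astype(int), fi[ok].astype(int), ri[ok].astype(int), tb[ok]),
        1,
    )
    return ResponseTensor(
        counts=counts, bin_ms=bin_ms, t_start_ms=t_start_ms, t_end_ms=t_end_ms,
        cell_ids=cells, face_ids=faces, mask=mask,
    )


def read_spike_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spike_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def save_tensor(tensor: ResponseTensor, prefix: str | Path) -> None:
    """Store a tensor as a flat text array plus a JSON sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".counts.txt"),
               tensor.counts.reshape(tensor.n_cells, -1), fmt="%g")
    meta = {
        "shape": list(tensor.counts.shape),
        "bin_ms": tensor.bin_ms,
        "t_start_ms": tensor.t_start_ms,
        "t_end_ms": tensor.t_end_ms,
        "cell_ids": [str(c) for c in tensor.cell_ids],
        "face_ids": [str(f) for f in tensor.face_ids],
        "mask": tensor.mask.astype(int).tolist(),
        "region_tag": tensor.region_tag,
        "normalized": tensor.normalized,
    }
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_tensor(prefix: str | Path) -> ResponseTensor:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    flat = np.loadtxt(prefix.with_suffix(".counts.txt"), ndmin=2)
    counts = flat.reshape(meta["shape"])
    if not meta["normalized"]:
        counts = counts.astype(np.int32)
    return ResponseTensor(
        counts=counts, bin_ms=meta["bin_ms"], t_start_ms=meta["t_start_ms"],
        t_end_ms=meta["t_end_ms"], cell_ids=np.array(meta["cell_ids"]),
        face_ids=np.array(meta["face_ids"]),
        mask=np.array(meta["mask"], dtype=bool),
        region_tag=meta["region_tag"], normalized=meta["normalized"],
    )


# ---------------------------------------------------------------------------
# windows and normalization


def _window_bins(tensor: ResponseTensor, t0_ms: float, t1_ms: float) -> np.ndarray:
    starts = tensor.bin_starts_ms
    sel = (starts >= t0_ms) & (starts + tensor.bin_ms <= t1_ms)
    if not sel.any():
        raise ValueError(f"window [{t0_ms}, {t1_ms}) contains no complete bin")
    return np.flatnonzero(sel)


def window_response_per_trial(
    tensor: ResponseTensor, t0_ms: float, t1_ms: float
) -> np.ndarray:
    """Per-trial firing rates (Hz) in ``[t0, t1)``: cells x faces x trials.

    Masked trials are NaN.
    """
    bins = _window_bins(tensor, t0_ms, t1_ms)
    seconds = len(bins) * tensor.bin_ms / 1000.0
    rate = tensor.counts[:, :, :, bins].sum(axis=3) / seconds
    rate = rate.astype(float)
    rate[:, ~tensor.mask] = np.nan
    return rate


def window_response(tensor: ResponseTensor, t0_ms: float, t1_ms: float) -> np.ndarray:
    """Trial-averaged firing rate (Hz) in ``[t0, t1)``: cells x faces."""
    per_trial = window_response_per_trial(tensor, t0_ms, t1_ms)
    with np.errstate(invalid="ignore"):
        return np.nanmean(per_trial, axis=2)


class Normalized(NamedTuple):
    """Per-cell normalized data plus the (invertible) normalization metadata."""

    values: np.ndarray
    kept: np.ndarray  # boolean over cells; False = degenerate, excluded
    center: np.ndarray
    scale: np.ndarray
    method: str


def normalize_per_cell(data: np.ndarray, method: str = "zscore") -> Normalized:
    """Normalize each cell (row / leading axis) across all its other axes.

    zscore: mean 0, s.d. 1 per cell; max: divide by per-cell max; none: identity.
    Zero-variance (or zero-max) cells are flagged in ``kept`` and their output row
    set to 0 rather than NaN.
    """
    if method not in {"zscore", "max", "none"}:
        raise ValueError("method must be one of zscore, max, none")
    data = np.asarray(data, dtype=float)
    flat = data.reshape(data.shape[0], -1)
    if method == "none":
        n = data.shape[0]
        return Normalized(data.copy(), np.ones(n, bool), np.zeros(n), np.ones(n), method)
    if method == "max":
        scale = np.nanmax(np.abs(flat), axis=1)
        kept = scale > 0
        safe = np.where(kept, scale, 1.0)
        out = data / safe.reshape((-1,) + (1,) * (data.ndim - 1))
        out[~kept] = 0.0
        return Normalized(out, kept, np.zeros(len(scale)), safe, method)
    center = np.nanmean(flat, axis=1)
    scale = np.nanstd(flat, axis=1)
    kept = scale > 0
    safe = np.where(kept, scale, 1.0)
    shape = (-1,) + (1,) * (data.ndim - 1)
    out = (data - center.reshape(shape)) / safe.reshape(shape)
    out[~kept] = 0.0
    return Normalized(out, kept, center, safe, method)


# ---------------------------------------------------------------------------
# rolling-window latency statistics


def rolling_windows(
    tensor: ResponseTensor, width_ms: int = 50, step_ms: int = 10
) -> list[tuple[int, int, int]]:
    """Causal rolling windows (label, t0, t1) with label = t1 (trailing edge)."""
    labels = np.arange(tensor.t_start_ms + width_ms, tensor.t_end_ms + 1, step_ms)
    return [(int(t), int(t - width_ms), int(t)) for t in labels]


def latency_from_pvalues(
    times_ms: np.ndarray, pvalues: np.ndarray, alpha: float, consecutive: int = 2
) -> int | None:
    """First time whose window starts a run of ``consecutive`` significant windows."""
    sig = np.asarray(pvalues) < alpha
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= consecutive:
            return int(times_ms[i - consecutive + 1])
    return None


def _paired_windows_trace(
    tensor: ResponseTensor,
    per_cell_stat,
    width_ms: int,
    step_ms: int,
    alpha: float,
    consecutive: int,
    alternative: str,
    method_tag: str,
) -> GeometryTrace:
    if tensor.n_cells < 3:
        raise InsufficientDataError("need at least 3 cells")
    wins = rolling_windows(tensor, width_ms, step_ms)
    times, values, sems, pvals, nulls = [], [], [], [], []
    for label, t0, t1 in wins:
        diff, null = per_cell_stat(t0, t1)
        diff = diff[np.isfinite(diff)]
        if len(diff) < 3:
            continue
        t_stat, p = stats.ttest_1samp(diff, 0.0, alternative=alternative)
        times.append(label)
        values.append(float(np.mean(diff)) + null)
        sems.append(float(stats.sem(diff)))
        pvals.append(float(p))
        nulls.append(null)
    times = np.array(times)
    pvals = np.array(pvals)
    latency = latency_from_pvalues(times, pvals, alpha, consecutive)
    return GeometryTrace(
        times_ms=times, value=np.array(values), sem=np.array(sems),
        null_level=np.array(nulls), latency_ms=latency, method_tag=method_tag,
        pvalues=pvals,
    )


def response_latency(
    tensor: ResponseTensor,
    baseline_window: tuple[int, int] = (-50, 0),
    width_ms: int = 50,
    step_ms: int = 10,
    alpha: float = 0.001,
    consecutive: int = 2,
) -> GeometryTrace:
    """Latency at which the population response exceeds baseline.

    Per window, a one-tailed paired t-test across cells of window rate minus each
    cell's baseline rate.  The trace value is the mean window rate across cells,
    the null level the mean baseline rate.
    """
    b0, b1 = baseline_window
    baseline = np.nanmean(window_response(tensor, b0, b1), axis=1)  # per cell

    def stat(t0, t1):
        rate = np.nanmean(window_response(tensor, t0, t1), axis=1)
        return rate - baseline, float(np.mean(baseline))

    return _paired_windows_trace(
        tensor, stat, width_ms, step_ms, alpha, consecutive,
        alternative="greater", method_tag="response_latency",
    )


def divergence_latency(
    tensor: ResponseTensor,
    familiar: np.ndarray,
    width_ms: int = 50,
    step_ms: int = 10,
    alpha: float = 0.001,
    consecutive: int = 2,
) -> GeometryTrace:
    """Latency at which familiar and unfamiliar mean responses diverge.

    Two-tailed paired t-test across cells of per-cell familiar-mean minus
    unfamiliar-mean rate.  Trace value is the mean familiar-unfamiliar difference.
    """
    familiar = np.asarray(familiar, dtype=bool)
    if familiar.sum() == 0 or (~familiar).sum() == 0:
        raise InsufficientDataError("need faces of both familiarity classes")

    def stat(t0, t1):
        rates = window_response(tensor, t0, t1)
        diff = np.nanmean(rates[:, familiar], axis=1) - np.nanmean(
            rates[:, ~familiar], axis=1
        )
        return diff, 0.0

    return _paired_windows_trace(
        tensor, stat, width_ms, step_ms, alpha, consecutive,
        alternative="two-sided", method_tag="divergence_latency",
    )
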