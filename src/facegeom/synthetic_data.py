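"""Synthetic face spaces and spiking populations with a controllable memory geometry.

The generator realizes a linear axis code: each cell's expected rate is
``r_i = c0_i + g_i * (c_i . f)`` for a face with feature vector ``f``.  On top of
that three familiarity effects, each independently switchable, reproduce the
geometry the analysis modules are built to detect:

* an early additive *subspace shift* of familiar-face responses, constructed in
  cell space orthogonal to every feature-encoding pattern (so it carries
  familiarity without disturbing feature decoding);
* a late per-cell *axis rotation* for familiar faces (the memory recoding), with
  an optional multiplicative ``familiar_gain``;
* an expectation-dependent *context gain* applied to the rarer familiarity class
  in mixed-ratio experiments.

Spike counts are Poisson per half-open time bin (Gaussian with matched variance,
or noiseless rates, when configured).  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .response_core import ResponseTensor

__all__ = [
    "FaceSet",
    "SimConfig",
    "PopulationModel",
    "sample_face_space",
    "make_population",
    "simulate_responses",
    "make_context_experiment",
    "write_simulated_dataset",
    "load_simulated_dataset",
]

CATEGORIES = ("human_face", "monkey_face", "object")


@dataclass
class FaceSet:
    """A set of stimuli: faces x standardized shape/appearance features, with labels."""

    face_ids: np.ndarray
    features: np.ndarray
    familiar: np.ndarray
    category: np.ndarray
    subset_tag: str = ""

    def __post_init__(self) -> None:
        self.face_ids = np.asarray(self.face_ids).astype(str)
        self.features = np.asarray(self.features, dtype=float)
        self.familiar = np.asarray(self.familiar, dtype=bool)
        self.category = np.asarray(self.category).astype(str)
        if self.features.ndim != 2 or self.features.shape[1] < 2:
            raise ValueError("features must be 2-d with d >= 2")
        n = len(self.face_ids)
        if not (len(self.familiar) == len(self.category) == self.features.shape[0] == n):
            raise ValueError("inconsistent FaceSet field lengths")
        if len(np.unique(self.face_ids)) != n:
            raise ValueError("face_id values must be unique")

    @property
    def n_faces(self) -> int:
        return len(self.face_ids)

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, idx) -> "FaceSet":
        idx = np.asarray(idx)
        return FaceSet(self.face_ids[idx], self.features[idx], self.familiar[idx],
                       self.category[idx], self.subset_tag)

    @staticmethod
    def concat(parts: Sequence["FaceSet"], subset_tag: str = "") -> "FaceSet":
        return FaceSet(
            np.concatenate([p.face_ids for p in parts]),
            np.vstack([p.features for p in parts]),
            np.concatenate([p.familiar for p in parts]),
            np.concatenate([p.category for p in parts]),
            subset_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"face_id": self.face_ids, "familiar": self.familiar,
                "category": self.category}
        cols.update({f"f{j + 1}": self.features[:, j] for j in range(self.d)})
        return pd.DataFrame(cols)

    @staticmethod
    def from_frame(df: pd.DataFrame, subset_tag: str = "") -> "FaceSet":
        fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        fcols.sort(key=lambda c: int(c[1:]))
        return FaceSet(df["face_id"].to_numpy(), df[fcols].to_numpy(dtype=float),
                       df["familiar"].to_numpy(), df["category"].to_numpy(), subset_tag)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str | Path, subset_tag: str = "") -> "FaceSet":
        return FaceSet.from_frame(pd.read_csv(path, sep="\t"), subset_tag)


@dataclass
class SimConfig:
    """Full generative specification of a synthetic experiment.

    shift_magnitude is the norm of the population shift vector in per-cell
    signal-s.d. units; rotation_angle_deg the per-cell axis rotation for familiar
    faces at long latency; familiar_gain a multiplicative drive gain in the
    rotated epoch; context_gain_rare the gain applied to the rarer familiarity
    class in context experiments.
    """

    n_cells: int = 150
    d_total: int = 120
    d_used: int = 20
    n_unfamiliar: int = 1000
    n_familiar: int = 36
    bin_ms: int = 10
    t_start_ms: int = -50
    t_end_ms: int = 300
    visual_onset_ms: int = 90
    shift_onset_ms: int = 100
    shift_magnitude: float = 2.0
    rotation_onset_ms: int = 200
    rotation_angle_deg: float = 60.0
    familiar_gain: float = 1.0
    context_gain_rare: float = 1.0
    baseline_hz: float = 10.0
    peak_hz: float = 50.0
    noise_model: str = "poisson"
    n_trials: int = 10
    seed: int = 0
    shift_mode: str = "orthogonal"
    probe_nonlinearity: str = "none"
    saturation_scale: float = 0.4

    def __post_init__(self) -> None:
        if self.noise_model not in {"poisson", "gaussian", "none"}:
            raise ValueError("noise_model must be poisson, gaussian or none")
        if self.shift_mode not in {"orthogonal", "in_subspace"}:
            raise ValueError("shift_mode must be orthogonal or in_subspace")
        if self.probe_nonlinearity not in {"none", "saturating"}:
            raise ValueError("probe_nonlinearity must be none or saturating")
        if self.d_used > self.d_total:
            raise ValueError("d_used must not exceed d_total")
        if self.n_familiar > self.n_unfamiliar:
            raise ValueError("n_familiar must not exceed n_unfamiliar")
        if self.rotation_onset_ms < self.visual_onset_ms:
            raise ValueError("rotation_onset_ms must be >= visual_onset_ms")
        if self.shift_onset_ms < self.visual_onset_ms:
            raise ValueError("shift_onset_ms must be >= visual_onset_ms")
        if not 0 <= self.rotation_angle_deg <= 90:
            raise ValueError("rotation_angle_deg must lie in [0, 90]")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be nonnegative")
        for name in ("bin_ms", "n_cells", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        span = self.t_end_ms - self.t_start_ms
        if span <= 0 or span % self.bin_ms != 0:
            raise ValueError("bin_ms must evenly divide [t_start_ms, t_end_ms)")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SimConfig":
        return SimConfig(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @staticmethod
    def from_file(path: str | Path) -> "SimConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return SimConfig.from_dict(d)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class PopulationModel:
    """Per-cell axis code parameters plus the population shift vector.

    ``axes`` rows are the unit preferred axes c_i; ``axes_rotated`` their rotated
    counterparts c_i'; ``shift_loadings`` the dimensionless per-cell shift
    components s_i (norm = shift_magnitude); the injected rate shift for cell i is
    ``gains_hz[i] * shift_loadings[i]`` Hz.
    """

    axes: np.ndarray
    axes_rotated: np.ndarray
    offsets_hz: np.ndarray
    gains_hz: np.ndarray
    shift_loadings: np.ndarray
    rotation_angle_deg: float

    @property
    def n_cells(self) -> int:
        return self.axes.shape[0]

    @property
    def d_used(self) -> int:
        return self.axes.shape[1]

    @property
    def shift_hz(self) -> np.ndarray:
        """Per-cell familiar-face rate shift (Hz).

        Scaled so the shift's population-vector norm equals
        ``shift_magnitude`` times the population signal s.d. (the norm of a
        typical signal fluctuation, ~ sqrt(n_cells) per-cell signal s.d.):
        cell i receives sqrt(n_cells) * g_i * s_i Hz.
        """
        return np.sqrt(self.n_cells) * self.gains_hz * self.shift_loadings


def sample_face_space(
    n: int,
    d: int,
    seed: int,
    familiar: bool = False,
    category: str = "monkey_face",
    prefix: str = "face",
    subset_tag: str = "",
) -> FaceSet:
    """Draw n faces i.i.d. standard normal in a d-dimensional face space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if d < 2:
        raise ValueError("d must be >= 2")
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}")
    rng = np.random.default_rng(seed)
    features = rng.standard_normal((n, d))
    ids = np.array([f"{prefix}{i:04d}" for i in range(n)])
    return FaceSet(ids, features, np.full(n, familiar), np.full(n, category),
                   subset_tag)


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def make_population(config: SimConfig) -> PopulationModel:
    """Instantiate the per-cell axis code defined by ``config``.

    Axes are uniform on the unit sphere in d_used dimensions; rotated axes are
    obtained by rotating each axis by rotation_angle_deg toward an independent
    random direction orthogonal to it.  The shift loading vector is built in cell
    space and orthogonalized against the feature-encoding patterns (columns of C
    and of diag(g)C) plus the uniform-rate and gain directions, then scaled to
    shift_magnitude.
    """
    rng = np.random.default_rng([config.seed, 101])
    n, d = config.n_cells, config.d_used
    axes = _unit_rows(rng.standard_normal((n, d)))

    w = rng.standard_normal((n, d))
    w -= (np.sum(w * axes, axis=1, keepdims=True)) * axes
    w = _unit_rows(w)
    theta = np.deg2rad(config.rotation_angle_deg)
    axes_rotated = np.cos(theta) * axes + np.sin(theta) * w

    gain_scale = (config.peak_hz - config.baseline_hz) / 4.0
    gains = gain_scale * rng.uniform(0.5, 1.5, size=n)
    offsets = config.baseline_hz + (config.peak_hz - config.baseline_hz) * rng.uniform(
        0.3, 0.7, size=n
    )

    loadings = np.zeros(n)
    if config.shift_magnitude > 0:
        if config.shift_mode == "in_subspace":
            v = gains * axes[:, 0]
            loadings = config.shift_magnitude * v / np.linalg.norm(v)
        else:
            # the rate-space shift is g*v: require it invisible to the raw
            # axis patterns C_j (-> v _|_ g*C_j), to the rate-space decoder
            # patterns g*C_j (-> v _|_ g^2*C_j), to the z-scored decoder
            # patterns (g*C_j)/sigma with sigma ~ g (-> v _|_ C_j), and to the
            # uniform-rate / mean-rate directions ({1, g})
            constraints = np.column_stack(
                [axes, gains[:, None] * axes, gains[:, None] ** 2 * axes,
                 np.ones(n), gains]
            )
            q, _ = np.linalg.qr(constraints)
            v = rng.standard_normal(n)
            v -= q @ (q.T @ v)
            norm = np.linalg.norm(v)
            if norm < 1e-8 * np.sqrt(n):
                warnings.warn(
                    "encoding span is full rank in cell space; orthogonal shift "
                    "unavailable, setting shift to 0"
                )
            else:
                loadings = config.shift_magnitude * v / norm
    if config.n_cells <= config.d_used and config.shift_magnitude > 0:
        warnings.warn("n_cells <= d_used: orthogonal complement may be empty")

    return PopulationModel(
        axes=axes, axes_rotated=axes_rotated, offsets_hz=offsets, gains_hz=gains,
        shift_loadings=loadings, rotation_angle_deg=config.rotation_angle_deg,
    )


def _expected_rate_segments(
    pop: PopulationModel, faces: FaceSet, config: SimConfig,
    context_gain: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(bin index array, cells x faces expected-rate matrix) per temporal segment."""
    f = faces.features
    if f.shape[1] == config.d_total:
        f = f[:, : config.d_used]
    if f.shape[1] != config.d_used:
        raise ValueError(
            f"faces have {faces.features.shape[1]} features; expected d_used="
            f"{config.d_used} (or d_total={config.d_total})"
        )
    fam = faces.familiar
    proj = pop.axes @ f.T            # cells x faces
    proj_rot = pop.axes_rotated @ f.T
    if config.probe_nonlinearity == "saturating":
        s = config.saturation_scale
        proj = np.where(fam[None, :], s * np.tanh(proj / s), proj)
        proj_rot = np.where(fam[None, :], s * np.tanh(proj_rot / s), proj_rot)

    evoked_early = pop.offsets_hz[:, None] + pop.gains_hz[:, None] * proj
    # familiar_gain scales the whole evoked familiar response in the rotated
    # epoch (suppression/enhancement of the memory recoding), not just the drive
    evoked_late = np.where(
        fam[None, :],
        config.familiar_gain
        * (pop.offsets_hz[:, None] + pop.gains_hz[:, None] * proj_rot),
        evoked_early,
    )
    shift_term = np.where(fam[None, :], pop.shift_hz[:, None], 0.0)

    starts = np.arange(config.t_start_ms, config.t_end_ms, config.bin_ms)
    breaks = sorted(
        {config.visual_onset_ms, config.shift_onset_ms, config.rotation_onset_ms}
    )
    base = np.full((pop.n_cells, faces.n_faces), config.baseline_hz)
    segments = []
    for lo, hi in zip([config.t_start_ms] + breaks, breaks + [config.t_end_ms]):
        bins = np.flatnonzero((starts >= lo) & (starts < hi))
        if len(bins) == 0:
            continue
        if lo < config.visual_onset_ms:
            rate = base.copy()
        else:
            rate = (evoked_late if lo >= config.rotation_onset_ms
                    else evoked_early).copy()
            if lo >= config.shift_onset_ms:
                rate = rate + shift_term
            if context_gain is not None:
                rate = rate * context_gain[None, :]
        segments.append((bins, np.maximum(rate, 0.0)))
    return segments


def simulate_responses(
    pop: PopulationModel,
    faces: FaceSet,
    config: SimConfig,
    context_gain: np.ndarray | None = None,
    trials_per_face: np.ndarray | None = None,
) -> ResponseTensor:
    """Simulate spike counts for every cell, face, trial and time bin.

    Expected rates follow the axis code with the configured familiarity effects;
    rates are floored at 0 before the noise draw.  ``trials_per_face`` allows
    unequal repetition counts (missing trials are masked).
    """
    rng = np.random.default_rng([config.seed, 202])
    segments = _expected_rate_segments(pop, faces, config, context_gain)
    n_bins = (config.t_end_ms - config.t_start_ms) // config.bin_ms
    n_trials = (config.n_trials if trials_per_face is None
                else int(np.max(trials_per_face)))
    shape = (pop.n_cells, faces.n_faces, n_trials, n_bins)
    dt = config.bin_ms / 1000.0

    if config.noise_model == "none":
        counts = np.zeros(shape, dtype=float)
        for bins, rate in segments:
            counts[:, :, :, bins] = (rate * dt)[:, :, None, None]
    else:
        counts = np.zeros(shape, dtype=np.int16)
        for bins, rate in segments:
            lam = np.broadcast_to(
                (rate * dt)[:, :, None, None],
                (pop.n_cells, faces.n_faces, n_trials, len(bins)),
            )
            if config.noise_model == "poisson":
                draw = rng.poisson(lam)
            else:  # gaussian with Poisson-matched variance, rounded, floored
                draw = np.rint(lam + np.sqrt(lam) * rng.standard_normal(lam.shape))
                draw = np.maximum(draw, 0)
            counts[:, :, :, bins] = draw.astype(np.int16)

    mask = np.ones((faces.n_faces, n_trials), dtype=bool)
    if trials_per_face is not None:
        mask = np.arange(n_trials)[None, :] < np.asarray(trials_per_face)[:, None]
        counts = counts.copy()
        counts[:, ~mask] = 0
    return ResponseTensor(
        counts=counts, bin_ms=config.bin_ms, t_start_ms=config.t_start_ms,
        t_end_ms=config.t_end_ms,
        cell_ids=np.array([f"cell{i:03d}" for i in range(pop.n_cells)]),
        face_ids=faces.face_ids, mask=mask, region_tag="sim",
        normalized=config.noise_model == "none",
    )


def make_context_experiment(
    pop: PopulationModel,
    faces_fam: FaceSet,
    faces_unfam: FaceSet,
    ratio: tuple[int, int],
    config: SimConfig,
) -> tuple[ResponseTensor, FaceSet]:
    """Simulate a mixed session with a familiar:unfamiliar presentation ratio.

    Per-face trial counts are scaled so the two classes' total presentation
    counts follow ``ratio`` (majority class at config.n_trials per face, minority
    faces at proportionally fewer, floor 1).  ``context_gain_rare`` multiplies
    the post-onset rates of the minority class (expectation: rare stimuli drive
    stronger responses).
    """
    rf, ru = ratio
    if rf < 1 or ru < 1:
        raise ValueError("ratio components must be >= 1")
    faces = FaceSet.concat([faces_fam, faces_unfam], subset_tag="context")
    fam = faces.familiar
    if not fam[: faces_fam.n_faces].all() or fam[faces_fam.n_faces:].any():
        raise ValueError("faces_fam must be all familiar, faces_unfam all unfamiliar")

    share_f = rf / (rf + ru)
    per_face_f = share_f / faces_fam.n_faces
    per_face_u = (1 - share_f) / faces_unfam.n_faces
    top = max(per_face_f, per_face_u)
    t_f = max(1, round(config.n_trials * per_face_f / top))
    t_u = max(1, round(config.n_trials * per_face_u / top))
    trials_per_face = np.where(fam, t_f, t_u)

    minority_is_fam = share_f < 0.5
    gain = np.where(fam == minority_is_fam, config.context_gain_rare, 1.0)
    tensor = simulate_responses(
        pop, faces, config, context_gain=gain, trials_per_face=trials_per_face
    )
    return tensor, faces


# ---------------------------------------------------------------------------
# dataset I/O (features.tsv, spikes.tsv, meta.json)


def write_simulated_dataset(
    out_dir: str | Path,
    pop: PopulationModel,
    faces: FaceSet,
    tensor: ResponseTensor,
    config: SimConfig,
) -> None:
    """Write features.tsv, spikes.tsv and meta.json for a simulated experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    faces.to_tsv(out / "features.tsv")

    rows = []
    edges = tensor.bin_starts_ms
    trial_id = 0
    rng = np.random.default_rng([config.seed, 303])
    for fi in range(tensor.n_faces):
        for ti in range(tensor.n_trials):
            if not tensor.mask[fi, ti]:
                continue
            for ci in range(tensor.n_cells):
                c = tensor.counts[ci, fi, ti]
                for bi in np.flatnonzero(c):
                    times = edges[bi] + tensor.bin_ms * rng.random(int(c[bi]))
                    for t in times:
                        rows.append((tensor.cell_ids[ci], trial_id,
                                     tensor.face_ids[fi], round(float(t), 3)))
            trial_id += 1
    pd.DataFrame(rows, columns=["cell_id", "trial_id", "face_id", "spike_time_ms"]
                 ).to_csv(out / "spikes.tsv", sep="\t", index=False)

    meta = {
        "config": config.to_dict(),
        "cell_ids": [str(c) for c in tensor.cell_ids],
        "face_ids": [str(f) for f in tensor.face_ids],
        "trials_per_face": tensor.mask.sum(axis=1).tolist(),
        "ground_truth": {
            "axes": pop.axes.tolist(),
            "axes_rotated": pop.axes_rotated.tolist(),
            "offsets_hz": pop.offsets_hz.tolist(),
            "gains_hz": pop.gains_hz.tolist(),
            "shift_loadings": pop.shift_loadings.tolist(),
        },
    }
    (out / "meta.json").write_text(json.dumps(meta))


def load_simulated_dataset(out_dir: str | Path):
    """Load features.tsv, spikes.tsv, meta.json back into package objects."""
    from .response_core import bin_spikes, read_spike_table

    out = Path(out_dir)
    meta = json.loads((out / "meta.json").read_text())
    config = SimConfig.from_dict(meta["config"])
    faces = FaceSet.read_tsv(out / "features.tsv")
    spikes = read_spike_table(out / "spikes.tsv")
    tensor = bin_spikes(
        spikes, config.bin_ms, config.t_start_ms, config.t_end_ms,
        cell_ids=meta["cell_ids"], face_ids=meta["face_ids"],
        n_trials=int(max(meta["trials_per_face"])),
    )
    gt = meta["ground_truth"]
    pop = PopulationModel(
        axes=np.array(gt["axes"]), axes_rotated=np.array(gt["axes_rotated"]),
        offsets_hz=np.array(gt["offsets_hz"]), gains_hz=np.array(gt["gains_hz"]),
        shift_loadings=np.array(gt["shift_loadings"]),
        rotation_angle_deg=config.rotation_angle_deg,
    )
    return tensor, faces, pop, config
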