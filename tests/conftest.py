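import numpy as np
import pytest

import facegeom as fg


def make_faces(n_fam, n_unfam, d=20, seed=0):
    fam = fg.sample_face_space(n_fam, d, seed=seed + 1, familiar=True, prefix="fam")
    unf = fg.sample_face_space(n_unfam, d, seed=seed + 2, prefix="unf")
    return fg.FaceSet.concat([fam, unf])


@pytest.fixture(scope="session")
def plain_experiment():
    """A small plain axis-code experiment: no shift, no rotation, Poisson noise."""
    cfg = fg.SimConfig(
        n_cells=50, n_unfamiliar=200, n_familiar=36, n_trials=8, seed=11,
        shift_magnitude=0.0, rotation_angle_deg=0.0,
    )
    faces = make_faces(36, 200, seed=40)
    pop = fg.make_population(cfg)
    tensor = fg.simulate_responses(pop, faces, cfg)
    return cfg, pop, faces, tensor


@pytest.fixture(scope="session")
def noiseless_linear_experiment():
    """Noiseless linear population with offsets high enough that rates never
    rectify: responses are exactly c0 + g (c.f) in every post-onset bin."""
    cfg = fg.SimConfig(
        n_cells=30, n_unfamiliar=150, n_familiar=10, n_trials=1, seed=5,
        shift_magnitude=0.0, rotation_angle_deg=0.0,
        baseline_hz=100.0, peak_hz=140.0, noise_model="none",
    )
    faces = make_faces(10, 150, seed=60)
    pop = fg.make_population(cfg)
    tensor = fg.simulate_responses(pop, faces, cfg)
    return cfg, pop, faces, tensor
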