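"""Shared fixtures: rendered face sets and one desk-scale trained model.

The model is trained once per session at desk-scale cascade sizes
(T=5, K=50, P=100, F=5, beta=1000) on 60 schematic faces with
annotation-set-like variety (heavy brows, some eyelid occlusion and
glints); 20 further faces are held out for generalization checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from irisloc import ferns, synth, training

TRAIN_SEED = 11
HELDOUT_SEED = 1101
MODEL_SEED = 7


def _face_set(n, seed):
    specs = synth.sample_face_specs(
        n, seed, brow_weight=2.0, eyelid_range=(0.0, 0.4), glint_prob=0.3
    )
    rendered = [synth.render_face(s) for s in specs]
    return [r[0] for r in rendered], [r[1] for r in rendered]


@pytest.fixture(scope="session")
def train_faces():
    return _face_set(60, TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_faces():
    return _face_set(20, HELDOUT_SEED)


@pytest.fixture(scope="session")
def face_model(train_faces) -> ferns.CascadeModel:
    images, shapes = train_faces
    return training.train_model(images, shapes, hyperparams=training.DESK_SCALE,
                                seed=MODEL_SEED)


@pytest.fixture()
def iris_patch():
    """Clean 48-px eye patch with a known center."""
    spec = synth.EyeFixtureSpec(
        size=(48, 48), iris_center=(24.0, 24.0), iris_radius=10.0, pupil_radius=4.0
    )
    img, center = synth.render_eye(spec)
    return img, np.array(center)


@pytest.fixture()
def quadratic_bowl():
    """L = x^2 + y^2 on a 41x41 grid centered at the origin."""
    n = 41
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    x, y = xx - n // 2, yy - n // 2
    return x, y, x**2 + y**2
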