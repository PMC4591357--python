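"""High-level training: cascade + AISC weights from annotated images."""

from __future__ import annotations

import numpy as np

from . import aisc, ferns

__all__ = ["train_model", "DESK_SCALE", "PAPER_SCALE"]

#: Reduced cascade sizes for fast experiments and tests.
DESK_SCALE = ferns.Hyperparams(T=5, K=50, P=100, F=5, beta=1000.0, n_inits=20)

#: Full-size cascade hyperparameters (T=10, K=500, P=300, F=5, beta=1000).
PAPER_SCALE = ferns.Hyperparams()


def train_model(
    images,
    true_shapes,
    boxes=None,
    hyperparams: ferns.Hyperparams = DESK_SCALE,
    seed: int = 0,
) -> ferns.CascadeModel:
    """Train the alignment cascade and fit per-eye AISC weights.

    ``boxes`` default to each shape's landmark bounding box expanded by
    the standard margin (the same convention tracking uses). AISC
    weights are fitted independently for the two eyes on the annotated
    shapes and stored in the model's named section.
    """
    true_shapes = [np.asarray(s, dtype=np.float64) for s in true_shapes]
    if boxes is None:
        boxes = [ferns.landmark_face_box(s) for s in true_shapes]
    model = ferns.train(list(images), true_shapes, list(boxes), hyperparams, seed=seed)
    for side in ("left", "right"):
        basis = aisc.default_basis(side)
        w = aisc.fit_weights(true_shapes, basis)
        model.aisc[side] = {
            "center_id": basis.center_id,
            "neighbor_ids": np.array(basis.neighbor_ids, dtype=np.intp),
            "omega": w.omega,
        }
    return model
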