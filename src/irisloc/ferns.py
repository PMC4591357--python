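"""Two-level cascaded fern regression for facial landmark alignment.

The aligner is a cascade of T stage regressors, each a sum of K random
ferns. A fern thresholds F shape-indexed pixel-difference features,
dropping each sample into one of 2^F bins; each bin stores a constant
shape increment. Training minimizes the residual between the current
shape estimate S and the annotated shape S_hat, stage by stage:

    S^t = S^{t-1} + R^t(I, S^{t-1}),        t = 1..T

with each fern's bin output the shrinkage-regularized mean residual of
the samples in the bin,

    delta_S_b = 1 / (1 + beta / |Omega_b|) * mean_{i in Omega_b}(S_hat_i - S_i),

so bins with few samples are damped toward zero (beta = 1000 by
default). Pixel features are *shape-indexed*: each of the P pool pixels
is stored as an offset from its nearest mean-shape landmark and mapped
through the similarity transform from the mean shape to the current
estimate, which makes features approximately invariant to translation,
scale and in-plane rotation. Within a stage the features are indexed by
the stage's input shape (the output of R^{t-1}), not updated fern by
fern. Residuals and increments live in the mean-shape frame and are
mapped back through the same similarity transform.

Feature selection is correlation-based: for each of the F slots the
residual matrix is projected onto a random direction and the
pixel-difference feature (from the implicit P^2 pool, via pairwise
covariances) with the largest absolute correlation to the projection is
chosen.

Training data are augmented by giving every sample ``n_inits``
different initial shapes borrowed from other samples' annotations
(similarity-aligned into the target's face box), 20 by default.
Prediction runs ``n_init`` perturbed initializations through the whole
cascade and averages the results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .shapes import normalize_to_box, place_in_box, shape_box, similarity_fit

__all__ = [
    "Fern",
    "StageRegressor",
    "CascadeModel",
    "Hyperparams",
    "augment",
    "index_pixels",
    "select_features",
    "train_fern",
    "train",
    "predict",
    "save_model",
    "load_model",
    "DegenerateDataError",
]

MODEL_FORMAT_VERSION = 1

#: Margin (fraction of landmark bbox) used whenever a face box is
#: derived from landmarks; train-time and track-time boxes must agree.
BOX_MARGIN = 0.1


class DegenerateDataError(RuntimeError):
    """Raised when every candidate feature has zero variance."""


@dataclass(frozen=True)
class Hyperparams:
    """Cascade sizes: T stages x K ferns, P pool pixels, F features/fern."""

    T: int = 10
    K: int = 500
    P: int = 300
    F: int = 5
    beta: float = 1000.0
    n_inits: int = 20


@dataclass
class Fern:
    feature_ids: np.ndarray  # (F, 2) indices into the stage's P-pixel pool
    thresholds: np.ndarray  # (F,)
    bin_outputs: np.ndarray  # (2^F, 2L) increments in the mean-shape frame

    def bin_of(self, pixel_values: np.ndarray) -> np.ndarray:
        """Bin index for each row of an (N, P) pixel-value matrix."""
        if len(self.feature_ids) == 0:
            return np.zeros(pixel_values.shape[0], dtype=np.intp)
        diffs = (
            pixel_values[:, self.feature_ids[:, 0]]
            - pixel_values[:, self.feature_ids[:, 1]]
        )
        bits = (diffs >= self.thresholds).astype(np.intp)
        return bits @ (1 << np.arange(len(self.feature_ids), dtype=np.intp))


@dataclass
class StageRegressor:
    anchor_landmarks: np.ndarray  # (P,) nearest mean-shape landmark per pool pixel
    anchor_offsets: np.ndarray  # (P, 2) offsets in the mean-shape (unit) frame
    ferns: list[Fern] = field(default_factory=list)


@dataclass
class CascadeModel:
    stages: list[StageRegressor]
    mean_shape: np.ndarray  # (L, 2) in the unit face-box frame
    hyperparams: Hyperparams
    rng_seed: int
    error_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    landmark_scheme: str = "schematic-29"
    aisc: dict = field(default_factory=dict)  # named section for selector weights

    @property
    def n_landmarks(self) -> int:
        return len(self.mean_shape)


# ---------------------------------------------------------------------------
# Training-data augmentation


def augment(
    true_shapes: list[np.ndarray],
    boxes: list,
    n_inits: int = 20,
    seed: int = 0,
    box_jitter: float = 0.1,
):
    """Give every sample ``n_inits`` initial shapes from other samples.

    Returns ``(sample_idx, init_shapes)``: for each augmented instance
    the index of its source sample and an initial shape, which is a
    different sample's annotated shape similarity-aligned (via its face
    box) into the target's box. Output length = n_inits * input length.

    ``box_jitter`` perturbs each placement box by a random translation
    (fraction of box size) and scale (1 +- box_jitter), emulating the
    noise of a real face detector relative to the annotation-derived
    box; without it the cascade never learns to correct a misplaced
    box, which tracking relies on.
    """
    n = len(true_shapes)
    if n < n_inits:
        raise ValueError(f"need at least n_inits={n_inits} samples, got {n}")
    rng = np.random.default_rng(seed)
    sample_idx, inits = [], []
    for i in range(n):
        pool = np.delete(np.arange(n), i) if n > n_inits else np.arange(n)
        donors = rng.choice(pool, size=n_inits, replace=False) if n_inits > 1 else [i]
        for j in donors:
            unit = normalize_to_box(true_shapes[j], boxes[j])
            x, y, w, h = boxes[i]
            if box_jitter > 0:
                dx, dy = rng.uniform(-box_jitter, box_jitter, 2) * (w, h)
                ds = 1.0 + rng.uniform(-box_jitter, box_jitter)
                x, y = x + dx - (ds - 1) * w / 2, y + dy - (ds - 1) * h / 2
                w, h = w * ds, h * ds
            inits.append(place_in_box(unit, (x, y, w, h)))
            sample_idx.append(i)
    return np.array(sample_idx, dtype=np.intp), inits


# ---------------------------------------------------------------------------
# Shape-indexed pixel features


def index_pixels(
    anchor_landmarks: np.ndarray,
    anchor_offsets: np.ndarray,
    current_shape: np.ndarray,
    mean_shape: np.ndarray,
    image_shape: tuple[int, int],
):
    """Map pool-pixel anchors into image coordinates for one shape.

    Each anchor's offset (stored relative to its nearest mean-shape
    landmark, in the mean frame) is mapped through the linear part of
    the similarity transform from the mean shape to the current shape
    and added to the corresponding current landmark. Points off the
    image are clamped to the border.
    """
    M = similarity_fit(mean_shape, current_shape)
    A = M[:2, :2]
    pos = current_shape[anchor_landmarks] + anchor_offsets @ A.T
    h, w = image_shape
    pos[:, 0] = np.clip(pos[:, 0], 0, w - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, h - 1)
    return pos


def _sample_pixels(img: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Nearest-neighbor intensity lookup at (x, y) positions."""
    h, w = img.shape
    c = np.clip(np.round(pos[:, 0]).astype(np.intp), 0, w - 1)
    r = np.clip(np.round(pos[:, 1]).astype(np.intp), 0, h - 1)
    return img[r, c]


# ---------------------------------------------------------------------------
# Fern training


def select_features(
    pixel_values: np.ndarray,
    residuals: np.ndarray,
    F: int,
    rng: np.random.Generator,
    _cov_cache: dict | None = None,
):
    """Correlation-based selection of F pixel-difference features.

    For each slot, project the residuals onto a random unit direction
    and pick the pair (a, b) whose difference feature has maximal
    absolute correlation with the projection, computed implicitly from
    pairwise pixel covariances. Thresholds are drawn uniformly from the
    central 80% of each chosen feature's observed range.

    Returns ``(feature_ids (F, 2), thresholds (F,))``.
    """
    N, P = pixel_values.shape
    if N < 2:
        raise ValueError(f"need at least 2 samples to select features, got {N}")
    if F == 0:
        return np.zeros((0, 2), dtype=np.intp), np.zeros(0)
    if _cov_cache is not None and "Vc" in _cov_cache:
        Vc, var_p, pair_var = _cov_cache["Vc"], _cov_cache["var"], _cov_cache["pair_var"]
    else:
        Vc = pixel_values - pixel_values.mean(axis=0)
        cov_pp = Vc.T @ Vc / N
        var_p = np.diag(cov_pp).copy()
        # var(a - b) for every pair
        pair_var = var_p[:, None] + var_p[None, :] - 2.0 * cov_pp
        if _cov_cache is not None:
            _cov_cache.update(Vc=Vc, var=var_p, pair_var=pair_var)
    usable = pair_var > 1e-12
    np.fill_diagonal(usable, False)
    if not usable.any():
        raise DegenerateDataError("all pixel-difference features have zero variance")

    ids = np.zeros((F, 2), dtype=np.intp)
    thresholds = np.zeros(F)
    for f in range(F):
        direction = rng.normal(size=residuals.shape[1])
        direction /= np.linalg.norm(direction) + 1e-30
        proj = residuals @ direction
        proj_c = proj - proj.mean()
        sd_y = np.sqrt(proj_c @ proj_c / N)
        cov_py = Vc.T @ proj_c / N  # (P,)
        num = cov_py[:, None] - cov_py[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(num) / (np.sqrt(pair_var) * (sd_y + 1e-30))
        corr[~usable] = -1.0
        a, b = np.unravel_index(int(np.argmax(corr)), corr.shape)
        ids[f] = (a, b)
        feat = pixel_values[:, a] - pixel_values[:, b]
        lo, hi = feat.min(), feat.max()
        span = hi - lo
        thresholds[f] = rng.uniform(lo + 0.1 * span, hi - 0.1 * span)
    return ids, thresholds


def train_fern(
    pixel_values: np.ndarray,
    residuals: np.ndarray,
    F: int = 5,
    beta: float = 1000.0,
    rng: np.random.Generator | None = None,
    _cov_cache: dict | None = None,
) -> Fern:
    """Select features, bin the samples, and fit shrunken bin means.

    Each bin's output is ``1/(1 + beta/|bin|)`` times the mean residual
    of its members; empty bins output zero. A bin holding a single
    sample with beta = 1000 therefore outputs residual / 1001.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ids, thresholds = select_features(pixel_values, residuals, F, rng, _cov_cache)
    fern = Fern(
        feature_ids=ids,
        thresholds=thresholds,
        bin_outputs=np.zeros((2 ** len(ids), residuals.shape[1])),
    )
    bins = fern.bin_of(pixel_values)
    counts = np.bincount(bins, minlength=fern.bin_outputs.shape[0]).astype(np.float64)
    sums = np.zeros_like(fern.bin_outputs)
    np.add.at(sums, bins, residuals)
    occupied = counts > 0
    shrink = 1.0 / (1.0 + beta / counts[occupied])
    fern.bin_outputs[occupied] = shrink[:, None] * sums[occupied] / counts[occupied, None]
    return fern


# ---------------------------------------------------------------------------
# Cascade training


def _sample_anchors(mean_shape: np.ndarray, P: int, rng: np.random.Generator):
    """Draw P pool pixels in the mean frame, anchored to nearest landmarks."""
    lo = mean_shape.min(axis=0) - 0.05
    hi = mean_shape.max(axis=0) + 0.05
    pts = rng.uniform(lo, hi, size=(P, 2))
    d2 = ((pts[:, None, :] - mean_shape[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1).astype(np.intp)
    offsets = pts - mean_shape[nearest]
    return nearest, offsets


def train(
    images: list[np.ndarray],
    true_shapes: list[np.ndarray],
    boxes: list,
    hyperparams: Hyperparams = Hyperparams(),
    seed: int = 0,
) -> CascadeModel:
    """Train the full two-level cascade.

    ``boxes`` are (x, y, w, h) face boxes, one per image; initial
    shapes for training come from :func:`augment`. The returned model
    records a per-stage mean-pixel-error trace.
    """
    hp = hyperparams
    rng = np.random.default_rng(seed)
    L = len(true_shapes[0])
    mean_shape = np.mean(
        [normalize_to_box(s, b) for s, b in zip(true_shapes, boxes)], axis=0
    )

    sample_idx, init_shapes = augment(
        true_shapes, boxes, n_inits=hp.n_inits, seed=int(rng.integers(2**31 - 1))
    )
    N = len(init_shapes)
    current = np.array(init_shapes)  # (N, L, 2)
    target = np.array([true_shapes[i] for i in sample_idx])  # (N, L, 2)
    imgs = [images[i] for i in sample_idx]

    stages: list[StageRegressor] = []
    trace = []
    for _t in range(hp.T):
        anchors_lm, anchors_off = _sample_anchors(mean_shape, hp.P, rng)
        A = np.zeros((N, 2, 2))
        V = np.zeros((N, hp.P))
        for n in range(N):
            M = similarity_fit(mean_shape, current[n])
            A[n] = M[:2, :2]
            pos = current[n][anchors_lm] + anchors_off @ A[n].T
            V[n] = _sample_pixels(imgs[n], pos)
        A_inv = np.linalg.inv(A)  # (N, 2, 2)

        stage = StageRegressor(anchor_landmarks=anchors_lm, anchor_offsets=anchors_off)
        cov_cache: dict = {}
        for _k in range(hp.K):
            resid = np.einsum("nab,nlb->nla", A_inv, target - current)
            fern = train_fern(
                V, resid.reshape(N, 2 * L), F=hp.F, beta=hp.beta, rng=rng,
                _cov_cache=cov_cache,
            )
            stage.ferns.append(fern)
            delta = fern.bin_outputs[fern.bin_of(V)].reshape(N, L, 2)
            if not np.all(np.isfinite(delta)):
                raise RuntimeError("non-finite shape update during training")
            current += np.einsum("nab,nlb->nla", A, delta)
        stages.append(stage)
        trace.append(float(np.mean(np.linalg.norm(target - current, axis=2))))

    return CascadeModel(
        stages=stages,
        mean_shape=mean_shape,
        hyperparams=hp,
        rng_seed=seed,
        error_trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# Prediction


def _run_cascade(img: np.ndarray, shape: np.ndarray, model: CascadeModel) -> np.ndarray:
    L = model.n_landmarks
    current = shape.copy()
    for stage in model.stages:
        M = similarity_fit(model.mean_shape, current)
        A = M[:2, :2]
        pos = current[stage.anchor_landmarks] + stage.anchor_offsets @ A.T
        h, w = img.shape
        pos[:, 0] = np.clip(pos[:, 0], 0, w - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, h - 1)
        v = _sample_pixels(img, pos)[None, :]
        for fern in stage.ferns:
            delta = fern.bin_outputs[fern.bin_of(v)[0]].reshape(L, 2)
            current += delta @ A.T
    return current


def predict(
    img: np.ndarray,
    face_box,
    model: CascadeModel,
    n_init: int = 5,
    seed: int = 0,
    perturbation: float = 0.05,
) -> np.ndarray:
    """Predict a shape: multi-initialization cascade run, averaged.

    The mean shape is placed in the face box for the first
    initialization; the remaining ``n_init - 1`` get random translation
    and scale perturbations of ``perturbation`` (fraction of box size).
    The final estimate is the per-landmark mean over all runs.
    """
    x, y, w, h = face_box
    ih, iw = img.shape
    if w <= 0 or h <= 0 or x + w < 0 or y + h < 0 or x > iw or y > ih:
        raise ValueError(f"face box {face_box} outside image of shape {img.shape}")
    rng = np.random.default_rng(seed)
    results = []
    for i in range(n_init):
        box = face_box
        if i > 0 and perturbation > 0:
            dx, dy = rng.uniform(-perturbation, perturbation, 2) * (w, h)
            ds = 1.0 + rng.uniform(-perturbation, perturbation)
            box = (x + dx - (ds - 1) * w / 2, y + dy - (ds - 1) * h / 2, w * ds, h * ds)
        init = place_in_box(model.mean_shape, box)
        results.append(_run_cascade(np.asarray(img, dtype=np.float64), init, model))
    return np.mean(results, axis=0)


def landmark_face_box(shape: np.ndarray, margin: float = BOX_MARGIN):
    """Face box derived from landmarks; the train/track box convention."""
    return shape_box(shape, margin=margin)


# ---------------------------------------------------------------------------
# Serialization: .npz container with a JSON header and dense arrays


def save_model(path, model: CascadeModel) -> None:
    hp = model.hyperparams
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "hyperparams": {"T": hp.T, "K": hp.K, "P": hp.P, "F": hp.F,
                        "beta": hp.beta, "n_inits": hp.n_inits},
        "rng_seed": model.rng_seed,
        "landmark_scheme": model.landmark_scheme,
        "n_landmarks": model.n_landmarks,
        "n_stages": len(model.stages),
        "aisc": {k: {"center_id": v["center_id"],
                     "neighbor_ids": list(map(int, v["neighbor_ids"])),
                     "omega": list(map(float, v["omega"]))}
                 for k, v in model.aisc.items()},
    }
    arrays = {
        "header_json": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        "mean_shape": model.mean_shape,
        "error_trace": model.error_trace,
    }
    for t, stage in enumerate(model.stages):
        arrays[f"stage{t}_anchor_landmarks"] = stage.anchor_landmarks
        arrays[f"stage{t}_anchor_offsets"] = stage.anchor_offsets
        arrays[f"stage{t}_feature_ids"] = np.stack([f.feature_ids for f in stage.ferns])
        arrays[f"stage{t}_thresholds"] = np.stack([f.thresholds for f in stage.ferns])
        arrays[f"stage{t}_bin_outputs"] = np.stack([f.bin_outputs for f in stage.ferns])
    np.savez(path, **arrays)


def load_model(path) -> CascadeModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header_json"]).decode())
        if header["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {header['format_version']}")
        hp = Hyperparams(**header["hyperparams"])
        stages = []
        for t in range(header["n_stages"]):
            ferns = [
                Fern(feature_ids=fid, thresholds=th, bin_outputs=bo)
                for fid, th, bo in zip(
                    data[f"stage{t}_feature_ids"],
                    data[f"stage{t}_thresholds"],
                    data[f"stage{t}_bin_outputs"],
                )
            ]
            stages.append(
                StageRegressor(
                    anchor_landmarks=data[f"stage{t}_anchor_landmarks"],
                    anchor_offsets=data[f"stage{t}_anchor_offsets"],
                    ferns=ferns,
                )
            )
        return CascadeModel(
            stages=stages,
            mean_shape=data["mean_shape"],
            hyperparams=hp,
            rng_seed=header["rng_seed"],
            error_trace=data["error_trace"],
            landmark_scheme=header["landmark_scheme"],
            aisc={k: {"center_id": v["center_id"],
                      "neighbor_ids": np.array(v["neighbor_ids"], dtype=np.intp),
                      "omega": np.array(v["omega"])}
                  for k, v in header["aisc"].items()},
        )
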