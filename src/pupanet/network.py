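"""LeNet-5 variant and the embedded group-contrast (Siamese) training loop.

Architecture (default): 1x28x28 input -> conv 10@4x4 -> ramp -> 2x2 pool ->
conv 20@4x4 -> ramp -> 2x2 pool -> flatten(320) -> linear -> k-dim
embedding (k=2 by default, so the trained feature space can be plotted
directly).  Both images of a contrast pass through one shared-weight
network; the margin-based contrastive loss pulls same-group pairs together
and pushes different-group pairs apart up to a margin m_c:

    L(a, b) = same * d^2 + (1 - same) * max(0, m_c - d)^2,   d = ||f(a) - f(b)||

All convolutions, pooling, gradients and the Adam/SGD updates are computed
directly with numpy; gradients are validated against central differences in
the test suite.
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contrasts import BatchPlan, enumerate_contrasts, plan_batches
from .synthetic import SpecimenImage

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedModel",
    "FeatureSpace",
    "init_weights",
    "forward",
    "contrastive_loss",
    "train",
    "embed_set",
    "classify_nearest_centroid",
]


class ModelError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    """Layer specification of the LeNet-5 variant.

    Kernel size 4 and the 10/20 filter counts reproduce the published layer
    shape algebra 28 -> 25 -> 12 -> 9 -> 4 with a 320-length flatten vector.
    """

    in_size: int = 28
    conv1_filters: int = 10
    conv2_filters: int = 20
    kernel: int = 4
    pool: int = 2
    embed_dim: int = 2
    pooling: str = "max"  # or "avg"

    def layer_shapes(self) -> list[tuple[int, ...]]:
        k, p = self.kernel, self.pool
        s1 = self.in_size - k + 1
        s2 = s1 // p
        s3 = s2 - k + 1
        s4 = s3 // p
        return [
            (1, self.in_size, self.in_size),
            (self.conv1_filters, s1, s1),
            (self.conv1_filters, s2, s2),
            (self.conv2_filters, s3, s3),
            (self.conv2_filters, s4, s4),
            (self.conv2_filters * s4 * s4,),
            (self.embed_dim,),
        ]

    def flatten_len(self) -> int:
        return self.layer_shapes()[5][0]

    def n_parameters(self) -> int:
        k = self.kernel
        c1 = self.conv1_filters * (k * k + 1)
        c2 = self.conv2_filters * (self.conv1_filters * k * k + 1)
        fc = self.embed_dim * self.flatten_len() + self.embed_dim
        return c1 + c2 + fc


def init_weights(spec: NetworkSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded uniform fan-in initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)
    k = spec.kernel

    def u(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)

    return {
        "W1": u((spec.conv1_filters, 1, k, k), k * k),
        "b1": u((spec.conv1_filters,), k * k),
        "W2": u((spec.conv2_filters, spec.conv1_filters, k, k), spec.conv1_filters * k * k),
        "b2": u((spec.conv2_filters,), spec.conv1_filters * k * k),
        "W3": u((spec.embed_dim, spec.flatten_len()), spec.flatten_len()),
        "b3": u((spec.embed_dim,), spec.flatten_len()),
    }


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # (B,C,H,W) -> (B, OH*OW, C*k*k), valid convolution patches
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    b, c, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k), (oh, ow)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    # inverse of _im2col with accumulation
    b, c, h, w = x_shape
    oh, ow = h - k + 1, w - k + 1
    d = dcols.reshape(b, oh, ow, c, k, k)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di:di + oh, dj:dj + ow] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dx


def _conv_forward(x, W, b):
    k = W.shape[-1]
    cols, (oh, ow) = _im2col(x, k)
    out = cols @ W.reshape(W.shape[0], -1).T + b
    return out.transpose(0, 2, 1).reshape(x.shape[0], W.shape[0], oh, ow), cols


def _pool_forward(x, p, mode):
    b, c, h, w = x.shape
    h2, w2 = h // p, w // p
    xc = x[:, :, :h2 * p, :w2 * p].reshape(b, c, h2, p, w2, p)
    xw = xc.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, p * p)
    if mode == "max":
        arg = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, arg[..., None], axis=-1)[..., 0]
        return out, arg
    out = xw.mean(axis=-1)
    return out, None


def _pool_backward(dout, arg, x_shape, p, mode):
    b, c, h, w = x_shape
    h2, w2 = h // p, w // p
    dwin = np.zeros((b, c, h2, w2, p * p), dtype=dout.dtype)
    if mode == "max":
        np.put_along_axis(dwin, arg[..., None], dout[..., None], axis=-1)
    else:
        dwin[:] = dout[..., None] / (p * p)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, :h2 * p, :w2 * p] = (
        dwin.reshape(b, c, h2, w2, p, p).transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h2 * p, w2 * p)
    )
    return dx


def _check_weights(spec: NetworkSpec, weights: dict) -> None:
    k = spec.kernel
    expect = {
        "W1": (spec.conv1_filters, 1, k, k),
        "b1": (spec.conv1_filters,),
        "W2": (spec.conv2_filters, spec.conv1_filters, k, k),
        "b2": (spec.conv2_filters,),
        "W3": (spec.embed_dim, spec.flatten_len()),
        "b3": (spec.embed_dim,),
    }
    for name, shape in expect.items():
        if name not in weights or weights[name].shape != shape:
            got = weights.get(name)
            raise ModelError(
                f"weight {name}: expected shape {shape}, got "
                f"{None if got is None else got.shape}"
            )


def _forward_full(spec: NetworkSpec, weights: dict, x: np.ndarray) -> dict:
    """Forward pass keeping every intermediate needed for the backward pass."""
    c = {"x": x}
    z1, c["cols1"] = _conv_forward(x, weights["W1"], weights["b1"])
    a1 = np.maximum(z1, 0.0)
    p1, c["arg1"] = _pool_forward(a1, spec.pool, spec.pooling)
    z2, c["cols2"] = _conv_forward(p1, weights["W2"], weights["b2"])
    a2 = np.maximum(z2, 0.0)
    p2, c["arg2"] = _pool_forward(a2, spec.pool, spec.pooling)
    flat = p2.reshape(x.shape[0], -1)
    emb = flat @ weights["W3"].T + weights["b3"]
    c.update(z1=z1, p1=p1, z2=z2, p2=p2, flat=flat, emb=emb)
    return c


def _backward_full(spec: NetworkSpec, weights: dict, cache: dict,
                   demb: np.ndarray) -> dict:
    k = spec.kernel
    grads = {}
    grads["W3"] = demb.T @ cache["flat"]
    grads["b3"] = demb.sum(axis=0)
    dflat = demb @ weights["W3"]
    dp2 = dflat.reshape(cache["p2"].shape)

    da2 = _pool_backward(dp2, cache["arg2"], cache["z2"].shape, spec.pool, spec.pooling)
    dz2 = da2 * (cache["z2"] > 0)
    dz2_flat = dz2.reshape(dz2.shape[0], dz2.shape[1], -1).transpose(0, 2, 1)
    grads["W2"] = np.einsum("bpf,bpc->fc", dz2_flat, cache["cols2"]).reshape(weights["W2"].shape)
    grads["b2"] = dz2_flat.sum(axis=(0, 1))
    dcols2 = dz2_flat @ weights["W2"].reshape(weights["W2"].shape[0], -1)
    dp1 = _col2im(dcols2, cache["p1"].shape, k)

    da1 = _pool_backward(dp1, cache["arg1"], cache["z1"].shape, spec.pool, spec.pooling)
    dz1 = da1 * (cache["z1"] > 0)
    dz1_flat = dz1.reshape(dz1.shape[0], dz1.shape[1], -1).transpose(0, 2, 1)
    grads["W1"] = np.einsum("bpf,bpc->fc", dz1_flat, cache["cols1"]).reshape(weights["W1"].shape)
    grads["b1"] = dz1_flat.sum(axis=(0, 1))
    return grads


def _as_batch(image: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None] if x.shape[0] == 1 else x[:, None]
    if x.shape[-2:] != (spec.in_size, spec.in_size):
        raise ModelError(
            f"input images must be {spec.in_size}x{spec.in_size}, got {x.shape[-2:]}"
        )
    return x


def forward(spec: NetworkSpec, weights: dict, image: np.ndarray,
            trace: bool = False):
    """Map prepared image(s) to embedding vector(s).

    Accepts a single (28,28) / (1,28,28) image or a (B,1,28,28) batch.  With
    ``trace=True`` also returns the intermediate layer shapes for
    verification against the published architecture table.
    """
    _check_weights(spec, weights)
    x = _as_batch(image, spec)
    cache = _forward_full(spec, weights, x)
    emb = cache["emb"]
    single = np.asarray(image).ndim < 4
    result = emb[0] if (single and emb.shape[0] == 1) else emb
    if trace:
        shapes = [cache["z1"].shape[1:], cache["p1"].shape[1:],
                  cache["z2"].shape[1:], cache["p2"].shape[1:],
                  cache["flat"].shape[1:]]
        return result, shapes
    return result


def contrastive_loss(emb_a: np.ndarray, emb_b: np.ndarray, same_group,
                     margin: float = 1.0):
    """Margin contrastive loss, averaged over the batch when batched."""
    a, b = np.atleast_2d(emb_a), np.atleast_2d(emb_b)
    if a.shape != b.shape:
        raise ValueError(f"embedding shape mismatch: {a.shape} vs {b.shape}")
    same = np.atleast_1d(same_group).astype(float)
    d = np.linalg.norm(a - b, axis=1)
    per_pair = same * d**2 + (1 - same) * np.maximum(0.0, margin - d) ** 2
    return float(per_pair.mean())


def _contrastive_grad(emb_a, emb_b, same, margin):
    """d(mean loss)/d emb_a, emb_b for a batch."""
    n = emb_a.shape[0]
    diff = emb_a - emb_b
    d = np.linalg.norm(diff, axis=1)
    safe = np.maximum(d, 1e-12)
    # same pairs: dL/da = 2*diff ; different: -2*(m-d)_+ * diff/d
    coef = np.where(same, 2.0, -2.0 * np.maximum(0.0, margin - d) / safe)
    da = coef[:, None] * diff / n
    return da, -da


@dataclass(frozen=True)
class TrainConfig:
    margin: float = 1.0
    lr: float = 1e-3
    optimizer: str = "adam"  # or "sgd"
    n_rounds: int = 10
    batch_size: int = 64
    embed_dim: int = 2
    pairs_per_round: int | None = None
    balanced: bool = True
    init_seed: int = 0
    shuffle_seed: int = 0
    eval_every: int = 50  # batches between training-error log points
    pooling: str = "max"

    def validate(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class FeatureSpace:
    """Per-specimen k-dim scores plus per-group centroids."""

    scores: pd.DataFrame          # specimen_id, group, score_1..score_k
    centroids: pd.DataFrame       # group, score_1..score_k (sorted by group)

    @property
    def k(self) -> int:
        return sum(c.startswith("score_") for c in self.scores.columns)

    def score_matrix(self) -> np.ndarray:
        cols = [c for c in self.scores.columns if c.startswith("score_")]
        return self.scores[cols].to_numpy()


@dataclass
class TrainedModel:
    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    config: TrainConfig
    log: pd.DataFrame            # round, batch, loss, train_error

    def weights_digest(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.weights):
            h.update(self.weights[k].tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        """Portable container: JSON with spec/config header and
        base64-encoded little-endian float64 weight blocks."""
        blob = {
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "weights": {
                k: {
                    "shape": list(v.shape),
                    "data": base64.b64encode(
                        np.ascontiguousarray(v, dtype="<f8").tobytes()).decode(),
                }
                for k, v in self.weights.items()
            },
            "digest": self.weights_digest(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = json.loads(Path(path).read_text())
        spec = NetworkSpec(**blob["spec"])
        config = TrainConfig(**blob["config"])
        weights = {
            k: np.frombuffer(base64.b64decode(v["data"]), dtype="<f8")
            .reshape(v["shape"]).copy()
            for k, v in blob["weights"].items()
        }
        return cls(spec, weights, config, pd.DataFrame())


def _stack_images(images: list[SpecimenImage], spec: NetworkSpec,
                  dtype=np.float64) -> np.ndarray:
    x = np.stack([np.asarray(im.pixels, dtype=dtype) for im in images])
    if x.max() > 1.5:
        raise ModelError("images must be prepared to [0,1] before training")
    return x[:, None]


def _nearest_centroid_error(emb, groups):
    labels = np.array(sorted(set(groups)))
    cents = np.stack([emb[np.asarray(groups) == g].mean(axis=0) for g in labels])
    d = np.linalg.norm(emb[:, None] - cents[None], axis=2)
    pred = labels[d.argmin(axis=1)]
    return float((pred != np.asarray(groups)).mean())


def train(images: list[SpecimenImage], manifest: pd.DataFrame,
          config: TrainConfig = TrainConfig(),
          plan: BatchPlan | None = None) -> TrainedModel:
    """Train the shared-weight contrast network.

    Each batch passes both members of every contrast through the network in
    a single concatenated forward pass, applies the contrastive loss, and
    backpropagates through the shared weights.  The log records per-batch
    loss and periodic nearest-centroid training-set error.
    """
    config.validate()
    groups = manifest["group"].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    # singleton groups are tolerated (they still supply different-group
    # pairs and a centroid), but some group must yield same-group pairs
    if len(uniq) < 2 or counts.max() < 2:
        raise ValueError("training requires >= 2 groups and a group with >= 2 specimens")

    spec = NetworkSpec(embed_dim=config.embed_dim, pooling=config.pooling)
    # single precision: the contrastive objective is insensitive to the last
    # float64 digits and single precision roughly halves the training time
    x = _stack_images(images, spec, dtype=np.float32)
    id_to_idx = {im.specimen_id: i for i, im in enumerate(images)}

    contrasts = enumerate_contrasts(manifest, ordered=False)
    if plan is None:
        plan = BatchPlan(batch_size=config.batch_size, n_rounds=config.n_rounds,
                         shuffle_seed=config.shuffle_seed,
                         pairs_per_round=config.pairs_per_round,
                         balanced=config.balanced)
    rounds = plan_batches(contrasts, plan)

    ia = np.array([id_to_idx[c.id_a] for c in contrasts])
    ib = np.array([id_to_idx[c.id_b] for c in contrasts])
    same = np.array([c.same_group for c in contrasts])

    weights = {k: v.astype(np.float32) for k, v in init_weights(spec, config.init_seed).items()}
    m = {k: np.zeros_like(v) for k, v in weights.items()}
    v2 = {k: np.zeros_like(v) for k, v in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    log_rows = []
    for r, batches in enumerate(rounds):
        for bi, idx in enumerate(batches):
            a_idx, b_idx = ia[idx], ib[idx]
            s = same[idx]
            nb = len(idx)
            xb = np.concatenate([x[a_idx], x[b_idx]])
            cache = _forward_full(spec, weights, xb)
            ea, eb = cache["emb"][:nb], cache["emb"][nb:]
            loss = contrastive_loss(ea, eb, s, config.margin)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at round {r}, batch {bi}")
            da, db = _contrastive_grad(ea, eb, s, config.margin)
            grads = _backward_full(spec, weights, cache,
                                   np.concatenate([da, db]))
            step += 1
            for k in weights:
                g = grads[k]
                if config.optimizer == "adam":
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v2[k] = beta2 * v2[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v2[k] / (1 - beta2**step)
                    weights[k] -= config.lr * mhat / (np.sqrt(vhat) + eps)
                else:
                    weights[k] -= config.lr * g

            train_err = np.nan
            if step % config.eval_every == 0:
                emb = _forward_full(spec, weights, x)["emb"]
                train_err = _nearest_centroid_error(emb, groups)
            log_rows.append({"round": r, "batch": bi, "loss": loss,
                             "train_error": train_err})
        emb = _forward_full(spec, weights, x)["emb"]
        log_rows[-1]["train_error"] = _nearest_centroid_error(emb, groups)

    log = pd.DataFrame(log_rows)
    return TrainedModel(spec, weights, config, log)


def embed_set(model: TrainedModel, images: list[SpecimenImage]) -> FeatureSpace:
    """Project specimens into the trained feature space and fit per-group
    centroids (arithmetic means of group scores)."""
    x = _stack_images(images, model.spec)
    emb = _forward_full(model.spec, model.weights, x)["emb"]
    k = model.spec.embed_dim
    cols = [f"score_{i + 1}" for i in range(k)]
    scores = pd.DataFrame(emb, columns=cols)
    scores.insert(0, "group", [im.group for im in images])
    scores.insert(0, "specimen_id", [im.specimen_id for im in images])
    centroids = (scores.groupby("group", as_index=False)[cols].mean()
                 .sort_values("group").reset_index(drop=True))
    return FeatureSpace(scores, centroids)


def classify_nearest_centroid(space: FeatureSpace,
                              query_scores: np.ndarray) -> pd.DataFrame:
    """Assign each query score vector to the group with the nearest
    centroid (Euclidean).  Exact ties go to the lexicographically first
    group label and are flagged."""
    if len(space.centroids) == 0:
        raise ValueError("no centroids fitted")
    q = np.atleast_2d(np.asarray(query_scores, dtype=float))
    cols = [c for c in space.centroids.columns if c.startswith("score_")]
    cents = space.centroids[cols].to_numpy()
    labels = space.centroids["group"].to_numpy()  # sorted lexicographically
    d = np.linalg.norm(q[:, None] - cents[None], axis=2)
    best = d.argmin(axis=1)  # argmin returns the first (lexicographic) min
    tie = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame({"group": labels[best], "tie": tie})
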