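"""Segmentation backends exercising the level-set losses end-to-end.

Two consumers of the losses are provided:

* ``evolution`` — deterministic per-image gradient descent directly on the
  level-set field ``phi`` (no learned parameters).  With the LSR loss it needs
  the ground truth and serves as the reference vehicle for loss-driven
  segmentation; with the LS loss it is classical two-region active-contour
  evolution on the image alone and is what :meth:`segment` uses on unseen
  slices.

* ``network`` — a minimal encoder–decoder trained by gradient descent on the
  configured loss.  Four multi-scale feature maps (3x3 convolutions at scales
  1, 2, 4, 8 with ReLU) are fused by global-average-pooling weights
  ``W_i = GAP(F_i) / sum_j GAP(F_j)`` before a sigmoid output head.  The
  architecture is deliberately tiny — it exists to exercise the GAP weighting
  and the losses, not to compete with full-scale networks.

Both backends are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.signal import correlate2d

from gastroseg.losses import (
    LossConfig,
    ls_gradient,
    ls_loss,
    lsr_gradient,
    lsr_loss,
)
from gastroseg.phantoms import CTSlice, MaskPair

__all__ = [
    "DegenerateFeaturesError",
    "DivergenceError",
    "SegmenterConfig",
    "gap",
    "gap_weights",
    "evolve_level_set",
    "train_segmenter",
    "segment",
    "EvolutionModel",
    "NetworkModel",
    "save_model",
    "load_model",
]

_SCALES = (1, 2, 4, 8)  # pooling factors of the four feature maps


class DegenerateFeaturesError(ValueError):
    """All four feature maps pool to zero; GAP weights are undefined."""


class DivergenceError(RuntimeError):
    """The optimization produced a non-finite loss."""

    def __init__(self, iteration: int) -> None:
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class SegmenterConfig:
    """Hyperparameters shared by both backends.

    ``loss`` selects the training objective; ``weighted_sum`` combines
    ``ls_weight * LS + lsr_weight * LSR``.  The evolution backend defaults to
    a softer step (epsilon 20) and mild regularizer weights so the fidelity
    terms dominate on normalized images.
    """

    backend: Literal["network", "evolution"] = "evolution"
    loss: Literal["ls", "lsr", "weighted_sum"] = "lsr"
    iterations: int = 300
    learning_rate: float = 0.2
    seed: int = 0
    ls_weight: float = 1.0
    lsr_weight: float = 1.0
    loss_config: LossConfig = field(
        default_factory=lambda: LossConfig(mu=0.1, chi=0.05, epsilon=20.0)
    )

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def gap(feature_map: np.ndarray) -> float:
    """Global average pooling: the arithmetic mean of all entries."""
    arr = np.asarray(feature_map, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot pool an empty feature map")
    return float(arr.mean())


def gap_weights(features: Sequence[np.ndarray], rectify: bool = True) -> np.ndarray:
    """Normalized GAP weights W_i = GAP(F_i) / sum_j GAP(F_j) over 4 maps.

    Maps are rectified (clipped at zero) first by default so the normalization
    is well-defined; weights then sum to 1.
    """
    if len(features) != 4:
        raise ValueError(f"exactly 4 feature maps required, got {len(features)}")
    maps = [np.asarray(f, dtype=float) for f in features]
    if rectify:
        maps = [np.maximum(f, 0.0) for f in maps]
    gaps = np.array([gap(f) for f in maps])
    total = gaps.sum()
    if total == 0:
        raise DegenerateFeaturesError("all feature maps pool to zero")
    return gaps / total


# ---------------------------------------------------------------------------
# evolution backend
# ---------------------------------------------------------------------------


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def _loss_and_grad(
    loss: str,
    image_n: np.ndarray,
    gt: np.ndarray | None,
    phi: np.ndarray,
    cfg: SegmenterConfig,
) -> tuple[float, np.ndarray]:
    lc = cfg.loss_config
    if loss == "ls":
        return ls_loss(image_n, phi, lc), ls_gradient(image_n, phi, lc)
    if gt is None:
        raise ValueError(f"loss {loss!r} requires a ground-truth mask")
    if loss == "lsr":
        return lsr_loss(gt, phi, lc), lsr_gradient(gt, phi, lc)
    if loss == "weighted_sum":
        l1, g1 = ls_loss(image_n, phi, lc), ls_gradient(image_n, phi, lc)
        l2, g2 = lsr_loss(gt, phi, lc), lsr_gradient(gt, phi, lc)
        return cfg.ls_weight * l1 + cfg.lsr_weight * l2, cfg.ls_weight * g1 + cfg.lsr_weight * g2
    raise ValueError(f"unknown loss {loss!r}")


def evolve_level_set(
    image: CTSlice | np.ndarray,
    ground_truth: np.ndarray | None = None,
    config: SegmenterConfig = SegmenterConfig(),
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Projected gradient descent on phi; returns (phi, per-iteration loss log).

    The image is min–max normalized to [0, 1] internally so the fidelity terms
    are on the same scale as the regularizers.  phi is initialized from the
    normalized image (or ``init``) and clipped to [0, 1] after every step.
    """
    img = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=float)
    img_n = _normalize(img)
    phi = _normalize(np.asarray(init, dtype=float)) if init is not None else img_n.copy()
    log: list[float] = []
    for it in range(config.iterations):
        loss, grad = _loss_and_grad(config.loss, img_n, ground_truth, phi, config)
        if not np.isfinite(loss):
            raise DivergenceError(it)
        log.append(loss)
        phi = np.clip(phi - config.learning_rate * grad, 0.0, 1.0)
    return phi, log


# ---------------------------------------------------------------------------
# network backend (pure numpy, analytic backprop)
# ---------------------------------------------------------------------------


def _pool(x: np.ndarray, s: int) -> np.ndarray:
    h, w = x.shape
    return x.reshape(h // s, s, w // s, s).mean(axis=(1, 3))


def _unpool(x: np.ndarray, s: int) -> np.ndarray:
    return np.repeat(np.repeat(x, s, axis=0), s, axis=1)


def _conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    # cross-correlation with zero padding (the deep-learning "conv")
    return correlate2d(x, k, mode="same", boundary="fill")


@dataclass
class NetworkModel:
    """Parameters of the numpy encoder–decoder: one 3x3 kernel + bias per scale,
    plus an affine sigmoid head.  ``kernels[i]`` acts at pooling factor
    ``_SCALES[i]``."""

    kernels: list[np.ndarray]
    biases: np.ndarray
    head_scale: float
    head_bias: float

    kind: str = "network"

    def forward(self, img: np.ndarray, return_cache: bool = False):
        if img.shape[0] % _SCALES[-1] or img.shape[1] % _SCALES[-1]:
            raise ValueError(
                f"network backend requires dimensions divisible by {_SCALES[-1]}, "
                f"got {img.shape}"
            )
        x = _normalize(img)
        pooled, pre, feats = [], [], []
        for i, s in enumerate(_SCALES):
            xs = _pool(x, s)
            z = _conv_same(xs, self.kernels[i]) + self.biases[i]
            f = np.maximum(z, 0.0)
            pooled.append(xs)
            pre.append(z)
            feats.append(_unpool(f, s))
        W = gap_weights(feats, rectify=True)
        fused = sum(w * f for w, f in zip(W, feats))
        zhead = self.head_scale * fused + self.head_bias
        phi = 1.0 / (1.0 + np.exp(-zhead))
        if return_cache:
            return phi, {"pooled": pooled, "pre": pre, "W": W, "fused": fused}
        return phi


def _init_network(seed: int) -> NetworkModel:
    rng = np.random.default_rng(seed)
    kernels = []
    for _ in _SCALES:
        k = rng.normal(0.0, 0.05, size=(3, 3))
        k[1, 1] += 1.0  # near-identity init: features start as smoothed image
        kernels.append(k)
    return NetworkModel(
        kernels=kernels,
        biases=np.full(len(_SCALES), 0.01),
        head_scale=6.0,
        head_bias=-3.0,  # sigmoid(6*f - 3): maps feature ~0.5 to phi ~0.5
    )


def _network_backward(
    model: NetworkModel, dphi: np.ndarray, phi: np.ndarray, cache: dict
) -> dict:
    dz = dphi * phi * (1.0 - phi)
    grads: dict = {
        "head_scale": float((dz * cache["fused"]).sum()),
        "head_bias": float(dz.sum()),
        "kernels": [],
        "biases": np.zeros(len(_SCALES)),
    }
    dfused = model.head_scale * dz
    for i, s in enumerate(_SCALES):
        # GAP weights treated as constants (detached) during backprop
        dF_full = cache["W"][i] * dfused
        h, w = dF_full.shape
        dF = dF_full.reshape(h // s, s, w // s, s).sum(axis=(1, 3))
        dpre = dF * (cache["pre"][i] > 0)
        grads["biases"][i] = float(dpre.sum())
        xpad = np.pad(cache["pooled"][i], 1)
        grads["kernels"].append(correlate2d(xpad, dpre, mode="valid"))
    return grads


@dataclass
class EvolutionModel:
    """State of the evolution backend: just the config (nothing is learned)."""

    config: SegmenterConfig
    kind: str = "evolution"


def train_segmenter(
    pairs: Sequence[tuple[CTSlice, MaskPair]],
    config: SegmenterConfig = SegmenterConfig(),
) -> tuple[EvolutionModel | NetworkModel, list[float]]:
    """Fit the configured backend on (slice, mask) pairs; returns (model, loss log).

    * ``evolution``: evolves phi per image with the configured loss and logs the
      mean loss per iteration; the returned model carries only the config.
    * ``network``: full-batch gradient descent on the encoder–decoder weights.

    A fixed ``config.seed`` makes the log bit-reproducible.  A non-finite loss
    aborts with :class:`DivergenceError` naming the iteration.
    """
    if len(pairs) < 2:
        raise ValueError("at least 2 training pairs required")
    if config.backend == "evolution":
        logs = []
        for slc, mp in pairs:
            _, log = evolve_level_set(slc, mp.ground_truth, config)
            logs.append(log)
        mean_log = list(np.mean(np.array(logs), axis=0))
        return EvolutionModel(config=config), mean_log

    model = _init_network(config.seed)
    imgs = [slc.pixels for slc, _ in pairs]
    gts = [mp.ground_truth.astype(float) for _, mp in pairs]
    log: list[float] = []
    lr = config.learning_rate
    for it in range(config.iterations):
        total = 0.0
        acc = None
        for img, gt in zip(imgs, gts):
            phi, cache = model.forward(img, return_cache=True)
            phi = np.clip(phi, 1e-7, 1.0 - 1e-7)
            loss, dphi = _loss_and_grad(config.loss, _normalize(img), gt, phi, config)
            # per-pixel mean keeps gradient magnitudes independent of image size
            loss, dphi = loss / phi.size, dphi / phi.size
            total += loss
            g = _network_backward(model, dphi, phi, cache)
            if acc is None:
                acc = g
            else:
                acc["head_scale"] += g["head_scale"]
                acc["head_bias"] += g["head_bias"]
                acc["biases"] += g["biases"]
                for a, b in zip(acc["kernels"], g["kernels"]):
                    a += b
        total /= len(pairs)
        if not np.isfinite(total):
            raise DivergenceError(it)
        log.append(total)
        n = len(pairs)
        model.head_scale -= lr * acc["head_scale"] / n
        model.head_bias -= lr * acc["head_bias"] / n
        model.biases = model.biases - lr * acc["biases"] / n
        model.kernels = [k - lr * dk / n for k, dk in zip(model.kernels, acc["kernels"])]
    return model, log


def segment(model: EvolutionModel | NetworkModel, slc: CTSlice) -> np.ndarray:
    """Produce a level-set field phi in [0, 1] for a slice.

    The evolution model runs image-driven (LS-loss) evolution — ground truth
    is unavailable at inference; the network model runs its forward pass.
    """
    if isinstance(model, NetworkModel):
        return model.forward(slc.pixels)
    cfg_dict = model.config.__dict__ | {"loss": "ls"}
    cfg = SegmenterConfig(**cfg_dict)
    phi, _ = evolve_level_set(slc, None, cfg)
    return phi


def save_model(model: EvolutionModel | NetworkModel, path: str | Path) -> Path:
    """Serialize a model to a single NPZ archive with a format-version field."""
    path = Path(path)
    if isinstance(model, NetworkModel):
        np.savez(
            path,
            version=np.array(1),
            kind=np.array("network"),
            biases=model.biases,
            head=np.array([model.head_scale, model.head_bias]),
            **{f"kernel{i}": k for i, k in enumerate(model.kernels)},
        )
    else:
        c = model.config
        lc = c.loss_config
        np.savez(
            path,
            version=np.array(1),
            kind=np.array("evolution"),
            scalars=np.array([c.iterations, c.learning_rate, c.seed, c.ls_weight, c.lsr_weight]),
            loss=np.array(c.loss),
            loss_cfg=np.array([lc.mu, lc.chi, lc.delta1, lc.delta2, lc.delta3, lc.epsilon]),
        )
    return path


def load_model(path: str | Path) -> EvolutionModel | NetworkModel:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != 1:
            raise ValueError(f"unsupported model version {int(z['version'])}")
        if str(z["kind"]) == "network":
            return NetworkModel(
                kernels=[z[f"kernel{i}"] for i in range(len(_SCALES))],
                biases=z["biases"],
                head_scale=float(z["head"][0]),
                head_bias=float(z["head"][1]),
            )
        s = z["scalars"]
        lc = z["loss_cfg"]
        return EvolutionModel(
            config=SegmenterConfig(
                backend="evolution",
                loss=str(z["loss"]),  # type: ignore[arg-type]
                iterations=int(s[0]),
                learning_rate=float(s[1]),
                seed=int(s[2]),
                ls_weight=float(s[3]),
                lsr_weight=float(s[4]),
                loss_config=LossConfig(
                    mu=float(lc[0]),
                    chi=float(lc[1]),
                    delta1=float(lc[2]),
                    delta2=float(lc[3]),
                    delta3=float(lc[4]),
                    epsilon=float(lc[5]),
                ),
            )
        )
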