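"""Level-set segmentation losses with a smoothed arctan step function.

Two losses are provided, both built on the two-region (Chan–Vese style)
decomposition of an image by a level-set field ``phi`` in [0, 1]:

* **LS loss** — the classical active-contour energy used as a training loss:
  contour-length and region-area regularizers plus two intensity-fidelity
  terms that pull the per-region means ``c1`` (inside) and ``c2`` (outside)
  toward the observed image::

      F = mu*length(phi) + chi*area(phi)
        + delta1 * sum (mu0 - c1)^2 * H(phi)
        + delta2 * sum (mu0 - c2)^2 * (1 - H(phi))

* **LSR loss** — a regularized variant that compares the prediction against a
  binary ground truth ``G`` instead of the raw image, adding a direct
  pixel-fidelity term.  It targets structures with distinct inner and outer
  edges (the gastric wall) where a single-edge energy under-segments::

      LSR = (1/delta1) * sum (G - c1)^2 * H(phi)
          + (1/delta2) * sum (G - c2)^2 * (1 - H(phi))
          + (1/delta3) * sum (G - phi)^2

Here ``H`` is the smoothed Heaviside step ``H(x) = (1 + (2/pi) arctan(eps*x)) / 2``
whose sharpness ``eps`` controls how closely the soft region indicator
approximates a hard one, and the step is evaluated on the *centered* field
``phi - 1/2`` so that for sharp ``eps``, ``H(phi - 1/2) ~ phi`` on binary
fields and the perfect-prediction limit ``LSR(G, phi=G) -> 0`` holds.

Region means ``c1``/``c2`` are the H-weighted averages of the reference field;
because they are weighted means, the loss is stationary with respect to them,
so the analytic gradient of the LSR loss does not pick up any term from their
dependence on ``phi`` (envelope argument) — the "detached" and "exact"
gradients coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gastroseg.phantoms import CTSlice

__all__ = [
    "LossConfig",
    "DegeneratePartitionError",
    "smoothed_step",
    "smoothed_step_literal",
    "smoothed_step_derivative",
    "curve_length",
    "region_area",
    "region_means",
    "ls_loss",
    "lsr_loss",
    "lsr_gradient",
    "ls_gradient",
]

#: Relative floor under which an H-weighted denominator counts as degenerate.
_DENOM_TOL = 1e-12


class DegeneratePartitionError(ValueError):
    """The level-set field puts (numerically) everything on one side."""


@dataclass(frozen=True)
class LossConfig:
    """Quantitative weights of the loss terms and step-function sharpness.

    All weights must be strictly positive.  ``epsilon`` controls the gradient
    of the smoothed step at the crossing; the default 100 makes H effectively
    hard on [0,1]-valued fields while staying differentiable.
    """

    mu: float = 1.0
    chi: float = 1.0
    delta1: float = 1.0
    delta2: float = 1.0
    delta3: float = 1.0
    epsilon: float = 100.0

    def __post_init__(self) -> None:
        for name in ("mu", "chi", "delta1", "delta2", "delta3", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def smoothed_step(x: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Smoothed Heaviside H(x) = (1 + (2/pi) arctan(eps*x)) / 2.

    Strictly increasing, H(0) = 1/2, limits 0 and 1 at -inf/+inf; ``epsilon``
    raises the gradient of the function at the origin.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    out = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(epsilon * np.asarray(x, dtype=float)))
    return float(out) if out.ndim == 0 else out


def smoothed_step_literal(x: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Audit-only variant with the printed constants H(x) = arctan(eps*x)/180 + 60.

    Dimensionally incoherent as a step function (range is not (0,1)); kept so
    the published form can be inspected.  Not used by any loss.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    out = np.arctan(epsilon * np.asarray(x, dtype=float)) / 180.0 + 60.0
    return float(out) if out.ndim == 0 else out


def smoothed_step_derivative(x: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """dH/dx = eps / (pi * (1 + (eps*x)^2)) for the arctan step."""
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    z = epsilon * np.asarray(x, dtype=float)
    out = epsilon / (np.pi * (1.0 + z * z))
    return float(out) if out.ndim == 0 else out


def _as_phi(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2:
        raise ValueError(f"phi must be 2-D, got ndim={phi.ndim}")
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi must be finite")
    if phi.min() < 0 or phi.max() > 1:
        raise ValueError("phi values must lie in [0, 1]")
    return phi


def _H_centered(phi: np.ndarray, epsilon: float) -> np.ndarray:
    # the step acts on the centered field so H(phi) ~ phi on sharp binary fields
    return smoothed_step(phi - 0.5, epsilon)  # type: ignore[return-value]


def curve_length(phi: np.ndarray, epsilon: float = 100.0) -> float:
    """Contour-length regularizer: sum of |forward differences| of H(phi - 1/2).

    The L1 norm of the discrete gradient of the soft indicator; for a sharp
    step this counts the boundary edges of the segmented region.  Forward
    (one-sided) differences; the last row/column has no forward neighbour and
    contributes nothing.
    """
    H = _H_centered(_as_phi(phi), epsilon)
    return float(np.abs(np.diff(H, axis=0)).sum() + np.abs(np.diff(H, axis=1)).sum())


def region_area(phi: np.ndarray, epsilon: float = 100.0) -> float:
    """Region-area regularizer: sum of H(phi - 1/2) (soft inside-pixel count)."""
    return float(_H_centered(_as_phi(phi), epsilon).sum())


def region_means(
    reference: np.ndarray, phi: np.ndarray, epsilon: float = 100.0
) -> tuple[float, float]:
    """H-weighted means of ``reference`` inside (c1) and outside (c2) the contour.

    c1 = sum(ref * H) / sum(H),  c2 = sum(ref * (1-H)) / sum(1-H),
    with H = H(phi - 1/2).  Raises :class:`DegeneratePartitionError` when the
    field puts numerically all weight on one side.
    """
    ref = np.asarray(reference, dtype=float)
    phi = _as_phi(phi)
    if ref.shape != phi.shape:
        raise ValueError(f"reference shape {ref.shape} != phi shape {phi.shape}")
    H = _H_centered(phi, epsilon)
    n = H.size
    s1, s0 = float(H.sum()), float((1.0 - H).sum())
    if s1 <= _DENOM_TOL * n or s0 <= _DENOM_TOL * n:
        raise DegeneratePartitionError(
            "level-set field is all-inside or all-outside; region means undefined"
        )
    c1 = float((ref * H).sum() / s1)
    c2 = float((ref * (1.0 - H)).sum() / s0)
    return c1, c2


def ls_loss(
    image: CTSlice | np.ndarray, phi: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Level-set (active contour) loss of ``phi`` against the observed image.

    mu*length + chi*area + delta1*sum (mu0-c1)^2 H + delta2*sum (mu0-c2)^2 (1-H).
    Non-negative; small when ``phi`` separates two homogeneous intensity regions.
    """
    mu0 = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=float)
    phi = _as_phi(phi)
    if mu0.shape != phi.shape:
        raise ValueError(f"image shape {mu0.shape} != phi shape {phi.shape}")
    eps = config.epsilon
    H = _H_centered(phi, eps)
    c1, c2 = region_means(mu0, phi, eps)
    fid1 = float(((mu0 - c1) ** 2 * H).sum())
    fid2 = float(((mu0 - c2) ** 2 * (1.0 - H)).sum())
    return (
        config.mu * curve_length(phi, eps)
        + config.chi * region_area(phi, eps)
        + config.delta1 * fid1
        + config.delta2 * fid2
    )


def lsr_loss(
    ground_truth: np.ndarray, phi: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Regularized level-set loss of ``phi`` against a binary ground truth.

    (1/delta1) sum (G-c1)^2 H + (1/delta2) sum (G-c2)^2 (1-H)
    + (1/delta3) sum (G-phi)^2, with H = H(phi - 1/2) and c1/c2 the H-weighted
    means of G.  Vanishes in the sharp limit at the perfect prediction phi = G
    (both classes present).
    """
    G = np.asarray(ground_truth, dtype=float)
    if not np.isin(G, (0.0, 1.0)).all():
        raise ValueError("ground_truth must be binary (0/1)")
    phi = _as_phi(phi)
    if G.shape != phi.shape:
        raise ValueError(f"ground_truth shape {G.shape} != phi shape {phi.shape}")
    eps = config.epsilon
    H = _H_centered(phi, eps)
    c1, c2 = region_means(G, phi, eps)
    f1 = float(((G - c1) ** 2 * H).sum()) / config.delta1
    f2 = float(((G - c2) ** 2 * (1.0 - H)).sum()) / config.delta2
    f3 = float(((G - phi) ** 2).sum()) / config.delta3
    return f1 + f2 + f3


def lsr_gradient(
    ground_truth: np.ndarray, phi: np.ndarray, config: LossConfig = LossConfig()
) -> np.ndarray:
    """d(LSR)/d(phi) at every pixel, c1/c2 treated as functions of phi.

    Because c1 and c2 are the H-weighted means of G, the terms arising from
    their dependence on phi cancel exactly (sum (G - c) * weight = 0), so the
    gradient reduces to::

        [ (G-c1)^2/delta1 - (G-c2)^2/delta2 ] * H'(phi - 1/2)
        + 2 (phi - G) / delta3
    """
    G = np.asarray(ground_truth, dtype=float)
    phi = _as_phi(phi)
    if G.shape != phi.shape:
        raise ValueError(f"ground_truth shape {G.shape} != phi shape {phi.shape}")
    eps = config.epsilon
    c1, c2 = region_means(G, phi, eps)
    Hp = smoothed_step_derivative(phi - 0.5, eps)
    fid = ((G - c1) ** 2 / config.delta1 - (G - c2) ** 2 / config.delta2) * Hp
    return fid + 2.0 * (phi - G) / config.delta3


def ls_gradient(
    image: CTSlice | np.ndarray, phi: np.ndarray, config: LossConfig = LossConfig()
) -> np.ndarray:
    """d(LS)/d(phi): fidelity terms plus length/area regularizer subgradients.

    The length term uses the sign pattern of the forward differences of H
    (subgradient of the L1 norm); region means are stationary as in
    :func:`lsr_gradient`.
    """
    mu0 = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=float)
    phi = _as_phi(phi)
    if mu0.shape != phi.shape:
        raise ValueError(f"image shape {mu0.shape} != phi shape {phi.shape}")
    eps = config.epsilon
    H = _H_centered(phi, eps)
    Hp = smoothed_step_derivative(phi - 0.5, eps)
    c1, c2 = region_means(mu0, phi, eps)

    # subgradient of sum |dH| under forward differences
    grad_H = np.zeros_like(H)
    dv = np.sign(np.diff(H, axis=0))
    grad_H[:-1, :] -= dv
    grad_H[1:, :] += dv
    dh = np.sign(np.diff(H, axis=1))
    grad_H[:, :-1] -= dh
    grad_H[:, 1:] += dh

    fid = (config.delta1 * (mu0 - c1) ** 2 - config.delta2 * (mu0 - c2) ** 2) * Hp
    return config.mu * grad_H * Hp + config.chi * Hp + fid
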