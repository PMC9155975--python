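"""Random-noise pixel insertion for enlarging a CT training set.

Geometric augmentation (rotation, flips, elastic warps) is a poor fit for
gastric CT because the wall's position and orientation carry information, so
the training set is enlarged instead by adding an independent random
perturbation to every pixel:

    Q* = Q + sigma * cos(180deg + a1) * sqrt(-2 ln a2),

with a1 uniform on [0deg, 360deg) and a2 uniform on (0, 1].  The product
cos(angle) * sqrt(-2 ln u) is exactly one branch of the Box-Muller transform,
so the perturbation is standard normal; the 180deg shift only flips the sign
of the cosine and leaves the distribution unchanged.  ``sigma`` (default 1)
scales the perturbation to keep pixel variation within a chosen range.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from gastroseg.phantoms import CTSlice

__all__ = ["noise_term", "insert_noise"]


def noise_term(alpha1: float | np.ndarray, alpha2: float | np.ndarray) -> float | np.ndarray:
    """Additive perturbation cos(180deg + alpha1) * sqrt(-2 ln alpha2).

    Parameters
    ----------
    alpha1
        Random angle in **degrees**.
    alpha2
        Random magnitude term in (0, 1]; the natural logarithm is used, which
        is what makes the term exactly standard normal for uniform draws.
    """
    a2 = np.asarray(alpha2, dtype=float)
    if np.any(a2 <= 0) or np.any(a2 > 1):
        raise ValueError("alpha2 must lie in (0, 1]")
    a1 = np.asarray(alpha1, dtype=float)
    out = np.cos(np.deg2rad(180.0 + a1)) * np.sqrt(-2.0 * np.log(a2))
    return float(out) if out.ndim == 0 else out


def insert_noise(
    slc: CTSlice,
    seed: int,
    sigma: float = 1.0,
    clamp: tuple[float, float] | None = None,
) -> CTSlice:
    """Return a copy of ``slc`` with i.i.d. noise terms added to every pixel.

    Per pixel, alpha1 ~ Uniform[0, 360) degrees and alpha2 ~ Uniform(0, 1];
    the same seed always reproduces the same output.  ``clamp=(lo, hi)``
    clips the result to a valid intensity range (either bound may be
    ``-inf``/``inf``).
    """
    rng = np.random.default_rng(seed)
    shape = slc.pixels.shape
    alpha1 = rng.uniform(0.0, 360.0, size=shape)
    alpha2 = 1.0 - rng.random(size=shape)  # in (0, 1]
    out = slc.pixels + sigma * noise_term(alpha1, alpha2)
    if clamp is not None:
        lo, hi = clamp
        out = np.clip(out, lo, hi)
    return dataclasses.replace(slc, pixels=out)
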