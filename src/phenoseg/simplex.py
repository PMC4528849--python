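"""Geometry of the probability simplex and the distances it induces.

Normalized surface feature histograms are compositions: nonnegative vectors
summing to one.  Two embeddings make Euclidean machinery applicable to them:

* the square-root map onto the positive quadrant of the unit sphere, under
  which squared Euclidean distance equals the Hellinger distance between the
  original histograms, and
* the centered log-ratio (clr) map onto the zero-sum hyperplane, under which
  Euclidean distance equals the Aitchison distance.

The clr map needs strictly positive input, so empty histogram bins are first
handled by :func:`replace_zeros`.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "euclidean_distance",
    "hellinger_distance",
    "sqr_transform",
    "replace_zeros",
    "clr_transform",
    "clr_inverse",
    "aitchison_distance",
]

_SIMPLEX_ATOL = 1e-9


def _as_array(x: ArrayLike, name: str = "x") -> NDArray[np.float64]:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite components")
    return a


def _check_simplex(x: NDArray[np.float64], name: str = "x") -> None:
    if np.any(x < -_SIMPLEX_ATOL):
        raise ValueError(f"{name} has negative components; not on the simplex")
    s = x.sum(axis=-1)
    if not np.allclose(s, 1.0, atol=1e-6):
        raise ValueError(f"{name} rows must sum to 1 (got {s})")


def euclidean_distance(x: ArrayLike, y: ArrayLike) -> float:
    """Euclidean distance ``sqrt(sum_i (x_i - y_i)^2)`` between two vectors."""
    xa, ya = _as_array(x), _as_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError(f"dimension mismatch: {xa.shape} vs {ya.shape}")
    return float(np.linalg.norm(xa - ya))


def hellinger_distance(x: ArrayLike, y: ArrayLike) -> float:
    """Hellinger distance between two histograms, ``sum_i (sqrt(x_i) - sqrt(y_i))^2``.

    This is the squared-difference form (no 1/2 factor, no outer square
    root): exactly the squared Euclidean distance between the square-root
    transforms of ``x`` and ``y``, which is what makes plain k-means on
    square-root-transformed histograms minimize it.
    """
    xa, ya = _as_array(x), _as_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError(f"dimension mismatch: {xa.shape} vs {ya.shape}")
    if np.any(xa < 0) or np.any(ya < 0):
        raise ValueError("histograms must be nonnegative")
    d = np.sqrt(xa) - np.sqrt(ya)
    return float(np.dot(d, d))


def sqr_transform(x: ArrayLike) -> NDArray[np.float64]:
    """Map a composition to the positive quadrant of the unit sphere.

    Componentwise square root; rows of simplex input come out with unit
    Euclidean norm.  Accepts a single vector or a matrix of row vectors.
    """
    xa = _as_array(x)
    _check_simplex(xa)
    return np.sqrt(np.clip(xa, 0.0, None))


def replace_zeros(x: ArrayLike, epsilon: float | None = None) -> NDArray[np.float64]:
    """Strictly positive version of a composition, for log-ratio transforms.

    Adds ``epsilon`` to *every* component (not only the zeros) and
    renormalizes each row to sum 1.  Adding to all components, rather than
    only to empty bins, keeps the perturbation uniform.  Default
    ``epsilon = 1/m`` where ``m`` is the number of bins.
    """
    xa = _as_array(x)
    m = xa.shape[-1]
    eps = 1.0 / m if epsilon is None else float(epsilon)
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    out = xa + eps
    return out / out.sum(axis=-1, keepdims=True)


def clr_transform(x: ArrayLike) -> NDArray[np.float64]:
    """Centered log-ratio transform ``ln(x_i / g(x))`` with g the geometric mean.

    Maps the simplex interior onto the hyperplane of zero-sum vectors.
    Input must be strictly positive (apply :func:`replace_zeros` first);
    a nonpositive component raises ``ValueError``.
    """
    xa = _as_array(x)
    if np.any(xa <= 0):
        raise ValueError(
            "clr requires strictly positive components; apply replace_zeros first"
        )
    lx = np.log(xa)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr_inverse(y: ArrayLike) -> NDArray[np.float64]:
    """Inverse clr: softmax ``exp(y_i) / sum_j exp(y_j)``, back on the simplex.

    The maximum is subtracted before exponentiating; analytically identical,
    numerically safe for large components.
    """
    ya = _as_array(y, "y")
    z = np.exp(ya - ya.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def aitchison_distance(x: ArrayLike, y: ArrayLike) -> float:
    """Aitchison distance: Euclidean distance between the clr images.

    The natural metric of compositional data analysis,
    ``sqrt(sum_i (ln(x_i/g(x)) - ln(y_i/g(y)))^2)``.  Both arguments must be
    strictly positive compositions.
    """
    cx, cy = clr_transform(x), clr_transform(y)
    if cx.shape != cy.shape:
        raise ValueError(f"dimension mismatch: {cx.shape} vs {cy.shape}")
    return float(np.linalg.norm(cx - cy))
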