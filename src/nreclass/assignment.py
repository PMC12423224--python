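"""Nearest-centroid assignment and soft classification probabilities.

An individual's standardised feature vector z is compared with the K
sex-specific cluster centroids c_k via Euclidean distance
d_k = ||z - c_k||.  The individual is assigned to the nearest centroid,
and the distances are converted to classification probabilities that sum
to one.  Three constructions are available:

``inverse_distance`` (default, the primary analysis)
    p_k proportional to 1/d_k.  Scale-invariant in the distances: only the
    *relative* geometry of the centroids matters.

``softmax``
    p_k proportional to exp(-d_k / temperature).

``rbf``
    p_k proportional to exp(-d_k^2 / (2 * bandwidth^2)) (Gaussian kernel).

All three rank probabilities inversely to distance, so the argmax
probability always coincides with the nearest centroid.  For a coincident
point (d_k = 0 within tolerance) the inverse-distance rule takes its
continuity limit: probability mass is split uniformly over the coincident
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .reference import ReferenceModel

__all__ = [
    "ClassificationResult",
    "ZERO_DISTANCE_TOL",
    "distances_to_centroids",
    "assign_nearest",
    "inverse_distance_probabilities",
    "softmax_probabilities",
    "rbf_probabilities",
    "probabilities_from_distances",
]

#: Distances below this (standardised units) are treated as exactly zero.
ZERO_DISTANCE_TOL = 1e-12

_METHODS = ("inverse_distance", "softmax", "rbf")


@dataclass(frozen=True)
class ClassificationResult:
    """Distances, probabilities and hard assignment for one individual."""

    id: str
    sex: str
    distances: tuple[float, ...]
    probabilities: tuple[float, ...]
    assigned_cluster: str
    assigned_probability: float
    min_distance: float
    method: str
    tie: bool = False
    nre: Optional[float] = None


def distances_to_centroids(
    z: np.ndarray, model: ReferenceModel, sex: str
) -> np.ndarray:
    """Euclidean distances from ``z`` to each centroid of ``sex``.

    Returned in the model's cluster order.  ``z`` may be a single vector
    of length p or an (n, p) array; the result is (K,) or (n, K).
    """
    z = np.asarray(z, dtype=float)
    centroids = model.centroid_matrix(sex)  # (K, p)
    if z.shape[-1] != centroids.shape[1]:
        raise ValueError(
            f"feature dimension {z.shape[-1]} does not match model "
            f"dimension {centroids.shape[1]}"
        )
    diff = z[..., np.newaxis, :] - centroids  # (..., K, p)
    return np.sqrt(np.sum(diff**2, axis=-1))


def assign_nearest(
    distances: Sequence[float], cluster_labels: Sequence[str]
) -> tuple[str, bool]:
    """Label of the minimal distance; ties broken by cluster order.

    Returns ``(label, tie)`` where ``tie`` flags an exact tie for the
    minimum.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if d.size != len(cluster_labels):
        raise ValueError("distances and labels differ in length")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    idx = int(np.argmin(d))  # first minimum wins
    tie = bool(np.sum(d == d[idx]) > 1)
    return cluster_labels[idx], tie


def inverse_distance_probabilities(distances: Sequence[float]) -> np.ndarray:
    """Normalised inverse distances: p_k = (1/d_k) / sum_j (1/d_j).

    Zero distances (within :data:`ZERO_DISTANCE_TOL`) receive the
    continuity limit: uniform mass over the coincident centroids, zero
    elsewhere.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    zero = d <= ZERO_DISTANCE_TOL
    if np.any(zero):
        p = np.zeros_like(d)
        p[zero] = 1.0 / zero.sum()
        return p
    inv = 1.0 / d
    total = inv.sum()
    if not np.isfinite(total) or total == 0:
        raise ValueError("cannot normalise inverse distances (all infinite?)")
    return inv / total


def softmax_probabilities(
    distances: Sequence[float], temperature: float
) -> np.ndarray:
    """Exponential-decay probabilities p_k proportional to exp(-d_k/T)."""
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    # subtract the minimum before exponentiation for numerical stability
    w = np.exp(-(d - d.min()) / temperature)
    return w / w.sum()


def rbf_probabilities(distances: Sequence[float], bandwidth: float) -> np.ndarray:
    """Gaussian-kernel probabilities p_k proportional to exp(-d_k^2/(2h^2))."""
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    q = d**2
    w = np.exp(-(q - q.min()) / (2.0 * bandwidth**2))
    return w / w.sum()


def probabilities_from_distances(
    distances: Sequence[float],
    method: str = "inverse_distance",
    *,
    temperature: Optional[float] = None,
    bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Dispatch to the chosen probability construction.

    ``softmax`` requires an explicit ``temperature`` and ``rbf`` an
    explicit ``bandwidth``; there are no silent defaults for either.
    """
    if method == "inverse_distance":
        return inverse_distance_probabilities(distances)
    if method == "softmax":
        if temperature is None:
            raise ValueError("softmax requires an explicit temperature")
        return softmax_probabilities(distances, temperature)
    if method == "rbf":
        if bandwidth is None:
            raise ValueError("rbf requires an explicit bandwidth")
        return rbf_probabilities(distances, bandwidth)
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
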