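"""Normalised relative entropy (NRE) of a classification-probability vector.

The NRE condenses the K classification probabilities of an individual into
a single certainty score on [0, 1]:

    NRE = 1 + (sum_k p_k * ln p_k) / ln K

with the convention 0 * ln 0 = 0.  It equals the Kullback-Leibler
divergence of p from the uniform distribution, divided by ln K.  NRE = 0
means complete uncertainty (all probabilities equal 1/K); NRE = 1 means
complete certainty (all mass on the assigned cluster).  It is a
conservative measure: an assigned probability of 97% over four clusters
yields an NRE of only about 0.87.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assignment import probabilities_from_distances

__all__ = ["NREValue", "nre", "nre_values", "nre_from_distances"]

_SUM_TOL = 1e-9
_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class NREValue:
    """An NRE together with the cluster count K used for normalisation."""

    value: float
    k: int


def _validate_simplex(p: np.ndarray) -> None:
    if p.ndim != 1 or p.size < 2:
        raise ValueError("probability vector must be 1-d with at least 2 entries")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    total = p.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"probabilities sum to {total}, not 1")


def nre(probabilities: Sequence[float]) -> NREValue:
    """Normalised relative entropy of one probability vector.

    K is taken from the vector length, so the same formula applies to
    subtype systems with any number of clusters.
    """
    p = np.asarray(probabilities, dtype=float)
    _validate_simplex(p)
    nonzero = p > 0
    plogp = np.sum(p[nonzero] * np.log(p[nonzero]))  # 0*ln 0 = 0
    value = 1.0 + plogp / np.log(p.size)
    if value < 0:
        if value < -_CLAMP_TOL:
            raise ValueError(f"NRE {value} below 0 beyond numerical tolerance")
        value = 0.0
    value = min(value, 1.0)
    return NREValue(value=float(value), k=int(p.size))


def nre_values(probabilities: np.ndarray) -> np.ndarray:
    """Row-wise NRE for an (n, K) array of probability vectors."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected an (n, K) array")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    out = 1.0 + plogp.sum(axis=1) / np.log(p.shape[1])
    return np.clip(out, 0.0, 1.0)


def nre_from_distances(
    distances: Sequence[float],
    method: str = "inverse_distance",
    *,
    temperature: Optional[float] = None,
    bandwidth: Optional[float] = None,
) -> tuple[np.ndarray, NREValue]:
    """Probabilities and NRE from centroid distances in one step."""
    p = probabilities_from_distances(
        distances, method, temperature=temperature, bandwidth=bandwidth
    )
    return p, nre(p)
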