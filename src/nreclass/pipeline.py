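"""End-to-end classification of a cohort table.

Composes standardisation, centroid distances, classification
probabilities and the NRE over a cohort DataFrame in the standard record
schema.  Eligibility filtering is a separate, explicit step
(:func:`nreclass.eligibility.filter_cohort`); this module assumes the
records it receives are the ones to classify.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .assignment import probabilities_from_distances, distances_to_centroids
from .entropy import nre_values
from .reference import ReferenceModel

__all__ = ["classify_cohort", "summarize_classification"]


def classify_cohort(
    records: pd.DataFrame,
    model: ReferenceModel,
    method: str = "inverse_distance",
    *,
    temperature: Optional[float] = None,
    bandwidth: Optional[float] = None,
) -> pd.DataFrame:
    """Classify every record of a cohort table.

    Returns one row per record with columns ``id``, ``sex``,
    ``dist_<cluster>`` and ``p_<cluster>`` per cluster (model order),
    ``assigned_cluster``, ``assigned_probability``, ``min_distance``
    (the absolute-certainty criterion the relative NRE does not capture),
    ``tie`` and ``nre``.
    """
    required = ["id", "sex", *model.variables]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    if records.empty:
        raise ValueError("cohort table is empty")

    frames = []
    for sex, group in records.groupby("sex", sort=False):
        if sex not in model.sexes:
            raise ValueError(f"unknown sex {sex!r} in cohort")
        x = group[list(model.variables)].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            bad = group.loc[~np.isfinite(x).all(axis=1), "id"].tolist()
            raise ValueError(
                f"non-finite clustering variables for record(s) {bad[:5]}"
            )
        loc, scale = model.scaling_arrays(sex)
        z = x.copy()
        for j, v in enumerate(model.variables):
            if model.transform_of(v) == "log":
                if np.any(z[:, j] <= 0):
                    raise ValueError(
                        f"log-transformed variable {v!r} must be positive"
                    )
                z[:, j] = np.log(z[:, j])
        z = (z - loc) / scale

        d = distances_to_centroids(z, model, sex)  # (n, K)
        p = np.vstack(
            [
                probabilities_from_distances(
                    row, method, temperature=temperature, bandwidth=bandwidth
                )
                for row in d
            ]
        )
        nearest = d.argmin(axis=1)
        ties = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1

        out = pd.DataFrame({"id": group["id"].to_numpy(), "sex": sex})
        for k, cluster in enumerate(model.clusters):
            out[f"dist_{cluster}"] = d[:, k]
        for k, cluster in enumerate(model.clusters):
            out[f"p_{cluster}"] = p[:, k]
        out["assigned_cluster"] = [model.clusters[i] for i in nearest]
        out["assigned_probability"] = p[np.arange(len(group)), nearest]
        out["min_distance"] = d.min(axis=1)
        out["tie"] = ties
        out["nre"] = nre_values(p)
        out["method"] = method
        frames.append(out)

    result = pd.concat(frames, ignore_index=True)
    order = {rid: i for i, rid in enumerate(records["id"])}
    return (
        result.sort_values("id", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )


def summarize_classification(
    classified: pd.DataFrame,
    model: ReferenceModel,
    *,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> dict:
    """Cohort-level summary: per-cluster n, median NRE with bootstrap CI,
    and median assigned probability."""
    from .outcome import bootstrap_ci

    def median_block(values: np.ndarray, boot_seed) -> dict:
        block = {"median": float(np.median(values)), "n": int(values.size)}
        if values.size >= 2:
            lo, hi = bootstrap_ci(np.median, values, n_boot=n_boot, seed=boot_seed)
            block["ci95"] = [lo, hi]
        return block

    rng = np.random.SeedSequence(seed)
    seeds = [int(s % (2**31)) for s in rng.generate_state(model.n_clusters + 2)]
    summary = {
        "n": int(len(classified)),
        "nre_overall": median_block(classified["nre"].to_numpy(), seeds[0]),
        "assigned_probability_overall": median_block(
            classified["assigned_probability"].to_numpy(), seeds[1]
        ),
        "per_cluster": {},
    }
    for k, cluster in enumerate(model.clusters):
        sub = classified.loc[
            classified["assigned_cluster"] == cluster, "nre"
        ].to_numpy()
        if sub.size:
            summary["per_cluster"][cluster] = median_block(sub, seeds[k + 2])
        else:
            summary["per_cluster"][cluster] = {"median": None, "n": 0}
    return summary
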