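"""Optional diagnostic plots (requires matplotlib, ``nreclass[plots]``).

Minimal helpers, not publication graphics: a per-individual spider chart
of classification probabilities against the complete-uncertainty baseline
(1/K per cluster), and an NRE-vs-feature scatter per assigned subtype to
inspect which clinical features drive low classification certainty.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["spider_chart", "nre_feature_scatter"]


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install nreclass[plots]"
        ) from exc
    return plt


def spider_chart(
    probabilities: Mapping[str, float],
    *,
    nre: Optional[float] = None,
    ax=None,
):
    """Radar plot of one individual's classification probabilities.

    The dashed reference polygon marks the complete-uncertainty baseline
    where every cluster has probability 1/K.
    """
    plt = _require_matplotlib()
    labels = list(probabilities)
    values = [probabilities[c] for c in labels]
    k = len(labels)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False).tolist()
    values_c = values + values[:1]
    angles_c = angles + angles[:1]
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles_c, values_c, "o-")
    ax.fill(angles_c, values_c, alpha=0.2)
    baseline = [1.0 / k] * (k + 1)
    ax.plot(angles_c, baseline, "k--", linewidth=1)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels)
    ax.set_ylim(0, 1)
    title = "Classification probabilities"
    if nre is not None:
        title += f" (NRE = {nre:.3f})"
    ax.set_title(title)
    return ax


def nre_feature_scatter(
    classified: pd.DataFrame,
    records: pd.DataFrame,
    feature: str,
    *,
    cluster: Optional[str] = None,
    ax=None,
):
    """Scatter of NRE against one clinical feature, optionally per subtype."""
    plt = _require_matplotlib()
    merged = classified.merge(records[["id", feature]], on="id")
    if cluster is not None:
        merged = merged[merged["assigned_cluster"] == cluster]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(merged[feature], merged["nre"], s=12, alpha=0.6)
    ax.set_xlabel(feature)
    ax.set_ylabel("NRE")
    ax.set_ylim(0, 1)
    if cluster is not None:
        ax.set_title(f"{cluster}: NRE vs {feature}")
    return ax
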