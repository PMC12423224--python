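"""Subtype-outcome regression with and without certainty weighting.

A continuous outcome (e.g. a predicted 10-year cardiovascular risk in %)
is regressed on subtype membership with a one-factor linear model.  In the
weighted variant each individual's weight is their NRE, so individuals who
closely match their subtype prototype contribute more to the per-subtype
contrasts and to R^2.  In the saturated one-factor model the fitted value
of a subtype is exactly the (weighted) mean outcome of its members; 95%
CIs come from t-based WLS standard errors with n - K degrees of freedom.

The weighted R^2 is 1 - SSR_w / SST_w with SST_w taken about the weighted
grand mean, the standard WLS convention (and the one statsmodels uses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SubtypeEstimate",
    "OutcomeFit",
    "fit_subtype_model",
    "compare_weightings",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class SubtypeEstimate:
    """Predicted mean outcome of one subtype with its 95% CI."""

    subtype: str
    mean: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n: int
    total_weight: float

    @property
    def defined(self) -> bool:
        return self.mean is not None


@dataclass(frozen=True)
class OutcomeFit:
    """A fitted one-factor (subtype) linear model of the outcome."""

    weighting: str  # "none" or "nre"
    intercept: float
    coefficients: dict[str, float]  # reference-level parameterisation
    reference_level: str
    estimates: tuple[SubtypeEstimate, ...]
    r_squared: float
    n_used: int
    n_dropped_missing_outcome: int

    def estimate_for(self, subtype: str) -> SubtypeEstimate:
        for est in self.estimates:
            if est.subtype == subtype:
                return est
        raise KeyError(subtype)

    @property
    def predicted_means(self) -> dict[str, Optional[float]]:
        return {e.subtype: e.mean for e in self.estimates}


def _complete_cases(
    outcome: Sequence[float],
    subtype_labels: Sequence[str],
    weights: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(subtype_labels, dtype=object)
    w = np.asarray(weights, dtype=float)
    if not (len(y) == len(labels) == len(w)):
        raise ValueError("outcome, labels and weights differ in length")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    keep = np.isfinite(y)
    return y[keep], labels[keep], w[keep], int((~keep).sum())


def fit_subtype_model(
    outcome: Sequence[float],
    subtype_labels: Sequence[str],
    weights: Sequence[float],
    *,
    weighting: str = "nre",
    subtype_order: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> OutcomeFit:
    """Fit the weighted least squares model of outcome on subtype.

    ``weights`` of all ones reduce exactly to OLS.  Records with a missing
    (NaN) outcome are dropped and counted.  A subtype whose total weight
    is zero has its estimates flagged undefined (mean and CI of ``None``)
    rather than fitted.
    """
    y, labels, w, n_dropped = _complete_cases(outcome, subtype_labels, weights)
    if y.size == 0:
        raise ValueError("no records with observed outcome")
    if np.all(w == 0):
        raise ValueError("all weights are zero")

    if subtype_order is None:
        subtype_order = list(dict.fromkeys(labels))
    subtype_order = [s for s in subtype_order if s in set(labels)]
    if len(subtype_order) < 2:
        raise ValueError("need at least 2 distinct subtypes with data")

    group_weight = {s: float(w[labels == s].sum()) for s in subtype_order}
    # subtypes whose total weight is zero cannot be estimated; they are
    # excluded from the design and reported with undefined estimates
    fit_levels = [s for s in subtype_order if group_weight[s] > 0]

    in_fit = np.isin(labels, fit_levels)
    yf, lf, wf = y[in_fit], labels[in_fit], w[in_fit]
    # rows with zero individual weight contribute nothing but are harmless;
    # keep them so n matches the complete-case subset of fitted levels.

    reference = fit_levels[0]
    design = pd.DataFrame({"const": 1.0}, index=range(len(yf)))
    for level in fit_levels[1:]:
        design[level] = (lf == level).astype(float)
    model = sm.WLS(yf, design, weights=wf)
    result = model.fit()

    intercept = float(result.params["const"])
    coefficients = {
        level: float(result.params[level]) for level in fit_levels[1:]
    }

    estimates: list[SubtypeEstimate] = []
    for s in subtype_order:
        n_s = int((labels == s).sum())
        if s not in fit_levels:
            estimates.append(
                SubtypeEstimate(s, None, None, None, n_s, group_weight[s])
            )
            continue
        row = pd.DataFrame(
            {col: [1.0 if col == "const" else float(col == s)]
             for col in design.columns}
        )
        pred = result.get_prediction(row)
        frame = pred.summary_frame(alpha=alpha)
        estimates.append(
            SubtypeEstimate(
                subtype=s,
                mean=float(frame["mean"].iloc[0]),
                ci_low=float(frame["mean_ci_lower"].iloc[0]),
                ci_high=float(frame["mean_ci_upper"].iloc[0]),
                n=n_s,
                total_weight=group_weight[s],
            )
        )

    return OutcomeFit(
        weighting=weighting,
        intercept=intercept,
        coefficients=coefficients,
        reference_level=reference,
        estimates=tuple(estimates),
        r_squared=float(result.rsquared),
        n_used=int(yf.size),
        n_dropped_missing_outcome=n_dropped,
    )


def compare_weightings(
    outcome: Sequence[float],
    subtype_labels: Sequence[str],
    nre_values: Sequence[float],
    *,
    subtype_order: Optional[Sequence[str]] = None,
) -> tuple[OutcomeFit, OutcomeFit, float, dict[str, Optional[float]]]:
    """Unweighted (OLS) vs NRE-weighted (WLS) fits on the same records.

    Returns ``(fit_unweighted, fit_weighted, delta_r_squared,
    per_subtype_mean_shift)`` where the shift is weighted minus unweighted
    predicted mean, in outcome units.
    """
    nre_arr = np.asarray(nre_values, dtype=float)
    if np.any((nre_arr < 0) | (nre_arr > 1)):
        raise ValueError("NRE weights must lie in [0, 1]")
    ones = np.ones_like(nre_arr)
    fit_u = fit_subtype_model(
        outcome, subtype_labels, ones, weighting="none", subtype_order=subtype_order
    )
    fit_w = fit_subtype_model(
        outcome, subtype_labels, nre_arr, weighting="nre",
        subtype_order=subtype_order,
    )
    delta = fit_w.r_squared - fit_u.r_squared
    shifts: dict[str, Optional[float]] = {}
    for est_u in fit_u.estimates:
        est_w = fit_w.estimate_for(est_u.subtype)
        if est_u.defined and est_w.defined:
            shifts[est_u.subtype] = est_w.mean - est_u.mean
        else:
            shifts[est_u.subtype] = None
    return fit_u, fit_w, float(delta), shifts


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: Sequence[float],
    n_boot: int = 2000,
    seed: Optional[int] = None,
    *,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a statistic of a univariate sample.

    Deterministic given ``seed``.  Used for the median-NRE and R^2
    intervals where no analytic standard error is assumed.
    """
    x = np.asarray(data, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    stats = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
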