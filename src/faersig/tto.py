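"""Time-to-onset analysis: inclusion accounting, binning, Weibull fit,
and a two-group onset comparison.

Onset is the number of days from therapy start to event onset (computed
upstream by :func:`faersig.preprocess.compute_tto_days`).  Every case
report falls into exactly one inclusion category (ok / missing /
incomplete / inconsistent / implausible); only "ok" reports enter the
analyses here.

The temporal risk profile is modelled with a two-parameter Weibull
distribution.  The shape parameter k governs the hazard trend: k < 1 is a
declining hazard (early-failure pattern), k = 1 constant, k > 1 increasing
(wear-out).  The scale parameter (days) locates the bulk of onsets.  Fits
are maximum likelihood with Wald 95% CIs from the observed information on
the log-parameter scale.

The glucocorticoid-vs-other onset comparison uses product-limit curves and
the two-sample log-rank test (all events observed — spontaneous reports
carry no censoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)

REJECTION_REASONS = ("none", "missing", "incomplete", "inconsistent", "implausible")


@dataclass(frozen=True)
class TTORecord:
    """Per-report time to onset with drug-class label and inclusion status."""

    primaryid: str
    tto_days: Optional[int]
    drug_class: str = "other"
    rejection_reason: str = "none"

    @property
    def included(self) -> bool:
        return self.rejection_reason == "none"


def tto_inclusion(dataset: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition case reports into inclusion categories.

    Expects the analysis-dataset columns ``tto_days`` / ``tto_reason``.
    Returns the included rows and a dict of category counts whose values
    sum to the number of input rows (exhaustive, exclusive partition).
    """
    reasons = dataset["tto_reason"]
    counts = {cat: int((reasons == cat).sum())
              for cat in ("missing", "incomplete", "inconsistent", "implausible")}
    included = dataset[reasons == "ok"]
    counts["included"] = len(included)
    return included.reset_index(drop=True), counts


def bin_tto(
    ttos: Iterable[float], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Histogram of onset days over left-open/right-closed bins.

    Default edges (30, 60, 90, 180, 360) give bins (0,30], (30,60],
    (60,90], (90,180], (180,360], (360, inf) — day 30 falls in the first
    bin.  Returns a DataFrame (bin, count, pct); counts sum to n and
    percentages to 100 within rounding.
    """
    edges = tuple(edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    t = np.asarray(list(ttos), dtype=float)
    if len(t) and (t <= 0).any():
        raise ValueError("onset days must be positive; rejections are filtered upstream")
    idx = np.searchsorted(edges, t, side="left")
    labels = (
        [f"{lo + 1}-{hi}" for lo, hi in zip((0,) + edges[:-1], edges)]
        + [f">{edges[-1]}"]
    )
    counts = np.bincount(idx, minlength=len(edges) + 1)
    n = counts.sum()
    pct = 100.0 * counts / n if n else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({"bin": labels, "count": counts, "pct": pct})


# ---------------------------------------------------------------------------
# Weibull fit
# ---------------------------------------------------------------------------

class WeibullFitError(ValueError):
    pass


def _weibull_nll(theta: np.ndarray, t: np.ndarray) -> float:
    """Negative log-likelihood in (log shape, log scale)."""
    k = np.exp(theta[0])
    lam = np.exp(theta[1])
    z = t / lam
    return -float(
        len(t) * (np.log(k) - k * np.log(lam))
        + (k - 1.0) * np.log(t).sum()
        - (z**k).sum()
    )


class WeibullTTO:
    """Weibull time-to-onset model (statsmodels-style: construct, then fit).

    Parameters
    ----------
    durations : positive onset days, uncensored.  At least 10 values are
        required and they must not all be equal (the MLE degenerates).
    """

    def __init__(self, durations: Iterable[float]):
        t = np.asarray(list(durations), dtype=float)
        if (t <= 0).any() or np.isnan(t).any():
            raise WeibullFitError("durations must be positive and non-missing")
        self.durations = t

    def fit(self) -> "WeibullTTOResults":
        t = self.durations
        if len(t) < 10:
            raise WeibullFitError(
                f"need at least 10 onset values for a stable fit, got {len(t)}"
            )
        if np.ptp(t) == 0:
            raise WeibullFitError("degenerate input: all onset values equal")
        # moment-based start: shape from log-variance, scale from the mean
        logs = np.log(t)
        k0 = max(min(np.pi / np.sqrt(6.0 * max(logs.var(), 1e-12)), 50.0), 0.02)
        lam0 = float(np.exp(logs.mean()))
        res = optimize.minimize(
            _weibull_nll,
            x0=np.array([np.log(k0), np.log(lam0)]),
            args=(t,),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        if not res.success:
            raise WeibullFitError(f"Weibull MLE failed: {res.message}")
        theta = res.x
        hess = approx_hess(theta, _weibull_nll, args=(t,))
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        shape, scale = float(np.exp(theta[0])), float(np.exp(theta[1]))
        shape_ci = (float(np.exp(theta[0] - 1.96 * se[0])), float(np.exp(theta[0] + 1.96 * se[0])))
        scale_ci = (float(np.exp(theta[1] - 1.96 * se[1])), float(np.exp(theta[1] + 1.96 * se[1])))
        return WeibullTTOResults(
            model=self,
            shape=shape,
            scale=scale,
            shape_ci=shape_ci,
            scale_ci=scale_ci,
            cov_log=cov,
            loglik=-float(res.fun),
            n_used=len(t),
        )


@dataclass
class WeibullTTOResults:
    """Maximum-likelihood Weibull fit with log-scale Wald CIs."""

    model: WeibullTTO
    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    cov_log: np.ndarray
    loglik: float
    n_used: int

    @property
    def hazard_interpretation(self) -> str:
        lo, hi = self.shape_ci
        if hi < 1.0:
            return "decreasing hazard (early-failure pattern)"
        if lo > 1.0:
            return "increasing hazard (wear-out pattern)"
        return "hazard consistent with constant (shape CI covers 1)"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.shape, self.scale],
                "ci_low": [self.shape_ci[0], self.scale_ci[0]],
                "ci_high": [self.shape_ci[1], self.scale_ci[1]],
            },
            index=["shape", "scale (days)"],
        )

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "shape_ci": list(self.shape_ci),
            "scale_days": self.scale,
            "scale_ci": list(self.scale_ci),
            "n_used": self.n_used,
            "loglik": self.loglik,
            "interpretation": self.hazard_interpretation,
        }


def fit_weibull(ttos: Iterable[float]) -> WeibullTTOResults:
    """Functional wrapper: ``WeibullTTO(ttos).fit()``."""
    return WeibullTTO(ttos).fit()


# ---------------------------------------------------------------------------
# two-group onset comparison
# ---------------------------------------------------------------------------

@dataclass
class OnsetComparison:
    """Two-sample log-rank result with per-group product-limit curves."""

    statistic: float
    p_value: float
    curves: Mapping[str, pd.DataFrame]
    group_sizes: Mapping[str, int]


def compare_onset_groups(
    durations: Iterable[float], groups: Iterable[str]
) -> OnsetComparison:
    """Log-rank comparison of onset between two drug classes.

    All onsets are observed events (no censoring), so the product-limit
    curves are empirical survival complements.  Both groups must be
    non-empty.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(list(durations), dtype=float)
    g = np.asarray(list(groups), dtype=object)
    labels = sorted(set(g))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two non-empty groups, got {labels}")
    t0, t1 = t[g == labels[0]], t[g == labels[1]]
    if len(t0) == 0 or len(t1) == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(t0, t1, event_observed_A=np.ones_like(t0), event_observed_B=np.ones_like(t1))
    curves = {}
    for lab, tt in zip(labels, (t0, t1)):
        kmf = KaplanMeierFitter()
        kmf.fit(tt, event_observed=np.ones_like(tt), label=str(lab))
        curves[str(lab)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "days", str(lab): "survival"}
        )
    return OnsetComparison(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
        group_sizes={str(labels[0]): len(t0), str(labels[1]): len(t1)},
    )
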