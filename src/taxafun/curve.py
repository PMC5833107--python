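"""Taxa-function response curves and robustness statistics.

The response curve models the expected functional shift f of a community as
a power law in the taxonomic perturbation magnitude t:

    f = t**b / exp(a)        i.e.   ln f = -a + b ln t

fitted by ordinary least squares on the log-log scale.  The coefficient
``a`` is the *attenuation* (higher => smaller shifts per unit perturbation,
more robust) and the exponent ``b`` the *buffering* (higher => stronger
suppression of shifts at small perturbations).

Before fitting, perturbations are re-sampled uniformly across taxonomic
distances: the observed ln t range is split into 50 non-overlapping windows
and each window is capped at 50 records.  This prevents the dense
small-distance perturbations from dominating the fit.

Community- or environment-level locations of attenuation/buffering are
summarised with the Hodges-Lehmann pseudomedian (the median of all Walsh
averages), with a 95% CI obtained by inverting the one-sample Wilcoxon
signed-rank statistic under its normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

__all__ = [
    "ResponseCurve",
    "RobustnessSummary",
    "window_subsample",
    "fit_response_curve",
    "predict_expected_shift",
    "pseudomedian_with_ci",
    "mood_median_test",
    "most_robust_environments",
]


@dataclass
class ResponseCurve:
    """Fitted power-law response curve of one community (or one function)."""

    attenuation: float
    buffering: float
    n_points: int
    residual_sum: float = np.nan
    scope: str = "community"

    def predict(self, t):
        """Expected functional shift at taxonomic distance t (> 0)."""
        t = np.asarray(t, dtype=float)
        if (t <= 0).any():
            raise ValidationError("taxonomic distance must be positive")
        out = t ** self.buffering * np.exp(-self.attenuation)
        return float(out) if out.ndim == 0 else out


@dataclass
class RobustnessSummary:
    """Hodges-Lehmann pseudomedian with a Wilcoxon-inversion 95% CI."""

    pseudomedian: float
    ci_low: float
    ci_high: float
    n: int


def window_subsample(t: np.ndarray, f: np.ndarray, n_windows: int = 50,
                     cap: int = 50, seed: int = 0,
                     return_counts: bool = False):
    """Uniform re-sampling of (t, f) records across ln-t windows.

    Records with non-positive t or f are dropped first (their count is
    reported via warning).  The [min ln t, max ln t] range is divided into
    ``n_windows`` equal windows; each window keeps at most ``cap`` records,
    chosen without replacement with a seeded generator.

    Returns a boolean mask over the input arrays (and optionally the number
    of dropped non-positive records).
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    valid = (t > 0) & (f > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records with non-positive t or f")
    idx = np.flatnonzero(valid)
    if len(np.unique(t[idx])) < 2:
        raise ValidationError("fewer than 2 distinct taxonomic distances")
    log_t = np.log(t[idx])
    lo, hi = log_t.min(), log_t.max()
    edges = np.linspace(lo, hi, n_windows + 1)
    which = np.clip(np.searchsorted(edges, log_t, side="right") - 1,
                    0, n_windows - 1)
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(t), dtype=bool)
    for w in range(n_windows):
        members = idx[which == w]
        if len(members) <= cap:
            keep[members] = True
        else:
            keep[rng.choice(members, size=cap, replace=False)] = True
    if return_counts:
        return keep, n_dropped
    return keep


def fit_response_curve(t: np.ndarray, f: np.ndarray,
                       scope: str = "community") -> ResponseCurve:
    """OLS fit of ln f on ln t; slope = buffering, intercept = -attenuation."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if (t <= 0).any() or (f <= 0).any():
        raise ValidationError("all t and f must be positive for the log-log fit")
    if len(np.unique(t)) < 2:
        raise ValidationError("degenerate design: need >= 2 distinct t values")
    x, y = np.log(t), np.log(f)
    (slope, intercept), res, *_ = np.polyfit(x, y, 1, full=True)
    rss = float(res[0]) if len(res) else 0.0
    return ResponseCurve(attenuation=-float(intercept), buffering=float(slope),
                         n_points=len(t), residual_sum=rss, scope=scope)


def predict_expected_shift(curve: ResponseCurve, t) -> float | np.ndarray:
    """Expected functional shift at distance t from a fitted curve."""
    return curve.predict(t)


def pseudomedian_with_ci(values, alpha: float = 0.05) -> RobustnessSummary:
    """Hodges-Lehmann pseudomedian and Wilcoxon-based confidence interval.

    The pseudomedian is the median of all Walsh averages
    (x_i + x_j)/2 for i <= j.  The CI is the classical Tukey interval: the
    k-th smallest and k-th largest Walsh averages, with k chosen from the
    normal approximation of the null distribution of the signed-rank
    statistic.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValidationError("empty sample")
    iu = np.triu_indices(n)
    walsh = np.sort((x[iu[0]] + x[iu[1]]) / 2.0)
    pm = float(np.median(walsh))
    m = len(walsh)  # n(n+1)/2
    z = stats.norm.ppf(1 - alpha / 2)
    c = m / 2.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = int(np.floor(c))
    k = max(k, 0)
    lo = walsh[k] if k < m else walsh[0]
    hi = walsh[m - 1 - k] if k < m else walsh[-1]
    return RobustnessSummary(pm, float(lo), float(hi), n)


def mood_median_test(*groups, ties: str = "below") -> float:
    """Mood's median test across >= 2 groups: p-value.

    Counts per group above the pooled grand median (values equal to the
    grand median count as "not above") and applies a chi-square test to the
    resulting contingency table.  If all pooled values are identical the
    test is undefined and p = 1 is returned with a warning.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical: median test undefined, p = 1")
        return 1.0
    try:
        _, p, _, _ = stats.median_test(*groups, ties=ties)
    except ValueError:
        # degenerate table (e.g. a zero row after tie handling)
        warnings.warn("median test degenerate for these groups, p = 1")
        return 1.0
    return float(p)


def most_robust_environments(per_env: dict[str, np.ndarray],
                             alpha: float = 0.05) -> set[str]:
    """Environments in which a function is most robust.

    A set S of environments qualifies when, for every environment in S, its
    attenuation values differ significantly (Mood's test, p < alpha) from
    every environment outside S, and do not differ significantly from any
    other environment inside S.  Environments are ranked by median
    attenuation and prefixes of increasing size are tested; the first
    qualifying prefix is returned (the empty set if none qualifies).
    """
    if len(per_env) < 2:
        raise ValidationError("need >= 2 environments")
    envs = sorted(per_env, key=lambda e: -np.median(per_env[e]))
    pcache: dict[tuple[str, str], float] = {}

    def pval(e1: str, e2: str) -> float:
        key = (e1, e2) if e1 <= e2 else (e2, e1)
        if key not in pcache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pcache[key] = mood_median_test(per_env[key[0]], per_env[key[1]])
        return pcache[key]

    for k in range(1, len(envs) + 1):
        inside, outside = envs[:k], envs[k:]
        ok = all(pval(a, b) < alpha for a in inside for b in outside) and \
            all(pval(a, b) >= alpha
                for i, a in enumerate(inside) for b in inside[i + 1:])
        if ok:
            return set(inside)
    return set()
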