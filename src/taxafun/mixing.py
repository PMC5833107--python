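"""Robustness estimation from pairs of real communities by linear mixing.

Simulated multiplier perturbations need predicted functional profiles;
when measured (e.g. shotgun metagenome-derived) functional profiles are
available for pairs of communities, small controlled perturbations of the
first community can instead be constructed by replacing a fraction m of its
taxonomic and functional profiles with the second community's:

    mixed taxon i     = a_i (1 - m) + b_i m
    mixed function j  = c_j (1 - m) + d_j m

A binary search on m targets specific weighted UniFrac distances from the
original community; records over a grid of target distances are then fitted
with the same log-log response-curve machinery as simulated perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import FunctionalProfile, TaxonomicProfile, ValidationError
from .curve import ResponseCurve, fit_response_curve
from .distance import TreeIndex, cosine_dissimilarity

__all__ = [
    "MixingRecord",
    "UnreachableTargetError",
    "mix_communities",
    "find_mixing_fraction",
    "mixing_based_curve",
    "default_mixing_grid",
]


class UnreachableTargetError(ValueError):
    """Target distance exceeds what full mixing (m = 1) can achieve."""


@dataclass
class MixingRecord:
    original_id: str
    mixin_id: str
    fraction: float
    target_t: float
    achieved_t: float
    taxonomic: TaxonomicProfile
    functional: FunctionalProfile


def _aligned_pair(p: TaxonomicProfile, q: TaxonomicProfile):
    sp, sq = p.to_series(), q.to_series()
    union = sp.index.union(sq.index)
    return (union.to_numpy(dtype=object),
            sp.reindex(union, fill_value=0.0).to_numpy(),
            sq.reindex(union, fill_value=0.0).to_numpy())


def _aligned_functional(f1: FunctionalProfile, f2: FunctionalProfile):
    s1, s2 = f1.to_series(), f2.to_series()
    union = s1.index.union(s2.index)
    return (union.to_numpy(dtype=object),
            s1.reindex(union, fill_value=0.0).to_numpy(),
            s2.reindex(union, fill_value=0.0).to_numpy())


def mix_communities(original: TaxonomicProfile, mixin: TaxonomicProfile,
                    m: float,
                    f_original: FunctionalProfile | None = None,
                    f_mixin: FunctionalProfile | None = None,
                    original_id: str = "original", mixin_id: str = "mixin",
                    target_t: float = float("nan"),
                    achieved_t: float = float("nan")) -> MixingRecord:
    """Convex combination of two communities' taxonomic (and functional) profiles."""
    if not 0.0 <= m <= 1.0:
        raise ValidationError("mixing fraction must lie in [0, 1]")
    taxa, a, b = _aligned_pair(original, mixin)
    mixed_tax = TaxonomicProfile(taxa, a * (1 - m) + b * m)
    mixed_fun = None
    if f_original is not None and f_mixin is not None:
        fids, c, d = _aligned_functional(f_original, f_mixin)
        mixed_fun = FunctionalProfile(fids, c * (1 - m) + d * m)
    return MixingRecord(original_id, mixin_id, m, target_t, achieved_t,
                        mixed_tax, mixed_fun)


def find_mixing_fraction(original: TaxonomicProfile, mixin: TaxonomicProfile,
                         tree, target_t: float, tol: float = 1e-9,
                         max_iter: int = 200,
                         normalized: bool = True) -> float:
    """Binary search for the mixing fraction at a target UniFrac distance.

    Searches m in [0, 1] for |d(original, mix(m)) - target| <= tol, relying
    on d being non-decreasing in m.  If the bracket shows the target beyond
    the m = 1 distance, :class:`UnreachableTargetError` is raised.  If the
    search exhausts ``max_iter`` without reaching ``tol`` (a monotonicity
    violation), a fine grid search is used as fallback with a warning.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    taxa, a, b = _aligned_pair(original, mixin)
    cols = idx.vectors_for_taxa(taxa, np.vstack([a, b]))
    va, vb = cols[0], cols[1]

    def dist(m: float) -> float:
        return idx.unifrac(va, va * (1 - m) + vb * m, normalized=normalized)

    if target_t < 0:
        raise ValidationError("target distance must be non-negative")
    if target_t <= tol:
        return 0.0
    d_full = dist(1.0)
    if target_t > d_full + tol:
        raise UnreachableTargetError(
            f"target {target_t} exceeds full-mixing distance {d_full}"
        )
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        d = dist(mid)
        if abs(d - target_t) <= tol:
            return mid
        if d < target_t:
            lo = mid
        else:
            hi = mid
    warnings.warn("binary search did not converge; falling back to grid search")
    grid = np.linspace(0.0, 1.0, 1_000_001)
    dists = np.array([dist(m) for m in grid[:: 1000]])
    j = int(np.argmin(np.abs(dists - target_t)))
    fine = grid[max(0, (j - 1) * 1000): (j + 1) * 1000 + 1]
    best = min(fine, key=lambda m: abs(dist(m) - target_t))
    return float(best)


def default_mixing_grid() -> np.ndarray:
    """Target weighted UniFrac distances 0.01, 0.02, ..., 0.10."""
    return np.round(np.arange(1, 11) * 0.01, 10)


def mixing_based_curve(original: TaxonomicProfile, mixin: TaxonomicProfile,
                       tree, f_original: FunctionalProfile,
                       f_mixin: FunctionalProfile,
                       t_grid: np.ndarray | None = None,
                       tol: float = 1e-9, normalized: bool = True
                       ) -> tuple[ResponseCurve, list[MixingRecord]]:
    """Fit a response curve from mixed-community perturbations of one pair.

    For each reachable target distance in ``t_grid`` the mixing fraction is
    found by binary search and the functional shift of the mixed profile
    from the original is measured with cosine dissimilarity; the (t, f)
    records are fitted on the log-log scale.  Unreachable grid points are
    dropped with a warning; fewer than 2 reachable points is an error.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if t_grid is None:
        t_grid = default_mixing_grid()
    records: list[MixingRecord] = []
    taxa, a, b = _aligned_pair(original, mixin)
    cols = idx.vectors_for_taxa(taxa, np.vstack([a, b]))
    va, vb = cols[0], cols[1]
    for target in t_grid:
        try:
            m = find_mixing_fraction(original, mixin, idx, target,
                                     tol=tol, normalized=normalized)
        except UnreachableTargetError:
            warnings.warn(f"target distance {target} unreachable for this pair")
            continue
        achieved = idx.unifrac(va, va * (1 - m) + vb * m, normalized=normalized)
        rec = mix_communities(original, mixin, m, f_original, f_mixin,
                              target_t=float(target), achieved_t=achieved)
        records.append(rec)
    t = np.array([r.achieved_t for r in records])
    f = np.array([cosine_dissimilarity(f_original, r.functional)
                  for r in records])
    ok = (t > 0) & (f > 0)
    if ok.sum() < 2:
        raise ValidationError(
            "fewer than 2 usable mixing records: pair unfittable"
        )
    curve = fit_response_curve(t[ok], f[ok], scope="mixing")
    return curve, records
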