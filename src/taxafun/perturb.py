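"""Stochastic multiplicative perturbation of taxonomic compositions.

A perturbation of maximum magnitude M draws, for each taxon with non-zero
abundance, a multiplier m_i uniform on (0, M] and a fair-coin direction
d_i in {-1, +1}; the perturbed abundance is a_i * m_i**d_i, renormalised to
sum 1.  The expected change in a taxon's abundance therefore scales with its
original abundance, and no taxon is created or destroyed (no migration).

The default experimental grid perturbs a community at 45 maximum magnitudes
evenly spaced on [1.2, 10], 100 perturbations each (4500 per community).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import PerturbationSpec, TaxonomicProfile, ValidationError

__all__ = [
    "sample_spec",
    "apply_perturbation",
    "magnitude_grid",
    "generate_perturbation_set",
    "perturbation_matrix",
]


def sample_spec(n: int, magnitude: float, seed=None) -> PerturbationSpec:
    """Draw multipliers uniform on (0, M] and fair-coin directions.

    ``seed`` may be an int or a numpy ``SeedSequence``/``Generator``.
    Uniformity on the half-open interval (0, M] is realised as M*(1 - U)
    with U uniform on [0, 1).
    """
    if magnitude <= 0:
        raise ValidationError("maximum perturbation magnitude must be > 0")
    if n < 1:
        raise ValidationError("need at least one taxon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = magnitude * (1.0 - rng.random(n))
    d = rng.choice((-1, 1), size=n)
    return PerturbationSpec(magnitude, m, d)


def apply_perturbation(profile: TaxonomicProfile,
                       spec: PerturbationSpec) -> TaxonomicProfile:
    """Apply a multiplier spec to a profile: p_i ∝ a_i * m_i**d_i.

    The spec must match the profile's non-zero taxa in length and order;
    zero-abundance taxa are absent from the result (support is preserved).
    """
    prof = profile.nonzero()
    if len(spec) != prof.n_taxa:
        raise ValidationError(
            f"spec length {len(spec)} != {prof.n_taxa} non-zero taxa"
        )
    raw = prof.abundances * spec.multipliers ** spec.directions
    return prof.renormalized(raw)


def magnitude_grid(n_magnitudes: int = 45, m_min: float = 1.2,
                   m_max: float = 10.0) -> np.ndarray:
    """Arithmetic grid of maximum magnitudes, inclusive of both endpoints."""
    if m_min <= 1:
        raise ValidationError("M_min must exceed 1 (multipliers must permit change)")
    if n_magnitudes < 1 or m_max < m_min:
        raise ValidationError("invalid magnitude grid")
    return np.linspace(m_min, m_max, n_magnitudes)


def perturbation_matrix(profile: TaxonomicProfile, n_magnitudes: int = 45,
                        m_min: float = 1.2, m_max: float = 10.0,
                        n_per_magnitude: int = 100, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, TaxonomicProfile]:
    """Vectorised perturbation set for one community.

    Returns ``(P, M, base)`` where ``base`` is the profile restricted to its
    non-zero taxa, ``P`` is (n_magnitudes*n_per_magnitude × n_taxa) with each
    row a perturbed composition summing to 1, and ``M`` the per-row maximum
    magnitude.  Sub-seeds per perturbation come from a spawned SeedSequence,
    so the set is reproducible regardless of iteration order.
    """
    base = profile.nonzero()
    if base.n_taxa < 2:
        warnings.warn("profile has < 2 taxa: every perturbation is the identity")
    grid = magnitude_grid(n_magnitudes, m_min, m_max)
    n_total = n_magnitudes * n_per_magnitude
    children = np.random.SeedSequence(seed).spawn(n_total)
    a = base.abundances
    P = np.empty((n_total, base.n_taxa))
    M = np.empty(n_total)
    k = 0
    for mag in grid:
        for _ in range(n_per_magnitude):
            rng = np.random.default_rng(children[k])
            m = mag * (1.0 - rng.random(base.n_taxa))
            d = rng.choice((-1, 1), size=base.n_taxa)
            raw = a * m ** d
            P[k] = raw / raw.sum()
            M[k] = mag
            k += 1
    return P, M, base


def generate_perturbation_set(profile: TaxonomicProfile,
                              n_magnitudes: int = 45, m_min: float = 1.2,
                              m_max: float = 10.0, n_per_magnitude: int = 100,
                              seed: int = 0) -> list[TaxonomicProfile]:
    """Perturbed profiles over the full magnitude grid (list form).

    Thin wrapper over :func:`perturbation_matrix` returning
    ``n_magnitudes * n_per_magnitude`` :class:`TaxonomicProfile` objects on
    the same taxon support as the input.
    """
    P, _, base = perturbation_matrix(profile, n_magnitudes, m_min, m_max,
                                     n_per_magnitude, seed)
    return [TaxonomicProfile(base.taxon_ids, row) for row in P]
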