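"""Dissimilarity measures: weighted UniFrac and cosine functional shift.

Taxonomic perturbation magnitude is measured with weighted UniFrac: the sum
over tree branches of branch length times the absolute difference in the
fraction of each community descending through that branch.  The normalised
variant divides by the abundance-weighted sum of root-to-leaf distances,
bounding the value in [0, 1].

Functional shift is the cosine dissimilarity between two functional
profiles, 1 - <a, b> / (|a||b|), which is invariant to global rescaling of
either profile.

:class:`TreeIndex` pre-computes a branch × leaf incidence matrix so that
distances from one community to thousands of perturbed compositions reduce
to a single matrix product.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .containers import (
    FunctionalProfile,
    MissingTaxaError,
    TaxonomicProfile,
    ValidationError,
)

__all__ = [
    "TreeIndex",
    "weighted_unifrac",
    "cosine_dissimilarity",
    "cosine_dissimilarity_many",
    "relative_function_shift",
    "dissimilarity_ratio",
]


class TreeIndex:
    """Pre-indexed rooted tree for fast repeated weighted UniFrac.

    Rows of ``incidence`` are branches (the edge above each non-root node),
    columns are leaves; entry 1 marks a leaf descending through that branch.
    ``B @ p`` then gives, for every branch, the fraction of community ``p``
    descending through it.
    """

    def __init__(self, tree: TreeNode):
        leaves = list(tree.tips())
        self.leaf_names = [t.name for t in leaves]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValidationError("duplicate leaf names in tree")
        self._leaf_pos = {n: i for i, n in enumerate(self.leaf_names)}
        n_leaves = len(leaves)

        branches = [n for n in tree.postorder(include_self=False)]
        self.branch_lengths = np.array(
            [0.0 if b.length is None else float(b.length) for b in branches]
        )
        if (self.branch_lengths < 0).any():
            raise ValidationError("negative branch length")
        self.incidence = np.zeros((len(branches), n_leaves))
        # postorder guarantees children are visited before parents
        sub: dict[int, np.ndarray] = {}
        for bi, node in enumerate(branches):
            row = np.zeros(n_leaves)
            if node.is_tip():
                row[self._leaf_pos[node.name]] = 1.0
            else:
                for child in node.children:
                    row += sub[id(child)]
            sub[id(node)] = row
            self.incidence[bi] = row
        # root-to-leaf distances for the normalised variant
        self.leaf_depths = self.branch_lengths @ self.incidence

    def profile_vector(self, profile: TaxonomicProfile) -> np.ndarray:
        """Abundance vector in leaf order; errors on taxa absent from tree."""
        v = np.zeros(len(self.leaf_names))
        missing = []
        for t, a in zip(profile.taxon_ids, profile.abundances):
            i = self._leaf_pos.get(t)
            if i is None:
                if a > 0:
                    missing.append(t)
                continue
            v[i] = a
        if missing:
            raise MissingTaxaError(missing, "tree leaves")
        return v

    def vectors_for_taxa(self, taxon_ids, abundance_matrix: np.ndarray
                         ) -> np.ndarray:
        """Scatter (n × n_taxa) abundances into (n × n_leaves) leaf order."""
        cols = []
        missing = []
        for t in taxon_ids:
            i = self._leaf_pos.get(t)
            if i is None:
                missing.append(t)
            cols.append(i)
        if missing:
            raise MissingTaxaError(missing, "tree leaves")
        out = np.zeros((abundance_matrix.shape[0], len(self.leaf_names)))
        out[:, np.asarray(cols)] = abundance_matrix
        return out

    def unifrac(self, p: np.ndarray, q: np.ndarray,
                normalized: bool = True) -> float:
        raw = float(self.branch_lengths @ np.abs(self.incidence @ (p - q)))
        if not normalized:
            return raw
        denom = float(self.leaf_depths @ (p + q))
        return raw / denom if denom > 0 else 0.0

    def unifrac_one_to_many(self, p: np.ndarray, Q: np.ndarray,
                            normalized: bool = True) -> np.ndarray:
        """Distances from one leaf vector ``p`` to each row of ``Q``."""
        diff = self.incidence @ (Q - p[None, :]).T  # branches × n
        raw = self.branch_lengths @ np.abs(diff)
        if not normalized:
            return raw
        denom = self.leaf_depths @ (Q + p[None, :]).T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, raw / denom, 0.0)
        return out


def weighted_unifrac(p: TaxonomicProfile, q: TaxonomicProfile,
                     tree: TreeNode | TreeIndex,
                     normalized: bool = True) -> float:
    """Weighted UniFrac dissimilarity between two communities on one tree."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    return idx.unifrac(idx.profile_vector(p), idx.profile_vector(q),
                       normalized=normalized)


def _as_vector(f) -> np.ndarray:
    if isinstance(f, FunctionalProfile):
        return f.abundances
    return np.asarray(f, dtype=float)


def _aligned_vectors(f1, f2) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(f1, FunctionalProfile) and isinstance(f2, FunctionalProfile):
        ids1, ids2 = list(f1.function_ids), list(f2.function_ids)
        if ids1 != ids2:
            # align on the union with implicit zeros
            s1, s2 = f1.to_series(), f2.to_series()
            union = s1.index.union(s2.index)
            return (s1.reindex(union, fill_value=0.0).to_numpy(),
                    s2.reindex(union, fill_value=0.0).to_numpy())
    return _as_vector(f1), _as_vector(f2)


def cosine_dissimilarity(f1, f2) -> float:
    """1 - cosine similarity of two functional profiles.

    Profiles with differing function sets are aligned on the union with
    implicit zeros.  Zero vectors are rejected.
    """
    a, b = _aligned_vectors(f1, f2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine dissimilarity undefined for zero profile")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


def cosine_dissimilarity_many(f: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Cosine dissimilarity of one profile ``f`` to each row of ``F``."""
    f = np.asarray(f, dtype=float)
    F = np.asarray(F, dtype=float)
    nf = np.linalg.norm(f)
    nF = np.linalg.norm(F, axis=1)
    if nf == 0 or (nF == 0).any():
        raise ValidationError("cosine dissimilarity undefined for zero profile")
    return np.clip(1.0 - (F @ f) / (nF * nf), 0.0, 2.0)


def relative_function_shift(f_orig: float, f_pert: float) -> float:
    """Magnitude of the relative change in one function's abundance.

    Direction-free: |f_pert - f_orig| / f_orig, suitable for fitting on a
    log scale.  Undefined when the original abundance is zero.
    """
    if f_orig <= 0:
        raise ValidationError("relative shift undefined for zero original abundance")
    return abs(f_pert - f_orig) / f_orig


def dissimilarity_ratio(functional: float, taxonomic: float) -> float:
    """Natural log of the functional/taxonomic dissimilarity ratio.

    Paired real communities with low functional divergence relative to
    their taxonomic divergence (a negative log-ratio) indicate a robust
    taxa-function mapping in that environment.
    """
    if taxonomic <= 0:
        raise ValidationError("taxonomic dissimilarity must be positive")
    if functional <= 0:
        raise ValidationError(
            "zero functional dissimilarity: log-ratio undefined, exclude record"
        )
    return float(np.log(functional / taxonomic))
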