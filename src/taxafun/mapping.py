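"""Linear genome-content mapping from taxonomic to functional profiles.

The functional profile of a community is modelled as a linear combination of
its members' genome content: the abundance of gene family j is
``sum_i a_i * c_ij`` where ``a_i`` is the relative abundance of taxon i and
``c_ij`` the copy number of family j in taxon i's genome.  Amplicon-derived
abundances are first corrected for 16S rRNA copy-number bias.  Gene-family
profiles can be summarised to pathways by evenly splitting each family's
abundance across the pathways that contain it.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import (
    FunctionalProfile,
    GenomeContentMatrix,
    PathwayHierarchy,
    TaxonomicProfile,
    ValidationError,
)

__all__ = [
    "normalize_by_copy_number",
    "predict_functional_profile",
    "predict_functional_matrix",
    "summarize_to_pathways",
    "pathway_split_matrix",
    "postnormalize",
]


def normalize_by_copy_number(profile: TaxonomicProfile,
                             content: GenomeContentMatrix,
                             renormalize: bool = True) -> TaxonomicProfile:
    """Divide each taxon's relative abundance by its 16S rRNA copy number.

    Taxa with many 16S copies are over-represented in amplicon counts; this
    correction recovers abundances proportional to organism counts.  With
    ``renormalize`` (default) the corrected abundances are rescaled to sum 1.
    """
    if content.rrna is None:
        raise ValidationError("genome content matrix carries no 16S copy numbers")
    prof = profile.nonzero()
    content.require_taxa(prof.taxon_ids)
    rrna = content.rrna.reindex(prof.taxon_ids.tolist())
    if rrna.isna().any():
        missing = rrna.index[rrna.isna()].tolist()
        raise ValidationError(f"no 16S copy number for taxa {missing}")
    corrected = prof.abundances / rrna.to_numpy()
    if renormalize:
        corrected = corrected / corrected.sum()
    return TaxonomicProfile(prof.taxon_ids, corrected / corrected.sum()
                            if not renormalize else corrected)


def predict_functional_profile(profile: TaxonomicProfile,
                               content: GenomeContentMatrix
                               ) -> FunctionalProfile:
    """Predict a community functional profile from taxon genome content.

    Returns the abundance-weighted sum of the member genomes' copy-number
    vectors (the linear taxa-function mapping).
    """
    prof = profile.nonzero()
    c = content.submatrix(prof.taxon_ids.tolist())
    abundances = prof.abundances @ c
    return FunctionalProfile(np.asarray(content.function_ids, dtype=object),
                             abundances)


def predict_functional_matrix(abundance_matrix: np.ndarray,
                              content_rows: np.ndarray) -> np.ndarray:
    """Vectorised mapping for many profiles on a fixed taxon set.

    ``abundance_matrix`` is (n_profiles × n_taxa) and ``content_rows`` the
    matching (n_taxa × n_functions) copy-number block; returns
    (n_profiles × n_functions) functional abundances.
    """
    return np.asarray(abundance_matrix) @ np.asarray(content_rows)


def pathway_split_matrix(function_ids: Sequence[str],
                         hierarchy: PathwayHierarchy,
                         level: Literal["pathway", "superpathway"] = "pathway",
                         unmapped: Literal["drop", "bin"] = "drop"
                         ) -> tuple[np.ndarray, list[str]]:
    """Even-split weight matrix (n_functions × n_pathways).

    A gene family appearing in k pathways contributes 1/k of its abundance
    to each; families absent from the hierarchy are dropped or routed to an
    ``unmapped`` bin.  Multiplying a functional-abundance matrix by this
    weight matrix performs the pathway summarisation.
    """
    if not hierarchy.mapping:
        raise ValidationError("empty pathway hierarchy")

    def groups_of(fn: str) -> frozenset | None:
        pws = hierarchy.mapping.get(str(fn))
        if pws is None:
            return None
        if level == "superpathway":
            if hierarchy.superpathways is None:
                raise ValidationError("hierarchy has no superpathway map")
            return frozenset(hierarchy.superpathways.get(p, p) for p in pws)
        return pws

    all_groups: set = set()
    per_fn = []
    for fn in function_ids:
        g = groups_of(fn)
        per_fn.append(g)
        if g:
            all_groups |= g
    cols = sorted(all_groups)
    if unmapped == "bin" and any(g is None for g in per_fn):
        cols = cols + ["unmapped"]
    col_index = {p: j for j, p in enumerate(cols)}
    w = np.zeros((len(per_fn), len(cols)))
    for i, g in enumerate(per_fn):
        if g is None:
            if unmapped == "bin":
                w[i, col_index["unmapped"]] = 1.0
            continue
        share = 1.0 / len(g)
        for p in g:
            w[i, col_index[p]] = share
    return w, cols


def summarize_to_pathways(profile: FunctionalProfile,
                          hierarchy: PathwayHierarchy,
                          level: Literal["pathway", "superpathway"] = "pathway",
                          unmapped: Literal["drop", "bin"] = "drop"
                          ) -> FunctionalProfile:
    """Summarise a gene-family profile to pathway (or superpathway) level.

    Total mapped abundance is conserved: a family's abundance is divided
    evenly among the pathways containing it.
    """
    w, cols = pathway_split_matrix(profile.function_ids, hierarchy,
                                   level=level, unmapped=unmapped)
    return FunctionalProfile(np.asarray(cols, dtype=object),
                             profile.abundances @ w)


def postnormalize(profile: FunctionalProfile,
                  mode: Literal["none", "sum", "median"] = "sum",
                  universal_functions: Sequence[str] | None = None
                  ) -> FunctionalProfile:
    """Global rescaling of a functional profile.

    ``sum`` scales to total 1; ``median`` scales by the median abundance of
    a user-supplied list of universal single-copy gene families.  Downstream
    robustness measures use cosine dissimilarity and are invariant to this
    choice.
    """
    if mode == "none":
        return profile
    if mode == "sum":
        scale = profile.abundances.sum()
    elif mode == "median":
        if not universal_functions:
            raise ValidationError("median mode needs universal_functions")
        s = profile.to_series()
        present = [f for f in universal_functions if f in s.index]
        if not present:
            raise ValidationError("no universal function found in profile")
        scale = float(np.median(s.loc[present]))
    else:
        raise ValidationError(f"unknown normalisation mode {mode!r}")
    if scale <= 0:
        raise ValidationError("non-positive normalisation scale")
    return FunctionalProfile(profile.function_ids, profile.abundances / scale)
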