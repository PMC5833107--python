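"""Gene-distribution features (GDFs) of a community.

Five summaries of how gene families are apportioned across the genomes of
the community's members:

* **average functional redundancy** — for each function, the Shannon
  evenness of per-species contributions (abundance × copy number) to that
  function's total abundance, averaged over functions weighted by each
  function's share of the community functional profile;
* **average functional similarity** — mean pairwise cosine similarity of
  the members' genome-content vectors;
* **average genome size** — unweighted mean of per-genome total copy
  number;
* **genome size variability** — coefficient of variation (population SD /
  mean) of genome size;
* **unique function abundance** — total functional-profile share of
  functions encoded by exactly one present species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenomeContentMatrix, TaxonomicProfile, ValidationError
from .mapping import predict_functional_profile

__all__ = [
    "GDFVector",
    "functional_redundancy",
    "average_functional_redundancy",
    "functional_similarity",
    "average_functional_similarity",
    "genome_size_features",
    "unique_function_abundance",
    "gdf_vector",
    "gdf_table",
    "gdf_pca",
]


@dataclass
class GDFVector:
    avg_functional_redundancy: float
    avg_functional_similarity: float
    avg_genome_size: float
    genome_size_variability: float
    unique_function_abundance: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "avg_functional_redundancy": self.avg_functional_redundancy,
                "avg_functional_similarity": self.avg_functional_similarity,
                "avg_genome_size": self.avg_genome_size,
                "genome_size_variability": self.genome_size_variability,
                "unique_function_abundance": self.unique_function_abundance,
            }
        )


def _present(profile: TaxonomicProfile, content: GenomeContentMatrix):
    prof = profile.nonzero()
    c = content.submatrix(prof.taxon_ids.tolist())
    return prof.abundances, c


def _redundancy_from_contributions(contrib: np.ndarray,
                                   mode: str = "evenness") -> float:
    contrib = contrib[contrib > 0]
    if contrib.size == 0:
        raise ValidationError("function encoded by no present species")
    if mode == "evenness":
        q = contrib / contrib.sum()
        return float(-(q * np.log(q)).sum())
    if mode == "literal":
        return float(-(contrib * np.log(contrib)).sum())
    raise ValidationError(f"unknown redundancy mode {mode!r}")


def functional_redundancy(function_id: str, profile: TaxonomicProfile,
                          content: GenomeContentMatrix,
                          mode: str = "evenness") -> float:
    """Shannon evenness of per-species contributions to one function.

    Species i contributes s_i * c_i (abundance times copy number).  In the
    default ``evenness`` mode contributions are normalised to proportions
    before the entropy -sum(q ln q); ``literal`` computes the unnormalised
    sum -sum(s_i c_i ln(s_i c_i)).  Zero when a single species encodes the
    function.
    """
    s, c = _present(profile, content)
    j = content.function_ids.index(function_id)
    return _redundancy_from_contributions(s * c[:, j], mode)


def average_functional_redundancy(profile: TaxonomicProfile,
                                  content: GenomeContentMatrix,
                                  mode: str = "evenness") -> float:
    """Redundancy averaged over functions, weighted by functional abundance."""
    s, c = _present(profile, content)
    fp = predict_functional_profile(profile, content)
    weights = fp.relative().to_numpy()
    contrib = s[:, None] * c  # species × functions
    present = contrib.sum(axis=0) > 0
    red = np.zeros(c.shape[1])
    for j in np.flatnonzero(present):
        red[j] = _redundancy_from_contributions(contrib[:, j], mode)
    return float((weights[present] * red[present]).sum()
                 / weights[present].sum())


def functional_similarity(genome_a: np.ndarray, genome_b: np.ndarray) -> float:
    """Cosine similarity of two genome-content vectors, in [0, 1]."""
    a = np.asarray(genome_a, dtype=float)
    b = np.asarray(genome_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("empty genome: similarity undefined")
    return float((a @ b) / (na * nb))


def average_functional_similarity(profile: TaxonomicProfile,
                                  content: GenomeContentMatrix) -> float:
    """Unweighted mean cosine similarity over unordered pairs of present species."""
    _, c = _present(profile, content)
    n = c.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 present species for pairwise similarity")
    norms = np.linalg.norm(c, axis=1)
    if (norms == 0).any():
        raise ValidationError("empty genome among present species")
    g = (c / norms[:, None]) @ (c / norms[:, None]).T
    iu = np.triu_indices(n, k=1)
    return float(g[iu].mean())


def genome_size_features(profile: TaxonomicProfile,
                         content: GenomeContentMatrix
                         ) -> tuple[float, float]:
    """(average genome size, coefficient of variation) over present species.

    Genome size is the total copy number of a species' gene families; the
    average is unweighted by abundance.  The CV uses the population SD; for
    a single present species it is undefined (NaN, with a warning).
    """
    _, c = _present(profile, content)
    sizes = c.sum(axis=1)
    avg = float(sizes.mean())
    if len(sizes) < 2:
        warnings.warn("single present species: genome size variability undefined")
        return avg, float("nan")
    return avg, float(sizes.std(ddof=0) / avg)


def unique_function_abundance(profile: TaxonomicProfile,
                              content: GenomeContentMatrix) -> float:
    """Functional-profile share of functions encoded by exactly one species."""
    _, c = _present(profile, content)
    encoders = (c > 0).sum(axis=0)
    fp = predict_functional_profile(profile, content)
    rel = fp.relative().to_numpy()
    return float(rel[encoders == 1].sum())


def gdf_vector(profile: TaxonomicProfile, content: GenomeContentMatrix,
               redundancy_mode: str = "evenness") -> GDFVector:
    """All five gene-distribution features of one community."""
    avg_size, cv = genome_size_features(profile, content)
    return GDFVector(
        avg_functional_redundancy=average_functional_redundancy(
            profile, content, mode=redundancy_mode),
        avg_functional_similarity=average_functional_similarity(profile, content),
        avg_genome_size=avg_size,
        genome_size_variability=cv,
        unique_function_abundance=unique_function_abundance(profile, content),
    )


def gdf_table(profiles: dict[str, TaxonomicProfile],
              content: GenomeContentMatrix,
              redundancy_mode: str = "evenness") -> pd.DataFrame:
    """GDF vectors for a set of communities (communities × 5 features)."""
    return pd.DataFrame(
        {cid: gdf_vector(p, content, redundancy_mode).to_series()
         for cid, p in profiles.items()}
    ).T


def gdf_pca(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of z-scored GDF columns.

    Constant columns are dropped with a warning.  Returns (scores,
    loadings, explained-variance fractions); scores are centred so the mean
    community projects to the origin.
    """
    if len(table) < 3:
        raise ValidationError("PCA needs >= 3 communities")
    sd = table.std(ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant GDF columns: {list(table.columns[~keep])}")
    x = table.loc[:, keep]
    z = (x - x.mean()) / x.std(ddof=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = pd.DataFrame(u * s, index=table.index,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=scores.columns)
    explained = s ** 2 / (s ** 2).sum()
    return scores, loadings, explained
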