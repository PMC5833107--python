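"""Core in-memory containers for community profiles and genome content.

The central objects are :class:`TaxonomicProfile` (relative abundances of
taxa in one community), :class:`GenomeContentMatrix` (per-taxon gene-family
copy numbers plus 16S rRNA copy numbers), :class:`FunctionalProfile`
(gene-family or pathway abundances of one community), and
:class:`PathwayHierarchy` (gene-family to pathway membership).  All are thin
validated wrappers around pandas/numpy structures so that downstream modules
can operate on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "TaxonomicProfile",
    "FunctionalProfile",
    "GenomeContentMatrix",
    "PathwayHierarchy",
    "PerturbationSpec",
    "PerturbationRecord",
]

_SUM_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


class MissingTaxaError(KeyError):
    """Raised when profile taxa are absent from a tree or content matrix."""

    def __init__(self, missing: Iterable[str], where: str):
        self.missing = sorted(map(str, missing))
        self.where = where
        super().__init__(
            f"{len(self.missing)} taxa missing from {where}: "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


@dataclass
class CountTable:
    """Integer read counts per (sample, taxon), with optional metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with taxon ids as columns;
        non-negative integers.
    taxonomy
        Optional lineage string per taxon (Series indexed by taxon id).
    metadata
        Optional per-sample metadata (environment, subsite, ...).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate taxon ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric counts")
        if (vals < 0).any():
            raise ValidationError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def profile(self, sample_id: str) -> "TaxonomicProfile":
        """Relative-abundance profile of one sample (zero taxa dropped)."""
        row = self.counts.loc[sample_id]
        row = row[row > 0]
        return TaxonomicProfile(row.index.to_numpy(dtype=object),
                                row.to_numpy(dtype=float) / row.sum())


@dataclass
class TaxonomicProfile:
    """Relative abundances of the taxa in one community (sum to 1)."""

    taxon_ids: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = np.asarray(self.taxon_ids, dtype=object)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.taxon_ids.shape != self.abundances.shape:
            raise ValidationError("taxon_ids and abundances differ in length")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if (self.abundances < 0).any():
            raise ValidationError("negative abundance")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"abundances sum to {self.abundances.sum()}, expected 1"
            )

    @classmethod
    def from_series(cls, s: pd.Series) -> "TaxonomicProfile":
        s = s[s > 0]
        return cls(s.index.to_numpy(dtype=object),
                   s.to_numpy(dtype=float) / s.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.abundances, index=self.taxon_ids)

    @property
    def n_taxa(self) -> int:
        """Number of taxa with non-zero abundance."""
        return int(np.count_nonzero(self.abundances))

    def nonzero(self) -> "TaxonomicProfile":
        """Restrict to taxa with non-zero abundance."""
        mask = self.abundances > 0
        if mask.all():
            return self
        return TaxonomicProfile(self.taxon_ids[mask], self.abundances[mask])

    def renormalized(self, raw: np.ndarray) -> "TaxonomicProfile":
        """New profile on the same taxa with ``raw`` renormalised to sum 1."""
        total = raw.sum()
        if total <= 0:
            raise ValidationError("cannot renormalise: non-positive total")
        return TaxonomicProfile(self.taxon_ids, raw / total)


@dataclass
class FunctionalProfile:
    """Non-negative abundances of gene families or pathways (arbitrary units)."""

    function_ids: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.function_ids = np.asarray(self.function_ids, dtype=object)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.function_ids.shape != self.abundances.shape:
            raise ValidationError("function_ids and abundances differ in length")
        if (self.abundances < 0).any():
            raise ValidationError("negative functional abundance")
        if not (self.abundances > 0).any():
            raise ValidationError("functional profile is all zero")

    def to_series(self) -> pd.Series:
        return pd.Series(self.abundances, index=self.function_ids)

    def relative(self) -> pd.Series:
        s = self.to_series()
        return s / s.sum()


@dataclass
class GenomeContentMatrix:
    """Per-taxon gene-family copy numbers and 16S rRNA copy numbers.

    ``copy_numbers`` is a DataFrame indexed by taxon id with gene-family ids
    as columns; each row is that taxon's genome-content vector.  ``rrna`` is
    the 16S copy number per taxon (> 0), used to correct amplicon-derived
    relative abundances for marker-gene copy-number bias.
    """

    copy_numbers: pd.DataFrame
    rrna: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.copy_numbers.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative copy number")
        if self.rrna is not None:
            self.rrna = self.rrna.astype(float)
            if (self.rrna <= 0).any():
                raise ValidationError("16S copy numbers must be positive")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.copy_numbers.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.copy_numbers.columns)

    def require_taxa(self, taxa: Sequence[str]) -> None:
        missing = set(map(str, taxa)) - set(map(str, self.copy_numbers.index))
        if missing:
            raise MissingTaxaError(missing, "genome content matrix")

    def submatrix(self, taxa: Sequence[str]) -> np.ndarray:
        """Copy-number rows for ``taxa`` in that order (taxa × functions)."""
        self.require_taxa(taxa)
        return self.copy_numbers.loc[list(taxa)].to_numpy(dtype=float)

    def genome_sizes(self, taxa: Sequence[str] | None = None) -> pd.Series:
        """Total copy number per genome (sum over gene families)."""
        df = self.copy_numbers if taxa is None else self.copy_numbers.loc[list(taxa)]
        return df.sum(axis=1)


@dataclass
class PathwayHierarchy:
    """Membership of gene families in pathways (and optionally superpathways)."""

    mapping: Mapping[str, frozenset]
    superpathways: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for fn, pws in self.mapping.items():
            pws = frozenset(pws)
            if not pws:
                raise ValidationError(f"function {fn!r} mapped to no pathway")
            clean[str(fn)] = pws
        self.mapping = clean

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   superpathways: Mapping[str, str] | None = None
                   ) -> "PathwayHierarchy":
        m: dict[str, set] = {}
        for fn, pw in pairs:
            m.setdefault(str(fn), set()).add(str(pw))
        return cls({k: frozenset(v) for k, v in m.items()}, superpathways)

    def pathways(self) -> list[str]:
        out: set = set()
        for pws in self.mapping.values():
            out |= pws
        return sorted(out)


@dataclass
class PerturbationSpec:
    """One realisation of multiplicative perturbation multipliers.

    ``multipliers`` m_i lie in (0, M]; ``directions`` d_i in {-1, +1}.  The
    perturbed abundance of taxon i is proportional to a_i * m_i**d_i.
    """

    magnitude: float
    multipliers: np.ndarray
    directions: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        if self.multipliers.shape != self.directions.shape:
            raise ValidationError("multipliers and directions differ in length")
        if (self.multipliers <= 0).any() or (self.multipliers > self.magnitude).any():
            raise ValidationError("multipliers must lie in (0, M]")
        if not np.isin(self.directions, (-1, 1)).all():
            raise ValidationError("directions must be -1 or +1")

    def __len__(self) -> int:
        return len(self.multipliers)


@dataclass
class PerturbationRecord:
    """One simulated perturbation: magnitude M, taxonomic distance t, shift f."""

    community_id: str
    magnitude: float
    t: float
    f: float

    @staticmethod
    def frame(records: Sequence["PerturbationRecord"]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "community_id": [r.community_id for r in records],
                "magnitude": [r.magnitude for r in records],
                "t": [r.t for r in records],
                "f": [r.f for r in records],
            }
        )
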