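"""Model/Results interface for taxa-function robustness estimation.

:class:`RobustnessModel` bundles one community's taxonomic profile with the
genome content of its members, a phylogeny, and an optional pathway
hierarchy.  ``fit()`` runs the full simulation protocol — multiplicative
perturbations over the magnitude grid, linear mapping to functional
profiles, weighted UniFrac vs cosine-shift measurement, uniform window
re-sampling, and the log-log least-squares fit — and returns a
:class:`RobustnessResults` carrying attenuation, buffering, diagnostics,
the gene-distribution features, and a ``summary()`` table.

Environment-level aggregation (pseudomedian + CI per environment, pairwise
rank-sum contrasts with FDR control) lives in
:func:`summarize_environments`; :func:`run_pipeline` orchestrates many
communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GenomeContentMatrix,
    PathwayHierarchy,
    TaxonomicProfile,
    ValidationError,
)
from .curve import (
    ResponseCurve,
    RobustnessSummary,
    fit_response_curve,
    pseudomedian_with_ci,
    window_subsample,
)
from .distance import TreeIndex, cosine_dissimilarity_many
from .gdf import GDFVector, gdf_vector
from .mapping import normalize_by_copy_number, pathway_split_matrix
from .perturb import perturbation_matrix

__all__ = ["RobustnessModel", "RobustnessResults", "summarize_environments",
           "run_pipeline"]

ZERO_SHIFT_TOL = 1e-12


class RobustnessModel:
    """Taxa-function robustness of one community under simulated perturbation.

    Parameters
    ----------
    profile
        Relative-abundance profile of the community (sums to 1).
    content
        Genome-content matrix covering the profile's taxa.
    tree
        Rooted phylogeny (skbio ``TreeNode`` or a pre-built
        :class:`~taxafun.distance.TreeIndex`) whose leaves cover the taxa.
    hierarchy
        Optional gene-family → pathway map; when given, functional shifts
        are measured on pathway-level profiles.
    copy_number_correction
        Divide abundances by 16S copy number before mapping (default True
        when the matrix carries 16S counts).
    normalized_unifrac
        Use the normalised (range [0, 1]) weighted UniFrac variant.
    """

    def __init__(self, profile: TaxonomicProfile, content: GenomeContentMatrix,
                 tree, hierarchy: PathwayHierarchy | None = None,
                 community_id: str = "community",
                 environment: str | None = None,
                 copy_number_correction: bool | None = None,
                 normalized_unifrac: bool = True):
        self.profile = profile.nonzero()
        self.content = content
        content.require_taxa(self.profile.taxon_ids.tolist())
        self.tree_index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
        self.hierarchy = hierarchy
        self.community_id = community_id
        self.environment = environment
        if copy_number_correction is None:
            copy_number_correction = content.rrna is not None
        if copy_number_correction and content.rrna is None:
            raise ValidationError("no 16S copy numbers available for correction")
        self.copy_number_correction = copy_number_correction
        self.normalized_unifrac = normalized_unifrac

        # effective mapping matrix on the community's taxa; dividing rows by
        # the 16S copy number folds the abundance correction into the map
        # (cosine shift is invariant to the global rescaling this implies)
        c = content.submatrix(self.profile.taxon_ids.tolist())
        if self.copy_number_correction:
            r = content.rrna.reindex(self.profile.taxon_ids.tolist()).to_numpy()
            c = c / r[:, None]
        self._map = c
        self._pathway_w = None
        self._function_labels = list(content.function_ids)
        if hierarchy is not None:
            self._pathway_w, cols = pathway_split_matrix(
                content.function_ids, hierarchy)
            self._function_labels = cols

    @classmethod
    def from_dataframe(cls, abundances: pd.Series, content: GenomeContentMatrix,
                       tree, **kwargs) -> "RobustnessModel":
        """Build from a pandas Series of (possibly unnormalised) abundances."""
        return cls(TaxonomicProfile.from_series(abundances), content, tree,
                   **kwargs)

    # ------------------------------------------------------------------

    def _functional(self, abundance_rows: np.ndarray) -> np.ndarray:
        f = abundance_rows @ self._map
        if self._pathway_w is not None:
            f = f @ self._pathway_w
        return f

    def simulate_records(self, n_magnitudes: int = 45, m_min: float = 1.2,
                         m_max: float = 10.0, n_per_magnitude: int = 100,
                         seed: int = 0) -> pd.DataFrame:
        """Perturbation records (magnitude M, distance t, shift f) for this community."""
        P, M, base = perturbation_matrix(self.profile, n_magnitudes, m_min,
                                         m_max, n_per_magnitude, seed)
        base_vec = self.tree_index.profile_vector(base)
        Q = self.tree_index.vectors_for_taxa(base.taxon_ids.tolist(), P)
        t = self.tree_index.unifrac_one_to_many(
            base_vec, Q, normalized=self.normalized_unifrac)
        f0 = self._functional(base.abundances[None, :])[0]
        F = self._functional(P)
        f = cosine_dissimilarity_many(f0, F)
        self._last_P = P  # reused by function-specific fitting
        self._last_F = F
        self._last_f0 = f0
        return pd.DataFrame({"community_id": self.community_id,
                             "magnitude": M, "t": t, "f": f})

    def fit(self, n_magnitudes: int = 45, m_min: float = 1.2,
            m_max: float = 10.0, n_per_magnitude: int = 100,
            n_windows: int = 50, window_cap: int = 50,
            seed: int = 0) -> "RobustnessResults":
        """Run the perturbation protocol and fit the response curve."""
        records = self.simulate_records(n_magnitudes, m_min, m_max,
                                        n_per_magnitude, seed)
        t = records["t"].to_numpy()
        f = records["f"].to_numpy()
        try:
            gdfs = gdf_vector(self._gdf_profile(), self.content)
        except ValidationError:
            gdfs = None

        unfittable = bool((f < ZERO_SHIFT_TOL).all())
        curve = None
        n_dropped = 0
        n_used = 0
        if not unfittable:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    keep, n_dropped = window_subsample(
                        t, f, n_windows=n_windows, cap=window_cap,
                        seed=seed, return_counts=True)
                curve = fit_response_curve(t[keep], f[keep])
                n_used = int(keep.sum())
            except ValidationError:
                unfittable = True
        return RobustnessResults(model=self, curve=curve, records=records,
                                 gdfs=gdfs, unfittable=unfittable,
                                 n_dropped=n_dropped, n_used=n_used,
                                 seed=seed)

    def _gdf_profile(self) -> TaxonomicProfile:
        if self.copy_number_correction:
            return normalize_by_copy_number(self.profile, self.content)
        return self.profile

    def fit_function_specific(self, n_magnitudes: int = 45, m_min: float = 1.2,
                              m_max: float = 10.0, n_per_magnitude: int = 100,
                              n_windows: int = 50, window_cap: int = 50,
                              seed: int = 0) -> dict[str, ResponseCurve]:
        """Per-function response curves from the same perturbation set.

        The shift of a single function is the magnitude of its relative
        abundance change; functions with zero original abundance, or whose
        shifts are all (numerically) zero, are skipped with a warning.
        """
        records = self.simulate_records(n_magnitudes, m_min, m_max,
                                        n_per_magnitude, seed)
        t = records["t"].to_numpy()
        curves: dict[str, ResponseCurve] = {}
        skipped: list[str] = []
        for j, fn in enumerate(self._function_labels):
            f0j = self._last_f0[j]
            if f0j <= 0:
                skipped.append(fn)
                continue
            fj = np.abs(self._last_F[:, j] - f0j) / f0j
            if (fj < ZERO_SHIFT_TOL).all():
                skipped.append(fn)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    keep = window_subsample(t, fj, n_windows=n_windows,
                                            cap=window_cap, seed=seed)
                curves[fn] = fit_response_curve(t[keep], fj[keep],
                                                scope=str(fn))
            except ValidationError:
                skipped.append(fn)
        if skipped:
            warnings.warn(f"skipped {len(skipped)} functions with zero "
                          "abundance or zero shift")
        return curves


@dataclass
class RobustnessResults:
    """Fitted robustness of one community.

    ``attenuation`` and ``buffering`` are the power-law coefficients of the
    response curve f = t**b / exp(a); higher attenuation means smaller
    functional shifts per unit taxonomic perturbation (higher robustness).
    ``unfittable`` marks communities whose perturbations produced no
    functional shift (e.g. identical member genomes).
    """

    model: RobustnessModel
    curve: ResponseCurve | None
    records: pd.DataFrame
    gdfs: GDFVector | None
    unfittable: bool
    n_dropped: int
    n_used: int
    seed: int

    @property
    def attenuation(self) -> float:
        return self.curve.attenuation if self.curve else float("nan")

    @property
    def buffering(self) -> float:
        return self.curve.buffering if self.curve else float("nan")

    def predict(self, t):
        """Expected functional shift at taxonomic distance t."""
        if self.curve is None:
            raise ValidationError("community is unfittable; no curve available")
        return self.curve.predict(t)

    def to_row(self) -> pd.Series:
        row = pd.Series({
            "community_id": self.model.community_id,
            "environment": self.model.environment,
            "attenuation": self.attenuation,
            "buffering": self.buffering,
            "n_perturbations": len(self.records),
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "unfittable": self.unfittable,
        })
        if self.gdfs is not None:
            row = pd.concat([row, self.gdfs.to_series()])
        return row

    def summary(self) -> str:
        lines = [
            "Taxa-Function Robustness Results",
            "=" * 40,
            f"community:        {self.model.community_id}",
            f"environment:      {self.model.environment or '-'}",
            f"taxa (non-zero):  {self.model.profile.n_taxa}",
            f"perturbations:    {len(self.records)}"
            f" (used {self.n_used}, dropped {self.n_dropped})",
        ]
        if self.unfittable or self.curve is None:
            lines.append("status:           UNFITTABLE (no functional shift)")
        else:
            lines += [
                f"attenuation (a):  {self.attenuation:.4f}",
                f"buffering (b):    {self.buffering:.4f}",
                f"response curve:   f = t^{self.buffering:.3f}"
                f" / e^{self.attenuation:.3f}",
                f"residual SS:      {self.curve.residual_sum:.4f}",
            ]
        if self.gdfs is not None:
            lines.append("-" * 40)
            for k, v in self.gdfs.to_series().items():
                lines.append(f"{k:<28}{v:.4f}")
        return "\n".join(lines)


def summarize_environments(results: list[RobustnessResults],
                           alpha: float = 0.05
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Environment-level robustness summaries and pairwise contrasts.

    Returns (summaries, contrasts): per environment the Hodges-Lehmann
    pseudomedian and 95% CI of attenuation and buffering; and per pair of
    environments the Wilcoxon rank-sum p-value on attenuation with
    Benjamini-Hochberg adjusted q-values.
    """
    rows = []
    by_env: dict[str, list[RobustnessResults]] = {}
    for r in results:
        if r.unfittable or r.model.environment is None:
            continue
        by_env.setdefault(r.model.environment, []).append(r)
    for env, rs in sorted(by_env.items()):
        for metric in ("attenuation", "buffering"):
            vals = np.array([getattr(r, metric) for r in rs])
            s = pseudomedian_with_ci(vals, alpha=alpha)
            rows.append({"environment": env, "metric": metric,
                         "pseudomedian": s.pseudomedian, "ci_low": s.ci_low,
                         "ci_high": s.ci_high, "n": s.n})
    summaries = pd.DataFrame(rows)

    envs = sorted(by_env)
    pairs, pvals = [], []
    for i, e1 in enumerate(envs):
        for e2 in envs[i + 1:]:
            a1 = [r.attenuation for r in by_env[e1]]
            a2 = [r.attenuation for r in by_env[e2]]
            stat, p = stats.ranksums(a1, a2)
            pairs.append({"env_a": e1, "env_b": e2, "statistic": stat,
                          "p_value": p})
            pvals.append(p)
    contrasts = pd.DataFrame(pairs)
    if len(contrasts):
        contrasts["q_value"] = stats.false_discovery_control(np.asarray(pvals))
    return summaries, contrasts


def run_pipeline(profiles: dict[str, TaxonomicProfile],
                 content: GenomeContentMatrix, tree,
                 hierarchy: PathwayHierarchy | None = None,
                 environments: dict[str, str] | None = None,
                 seed: int = 0, out_dir: str | Path | None = None,
                 **fit_kwargs) -> list[RobustnessResults]:
    """Fit every community and (optionally) write curves/gdfs/summaries TSVs.

    Sub-seeds per community are spawned from ``seed``, so results are
    independent of iteration order.  Communities with fewer than two
    non-zero taxa are skipped with a warning.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    results = []
    for (cid, prof), child in zip(sorted(profiles.items()), children):
        if prof.nonzero().n_taxa < 2:
            warnings.warn(f"skipping community {cid}: fewer than 2 taxa")
            continue
        env = environments.get(cid) if environments else None
        model = RobustnessModel(prof, content, idx, hierarchy=hierarchy,
                                community_id=cid, environment=env)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(model.fit(seed=sub_seed, **fit_kwargs))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = pd.DataFrame([r.to_row() for r in results])
        curve_cols = ["community_id", "environment", "attenuation",
                      "buffering", "n_perturbations", "n_used", "n_dropped",
                      "unfittable"]
        table[curve_cols].to_csv(out / "curves.tsv", sep="\t", index=False)
        gdf_cols = [c for c in table.columns if c not in curve_cols]
        if gdf_cols:
            table[["community_id"] + gdf_cols].to_csv(
                out / "gdfs.tsv", sep="\t", index=False)
        if environments:
            summaries, contrasts = summarize_environments(results)
            summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
            contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
    return results
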