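"""Reading, writing, and sample-level processing of community data.

Tabular inputs are TSV with a header row (taxa as columns for OTU tables,
gene families as columns for genome-content matrices); BIOM-style JSON OTU
tables are also accepted.  Trees are newick, parsed with scikit-bio.  All
stochastic operations take an explicit seed; there is no global random state.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    CountTable,
    GenomeContentMatrix,
    MissingTaxaError,
    PathwayHierarchy,
    TaxonomicProfile,
    ValidationError,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_tree",
    "read_genome_content",
    "read_hierarchy",
    "read_functional_profiles",
    "read_inputs",
    "filter_chloroplast",
    "qc_filter_and_rarefy",
    "subsample_otus",
    "pool_subsites",
    "weighted_sample_without_replacement",
]

RRNA_COLUMN = "16S_rRNA_Count"


def read_count_table(path: str | Path, taxonomy_path: str | Path | None = None,
                     metadata_path: str | Path | None = None) -> CountTable:
    """Read an OTU/taxon count table (TSV taxa × samples, or BIOM-style JSON).

    TSV layout follows the common OTU-table convention: taxa as rows,
    samples as columns, with an optional trailing ``taxonomy`` column.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".biom"}:
        return _read_biom_json(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    taxonomy = None
    tax_cols = [c for c in df.columns if c.lower() == "taxonomy"]
    if tax_cols:
        taxonomy = df[tax_cols[0]].astype(str)
        df = df.drop(columns=tax_cols)
    try:
        counts = df.T.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if taxonomy_path is not None:
        tx = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy = tx.iloc[:, 0].astype(str)
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    counts.index = counts.index.map(str)
    counts.columns = counts.columns.map(str)
    counts.index.name = None
    counts.columns.name = None
    return CountTable(counts, taxonomy=taxonomy, metadata=metadata)


def _read_biom_json(path: Path) -> CountTable:
    """BIOM-style JSON (sparse or dense 'data' with 'rows'=taxa, 'columns'=samples)."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    lineages = {
        r["id"]: "; ".join(np.atleast_1d((r.get("metadata") or {})["taxonomy"]).tolist())
        for r in doc["rows"]
        if (r.get("metadata") or {}).get("taxonomy")
    }
    taxonomy = pd.Series(lineages) if lineages else None
    counts = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CountTable(counts, taxonomy=taxonomy)


def write_count_table(table: CountTable, path: str | Path,
                      header_comment: str | None = None) -> None:
    """Write a count table as TSV (taxa × samples) with optional # header."""
    out = table.counts.T
    if table.taxonomy is not None:
        out = out.copy()
        out["taxonomy"] = table.taxonomy.reindex(out.index)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index_label="taxon_id")


def read_tree(path: str | Path) -> TreeNode:
    """Parse a rooted newick tree; unset branch lengths become 0."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(f"negative branch length on {node.name!r}")
    return tree


def read_genome_content(path: str | Path,
                        rrna_column: str = RRNA_COLUMN) -> GenomeContentMatrix:
    """Read a taxa × gene-family copy-number TSV.

    A column named ``rrna_column`` (default ``16S_rRNA_Count``) is split off
    as the per-taxon 16S copy number.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    df.index.name = None
    rrna = None
    if rrna_column in df.columns:
        rrna = df[rrna_column].astype(float)
        df = df.drop(columns=[rrna_column])
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return GenomeContentMatrix(df, rrna=rrna)


def write_genome_content(content: GenomeContentMatrix, path: str | Path) -> None:
    out = content.copy_numbers.copy()
    if content.rrna is not None:
        out.insert(0, RRNA_COLUMN, content.rrna)
    out.to_csv(path, sep="\t", index_label="taxon_id")


def read_hierarchy(path: str | Path) -> PathwayHierarchy:
    """Read a two-column (function_id, pathway_id) TSV with repeated rows."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError("hierarchy table needs >= 2 columns")
    pairs = zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))
    super_map = None
    if df.shape[1] >= 3 and df.iloc[:, 2].notna().any():
        super_map = dict(
            zip(df.iloc[:, 1].astype(str), df.iloc[:, 2].astype(str))
        )
    return PathwayHierarchy.from_pairs(pairs, superpathways=super_map)


def read_functional_profiles(path: str | Path) -> pd.DataFrame:
    """Read a functions × samples TSV of functional abundances."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.T.astype(float)


def read_inputs(otu_table: str | Path, tree: str | Path | None = None,
                genome_content: str | Path | None = None,
                hierarchy: str | Path | None = None,
                metadata: str | Path | None = None):
    """Read the full input bundle and cross-validate taxon coverage.

    Returns ``(CountTable, TreeNode | None, GenomeContentMatrix | None,
    PathwayHierarchy | None)``.  Taxa present in the table but absent from
    the tree leaves or the genome-content matrix raise
    :class:`~taxafun.containers.MissingTaxaError` naming the offenders.
    """
    table = read_count_table(otu_table, metadata_path=metadata)
    tr = read_tree(tree) if tree is not None else None
    gc = read_genome_content(genome_content) if genome_content is not None else None
    hi = read_hierarchy(hierarchy) if hierarchy is not None else None

    taxa = set(table.taxon_ids)
    if tr is not None:
        leaves = {t.name for t in tr.tips()}
        missing = taxa - leaves
        if missing:
            raise MissingTaxaError(missing, "tree leaves")
    if gc is not None:
        gc.require_taxa(sorted(taxa))
    return table, tr, gc, hi


# ---------------------------------------------------------------------------
# sample processing


def filter_chloroplast(table: CountTable,
                       label: str = "chloroplast") -> CountTable:
    """Drop taxa whose lineage contains ``label`` (case-insensitive).

    Removes amplicon reads of plant-plastid origin that would otherwise be
    counted as community members.
    """
    if table.taxonomy is None:
        raise ValidationError("chloroplast filtering requires taxonomy labels")
    lineages = table.taxonomy.reindex(table.taxon_ids).fillna("")
    keep = ~lineages.str.contains(label, case=False, regex=False)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not kept:
        warnings.warn("all taxa matched the chloroplast label; table is empty")
    return CountTable(table.counts[kept],
                      taxonomy=table.taxonomy.reindex(kept),
                      metadata=table.metadata)


def qc_filter_and_rarefy(table: CountTable, min_taxa: int = 10,
                         min_reads: int = 5000, depth: int = 5000,
                         seed: int = 0) -> CountTable:
    """Drop shallow/low-richness samples, then rarefy the rest.

    Samples with fewer than ``min_taxa`` non-zero taxa or fewer than
    ``min_reads`` total reads are removed; the remainder are down-sampled
    without replacement (multivariate hypergeometric) to exactly ``depth``
    reads, equalising sampling effort across samples.
    """
    if depth > min_reads:
        raise ValidationError("rarefaction depth cannot exceed min_reads")
    counts = table.counts
    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    keep = (totals >= min_reads) & (richness >= min_taxa)
    removed = list(counts.index[~keep])
    if removed:
        warnings.warn(f"removed {len(removed)} samples failing QC: "
                      + ", ".join(map(str, removed[:10])))
    rng = np.random.default_rng(seed)
    rows = []
    for sid in counts.index[keep]:
        row = counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(row, depth))
    rare = pd.DataFrame(rows, index=counts.index[keep], columns=counts.columns)
    meta = table.metadata.loc[rare.index] if table.metadata is not None else None
    return CountTable(rare, taxonomy=table.taxonomy, metadata=meta)


def weighted_sample_without_replacement(ids: np.ndarray, weights: np.ndarray,
                                        k: int, rng: np.random.Generator
                                        ) -> np.ndarray:
    """Successive weighted draws without replacement (weights renormalised)."""
    ids = np.asarray(ids, dtype=object)
    w = np.asarray(weights, dtype=float).copy()
    chosen = []
    for _ in range(k):
        p = w / w.sum()
        j = rng.choice(len(ids), p=p)
        chosen.append(j)
        w[j] = 0.0
    return ids[np.asarray(chosen)]


def subsample_otus(profile: TaxonomicProfile, k: int = 10,
                   seed: int = 0) -> TaxonomicProfile:
    """Subsample a community to ``k`` taxa, retention odds ∝ abundance.

    Used as a diversity control: communities from environments of very
    different richness are reduced to a common number of taxa while
    approximately preserving the shape of the abundance distribution.
    Abundances of the retained taxa are renormalised to sum 1.
    """
    prof = profile.nonzero()
    if prof.n_taxa < k:
        raise ValidationError(
            f"profile has {prof.n_taxa} taxa, cannot subsample to {k}"
        )
    rng = np.random.default_rng(seed)
    kept = weighted_sample_without_replacement(
        prof.taxon_ids, prof.abundances, k, rng
    )
    s = prof.to_series().loc[list(kept)]
    return TaxonomicProfile.from_series(s)


def pool_subsites(metadata: pd.DataFrame, pooling: dict[str, str],
                  column: str = "subsite") -> pd.DataFrame:
    """Relabel bilaterally symmetric subsites to a pooled name.

    ``pooling`` maps original subsite labels (e.g. left/right antecubital
    fossa) to their pooled label.
    """
    out = metadata.copy()
    out[column] = out[column].replace(pooling)
    return out
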