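"""Synthetic communities, trees, and genome content for end-to-end testing.

The generator emulates the statistical shape of the real inputs rather than
any particular organism inventory: long-tailed (lognormal) relative
abundances, a random rooted bifurcating tree with exponential branch
lengths, and genome-content matrices with a single *redundancy* knob
``rho``: a fraction rho of gene families form a core genome shared by every
taxon, and the remainder are private to single taxa (assigned round-robin).
At rho = 1 all genomes are identical and community function cannot shift;
at rho = 0 genomes share only a minimal single-copy marker family and most
functional mass is taxon-private.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    GenomeContentMatrix,
    PathwayHierarchy,
    TaxonomicProfile,
    ValidationError,
)

__all__ = [
    "ScenarioConfig",
    "generate_tree",
    "generate_genome_content",
    "generate_community",
    "generate_hierarchy",
    "generate_scenario",
]

MARKER_FUNCTION = "F_marker"


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic community scenario.

    ``redundancy`` (rho) interpolates between fully private accessory
    genomes (0) and identical genomes (1).  ``sigma`` is the lognormal
    shape of the abundance distribution; 1.0 gives the long-tailed profiles
    typical of 16S surveys.
    """

    n_taxa: int = 30
    n_functions: int = 150
    redundancy: float = 0.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValidationError("redundancy must lie in [0, 1]")
        if self.n_taxa < 2:
            raise ValidationError("need >= 2 taxa")


def taxon_names(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def generate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees under a new
    internal node, each child edge receiving an Exp(1) length.
    """
    if n_taxa < 2:
        raise ValidationError("need >= 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in taxon_names(n_taxa)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        left, right = nodes[i], nodes[j]
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[left, right])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_genome_content(config: ScenarioConfig) -> GenomeContentMatrix:
    """Core/accessory genome-content matrix with redundancy knob rho.

    ``floor(rho * n_functions)`` core families are present in every genome;
    the remaining families are private, dealt round-robin to single taxa.
    A universal single-copy marker family is always included so that every
    genome is non-empty even at rho = 0.  Copy numbers are drawn from
    {1, 2, 3} and 16S copy numbers from {1, ..., 5}.
    """
    rng = np.random.default_rng(config.seed)
    taxa = taxon_names(config.n_taxa)
    n_core = int(np.floor(config.redundancy * config.n_functions))
    functions = [MARKER_FUNCTION] + [f"F{j:04d}" for j in range(config.n_functions)]
    mat = np.zeros((config.n_taxa, len(functions)))
    mat[:, 0] = 1.0  # shared single-copy marker
    for j in range(n_core):
        # shared core: one copy number per function, identical in all genomes
        mat[:, 1 + j] = rng.integers(1, 4)
    for j in range(n_core, config.n_functions):
        owner = (j - n_core) % config.n_taxa
        mat[owner, 1 + j] = rng.integers(1, 4)
    rrna = pd.Series(rng.integers(1, 6, size=config.n_taxa).astype(float),
                     index=taxa)
    return GenomeContentMatrix(pd.DataFrame(mat, index=taxa, columns=functions),
                               rrna=rrna)


def generate_community(n_taxa: int, sigma: float = 1.0,
                       seed: int = 0) -> TaxonomicProfile:
    """Long-tailed relative-abundance profile: normalised lognormal draws."""
    if n_taxa < 1:
        raise ValidationError("need >= 1 taxon")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        raw = np.ones(n_taxa)
    else:
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    return TaxonomicProfile(np.array(taxon_names(n_taxa), dtype=object),
                            raw / raw.sum())


def generate_hierarchy(content: GenomeContentMatrix, n_pathways: int = 10,
                       seed: int = 0) -> PathwayHierarchy:
    """Random function→pathway map: each family joins 1-3 pathways."""
    rng = np.random.default_rng(seed)
    pathways = [f"P{i:02d}" for i in range(n_pathways)]
    pairs = []
    for fn in content.function_ids:
        k = int(rng.integers(1, 4))
        for p in rng.choice(n_pathways, size=k, replace=False):
            pairs.append((fn, pathways[p]))
    return PathwayHierarchy.from_pairs(pairs)


def generate_scenario(config: ScenarioConfig):
    """Full input bundle (profile, tree, genome content, hierarchy).

    Sub-seeds for the four components are spawned from ``config.seed`` so
    each component is independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    profile = generate_community(config.n_taxa, config.sigma, seed=seeds[0])
    tree = generate_tree(config.n_taxa, seed=seeds[1])
    content = generate_genome_content(
        ScenarioConfig(config.n_taxa, config.n_functions, config.redundancy,
                       config.sigma, seed=seeds[2])
    )
    hierarchy = generate_hierarchy(content, seed=seeds[3])
    return profile, tree, content, hierarchy
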