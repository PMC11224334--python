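"""Phylogenetic trees and the species correlation matrix they induce.

The hierarchical model's coefficient prior mixes a tree-derived correlation
matrix C with the identity through the phylogenetic-signal parameter rho.
C is the standard Brownian-motion correlation on an ultrametric tree: the
shared root-to-MRCA path length of two species divided by the tree height.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class TaxonTree:
    """Rooted ultrametric tree over the modelled species with its correlation matrix."""

    tree: dendropy.Tree
    species: list[str]
    corr: np.ndarray  # (S, S), symmetric, unit diagonal, PSD

    def __post_init__(self):
        C = self.corr
        if C.shape != (len(self.species), len(self.species)):
            raise ValueError("corr shape must match species count")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("corr must be symmetric with unit diagonal")

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TaxonTree":
        species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        corr = _tree_correlation(tree, species)
        return cls(tree=tree, species=species, corr=corr)

    @classmethod
    def from_newick(cls, newick: str) -> "TaxonTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_tree(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick")

    def subset(self, species: list[str]) -> "TaxonTree":
        """Restrict to a species subset (order follows the given list)."""
        missing = set(species) - set(self.species)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        idx = [self.species.index(s) for s in species]
        sub = dendropy.Tree(self.tree)
        sub.retain_taxa_with_labels(species)
        return TaxonTree(tree=sub, species=list(species), corr=self.corr[np.ix_(idx, idx)])


def _tree_correlation(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Brownian correlation: shared path length fraction of root-to-tip distance."""
    n = len(species)
    if n == 1:
        return np.ones((1, 1))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
    height = tree.max_distance_from_root()
    if height <= 0:
        return np.eye(n)
    # ultrametric: depth of MRCA(i,j) below the root is height - d_ij / 2
    corr = 1.0 - dist / (2.0 * height)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, 0.0, 1.0)


def simulate_tree(n_species: int, seed: int = 0) -> TaxonTree:
    """Simulate an ultrametric pure-birth (Yule) tree with exponential branch times.

    Deterministic for a fixed seed. Species are labelled sp01, sp02, ...
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    width = max(2, len(str(n_species)))
    labels = [f"sp{str(i + 1).zfill(width)}" for i in range(n_species)]
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n_species == 1:
        tree.seed_node.taxon = taxa.get_taxon(labels[0])
        tree.seed_node.edge.length = 1.0
        return TaxonTree(tree=tree, species=labels, corr=np.ones((1, 1)))

    # classic Yule construction: split a uniformly chosen pending lineage at
    # exponentially spaced event times, then extend all tips to the final time.
    # A stem lineage precedes the first split so every pair shares root path.
    stem = tree.seed_node.new_child()
    active = [stem]
    birth_times = {stem: 0.0}
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = node.new_child()
            birth_times[child] = t
            active.append(child)
        node.edge.length = t - birth_times[node] if node.parent_node else None
        birth_times[node] = t  # split time, used for edge length of children

    t_end = t + rng.exponential(1.0 / len(active))
    order = rng.permutation(n_species)
    for k, leaf in enumerate(active):
        leaf.edge.length = t_end - birth_times[leaf]
        leaf.taxon = taxa.get_taxon(labels[order[k]])
    # internal edges
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = birth_times[node] - birth_times[node.parent_node]
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None
    return TaxonTree.from_tree(tree)
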