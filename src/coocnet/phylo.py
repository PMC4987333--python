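"""Newick trees and cophenetic (patristic) distances.

Trees are consumed, never estimated: the wrapper parses Newick, checks tip
labels, and turns the tree into the phylogenetic distance matrix used by the
assembly and dispersion analyses. Parsing and path-length bookkeeping are
delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datatypes import DataValidationError, DistanceMatrix


@dataclass
class PhyloTree:
    """A rooted tree with labelled tips and non-negative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DataValidationError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise DataValidationError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [
            leaf.taxon.label if leaf.taxon is not None else ""
            for leaf in self.tree.leaf_node_iter()
        ]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        return float(np.ptp(depths)) <= tol


def parse_newick(text: str, missing_lengths: str = "error") -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    ``missing_lengths`` is either ``"error"`` or ``"one"`` (treat absent
    branch lengths as 1.0, the usual cladogram convention).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise DataValidationError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or len(tree.leaf_nodes()) == 0:
        raise DataValidationError("Newick string contains no tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if missing_lengths == "one":
                edge.length = 1.0
            else:
                raise DataValidationError("branch without length (set missing_lengths='one')")
    return PhyloTree(tree)


def read_newick(path: str | Path, missing_lengths: str = "error") -> PhyloTree:
    return parse_newick(Path(path).read_text(), missing_lengths=missing_lengths)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def cophenetic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the tree path between every pair of tips."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    arr = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            arr[i, j] = arr[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(
        values=pd.DataFrame(arr, index=labels, columns=labels), kind="phylogenetic"
    )
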