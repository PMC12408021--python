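"""Strain trees from marker-SNV and gene-content distances.

Distance matrices come from normalised Hamming distance over aligned
marker haplotypes or Jaccard distance over pangenome gene sets; trees are
built by neighbour joining (scikit-bio) with negative branch lengths
clamped to zero and the deficit transferred to the sibling edge. Trees
round-trip through Newick.
"""
from __future__ import annotations

import io

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode

from .tables import DistanceMatrix

AMBIGUOUS = set("N-?X")


class StrainTree:
    """Leaf-labelled tree with per-leaf annotations (infant, group, ...)."""

    def __init__(self, tree: TreeNode, annotations: pd.DataFrame | None = None):
        labels = [t.name for t in tree.tips()]
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        if any(l is None for l in labels):
            raise ValueError("unlabelled leaf")
        self.tree = tree
        self.annotations = annotations  # index: leaf label

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def annotate(self, annotations: pd.DataFrame) -> "StrainTree":
        missing = set(self.leaf_names) - set(annotations.index)
        if missing:
            raise ValueError(f"annotations missing for leaves: {sorted(missing)[:5]}")
        self.annotations = annotations
        return self

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StrainTree({len(self.leaf_names)} leaves)"


def snv_distance_matrix(haplotypes: pd.DataFrame) -> DistanceMatrix:
    """Normalised Hamming distance over positions where both rows are
    unambiguous. ``haplotypes``: genomes x aligned sites, single characters.
    """
    if not isinstance(haplotypes, pd.DataFrame):
        # mapping/Series of id -> aligned string
        items = dict(haplotypes)
        lengths = {len(v) for v in items.values()}
        if len(lengths) > 1:
            raise ValueError(f"haplotype length mismatch: {sorted(lengths)}")
        haplotypes = pd.DataFrame([list(v) for v in items.values()],
                                  index=list(items.keys()))
    mat = haplotypes.values.astype(str)
    n, m = mat.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    ok = ~np.isin(np.char.upper(mat), list(AMBIGUOUS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            if not comparable.any():
                raise ValueError(f"no comparable sites between rows {i} and {j}")
            mism = (mat[i][comparable] != mat[j][comparable]).sum()
            d[i, j] = d[j, i] = mism / comparable.sum()
    return DistanceMatrix(list(haplotypes.index), d, metric="snv")


def gene_content_distance(gpm: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance between genome gene sets.

    ``gpm``: binary genes x genomes matrix.
    """
    x = (gpm.values > 0).astype(float)
    sizes = x.sum(axis=0)
    if (sizes == 0).any():
        empty = [g for g, s in zip(gpm.columns, sizes) if s == 0]
        raise ValueError(f"genomes with zero genes: {empty[:5]}")
    inter = x.T @ x
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(gpm.columns), d, metric="jaccard")


def _clamp_negative_lengths(tree: TreeNode) -> TreeNode:
    """Clamp negative branch lengths to 0, moving the deficit onto the
    sibling edge so root-to-tip path lengths are preserved where possible."""
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            for sib in node.siblings():
                if sib.length is not None:
                    sib.length = max(0.0, sib.length + deficit)
    return tree


def build_tree(dm: DistanceMatrix, method: str = "nj") -> StrainTree:
    """Neighbour-joining tree from a distance matrix (>= 3 leaves)."""
    if len(dm.ids) < 3:
        raise ValueError("need >= 3 leaves to build a tree")
    if method != "nj":
        raise ValueError(f"unknown method {method!r}")
    tree = skbio.tree.nj(dm.to_skbio())
    tree = _clamp_negative_lengths(tree)
    return StrainTree(tree)


def read_newick(text_or_path) -> StrainTree:
    """Parse Newick text (or a file path) into a StrainTree."""
    text = str(text_or_path)
    if "(" in text or ";" in text:
        handle = io.StringIO(text)
    else:
        handle = open(text)
    try:
        tree = TreeNode.read(handle, format="newick")
    finally:
        handle.close()
    return StrainTree(tree)


def write_newick(tree: StrainTree, path=None) -> str:
    buf = io.StringIO()
    tree.tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
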