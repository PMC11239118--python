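"""Phylogenetic eigenvector filters with broken-stick retention.

The phylogenetic covariance matrix of a rooted tree (entry i,j = shared
root-to-MRCA path length) is eigendecomposed; the leading eigenvectors
("phylogenetic filters") summarise relatedness as continuous predictors a
tree-based learner can consume. The number retained follows the broken-stick
rule: keep leading components while their relative eigenvalue exceeds the
expected proportion of a randomly broken unit stick, stopping at the first
failure, with a floor of one filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = ["FilterSet", "broken_stick", "derive_filters", "read_newick",
           "tree_to_covariance"]


@dataclass
class FilterSet:
    """Retained eigenvectors (species x k, orthonormal columns, sign fixed so
    each column's largest-magnitude loading is positive) plus the full
    descending eigenvalue spectrum."""

    eigenvalues: np.ndarray
    vectors: pd.DataFrame
    retained: int
    tree_id: str = "tree"

    def __post_init__(self):
        if self.retained < 1:
            raise ValueError("must retain at least one filter")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def species(self) -> pd.Index:
        return self.vectors.index

    def to_csv(self, path) -> None:
        """Species x filters CSV plus a JSON sidecar of eigenvalues."""
        self.vectors.to_csv(path, index_label="species")
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "tree_id": self.tree_id,
                    "retained": self.retained,
                    "eigenvalues": [float(v) for v in self.eigenvalues],
                },
                fh,
                indent=1,
            )

    @classmethod
    def read_csv(cls, path) -> "FilterSet":
        vectors = pd.read_csv(path, index_col="species")
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(
            eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
            vectors=vectors,
            retained=int(meta["retained"]),
            tree_id=meta["tree_id"],
        )


def read_newick(path_or_string, is_path: bool = True) -> dendropy.Tree:
    """Read a Newick tree with branch lengths; the tree is treated as rooted
    at the Newick root node."""
    kwargs = {"path": path_or_string} if is_path else {"data": path_or_string}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    tree.is_rooted = True
    return tree


def tree_to_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Species x species phylogenetic covariance: entry (i, j) is the shared
    root-to-MRCA path length; the diagonal is the root-to-tip depth."""
    if not tree.is_rooted:
        raise ValueError("tree is unrooted: root it before deriving a covariance")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [pos[node.taxon.label]]
            continue
        depth = node.distance_from_root()
        kids = [c._tipset for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.asarray(kids[a])
                ib = np.asarray(kids[b])
                cov[np.ix_(ia, ib)] = depth
                cov[np.ix_(ib, ia)] = depth
        node._tipset = [i for k in kids for i in k]
    for leaf in tree.leaf_node_iter():
        i = pos[leaf.taxon.label]
        cov[i, i] = leaf.distance_from_root()
    return pd.DataFrame(cov, index=labels, columns=labels)


def broken_stick(p: int) -> np.ndarray:
    """Expected proportions b_k = (1/p) * sum_{i=k..p} 1/i of a unit stick
    broken at p-1 uniform points; the components sum to one."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def derive_filters(
    cov: pd.DataFrame | np.ndarray,
    tree_id: str = "tree",
    rule: str = "sequential",
) -> FilterSet:
    """Eigendecompose a covariance matrix and retain filters by the
    broken-stick rule.

    ``rule="sequential"`` (default) keeps leading components until the first
    one whose relative eigenvalue does not exceed its broken-stick
    proportion; ``rule="all_passing"`` keeps every passing component. At
    least one filter is always retained.
    """
    if isinstance(cov, pd.DataFrame):
        labels = list(cov.index)
        mat = cov.to_numpy(dtype=float)
    else:
        mat = np.asarray(cov, dtype=float)
        labels = [f"s{i}" for i in range(mat.shape[0])]
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    evals, evecs = np.linalg.eigh((mat + mat.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise ValueError("covariance matrix has no variance")
    props = evals / total
    b = broken_stick(len(evals))
    if rule == "sequential":
        k = 0
        for pk, bk in zip(props, b):
            if pk > bk:
                k += 1
            else:
                break
    elif rule == "all_passing":
        k = int(np.sum(props > b))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    k = max(k, 1)
    kept = evecs[:, :k].copy()
    for j in range(k):  # sign convention: largest-|loading| entry positive
        i = np.argmax(np.abs(kept[:, j]))
        if kept[i, j] < 0:
            kept[:, j] *= -1
    vectors = pd.DataFrame(
        kept, index=pd.Index(labels, name="species"),
        columns=[f"PF{j + 1}" for j in range(k)],
    )
    return FilterSet(eigenvalues=evals, vectors=vectors, retained=k, tree_id=tree_id)
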