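"""Weighted UniFrac on a rooted reference tree and Principal Coordinate
Analysis.

Abundance weights follow the chip's validated intensity-to-amplicon
relationship: the log2 of the (floored-at-1, so non-negative) hybridization
intensity of each present OTU, normalized within each sample to sum to 1.
The normalized weighted UniFrac between samples A and B is

    u = sum_b  l_b * |p_A(b) - p_B(b)|          over all branches b
    D = sum_leaf  depth(leaf) * (p_A(leaf) + p_B(leaf))
    distance = u / D in [0, 1]

where p(b) is the summed normalized weight of the leaves below branch b and
depth is the root-to-leaf path length.  PCoA is classical metric scaling:
Gower double-centering of -d^2/2, eigendecomposition, coordinates =
eigenvectors scaled by sqrt(eigenvalue), per-axis percent variation as the
share of the sum of positive eigenvalues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .community_matrix import CommunityMatrix


class OrdinationError(ValueError):
    pass


@dataclass
class LeafWeights:
    sample_id: str
    weights: dict[str, float]  # otu_id -> weight, absent leaves omitted or 0
    normalized: bool = False

    def normalize(self) -> "LeafWeights":
        total = sum(self.weights.values())
        if total <= 0:
            raise OrdinationError(
                f"sample {self.sample_id!r}: no positive leaf weights"
            )
        return LeafWeights(
            self.sample_id,
            {k: v / total for k, v in self.weights.items()},
            normalized=True,
        )


def leaf_weights(
    m: CommunityMatrix, column: str, normalize: bool = True
) -> LeafWeights:
    """Log2-intensity abundance weights of one sample column.

    Intensities were floored at 1 during preprocessing, so log2 is >= 0;
    absent OTUs (value 0 in the matrix) contribute weight 0.
    """
    if m.kind != "raw":
        raise OrdinationError("leaf weights use raw hybridization intensities")
    col = m.values[column]
    weights = {}
    for otu, v in col.items():
        if v > 0:
            if v < 1:
                raise OrdinationError(
                    f"intensity {v} < 1 for {otu!r}; preprocessing must floor at 1"
                )
            weights[otu] = math.log2(v)
    lw = LeafWeights(column, weights)
    return lw.normalize() if normalize else lw


def prune_zero_weight(tree: TreeNode, keep) -> TreeNode:
    """Drop leaves outside ``keep``, preserving every kept leaf's
    root-to-leaf depth (unary internal nodes are collapsed by summing branch
    lengths; the root is never collapsed).  Distances between samples whose
    weights live on the kept leaves are invariant under this pruning.
    """
    keep = set(keep)
    tree = tree.copy()
    while True:
        drop = [t for t in tree.tips() if t.name not in keep]
        if not drop:
            break
        for tip in drop:
            tip.parent.remove(tip)
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse(include_self=False)):
            if not node.is_tip() and len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                parent.remove(node)
                parent.append(child)
                changed = True
    return tree


def _subtree_weights(tree: TreeNode, w: dict[str, float]) -> None:
    """Attach summed normalized leaf weight below each node as ``_pw``."""
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._pw = w.get(node.name, 0.0)
        else:
            node._pw = sum(c._pw for c in node.children)


def weighted_unifrac(
    tree: TreeNode,
    wa: LeafWeights,
    wb: LeafWeights,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two samples' normalized leaf weights."""
    leaves = {t.name for t in tree.tips()}
    for lw in (wa, wb):
        if not lw.normalized:
            raise OrdinationError("leaf weights must be normalized")
        extra = set(lw.weights) - leaves
        extra = {k for k in extra if lw.weights[k] != 0}
        if extra:
            raise OrdinationError(
                f"sample {lw.sample_id!r}: weight on leaves not in the tree: "
                f"{sorted(extra)[:5]}"
            )
    _subtree_weights(tree, wa.weights)
    pa = {id(n): n._pw for n in tree.traverse(include_self=True)}
    _subtree_weights(tree, wb.weights)
    u = 0.0
    for node in tree.traverse(include_self=False):
        u += (node.length or 0.0) * abs(pa[id(node)] - node._pw)
    if not normalized:
        return u
    denom = 0.0
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        denom += depth * (wa.weights.get(tip.name, 0.0) + wb.weights.get(tip.name, 0.0))
    if denom == 0:
        return 0.0
    return u / denom


def unifrac_matrix(
    tree: TreeNode,
    samples: list[LeafWeights],
    normalized: bool = True,
) -> DistanceMatrix:
    if len(samples) < 2:
        raise OrdinationError("need at least 2 samples")
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = weighted_unifrac(
                tree, samples[i], samples[j], normalized=normalized
            )
    return DistanceMatrix(out, ids=[s.sample_id for s in samples])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes (P1, P2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variation: np.ndarray  # per retained axis, % of positive-eigenvalue sum

    def to_dict(self) -> dict:
        return {
            "axes": list(self.coordinates.columns),
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "pct_variation": [float(v) for v in self.pct_variation],
        }


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical (metric) PCoA by Gower double-centering.

    Axes with non-positive eigenvalues carry no coordinates; percent
    variation is relative to the sum of positive eigenvalues.  The sign of
    each axis is fixed by making its first nonzero coordinate positive.
    """
    n = len(d.ids)
    if n < 3:
        raise OrdinationError("PCoA needs at least 3 samples")
    if n_axes is not None and not 1 <= n_axes <= n - 1:
        raise OrdinationError(f"n_axes {n_axes} outside 1..{n - 1}")
    sq = d.data.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-12
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise OrdinationError("no positive eigenvalues; degenerate distances")
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for a in range(k):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    pct = evals[:k] / evals[:n_pos].sum() * 100.0
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"P{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals,
        pct_variation=pct,
    )


def write_pcoa(result: PcoaResult, tsv_path, json_path=None) -> None:
    result.coordinates.to_csv(tsv_path, sep="\t", index_label="sample")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
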