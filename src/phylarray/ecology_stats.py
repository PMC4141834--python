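"""Community-comparison statistics: Bray-Curtis distances, agglomerative
clustering, MRPP and indicator-species (INDVAL) analysis.

MRPP (multi-response permutation procedure) tests a-priori groups against a
distance matrix: the observed statistic is the group-size-weighted mean
within-group pairwise distance, delta = sum_g (n_g / N) * mean d(i,j | i,j in g),
its null distribution comes from permuting the sample -> group assignment,
the chance-corrected within-group agreement is A = 1 - delta_obs/delta_exp,
and p is the probability of a permuted delta at or below the observed one.
When the number of distinct label arrangements is small (<= 10,000) the
permutation distribution is enumerated exhaustively; otherwise Monte Carlo
with an add-one correction, p = (1 + #{delta_perm <= delta_obs}) / (1 + B).

INDVAL (Dufrene-Legendre indicator value) combines specificity
a(i,j) = mean abundance of OTU i in group j / sum over groups of the means,
and fidelity b(i,j) = fraction of group-j members where i is present;
INDVAL(i,j) = a * b * 100.  Each OTU's statistic is its maximum over groups,
tested by Monte Carlo label permutation.

Clustering is Lance-Williams agglomeration with either group-average (UPGMA)
or flexible-beta linkage (alpha = (1-beta)/2, gamma = 0, default beta =
-0.25); equal-distance merge candidates are broken toward the
lexicographically smallest cluster-index pair so results are deterministic.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community_matrix import CommunityMatrix

EXHAUSTIVE_LIMIT = 10_000


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupLabels:
    """Sample -> a-priori group assignment."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.group_names) < 2:
            raise StatsError("need at least 2 groups")

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.labels.values():
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def vector(self, ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise StatsError(f"samples without group label: {missing[:5]}")
        names = self.group_names
        return np.array([names.index(self.labels[i]) for i in ids])

    def sizes(self, ids: Sequence[str]) -> np.ndarray:
        vec = self.vector(ids)
        return np.bincount(vec, minlength=len(self.group_names))


def matrix_groups(m: CommunityMatrix) -> GroupLabels:
    """Group labels carried by a community matrix (condition per column)."""
    return GroupLabels({col: m.column_groups[col] for col in m.array_ids})


# ---------------------------------------------------------------------------
# distances


def bray_curtis(m: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    Guarded by the kind tag: only relativized or arcsine-transformed matrices
    may enter (raw intensities would let bright arrays dominate).
    """
    if m.kind not in ("relativized", "arcsine"):
        raise StatsError(
            f"Bray-Curtis requires a relativized or arcsine matrix, got {m.kind!r}"
        )
    cols = m.values.values.T
    if (cols.sum(axis=1) == 0).any():
        raise StatsError("all-zero sample column; Bray-Curtis undefined")
    condensed = pdist(cols, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=m.array_ids)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class Dendrogram:
    """Agglomeration history in scipy linkage convention.

    ``merges[k] = (i, j, height, size)`` joins clusters ``i`` and ``j``
    (leaves are 0..n-1, the k-th merge creates cluster ``n + k``).
    """

    ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    linkage: str
    beta: float | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_linkage(self) -> np.ndarray:
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    def leaf_order(self) -> list[str]:
        def leaves(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            i, j, _, _ = self.merges[node - self.n_leaves]
            return leaves(i) + leaves(j)

        root = self.n_leaves + len(self.merges) - 1
        return [self.ids[i] for i in leaves(root)]


def cluster(
    d: DistanceMatrix, linkage: str = "group_average", beta: float = -0.25
) -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    ``group_average`` is UPGMA (merge height = unweighted mean inter-cluster
    distance); ``flexible_beta`` uses the Lance-Williams update with
    alpha_i = alpha_j = (1 - beta)/2 and gamma = 0.
    """
    if linkage not in ("group_average", "flexible_beta"):
        raise StatsError(f"unknown linkage {linkage!r}")
    n = len(d.ids)
    if n < 2:
        raise StatsError("clustering needs at least 2 samples")
    # dist[(i, j)] with i < j over active cluster indices
    dist: dict[tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = float(d[a, b])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    nxt = n
    while len(active) > 1:
        # smallest distance; ties -> lexicographically smallest index pair
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        d_ij = h
        ni, nj = size[i], size[j]
        for k in active - {i, j}:
            dki = dist.pop((min(i, k), max(i, k)))
            dkj = dist.pop((min(j, k), max(j, k)))
            if linkage == "group_average":
                dnew = (ni * dki + nj * dkj) / (ni + nj)
            else:
                alpha = (1.0 - beta) / 2.0
                dnew = alpha * dki + alpha * dkj + beta * d_ij
            dist[(k, nxt)] = dnew
        del dist[(i, j)]
        active -= {i, j}
        active.add(nxt)
        size[nxt] = ni + nj
        merges.append((i, j, h, ni + nj))
        nxt += 1
    return Dendrogram(
        tuple(d.ids),
        tuple(merges),
        linkage,
        beta if linkage == "flexible_beta" else None,
    )


def cut_dendrogram(dend: Dendrogram, level: int) -> dict[str, int]:
    """Group assignment at a hierarchical cluster level.

    Level ``k`` removes the top ``k - 1`` merges, leaving ``k`` clusters
    (level 1 = everything together, level n = every sample alone).  Clusters
    are numbered 1..k in order of their first leaf.
    """
    n = dend.n_leaves
    if not 1 <= level <= n:
        raise StatsError(f"cluster level {level} outside 1..{n}")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j, _, _) in enumerate(dend.merges[: n - level]):
        parent[find(i)] = n + k
        parent[find(j)] = n + k
    roots: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        out[dend.ids[leaf]] = roots[r]
    return out


# ---------------------------------------------------------------------------
# MRPP


@dataclass
class MrppResult:
    delta_observed: float
    delta_expected: float
    A: float
    p: float
    n_permutations: int
    seed: int | None
    method: str  # "exhaustive" | "monte_carlo"
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "delta_observed": self.delta_observed,
            "delta_expected": self.delta_expected,
            "A": self.A,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
            "group_sizes": self.group_sizes,
        }


def _delta(square: np.ndarray, vec: np.ndarray, n_groups: int) -> float:
    n = len(vec)
    delta = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(vec == g)
        ng = len(idx)
        sub = square[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(ng, k=1)].mean()
        delta += (ng / n) * mean_within
    return float(delta)


def _distinct_assignments(sizes: Sequence[int]) -> Iterator[np.ndarray]:
    """All distinct assignments of n items into labeled groups of given sizes."""
    n = sum(sizes)

    def rec(remaining: tuple[int, ...], g: int, out: np.ndarray):
        if g == len(sizes) - 1:
            out[list(remaining)] = g
            yield out
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            out[list(combo)] = g
            rest = tuple(x for x in remaining if x not in set(combo))
            yield from rec(rest, g + 1, out)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def n_arrangements(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def mrpp(
    d: DistanceMatrix,
    groups: GroupLabels,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "auto",
) -> MrppResult:
    """Multi-response permutation procedure on a distance matrix.

    Group weights are C_g = n_g / N.  ``method='auto'`` enumerates the
    permutation distribution exhaustively when the number of distinct label
    arrangements is at most 10,000, and falls back to Monte Carlo otherwise;
    the same permutation stream feeds both delta_expected and p.
    """
    ids = list(d.ids)
    vec = groups.vector(ids)
    sizes = np.bincount(vec)
    if (sizes < 2).any():
        raise StatsError("every group needs at least 2 samples for MRPP")
    square = d.data
    n_groups = len(sizes)
    delta_obs = _delta(square, vec, n_groups)

    if method == "auto":
        method = (
            "exhaustive"
            if n_arrangements(sizes) <= EXHAUSTIVE_LIMIT
            else "monte_carlo"
        )
    if method == "exhaustive":
        deltas = np.array(
            [_delta(square, v, n_groups) for v in _distinct_assignments(sizes)]
        )
        p = float((deltas <= delta_obs + 1e-12).mean())
        n_used = len(deltas)
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        deltas = np.array(
            [
                _delta(square, rng.permutation(vec), n_groups)
                for _ in range(n_permutations)
            ]
        )
        p = float((1 + (deltas <= delta_obs + 1e-12).sum()) / (1 + n_permutations))
        n_used = n_permutations
    else:
        raise StatsError(f"unknown MRPP method {method!r}")
    delta_exp = float(deltas.mean())
    A = 1.0 - delta_obs / delta_exp if delta_exp > 0 else 1.0
    names = groups.group_names
    return MrppResult(
        delta_observed=delta_obs,
        delta_expected=delta_exp,
        A=A,
        p=p,
        n_permutations=n_used,
        seed=seed,
        method=method,
        group_sizes={names[g]: int(sizes[g]) for g in range(n_groups)},
    )


# ---------------------------------------------------------------------------
# INDVAL


@dataclass
class IndvalTable:
    """Per-OTU indicator values, best group and permutation p."""

    table: pd.DataFrame  # index otu_id; columns: indval_<g>..., best_group, indval, p
    a_spec: pd.DataFrame  # otu x group specificity
    b_fid: pd.DataFrame  # otu x group fidelity
    n_permutations: int
    seed: int | None
    zero_abundance_otus: tuple[str, ...] = ()

    def top(self, min_indval: float = 0.0, max_p: float = 1.0) -> pd.DataFrame:
        t = self.table
        return t[(t["indval"] >= min_indval) & (t["p"] <= max_p)]

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "zero_abundance_otus": list(self.zero_abundance_otus),
            "otus": {
                otu: {
                    "best_group": row["best_group"],
                    "indval": row["indval"],
                    "p": row["p"],
                }
                for otu, row in self.table.iterrows()
            },
        }


def _indval_components(
    X: np.ndarray, P: np.ndarray, vec: np.ndarray, n_groups: int
):
    """Specificity a, fidelity b and indval (otu x group) for one labeling."""
    means = np.empty((X.shape[0], n_groups))
    fid = np.empty((X.shape[0], n_groups))
    for g in range(n_groups):
        idx = vec == g
        means[:, g] = X[:, idx].mean(axis=1)
        fid[:, g] = P[:, idx].mean(axis=1)
    total = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / np.where(total > 0, total, 1.0), 0.0)
    return a, fid, a * fid * 100.0


def indval(
    m: CommunityMatrix,
    groups: GroupLabels,
    presence: pd.DataFrame | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> IndvalTable:
    """Indicator-species analysis of a community matrix.

    Abundance comes from the (typically relativized) matrix; presence for the
    fidelity term defaults to the matrix's own presence pattern but should be
    the calling module's presence table when available.  Significance of each
    OTU's maximum indicator value is assessed by Monte Carlo permutation of
    the sample -> group assignment (add-one corrected).
    """
    if m.kind == "row_z":
        raise StatsError("indval needs a non-negative abundance matrix")
    ids = m.array_ids
    vec = groups.vector(ids)
    n_groups = len(groups.group_names)
    if n_groups < 2:
        raise StatsError("indval needs at least 2 groups")
    X = m.values.values.astype(float)
    if presence is None:
        P = (X > 0).astype(float)
    else:
        P = presence.reindex(index=m.otu_ids, columns=ids).fillna(False).values
        P = P.astype(float)
    a, b, iv = _indval_components(X, P, vec, n_groups)
    obs = iv.max(axis=1)
    best = iv.argmax(axis=1)
    zero_total = X.sum(axis=1) == 0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs))
    for _ in range(n_permutations):
        perm = rng.permutation(vec)
        _, _, iv_p = _indval_components(X, P, perm, n_groups)
        exceed += iv_p.max(axis=1) >= obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)

    names = groups.group_names
    table = pd.DataFrame(
        {
            **{f"indval_{names[g]}": iv[:, g] for g in range(n_groups)},
            "best_group": [names[g] for g in best],
            "indval": obs,
            "p": p,
            "zero_abundance": zero_total,
        },
        index=pd.Index(m.otu_ids, name="otu_id"),
    )
    table.loc[zero_total, "indval"] = 0.0
    table = table.sort_values(["indval", "otu_id"], ascending=[False, True])
    return IndvalTable(
        table=table,
        a_spec=pd.DataFrame(a, index=m.otu_ids, columns=names),
        b_fid=pd.DataFrame(b, index=m.otu_ids, columns=names),
        n_permutations=n_permutations,
        seed=seed,
        zero_abundance_otus=tuple(np.asarray(m.otu_ids)[zero_total]),
    )


# ---------------------------------------------------------------------------
# serialization


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.data, index=d.ids, columns=d.ids).to_csv(
        path, sep="\t", index_label="id"
    )


def write_mrpp(result: MrppResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_indval(table: IndvalTable, tsv_path, json_path=None) -> None:
    table.table.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(table.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_dendrogram(dend: Dendrogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "ids": list(dend.ids),
                "merges": [list(m) for m in dend.merges],
                "linkage": dend.linkage,
                "beta": dend.beta,
                "leaf_order": dend.leaf_order(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
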