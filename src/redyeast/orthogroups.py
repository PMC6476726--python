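"""Presence/absence analytics over orthogroup membership.

A genomes x orthogroups binary matrix drives Jaccard distances,
agglomerative clustering of the genomes, core/unique Venn partitioning and
single-copy orthologue extraction; topology agreement between the
resulting dendrogram and an independently estimated species tree is
measured with the unrooted Robinson-Foulds distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from .errors import UsageError
from .io_formats import OrthoGroup, parse_newick

__all__ = [
    "ClusterParams",
    "presence_matrix",
    "jaccard_distances",
    "cluster_genomes",
    "venn_partition",
    "single_copy_groups",
    "rf_distance",
]


@dataclass(frozen=True)
class ClusterParams:
    """linkage: average (UPGMA-like, default), complete or single."""

    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "complete", "single"):
            raise UsageError("linkage must be one of average, complete, single")


def presence_matrix(groups: Sequence[OrthoGroup], genomes: Sequence[str]) -> pd.DataFrame:
    """Genomes x groups 0/1 matrix; cell 1 iff the genome has >= 1 member.

    Genomes absent from every group yield an all-zero row and a warning.
    """
    mat = pd.DataFrame(
        0, index=list(genomes), columns=[g.group_id for g in groups], dtype=np.int8
    )
    for g in groups:
        for sp in g.members:
            if sp in mat.index:
                mat.loc[sp, g.group_id] = 1
    empty = mat.index[mat.sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(f"genomes with no orthogroup members: {empty}", stacklevel=2)
    return mat


def jaccard_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between the genome presence sets.

    d(X, Y) = 1 − |X ∩ Y| / |X ∪ Y|; defined as 0 when both sets are
    empty.
    """
    M = matrix.to_numpy(dtype=np.int64)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def cluster_genomes(dist: pd.DataFrame, params: ClusterParams | None = None) -> str:
    """Agglomerative clustering of the genomes; returns a newick string
    with ultrametric node heights (merge distance / 2).

    Ties in the merge queue are broken toward the pair whose
    lexicographically smallest member label is smallest, making the result
    independent of input order.
    """
    params = params or ClusterParams()
    labels = list(dist.index)
    if len(labels) < 2:
        raise UsageError("need at least two genomes to cluster")
    # cluster id -> (member labels, newick fragment, height)
    active: dict[int, tuple[tuple[str, ...], str, float]] = {
        i: ((lab,), lab, 0.0) for i, lab in enumerate(labels)
    }
    d: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(labels)), 2):
        d[(i, j)] = float(dist.iloc[i, j])
    sizes = {i: 1 for i in active}
    next_id = len(labels)
    while len(active) > 1:
        def tie_key(pair):
            i, j = pair
            return (
                d[pair],
                min(min(active[i][0]), min(active[j][0])),
                min(active[i][0] + active[j][0]),
            )
        i, j = min(d, key=tie_key)
        height = d[(i, j)] / 2.0
        mi, ni, hi = active[i]
        mj, nj, hj = active[j]
        # put the lexicographically smaller subtree first
        if min(mj) < min(mi):
            (mi, ni, hi), (mj, nj, hj) = (mj, nj, hj), (mi, ni, hi)
        newick = f"({ni}:{height - hi:.10g},{nj}:{height - hj:.10g})"
        merged = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            if params.linkage == "average":
                val = (a * sizes[i] + b * sizes[j]) / (sizes[i] + sizes[j])
            elif params.linkage == "complete":
                val = max(a, b)
            else:
                val = min(a, b)
            d[(min(merged, k), max(merged, k))] = val
        d.pop((i, j))
        active[merged] = (tuple(sorted(mi + mj)), newick, height)
        sizes[merged] = sizes[i] + sizes[j]
        del active[i], active[j], sizes[i], sizes[j]
    (_, newick, _), = active.values()
    return newick + ";"


def venn_partition(matrix: pd.DataFrame) -> dict[frozenset, int]:
    """Count groups per exact genome subset.

    The counts over all non-empty subsets partition the group set; the
    all-genomes subset holds the core orthologues and singleton subsets the
    genome-unique ones.
    """
    counts: dict[frozenset, int] = {}
    arr = matrix.to_numpy()
    genomes = np.array(matrix.index)
    for col in range(arr.shape[1]):
        subset = frozenset(genomes[arr[:, col] > 0])
        if not subset:
            raise UsageError("presence matrix contains an all-zero column")
        counts[subset] = counts.get(subset, 0) + 1
    return counts


def single_copy_groups(groups: Iterable[OrthoGroup], genomes: Sequence[str]) -> list[OrthoGroup]:
    """Groups with exactly one member in every listed genome."""
    wanted = set(genomes)
    out = []
    for g in groups:
        if set(g.members) >= wanted and all(len(g.members[sp]) == 1 for sp in wanted):
            out.append(g)
    return out


def rf_distance(tree1: Union[str, dendropy.Tree], tree2: Union[str, dendropy.Tree]) -> int:
    """Unrooted Robinson-Foulds distance (bipartitions in exactly one
    tree); 0 iff the topologies agree.  Leaf sets must match."""
    tns = dendropy.TaxonNamespace()

    def load(t):
        if isinstance(t, dendropy.Tree):
            t = t.as_string(schema="newick")
        return dendropy.Tree.get(data=t, schema="newick", taxon_namespace=tns)

    t1, t2 = load(tree1), load(tree2)
    leaves1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise UsageError(f"leaf sets differ: {sorted(leaves1 ^ leaves2)}")
    for t in (t1, t2):
        t.is_rooted = False
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))
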