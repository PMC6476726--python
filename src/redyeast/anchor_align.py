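"""Exact-match anchors, anchor clustering and cluster-level filters.

This is a from-scratch reconstruction of a minimal reference-guided
aligner: maximal exact matches (MEMs) of at least ``min_match`` bp are
found on both strands, chained into clusters with the classic
maxgap/mincluster rules, scored for identity by a global alignment of the
clustered spans, and filtered on a minimum aligned span and a strict
identity threshold.

Anchor seeding uses fixed-length k-mer matching (k = ``min_match``)
extended outwards to maximality; with the default k of 20 the chance of a
spurious seed between unrelated sequences at these genome sizes is
negligible.  ``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib
import numpy as np

from . import _kmers

from .errors import InternalError, UsageError
from .io_formats import SeqRecord, revcomp

__all__ = [
    "AnchorMatch",
    "AlignParams",
    "AlignmentCluster",
    "find_anchors",
    "cluster_anchors",
    "score_cluster",
    "filter_clusters",
    "align_assemblies",
]


@dataclass(frozen=True)
class AnchorMatch:
    """A maximal exact match between a query and a reference scaffold.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; a ``-`` anchor matches the reverse complement of the query
    interval against the reference interval.
    """

    query_id: str
    ref_id: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class AlignParams:
    """Anchor-chaining and cluster-filter parameters.

    min_match   anchor seed length (bp)
    maxgap      largest allowed coordinate gap between chained anchors (bp)
    mincluster  minimum summed anchor length for a cluster to survive (bp)
    min_align_len  minimum aligned query span for a cluster to pass the
                   final filter (bp)
    min_identity   identity threshold; the filter keeps clusters with
                   identity strictly greater than this
    """

    min_match: int = 20
    maxgap: int = 500
    mincluster: int = 100
    min_align_len: int = 1500
    min_identity: float = 0.97

    def __post_init__(self) -> None:
        if min(self.min_match, self.maxgap, self.mincluster, self.min_align_len) <= 0:
            raise UsageError("alignment parameters must be positive")
        if not 0.0 < self.min_identity <= 1.0:
            raise UsageError("min_identity must lie in (0, 1]")


@dataclass(frozen=True)
class AlignmentCluster:
    """A chained set of co-diagonal anchors with one orientation."""

    query_id: str
    ref_id: str
    strand: str
    anchors: tuple[AnchorMatch, ...]
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    anchor_length_sum: int
    identity: float | None = None

    @property
    def aligned_length(self) -> int:
        return self.q_end - self.q_start


# ---------------------------------------------------------------------------
# anchor discovery


class _RefIndex:
    """Sorted k-mer code index over one reference sequence."""

    def __init__(self, ref: SeqRecord, k: int):
        self.ref = ref
        self.k = k
        codes, valid = _kmers.kmer_codes(_kmers.encode(ref.sequence), k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup(self, qcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        left = np.searchsorted(self.codes, qcodes, side="left")
        right = np.searchsorted(self.codes, qcodes, side="right")
        return left, right


def _extend_maximal(q: str, r: str, qi: int, ri: int, k: int) -> tuple[int, int, int]:
    """Extend an exact seed at (qi, ri) to a maximal match.

    Returns (q_start, q_end, r_start_offset) with r_start = ri - (qi - q_start).
    N breaks a match unconditionally.
    """
    s = 0
    while qi - s - 1 >= 0 and ri - s - 1 >= 0:
        a, b = q[qi - s - 1], r[ri - s - 1]
        if a != b or a == "N":
            break
        s += 1
    e = k
    nq, nr = len(q), len(r)
    while qi + e < nq and ri + e < nr:
        a, b = q[qi + e], r[ri + e]
        if a != b or a == "N":
            break
        e += 1
    return qi - s, qi + e, ri - s


def _anchors_one_strand(qseq: str, index: _RefIndex) -> list[tuple[int, int, int]]:
    """Maximal exact matches of qseq (forward) vs the indexed reference.

    Returns (q_start, q_end, r_start) triples in the coordinates of qseq.
    """
    k = index.k
    qcodes, qvalid = _kmers.kmer_codes(_kmers.encode(qseq), k)
    if qcodes.size == 0:
        return []
    left, right = index.lookup(qcodes)
    hits = np.nonzero(qvalid & (right > left))[0]
    rseq = index.ref.sequence
    covered: dict[int, int] = {}  # diagonal -> q_end of last maximal match
    out: list[tuple[int, int, int]] = []
    for qi in hits:
        qi = int(qi)
        for idx in range(left[qi], right[qi]):
            ri = int(index.pos[idx])
            diag = ri - qi
            if covered.get(diag, -1) > qi:
                continue
            qs, qe, rs = _extend_maximal(qseq, rseq, qi, ri, k)
            covered[diag] = qe
            out.append((qs, qe, rs))
    return out


def find_anchors(query: SeqRecord, ref: SeqRecord, min_match: int = 20) -> list[AnchorMatch]:
    """All maximal exact matches of length >= min_match on both strands.

    Maximality is with respect to single-base extension; matches containing
    N do not exist because N matches nothing.
    """
    if len(query) == 0 or len(ref) == 0:
        raise UsageError("sequences must be non-empty")
    index = _RefIndex(ref, min_match)
    return _find_anchors_indexed(query, index)


def _find_anchors_indexed(query: SeqRecord, index: _RefIndex) -> list[AnchorMatch]:
    anchors: list[AnchorMatch] = []
    ref = index.ref
    for qs, qe, rs in _anchors_one_strand(query.sequence, index):
        anchors.append(
            AnchorMatch(query.id, ref.id, qs, qe, rs, rs + (qe - qs), "+")
        )
    rc = revcomp(query.sequence)
    n = len(query)
    for qs, qe, rs in _anchors_one_strand(rc, index):
        anchors.append(
            AnchorMatch(query.id, ref.id, n - qe, n - qs, rs, rs + (qe - qs), "-")
        )
    anchors.sort(key=lambda a: (a.q_start, a.r_start, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# clustering


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _chainable(a: AnchorMatch, b: AnchorMatch, maxgap: int) -> bool:
    """a precedes b in query order; same strand assumed.

    For ``+`` anchors the conserved quantity is the diagonal r_start −
    q_start; for ``-`` anchors it is the anti-diagonal q_start + r_end
    (constant along a reverse-strand co-linear run).
    """
    gap_q = b.q_start - a.q_end
    if gap_q > maxgap:
        return False
    if a.strand == "+":
        gap_r = b.r_start - a.r_end
        diag_a, diag_b = a.r_start - a.q_start, b.r_start - b.q_start
    else:
        gap_r = a.r_start - b.r_end
        diag_a, diag_b = a.q_start + a.r_end, b.q_start + b.r_end
    return gap_r <= maxgap and abs(diag_a - diag_b) <= maxgap


def cluster_anchors(anchors: Sequence[AnchorMatch], params: AlignParams) -> list[AlignmentCluster]:
    """Single-linkage chaining of anchors into clusters, per strand.

    Two anchors fall in one cluster iff (transitively) their query gap,
    reference gap and diagonal offset difference are all <= maxgap.
    Clusters whose summed anchor length is below mincluster are discarded.
    The chaining is a closure, so the result does not depend on input
    order.
    """
    if not anchors:
        return []
    qids = {a.query_id for a in anchors}
    rids = {a.ref_id for a in anchors}
    if len(qids) > 1 or len(rids) > 1:
        raise UsageError("cluster_anchors expects anchors from a single (query, ref) pair")
    out: list[AlignmentCluster] = []
    for strand in "+-":
        group = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (a.q_start, a.q_end, a.r_start),
        )
        if not group:
            continue
        maxlen = max(a.length for a in group)
        uf = _UnionFind(len(group))
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.q_start - a.q_start > params.maxgap + maxlen:
                    break
                if _chainable(a, b, params.maxgap):
                    uf.union(i, j)
        buckets: dict[int, list[AnchorMatch]] = {}
        for i, a in enumerate(group):
            buckets.setdefault(uf.find(i), []).append(a)
        for members in buckets.values():
            total = sum(m.length for m in members)
            if total < params.mincluster:
                continue
            members.sort(key=lambda a: (a.q_start, a.r_start))
            out.append(
                AlignmentCluster(
                    query_id=members[0].query_id,
                    ref_id=members[0].ref_id,
                    strand=strand,
                    anchors=tuple(members),
                    q_start=min(m.q_start for m in members),
                    q_end=max(m.q_end for m in members),
                    r_start=min(m.r_start for m in members),
                    r_end=max(m.r_end for m in members),
                    anchor_length_sum=total,
                )
            )
    out.sort(key=lambda c: (c.q_start, c.r_start, c.strand))
    return out


# ---------------------------------------------------------------------------
# scoring and filtering


def _global_identity(a: str, b: str) -> float:
    """Matching columns over alignment columns of a minimum-edit global
    alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches / columns if columns else 0.0


def score_cluster(cluster: AlignmentCluster, query: SeqRecord, ref: SeqRecord) -> AlignmentCluster:
    """Attach an identity estimate to a cluster.

    The clustered query span is globally aligned (minimum edit distance)
    against the clustered reference span — reverse-complemented first for
    ``-`` clusters — and identity is matching columns / alignment columns.
    """
    if cluster.q_end > len(query) or cluster.r_end > len(ref):
        raise InternalError("cluster span exceeds sequence bounds")
    qspan = query.sequence[cluster.q_start : cluster.q_end]
    rspan = ref.sequence[cluster.r_start : cluster.r_end]
    if cluster.strand == "-":
        qspan = revcomp(qspan)
    return replace(cluster, identity=_global_identity(qspan, rspan))


def filter_clusters(clusters: Iterable[AlignmentCluster], params: AlignParams) -> list[AlignmentCluster]:
    """Keep clusters with aligned span >= min_align_len and identity
    strictly greater than min_identity."""
    kept = []
    for c in clusters:
        if c.identity is None:
            raise UsageError("clusters must be scored before filtering")
        if c.aligned_length >= params.min_align_len and c.identity > params.min_identity:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# whole-assembly driver


def align_assemblies(
    queries: Sequence[SeqRecord],
    refs: Sequence[SeqRecord],
    params: AlignParams | None = None,
) -> list[AlignmentCluster]:
    """Anchor, chain, score and filter every query against every reference.

    Returns the surviving clusters for all (query, reference) pairs.
    """
    params = params or AlignParams()
    indexes = [_RefIndex(r, params.min_match) for r in refs]
    survivors: list[AlignmentCluster] = []
    for q in queries:
        for idx in indexes:
            anchors = _find_anchors_indexed(q, idx)
            if not anchors:
                continue
            clusters = cluster_anchors(anchors, params)
            scored = [score_cluster(c, q, idx.ref) for c in clusters]
            survivors.extend(filter_clusters(scored, params))
    return survivors
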