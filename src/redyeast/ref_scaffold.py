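"""Reference-guided scaffolding: placement, ordering, joining and assembly
statistics.

Each query scaffold is assigned to the reference scaffold carrying the most
supporting aligned sequence, oriented by the majority strand of that
support, ordered along the reference and joined into one superscaffold per
occupied reference scaffold with runs of N marking the joins.  A minimum
scaffold length filter and the usual assembly summary statistics (count,
total length, N50, largest) round the module off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .anchor_align import AlignParams, AlignmentCluster, align_assemblies
from .errors import InternalError, UsageError
from .io_formats import SeqRecord, revcomp

__all__ = [
    "Placement",
    "ScaffoldParams",
    "SuperScaffold",
    "AssemblyStats",
    "place_scaffolds",
    "order_and_join",
    "filter_min_length",
    "assembly_stats",
    "scaffold_assembly",
]


@dataclass(frozen=True)
class Placement:
    """Assignment of one query scaffold to a reference scaffold."""

    query_id: str
    ref_id: str
    ref_anchor_pos: int  # min reference start among supporting clusters
    orientation: str
    placed_length: int  # full query length
    support: int  # summed aligned_length of supporting clusters


@dataclass(frozen=True)
class ScaffoldParams:
    """Joining and filtering parameters.

    min_gap           smallest N run inserted between consecutive placements
    fixed_gap         when set, every joint uses exactly this many Ns instead
                      of the reference-distance estimate
    append_unplaced   emit queries without a surviving alignment as extra
                      records (off by default)
    min_scaffold_len  length threshold of the final assembly filter
    """

    min_gap: int = 100
    fixed_gap: int | None = None
    append_unplaced: bool = False
    min_scaffold_len: int = 2000

    def __post_init__(self) -> None:
        if self.min_gap < 1:
            raise UsageError("min_gap must be >= 1")


@dataclass
class SuperScaffold:
    """One joined output scaffold per occupied reference scaffold."""

    object_id: str
    ref_id: str
    placements: list[Placement]
    gaps: list[int]
    sequence: str


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_length: int
    n50: int
    largest: int


# ---------------------------------------------------------------------------


def place_scaffolds(
    clusters: Sequence[AlignmentCluster],
    query_lengths: Mapping[str, int],
) -> tuple[list[Placement], list[str]]:
    """Assign each query with surviving clusters to one reference scaffold.

    The reference maximizing total supporting aligned length wins; the
    orientation is the strand holding the majority of that support; the
    anchor position is the smallest reference start among the supporting
    clusters.  Queries without any surviving cluster are returned unplaced.
    """
    by_query: dict[str, list[AlignmentCluster]] = {}
    for c in clusters:
        by_query.setdefault(c.query_id, []).append(c)
    placements: list[Placement] = []
    for qid, qclusters in by_query.items():
        support_by_ref: dict[str, int] = {}
        for c in qclusters:
            support_by_ref[c.ref_id] = support_by_ref.get(c.ref_id, 0) + c.aligned_length
        # deterministic: largest support, then lexicographic ref id
        ref_id = min(support_by_ref, key=lambda r: (-support_by_ref[r], r))
        chosen = [c for c in qclusters if c.ref_id == ref_id]
        minus = sum(c.aligned_length for c in chosen if c.strand == "-")
        plus = sum(c.aligned_length for c in chosen if c.strand == "+")
        placements.append(
            Placement(
                query_id=qid,
                ref_id=ref_id,
                ref_anchor_pos=min(c.r_start for c in chosen),
                orientation="-" if minus > plus else "+",
                placed_length=query_lengths[qid],
                support=plus + minus,
            )
        )
    unplaced = sorted(set(query_lengths) - set(by_query))
    placements.sort(key=lambda p: (p.ref_id, p.ref_anchor_pos, -p.support, p.query_id))
    return placements, unplaced


def order_and_join(
    placements: Sequence[Placement],
    query_seqs: Mapping[str, str],
    ref_ids: Sequence[str],
    params: ScaffoldParams | None = None,
) -> list[SuperScaffold]:
    """Order placements along each reference scaffold and join them with N
    runs.

    The gap between consecutive placements is the estimated reference
    distance ``next.ref_anchor_pos − (cur.ref_anchor_pos + cur.placed_length)``
    floored at ``min_gap`` (or a fixed size when configured).  Reverse
    placements are reverse-complemented.  One output record per reference
    scaffold that received at least one placement, in the order of
    ``ref_ids``.
    """
    params = params or ScaffoldParams()
    seen: set[str] = set()
    for p in placements:
        if p.query_id in seen:
            raise InternalError(f"query '{p.query_id}' placed more than once")
        seen.add(p.query_id)
    by_ref: dict[str, list[Placement]] = {}
    for p in placements:
        by_ref.setdefault(p.ref_id, []).append(p)
    out: list[SuperScaffold] = []
    for rid in ref_ids:
        if rid not in by_ref:
            continue
        ordered = sorted(by_ref[rid], key=lambda p: (p.ref_anchor_pos, -p.support, p.query_id))
        gaps: list[int] = []
        parts: list[str] = []
        for i, p in enumerate(ordered):
            if i > 0:
                prev = ordered[i - 1]
                est = p.ref_anchor_pos - (prev.ref_anchor_pos + prev.placed_length)
                gap = params.fixed_gap if params.fixed_gap is not None else max(est, params.min_gap)
                gaps.append(gap)
                parts.append("N" * gap)
            seq = query_seqs[p.query_id]
            parts.append(revcomp(seq) if p.orientation == "-" else seq)
        out.append(
            SuperScaffold(
                object_id=f"{rid}_scaffolded",
                ref_id=rid,
                placements=list(ordered),
                gaps=gaps,
                sequence="".join(parts),
            )
        )
    return out


def filter_min_length(assembly: Iterable[SeqRecord], min_scaffold_len: int = 2000) -> list[SeqRecord]:
    """Drop scaffolds shorter than ``min_scaffold_len`` (kept at exactly the
    threshold); input order preserved."""
    kept = [r for r in assembly if len(r) >= min_scaffold_len]
    if not kept:
        warnings.warn("length filter removed every scaffold", stacklevel=2)
    return kept


def assembly_stats(assembly: Sequence[SeqRecord]) -> AssemblyStats:
    """Scaffold count, total length, N50 and largest scaffold.

    N50 is the length of the first scaffold, taken in descending length
    order, at which the running total reaches half the assembly length.
    """
    lengths = sorted((len(r) for r in assembly), reverse=True)
    if not lengths:
        return AssemblyStats(0, 0, 0, 0)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return AssemblyStats(len(lengths), total, n50, lengths[0])


# ---------------------------------------------------------------------------


def scaffold_assembly(
    queries: Sequence[SeqRecord],
    refs: Sequence[SeqRecord],
    align_params: AlignParams | None = None,
    scaffold_params: ScaffoldParams | None = None,
) -> tuple[list[SuperScaffold], list[Placement], list[str]]:
    """Full reference-guided pipeline: align, place, order and join.

    Returns (superscaffolds, placements, unplaced query ids).  Unplaced
    queries are appended as extra superscaffold-less records only when
    ``append_unplaced`` is set, in which case they appear as single-record
    SuperScaffolds with their own id.
    """
    align_params = align_params or AlignParams()
    scaffold_params = scaffold_params or ScaffoldParams()
    clusters = align_assemblies(queries, refs, align_params)
    placements, unplaced = place_scaffolds(clusters, {q.id: len(q) for q in queries})
    seqs = {q.id: q.sequence for q in queries}
    supers = order_and_join(placements, seqs, [r.id for r in refs], scaffold_params)
    if scaffold_params.append_unplaced:
        for qid in unplaced:
            supers.append(
                SuperScaffold(
                    object_id=qid,
                    ref_id="",
                    placements=[Placement(qid, "", 0, "+", len(seqs[qid]), 0)],
                    gaps=[],
                    sequence=seqs[qid],
                )
            )
    return supers, placements, unplaced
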