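"""Collinear synteny-block detection from orthologous gene anchors.

Anchors are (gene, gene) orthologue pairs with ordinal positions along
their scaffolds.  Within one scaffold pair the chainer repeatedly extracts
the maximum-cardinality strictly monotone chain (co-monotone for ``+``
blocks, anti-monotone for ``-``) subject to an ordinal gap bound on both
genomes, keeping chains of at least ``min_block_genes`` anchors.  Blocks
are therefore mutually disjoint in anchors and the result is invariant to
input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import UsageError

__all__ = [
    "AnchorPair",
    "SyntenyParams",
    "SyntenyBlock",
    "chain_anchors",
    "find_blocks",
    "summarize_synteny",
]


@dataclass(frozen=True)
class AnchorPair:
    """One orthologous gene pair anchoring two scaffolds."""

    gene_a: str
    gene_b: str
    scaffold_a: str
    scaffold_b: str
    ordinal_a: int
    ordinal_b: int


@dataclass(frozen=True)
class SyntenyParams:
    """min_block_genes: smallest reported block (the classic five-gene
    cut-off); max_gene_gap: largest number of skipped ordinals between
    consecutive block members, on either genome (None = unbounded)."""

    min_block_genes: int = 5
    max_gene_gap: int | None = 25

    def __post_init__(self) -> None:
        if self.min_block_genes < 2:
            raise UsageError("min_block_genes must be >= 2")


@dataclass(frozen=True)
class SyntenyBlock:
    scaffold_a: str
    scaffold_b: str
    orientation: str
    members: tuple[AnchorPair, ...]

    @property
    def score(self) -> int:
        return len(self.members)


def _gap_ok(d: int, max_gap: int | None) -> bool:
    # d is the ordinal difference between consecutive members (>= 1);
    # d - 1 genes were skipped.
    return max_gap is None or d - 1 <= max_gap


def _best_chain(anchors: list[AnchorPair], sign: int, max_gap: int | None) -> list[int]:
    """Maximum-cardinality strictly monotone chain (sign=+1 co-monotone,
    -1 anti-monotone) with the gap bound on both ordinals.

    Returns member indices into ``anchors``.  Ties are broken toward the
    chain with the smaller starting ordinal_a, then deterministically by
    anchor sort order.
    """
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].ordinal_a, sign * anchors[i].ordinal_b),
    )
    n = len(order)
    # dp value: (length, -start_a) maximized; predecessor recorded
    length = [1] * n
    start_a = [anchors[order[i]].ordinal_a for i in range(n)]
    pred = [-1] * n
    for i in range(n):
        ai = anchors[order[i]]
        for j in range(i):
            aj = anchors[order[j]]
            da = ai.ordinal_a - aj.ordinal_a
            db = sign * (ai.ordinal_b - aj.ordinal_b)
            if da <= 0 or db <= 0:
                continue
            if not (_gap_ok(da, max_gap) and _gap_ok(db, max_gap)):
                continue
            cand = (length[j] + 1, -start_a[j])
            if cand > (length[i], -start_a[i]) or (
                cand == (length[i], -start_a[i]) and pred[i] == -1
            ):
                length[i], start_a[i], pred[i] = length[j] + 1, start_a[j], j
    best = max(range(n), key=lambda i: (length[i], -start_a[i], -anchors[order[i]].ordinal_a))
    chain = []
    i = best
    while i != -1:
        chain.append(order[i])
        i = pred[i]
    chain.reverse()
    return chain


def chain_anchors(pairs: Sequence[AnchorPair], params: SyntenyParams | None = None) -> list[SyntenyBlock]:
    """Extract disjoint synteny blocks from the anchors of one scaffold
    pair.

    The best chain over the remaining anchors (either orientation) is
    extracted repeatedly until no chain reaches ``min_block_genes``.
    Orientation ties go to the chain with the smaller starting ordinal_a,
    then to ``+``.
    """
    params = params or SyntenyParams()
    if not pairs:
        return []
    sa = {p.scaffold_a for p in pairs}
    sb = {p.scaffold_b for p in pairs}
    if len(sa) > 1 or len(sb) > 1:
        raise UsageError("chain_anchors expects anchors from a single scaffold pair")
    remaining = sorted(pairs, key=lambda p: (p.ordinal_a, p.ordinal_b, p.gene_a, p.gene_b))
    blocks: list[SyntenyBlock] = []
    while remaining:
        fwd = _best_chain(remaining, +1, params.max_gene_gap)
        rev = _best_chain(remaining, -1, params.max_gene_gap)
        key_f = (len(fwd), -remaining[fwd[0]].ordinal_a, 1)
        key_r = (len(rev), -remaining[rev[0]].ordinal_a, 0)
        chain, sign = (fwd, "+") if key_f >= key_r else (rev, "-")
        if len(chain) < params.min_block_genes:
            break
        members = tuple(remaining[i] for i in chain)
        blocks.append(
            SyntenyBlock(
                scaffold_a=members[0].scaffold_a,
                scaffold_b=members[0].scaffold_b,
                orientation=sign,
                members=members,
            )
        )
        picked = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in picked]
    blocks.sort(key=lambda b: b.members[0].ordinal_a)
    return blocks


def find_blocks(
    gene_map_a: pd.DataFrame,
    gene_map_b: pd.DataFrame,
    ortholog_pairs: Iterable[tuple[str, str]],
    params: SyntenyParams | None = None,
) -> list[SyntenyBlock]:
    """Build anchors from two gene maps plus orthologue pairs and chain
    them per scaffold pair."""
    params = params or SyntenyParams()
    a_info = gene_map_a.set_index("gene_id")[["scaffold_id", "ordinal"]]
    b_info = gene_map_b.set_index("gene_id")[["scaffold_id", "ordinal"]]
    buckets: dict[tuple[str, str], list[AnchorPair]] = {}
    seen: set[tuple[str, str]] = set()
    for ga, gb in ortholog_pairs:
        if (ga, gb) in seen:
            raise UsageError(f"duplicate orthologue pair ({ga}, {gb})")
        seen.add((ga, gb))
        if ga not in a_info.index or gb not in b_info.index:
            continue
        ra, rb = a_info.loc[ga], b_info.loc[gb]
        ap = AnchorPair(ga, gb, ra.scaffold_id, rb.scaffold_id, int(ra.ordinal), int(rb.ordinal))
        buckets.setdefault((ap.scaffold_a, ap.scaffold_b), []).append(ap)
    blocks: list[SyntenyBlock] = []
    for key in sorted(buckets):
        blocks.extend(chain_anchors(buckets[key], params))
    return blocks


def summarize_synteny(blocks: Iterable[SyntenyBlock]) -> tuple[int, int]:
    """(number of scaffold pairs holding at least one block, total gene
    pairs across all blocks)."""
    pairs = set()
    genes = 0
    for b in blocks:
        pairs.add((b.scaffold_a, b.scaffold_b))
        genes += b.score
    return len(pairs), genes
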