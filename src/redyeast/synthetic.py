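"""Synthetic inputs with known ground truth.

The generators emulate the statistical structure of a small red-yeast
comparative study: two closely related (~97% identical) genomes, shotgun
reads at a stated coverage, gene families evolving by loss along a small
species tree, gene orders rearranged by segmental inversions, and
replicated qPCR Ct measurements with known fold changes.

Every generator is a pure function of its arguments: the root seed is
combined with a stable per-generator label so that adding one generator
never perturbs the random stream of another.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .io_formats import OrthoGroup, SeqRecord, parse_newick, revcomp

__all__ = [
    "TruthPlacement",
    "child_rng",
    "simulate_genome",
    "fragment_and_shuffle",
    "simulate_reads",
    "simulate_gene_families",
    "simulate_gene_orders",
    "simulate_ct",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthPlacement:
    """Where a simulated fragment came from on its source scaffold."""

    fragment_id: str
    source_ref_id: str
    ref_start: int  # 0-based half-open on the source
    ref_end: int
    orientation: str  # '+' or '-'


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive an independent generator from (root seed, stable label)."""
    digest = hashlib.blake2s(label.encode(), digest_size=4).digest()
    return np.random.default_rng(np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")]))


# ---------------------------------------------------------------------------
# genomes and fragments


def simulate_genome(length: int, gc: float, seed: int, record_id: str = "genome") -> SeqRecord:
    """I.i.d. random genome with the requested GC fraction (split evenly
    between G and C)."""
    if length < 1:
        raise UsageError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise UsageError("gc must lie in [0, 1]")
    rng = child_rng(seed, f"genome:{record_id}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=length, p=p)
    return SeqRecord(id=record_id, sequence=_BASES[idx].tobytes().decode())


def _breakpoints(length: int, n_fragments: int, min_len: int, rng: np.random.Generator) -> list[int]:
    """n_fragments-1 internal cuts, all fragments >= min_len.

    Uses the stick-breaking reduction: draw in the shrunken interval, sort,
    then add the minimum lengths back.
    """
    if n_fragments * min_len > length:
        raise UsageError(
            f"cannot cut {length} bp into {n_fragments} fragments of >= {min_len} bp"
        )
    slack = length - n_fragments * min_len
    cuts = np.sort(rng.choice(slack + 1, size=n_fragments - 1, replace=False)) if slack else np.zeros(
        n_fragments - 1, dtype=int
    )
    return [int(c) + (i + 1) * min_len for i, c in enumerate(cuts)]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # replace with one of the three other bases, never N
        lut = {b: [x for x in b"ACGT" if x != b] for b in b"ACGT"}
        choices = rng.integers(0, 3, size=hit.size)
        for pos, c in zip(hit, choices):
            b = arr[pos]
            if b in lut:
                arr[pos] = lut[b][c]
    return arr.tobytes().decode()


def fragment_and_shuffle(
    genome: Union[SeqRecord, Sequence[SeqRecord]],
    n_fragments: int,
    p_invert: float,
    substitution_rate: float,
    seed: int,
    min_fragment_len: int = 200,
) -> tuple[list[SeqRecord], list[TruthPlacement]]:
    """Cut one or more source scaffolds into fragments, invert and mutate
    some, and emit them in a shuffled order with a truth table.

    When several source scaffolds are given the fragment budget is split
    proportionally to scaffold length (each scaffold gets at least one).
    Fragments tile each source without gaps or overlap; with
    ``substitution_rate=0`` and ``p_invert=0`` the truth-ordered
    concatenation reproduces the sources exactly.
    """
    if not 0.0 <= p_invert <= 1.0 or not 0.0 <= substitution_rate <= 1.0:
        raise UsageError("p_invert and substitution_rate must lie in [0, 1]")
    sources = [genome] if isinstance(genome, SeqRecord) else list(genome)
    total = sum(len(s) for s in sources)
    if n_fragments > total // 2:
        raise UsageError("n_fragments must not exceed half the total genome length")
    rng = child_rng(seed, "fragments")

    # proportional allocation with one fragment minimum per source
    alloc = [1] * len(sources)
    rest = n_fragments - len(sources)
    if rest < 0:
        raise UsageError("need at least one fragment per source scaffold")
    weights = np.array([len(s) for s in sources], dtype=float)
    extra = np.floor(rest * weights / weights.sum()).astype(int)
    alloc = [a + e for a, e in zip(alloc, extra)]
    i = 0
    while sum(alloc) < n_fragments:
        alloc[i % len(sources)] += 1
        i += 1

    fragments: list[SeqRecord] = []
    truth: list[TruthPlacement] = []
    frag_no = 0
    for src, n_frag in zip(sources, alloc):
        cuts = [0] + _breakpoints(len(src), n_frag, min_fragment_len, rng) + [len(src)]
        for a, b in zip(cuts[:-1], cuts[1:]):
            frag_no += 1
            fid = f"frag_{frag_no:04d}"
            seq = src.sequence[a:b]
            orient = "-" if rng.random() < p_invert else "+"
            if orient == "-":
                seq = revcomp(seq)
            seq = _mutate(seq, substitution_rate, rng)
            fragments.append(SeqRecord(id=fid, sequence=seq))
            truth.append(TruthPlacement(fid, src.id, a, b, orient))
    order = rng.permutation(len(fragments))
    return [fragments[i] for i in order], truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: SeqRecord,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> list[SeqRecord]:
    """Uniform single-end shotgun reads with i.i.d. substitution errors.

    ``ceil(coverage * L / read_length)`` reads, uniform start positions,
    uniform strand.
    """
    L = len(genome)
    if read_length > L:
        raise UsageError("read_length exceeds genome length")
    rng = child_rng(seed, "reads")
    n_reads = math.ceil(coverage * L / read_length)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5

    # 2-bit matrix of all reads (A=0 C=1 G=2 T=3); genomes are N-free here
    enc = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        enc[b] = i
    garr = enc[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]
    mat = garr[starts[:, None] + np.arange(read_length)]
    mat[flip] = 3 - mat[flip, ::-1]  # reverse complement in 2-bit space
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4
    blob = _BASES[mat.reshape(-1)].tobytes().decode()
    return [
        SeqRecord(id=f"read_{i:07d}", sequence=blob[i * read_length : (i + 1) * read_length])
        for i in range(n_reads)
    ]


# ---------------------------------------------------------------------------
# gene families on a tree


def simulate_gene_families(
    tree: Union[str, dendropy.Tree],
    n_families: int,
    seed: int,
    duplication_rate: float = 0.0,
) -> tuple[list[OrthoGroup], pd.DataFrame]:
    """Evolve gene families by stochastic loss along a tree.

    Each family is present (single copy) at the root and is lost
    independently along every branch with that branch's loss probability,
    read from the branch length.  A family retained in a taxon contributes
    exactly one gene there (plus optional extra copies at
    ``duplication_rate``, off by default).  Families lost everywhere are
    dropped, so the truth presence/absence matrix has no all-zero column.

    Returns the orthogroup list and the truth matrix (taxa x families,
    0/1 ints).
    """
    t = parse_newick(tree) if isinstance(tree, str) else tree
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise UsageError("every branch needs a loss probability as its length")
        if not 0.0 <= edge.length <= 1.0:
            raise UsageError("branch loss probabilities must lie in [0, 1]")
    taxa = sorted(lf.taxon.label for lf in t.leaf_node_iter())
    rng = child_rng(seed, "families")

    presence = np.zeros((len(taxa), n_families), dtype=np.int8)
    tax_index = {lab: i for i, lab in enumerate(taxa)}

    for fam in range(n_families):
        state: dict[int, bool] = {id(t.seed_node): True}
        for node in t.preorder_node_iter():
            if node is t.seed_node:
                continue
            parent_alive = state[id(node.parent_node)]
            alive = parent_alive and rng.random() >= (node.edge.length or 0.0)
            state[id(node)] = alive
            if node.is_leaf() and alive:
                presence[tax_index[node.taxon.label], fam] = 1

    keep = presence.sum(axis=0) > 0
    presence = presence[:, keep]
    fam_ids = [f"OG{i + 1:05d}" for i in range(presence.shape[1])]

    groups: list[OrthoGroup] = []
    for j, fid in enumerate(fam_ids):
        members: dict[str, tuple[str, ...]] = {}
        for i, tax in enumerate(taxa):
            if presence[i, j]:
                copies = 1
                if duplication_rate > 0 and rng.random() < duplication_rate:
                    copies = 2
                members[tax] = tuple(f"{fid}_{tax}_g{c + 1}" for c in range(copies))
        groups.append(OrthoGroup(group_id=fid, members=members))
    truth = pd.DataFrame(presence, index=taxa, columns=fam_ids)
    return groups, truth


# ---------------------------------------------------------------------------
# gene orders


def simulate_gene_orders(
    n_genes: int,
    n_inversions: int,
    inversion_span: int,
    seed: int,
    gene_length: int = 500,
    spacer: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]], list[dict]]:
    """Two single-scaffold genomes whose gene orders differ by segmental
    inversions.

    Genome B carries genome A's gene order with ``n_inversions``
    non-overlapping reversals of ``inversion_span`` consecutive genes.
    Returns (gene map A, gene map B, orthologue pairs, truth blocks); truth
    blocks are the maximal runs of conserved (or anti-conserved) adjacency,
    each a dict with keys ``genes`` (list of A-gene ids) and ``orientation``.
    """
    if n_inversions * inversion_span > n_genes:
        raise UsageError("inversions exceed the gene complement")
    rng = child_rng(seed, "orders")

    # choose non-overlapping inversion start ordinals via stick breaking
    starts: list[int] = []
    if n_inversions:
        slack = n_genes - n_inversions * inversion_span
        cuts = np.sort(rng.choice(slack + 1, size=n_inversions, replace=False))
        starts = [int(c) + i * inversion_span for i, c in enumerate(cuts)]

    order = list(range(n_genes))
    sign = [1] * n_genes
    for s in starts:
        order[s : s + inversion_span] = order[s : s + inversion_span][::-1]
        for k in range(s, s + inversion_span):
            sign[k] = -1

    def gmap(genome: str, perm: Iterable[int], signs: Iterable[int]) -> pd.DataFrame:
        rows = []
        for ordinal, (g, sg) in enumerate(zip(perm, signs)):
            start = ordinal * (gene_length + spacer) + 1
            rows.append(
                {
                    "gene_id": f"{genome}_g{g:04d}",
                    "genome": genome,
                    "scaffold_id": f"{genome}_s1",
                    "start": start,
                    "end": start + gene_length - 1,
                    "strand": "+" if sg > 0 else "-",
                    "ordinal": ordinal,
                }
            )
        return pd.DataFrame(rows)

    map_a = gmap("A", range(n_genes), [1] * n_genes)
    map_b = gmap("B", order, sign)
    pairs = [(f"A_g{g:04d}", f"B_g{g:04d}") for g in range(n_genes)]

    blocks: list[dict] = []
    bounds = sorted({0, n_genes} | {s for s in starts} | {s + inversion_span for s in starts})
    for a, b in zip(bounds[:-1], bounds[1:]):
        orientation = "-" if a in starts else "+"
        blocks.append(
            {"genes": [f"A_g{g:04d}" for g in range(a, b)], "orientation": orientation}
        )
    return map_a, map_b, pairs, blocks


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct(
    ct_design: Sequence[tuple[str, float, float]],
    n_replicates: int,
    seed: int,
    housekeeping_gene: str = "GAPDH",
    control_label: str = "control",
    treated_label: str = "treated",
    base_ct: float = 20.0,
    housekeeping_ct: float = 15.0,
) -> pd.DataFrame:
    """Replicated Ct values with known fold changes.

    Each design row is ``(gene, true_fold, noise_sd)``.  The treated-sample
    target Ct is shifted by ``-log2(true_fold)`` relative to control; the
    housekeeping gene is unshifted; Gaussian noise of the stated sd is added
    per replicate.
    """
    if n_replicates < 1:
        raise UsageError("need at least one replicate")
    rng = child_rng(seed, "ct")
    rows = []
    for sample in (control_label, treated_label):
        for rep in range(1, n_replicates + 1):
            for gene, fold, sd in ct_design:
                if fold <= 0:
                    raise DataError("true fold changes must be positive")
                ct = base_ct
                if sample == treated_label:
                    ct -= math.log2(fold)
                ct += rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append({"sample": sample, "gene": gene, "replicate": rep, "ct": ct})
            sd_hk = max((d[2] for d in ct_design), default=0.0)
            hk = housekeeping_ct + (rng.normal(0.0, sd_hk) if sd_hk > 0 else 0.0)
            rows.append({"sample": sample, "gene": housekeeping_gene, "replicate": rep, "ct": hk})
    return pd.DataFrame(rows)
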