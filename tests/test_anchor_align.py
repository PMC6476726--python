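"""Anchor discovery, chaining and filtering, checked against brute-force
oracles."""

import numpy as np
import pytest

from redyeast.anchor_align import (
    AlignParams,
    AnchorMatch,
    cluster_anchors,
    filter_clusters,
    find_anchors,
    score_cluster,
)
from redyeast.errors import UsageError
from redyeast.io_formats import SeqRecord, revcomp
from conftest import random_seq

# ---------------------------------------------------------------------------
# independent oracles


def brute_mems(q: str, r: str, k: int) -> set:
    """Enumerate maximal exact matches by scanning every diagonal of the
    match matrix; N matches nothing."""
    out = set()
    for strand in "+-":
        qs = q if strand == "+" else revcomp(q)
        qa = np.frombuffer(qs.encode(), dtype=np.uint8)
        ra = np.frombuffer(r.encode(), dtype=np.uint8)
        eq = (qa[:, None] == ra[None, :]) & (qa[:, None] != ord("N"))
        nq, nr = len(qa), len(ra)
        for d in range(-(nq - 1), nr):
            diag = np.diagonal(eq, offset=d)
            i0 = max(0, -d)  # query index of diag[0]
            run = 0
            for t, m in enumerate(list(diag) + [False]):
                if m:
                    run += 1
                    continue
                if run >= k:
                    qs_i, qe_i = i0 + t - run, i0 + t
                    rs_i = qs_i + d
                    if strand == "+":
                        out.add((qs_i, qe_i, rs_i, rs_i + run, "+"))
                    else:
                        out.add((nq - qe_i, nq - qs_i, rs_i, rs_i + run, "-"))
                run = 0
    return out


def nw_identity(a: str, b: str) -> float:
    """Tiny Needleman-Wunsch with unit mismatch/gap costs; identity is
    matching columns over alignment columns of the traceback path."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1, j - 1] + (a[i - 1] != b[j - 1])
            D[i, j] = min(sub, D[i - 1, j] + 1, D[i, j - 1] + 1)
    i, j, matches, cols = n, m, 0, 0
    while i or j:
        if i and j and D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i and D[i, j] == D[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


def _aset(anchors):
    return {(a.q_start, a.q_end, a.r_start, a.r_end, a.strand) for a in anchors}


# ---------------------------------------------------------------------------
# find_anchors


class TestFindAnchors:
    def test_identity_gives_one_full_anchor(self, rng):
        s = SeqRecord("s", random_seq(rng, 300))
        (a,) = [x for x in find_anchors(s, s, 20) if x.strand == "+"]
        assert (a.q_start, a.q_end, a.r_start, a.r_end) == (0, 300, 0, 300)

    def test_revcomp_gives_one_minus_anchor(self, rng):
        r = SeqRecord("r", random_seq(rng, 300))
        q = SeqRecord("q", revcomp(r.sequence))
        anchors = find_anchors(q, r, 20)
        minus = [a for a in anchors if a.strand == "-"]
        assert len(minus) == 1
        a = minus[0]
        assert (a.q_start, a.q_end, a.r_start, a.r_end) == (0, 300, 0, 300)

    def test_substitution_splits_anchor(self, rng):
        ref = SeqRecord("r", random_seq(rng, 1000))
        sub = list(ref.sequence[200:500])
        sub[150] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[150]]
        q = SeqRecord("q", "".join(sub))
        plus = sorted(
            (a for a in find_anchors(q, ref, 20) if a.strand == "+" and a.length > 50),
            key=lambda a: a.q_start,
        )
        assert [(a.q_start, a.q_end) for a in plus] == [(0, 150), (151, 300)]
        assert [a.r_start for a in plus] == [200, 351]

    def test_n_matches_nothing(self):
        q = SeqRecord("q", "ACGTACGTNACGTACGT")
        r = SeqRecord("r", "ACGTACGTNACGTACGT")
        anchors = find_anchors(q, r, 4)
        # the N column never sits inside an anchor
        for a in anchors:
            assert "N" not in q.sequence[a.q_start : a.q_end]

    def test_equivalence_with_brute_force(self, rng):
        """Seeded random pairs up to 400 bp: the index-based MEM finder
        agrees exactly with diagonal-scanning enumeration."""
        trials = 0
        for _ in range(200):
            n = int(rng.integers(30, 401))
            m = int(rng.integers(30, 401))
            k = int(rng.integers(4, 9))
            alphabet = "ACGT" if rng.random() < 0.8 else "ACGTN"
            q, r = random_seq(rng, n, alphabet), random_seq(rng, m, alphabet)
            got = _aset(find_anchors(SeqRecord("q", q), SeqRecord("r", r), k))
            assert got == brute_mems(q, r, k)
            trials += 1
        assert trials == 200

    def test_strand_symmetry(self, rng):
        q = random_seq(rng, 250)
        r = SeqRecord("r", random_seq(rng, 250) + q[40:160] + random_seq(rng, 30))
        fwd = find_anchors(SeqRecord("q", q), r, 12)
        rev = find_anchors(SeqRecord("q", revcomp(q)), r, 12)
        n = len(q)
        mirrored = {
            (n - a.q_end, n - a.q_start, a.r_start, a.r_end, {"+": "-", "-": "+"}[a.strand])
            for a in rev
        }
        assert _aset(fwd) == mirrored


# ---------------------------------------------------------------------------
# clustering


def _anchor(qs, qe, rs, strand="+", qid="q", rid="r"):
    return AnchorMatch(qid, rid, qs, qe, rs, rs + (qe - qs), strand)


class TestClusterAnchors:
    def test_same_diagonal_within_maxgap_joins(self):
        a = _anchor(0, 100, 0)
        b = _anchor(500, 600, 500)  # 400 bp gaps on both axes
        (c,) = cluster_anchors([a, b], AlignParams())
        assert c.anchor_length_sum == 200 and len(c.anchors) == 2

    def test_separation_beyond_maxgap_splits(self):
        a = _anchor(0, 100, 0)
        b = _anchor(700, 800, 700)  # 600 bp gaps
        clusters = cluster_anchors([a, b], AlignParams())
        assert len(clusters) == 2

    def test_mincluster_boundary(self):
        assert cluster_anchors([_anchor(0, 99, 0)], AlignParams()) == []
        kept = cluster_anchors([_anchor(0, 100, 0)], AlignParams())
        assert len(kept) == 1

    def test_diagonal_offset_rule(self):
        a = _anchor(0, 100, 0)
        b = _anchor(120, 220, 720)  # query gap 20, ref gap 500, diagonal offset 600
        assert len(cluster_anchors([a, b], AlignParams())) == 2

    def test_order_invariance(self, rng):
        anchors = [
            _anchor(int(s), int(s) + 30, int(s) + int(d))
            for s, d in zip(rng.integers(0, 3000, 15), rng.integers(-40, 40, 15))
        ]
        p = AlignParams(mincluster=30)
        ref = cluster_anchors(anchors, p)
        for _ in range(5):
            perm = [anchors[i] for i in rng.permutation(len(anchors))]
            assert cluster_anchors(perm, p) == ref

    def test_minus_strand_chain_is_anti_monotone(self, rng):
        ref = SeqRecord("r", random_seq(rng, 3000))
        sub = list(revcomp(ref.sequence[500:2500]))
        for pos in range(100, 2000, 200):  # sprinkle substitutions
            sub[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[pos]]
        q = SeqRecord("q", "".join(sub))
        anchors = find_anchors(q, ref, 20)
        clusters = cluster_anchors(anchors, AlignParams())
        big = max(clusters, key=lambda c: c.anchor_length_sum)
        assert big.strand == "-" and len(big.anchors) > 3
        rs = [a.r_start for a in big.anchors]  # members sorted by query coord
        assert rs == sorted(rs, reverse=True)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(UsageError):
            cluster_anchors([_anchor(0, 50, 0, qid="a"), _anchor(0, 50, 0, qid="b")], AlignParams())


# ---------------------------------------------------------------------------
# scoring and filtering


class TestScoreAndFilter:
    def test_identical_spans_identity_one(self, rng):
        s = SeqRecord("s", random_seq(rng, 200))
        (c,) = cluster_anchors(find_anchors(s, s, 20), AlignParams())
        c = score_cluster(c, s, s)
        assert c.identity == 1.0

    def test_six_substitutions_in_200(self, rng):
        ref = SeqRecord("r", random_seq(rng, 200))
        sub = list(ref.sequence)
        for pos in (20, 50, 80, 110, 140, 170):
            sub[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[pos]]
        q = SeqRecord("q", "".join(sub))
        clusters = cluster_anchors(find_anchors(q, ref, 10), AlignParams(min_match=10))
        c = score_cluster(max(clusters, key=lambda c: c.anchor_length_sum), q, ref)
        assert c.identity == pytest.approx(0.97)
        assert c.identity == pytest.approx(nw_identity(q.sequence, ref.sequence))

    def test_five_bp_deletion(self, rng):
        q = SeqRecord("q", random_seq(rng, 200))
        ref = SeqRecord("r", q.sequence[:100] + q.sequence[105:])  # 195 bp
        clusters = cluster_anchors(find_anchors(q, ref, 10), AlignParams(min_match=10))
        c = score_cluster(max(clusters, key=lambda c: c.anchor_length_sum), q, ref)
        assert c.q_start == 0 and c.q_end == 200
        assert c.identity == pytest.approx(195 / 200)
        assert c.identity == pytest.approx(nw_identity(q.sequence, ref.sequence))

    def test_identity_matches_dp_oracle_on_random_mutated_spans(self, rng):
        for _ in range(10):
            ref = SeqRecord("r", random_seq(rng, 150))
            sub = list(ref.sequence)
            for pos in rng.choice(150, size=3, replace=False):
                sub[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[pos]]
            q = SeqRecord("q", "".join(sub))
            clusters = cluster_anchors(
                find_anchors(q, ref, 8), AlignParams(min_match=8, mincluster=50)
            )
            c = score_cluster(max(clusters, key=lambda c: c.anchor_length_sum), q, ref)
            if c.q_start == 0 and c.q_end == 150:  # full-span cluster
                assert c.identity == pytest.approx(nw_identity(q.sequence, ref.sequence))

    def _cluster(self, length, identity):
        a = _anchor(0, length, 0)
        return cluster_anchors([a], AlignParams(mincluster=1))[0].__class__(
            query_id="q", ref_id="r", strand="+", anchors=(a,),
            q_start=0, q_end=length, r_start=0, r_end=length,
            anchor_length_sum=length, identity=identity,
        )

    def test_filter_boundaries(self):
        p = AlignParams()
        assert filter_clusters([self._cluster(1600, 0.99)], p)
        assert not filter_clusters([self._cluster(1499, 0.99)], p)
        assert not filter_clusters([self._cluster(1600, 194 / 200)], p)  # exactly 0.97
        assert filter_clusters([self._cluster(1500, 0.9701)], p)
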