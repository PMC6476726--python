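"""Canonical k-mer counting and spectrum-based genome-size / ploidy
estimation.

The multiplicity histogram of canonical k-mers from a shotgun read set has
a low-multiplicity error component, a main peak at the per-base k-mer
coverage c, and — in a diploid with appreciable heterozygosity — a
companion peak at c/2 (heterozygous k-mers present on only one haplotype).
Genome size follows as the number of error-free k-mer instances divided by
the coverage peak; ploidy is called from the presence of a companion peak
at half (or, symmetrically, double) the modal multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from . import _kmers
from .errors import UsageError
from .io_formats import SeqRecord

__all__ = [
    "KmerHistogram",
    "SpectrumParams",
    "SpectrumModel",
    "count_kmers",
    "fit_spectrum",
]


@dataclass(frozen=True)
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers."""

    k: int
    counts: Mapping[int, int]

    def total_instances(self) -> int:
        return sum(m * h for m, h in self.counts.items())


@dataclass(frozen=True)
class SpectrumParams:
    """Peak-calling knobs.

    smooth_window         centred moving-average width for valley/peak search
    secondary_rel_tol     relative window around c/2 (and 2c) searched for a
                          companion peak
    secondary_min_height  minimum companion height as a fraction of the main
                          peak height
    tail_factor           multiplicities above tail_factor * c are excluded
                          from peak search (still counted in the size sum)
    """

    smooth_window: int = 3
    secondary_rel_tol: float = 0.25
    secondary_min_height: float = 0.10
    tail_factor: int = 10


@dataclass(frozen=True)
class SpectrumModel:
    error_cutoff: int | None
    main_peak: int | None
    secondary_peak: int | None
    genome_size_estimate: float | None
    ploidy_call: str  # haploid | diploid | ambiguous


# ---------------------------------------------------------------------------
# counting


def count_kmers(reads: Sequence[Union[SeqRecord, str]], k: int = 31) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read set.

    Each k-mer is pooled with its reverse complement under the
    lexicographically smaller spelling; windows containing N are skipped.
    k must be odd (a palindromic even k-mer has no unique canonical form).
    """
    if k % 2 == 0:
        raise UsageError("k must be odd for canonical counting")
    if k < 3:
        raise UsageError("k must be >= 3")
    seqs = [r.sequence if isinstance(r, SeqRecord) else r for r in reads]
    if not seqs:
        return KmerHistogram(k, {})
    blob = "N".join(seqs)  # the joining N invalidates cross-read windows
    arr = _kmers.encode(blob)
    fwd, valid = _kmers.kmer_codes(arr, k)
    rev = _kmers.revcomp_codes(arr, k)
    canon = np.minimum(fwd[valid], rev[valid])
    if canon.size == 0:
        return KmerHistogram(k, {})
    _, mult = np.unique(canon, return_counts=True)
    ms, hs = np.unique(mult, return_counts=True)
    return KmerHistogram(k, {int(m): int(h) for m, h in zip(ms, hs)})


# ---------------------------------------------------------------------------
# spectrum fitting


def _smooth(h: np.ndarray, window: int) -> np.ndarray:
    kern = np.ones(window) / window
    return np.convolve(h, kern, mode="same")


def fit_spectrum(hist: KmerHistogram, params: SpectrumParams | None = None) -> SpectrumModel:
    """Locate the error valley and coverage peak(s) and estimate genome
    size.

    The histogram is smoothed with a centred moving average; the error
    cutoff m_err is the first multiplicity at which the smoothed spectrum
    turns upward.  The main peak c is the modal multiplicity above m_err.
    Genome size is sum_{m > m_err} m * h(m) divided by a sub-integer
    refinement of the coverage peak (the count-weighted centroid of the
    five bins around c).  A companion peak near c/2 — or, when the
    heterozygous peak happens to be the taller one, near 2c (the two cases
    are canonicalized so that ``main_peak`` is the homozygous peak) — with
    sufficient height yields a diploid call.
    """
    params = params or SpectrumParams()
    if not hist.counts:
        raise UsageError("empty histogram")
    max_m = max(hist.counts)
    if max_m < 3:
        raise UsageError("histogram must extend to multiplicity >= 3")
    h = np.zeros(max_m + 2)
    for m, c in hist.counts.items():
        h[m] = c
    # the histogram has no multiplicity-0 bin; replicate h(1) there so the
    # moving average does not fabricate an upturn at m=1
    hpad = h.copy()
    hpad[0] = h[1]
    s = _smooth(hpad, params.smooth_window)

    # first upturn of the smoothed spectrum = error/signal valley
    m_err = None
    for m in range(1, max_m):
        if s[m] < s[m + 1]:
            m_err = m
            break
    if m_err is None:
        warnings.warn("monotone-decreasing spectrum: no coverage peak", stacklevel=2)
        return SpectrumModel(None, None, None, None, "ambiguous")

    c0 = int(np.argmax(h[m_err + 1 :]) + m_err + 1)
    search_hi = min(max_m, params.tail_factor * c0)
    if h[c0] <= 0:
        warnings.warn("no signal above the error region", stacklevel=2)
        return SpectrumModel(m_err, None, None, None, "ambiguous")

    # local maxima of the smoothed spectrum in the signal region
    peaks = [
        m
        for m in range(m_err + 1, search_hi + 1)
        if s[m] >= s[m - 1] and s[m] >= s[m + 1] and h[m] > 0
    ]

    def companion(center: float) -> int | None:
        lo = center * (1 - params.secondary_rel_tol)
        hi = center * (1 + params.secondary_rel_tol)
        cands = [
            m
            for m in peaks
            if lo <= m <= hi and h[m] >= params.secondary_min_height * h[c0] and m != c0
        ]
        return max(cands, key=lambda m: h[m]) if cands else None

    half = companion(c0 / 2)
    double = companion(2 * c0)
    if half is not None:
        main, secondary, ploidy = c0, half, "diploid"
    elif double is not None:
        main, secondary, ploidy = double, c0, "diploid"
    else:
        main, secondary, ploidy = c0, None, "haploid"

    # sub-integer coverage refinement.  For a single-peak spectrum the
    # count-weighted mean multiplicity of the whole signal region is an
    # almost unbiased estimate of the coverage peak (errors sit below
    # m_err, so the mean is taken over genomic k-mers only).  For a
    # two-peak spectrum the mean is restricted to a re-centred +-25%
    # window around the homozygous peak so the heterozygous peak cannot
    # drag it down.
    total = sum(m * c for m, c in hist.counts.items() if m > m_err)
    n_distinct = sum(c for m, c in hist.counts.items() if m > m_err)
    if ploidy == "haploid":
        c_ref = total / n_distinct
    else:
        c_ref = float(main)
        for _ in range(3):
            lo = max(m_err + 1, int(np.floor(c_ref * (1 - params.secondary_rel_tol))))
            hi = min(max_m, int(np.ceil(c_ref * (1 + params.secondary_rel_tol))))
            w = h[lo : hi + 1]
            if w.sum() == 0:
                c_ref = float(main)
                break
            c_ref = float(np.dot(np.arange(lo, hi + 1), w) / w.sum())
    genome_size = total / c_ref
    return SpectrumModel(m_err, main, secondary, genome_size, ploidy)
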