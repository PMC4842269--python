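"""Salience-function peak calling and (+)/(-) library pairing.

A TSS manifests in dRNA-seq as a sharp jump in read 5'-end counts at one
genomic position, enriched in the TEX-treated (+) library.  The salience
function turns that jump into a local maximum: it contrasts the mean
read-start signal immediately downstream of a position (the m+1 positions
from the position itself to m bp downstream, in transcription direction)
against the mean over the m positions upstream,

    Y[j] = (1/m) * sum_{x=0..m} f[j + x*d]  -  (1/m) * sum_{x=1..m} f[j - x*d]

with d = +1 on the plus strand and d = -1 on the minus strand, and f the
per-position read-start count.  The two windows are deliberately asymmetric
(m+1 vs m positions, both weighted 1/m), so constant coverage c yields
Y = c/m rather than 0; an ideal step of height h peaks at h*(m+1)/m exactly
at the step.  Positions within m of the replicon edge use truncated windows
with the same 1/m weights and are flagged as edge peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CoverageTrack


@dataclass
class SalienceParams:
    """Tunable parameters of peak calling.

    m:                  convolution half-width in bp (window sizes m+1 and m)
    prune_window:       peaks closer than this to a larger retained peak are removed
    max_pair_separation: maximal |(+) - (-)| peak distance for TSS candidates
    """

    m: int = 10
    prune_window: int = 5
    max_pair_separation: int = 2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.prune_window < 1:
            raise ValueError("prune_window must be >= 1")
        if self.max_pair_separation < 0:
            raise ValueError("max_pair_separation must be >= 0")


@dataclass
class Peak:
    """A retained local maximum of the salience function."""

    replicon_id: str
    strand: str
    condition: str
    treatment: str
    position: int        # 1-based
    height: float        # read starts at the position
    salience: float
    edge: bool = False   # within m of the replicon boundary (truncated window)


@dataclass
class TSSCandidate:
    """A (+)-library peak paired with a (-)-library peak 0..max_sep bp away.

    The candidate coordinate is the (+)-library peak coordinate.
    """

    replicon_id: str
    strand: str
    condition: str
    position: int
    plus_peak: Peak
    minus_peak: Peak

    @property
    def pair_distance(self) -> int:
        return abs(self.plus_peak.position - self.minus_peak.position)


def compute_salience(read_starts: np.ndarray, strand: str, m: int) -> np.ndarray:
    """Salience value at every position of a dense read-start track.

    Vectorized with cumulative sums; windows truncate at the array ends.
    """
    f = np.asarray(read_starts, dtype=float)
    L = len(f)
    if m >= L:
        raise ValueError(f"convolution step m={m} must be smaller than track length {L}")
    csum = np.concatenate(([0.0], np.cumsum(f)))  # csum[i] = sum f[0:i]

    def window_sum(lo_off: int, hi_off: int) -> np.ndarray:
        # sum of f over 0-based offsets j+lo_off .. j+hi_off, truncated to array
        j = np.arange(L)
        lo = np.clip(j + lo_off, 0, L)
        hi = np.clip(j + hi_off + 1, 0, L)
        hi = np.maximum(hi, lo)
        return csum[hi] - csum[lo]

    if strand == "+":
        down = window_sum(0, m)     # j .. j+m
        up = window_sum(-m, -1)     # j-m .. j-1
    elif strand == "-":
        down = window_sum(-m, 0)    # j-m .. j (downstream = decreasing coordinate)
        up = window_sum(1, m)
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return (down - up) / m


def salience_at(read_starts: np.ndarray, position: int, strand: str, m: int) -> float:
    """Salience at a single 1-based position (same truncation rules)."""
    f = np.asarray(read_starts, dtype=float)
    L = len(f)
    j = position - 1
    if strand == "+":
        down = f[max(0, j):min(L, j + m + 1)].sum()
        up = f[max(0, j - m):max(0, j)].sum()
    else:
        down = f[max(0, j - m):min(L, j + 1)].sum()
        up = f[min(L, j + 1):min(L, j + m + 1)].sum()
    return (down - up) / m


def _plateau_maxima(y: np.ndarray, read_starts: np.ndarray, strand: str) -> list[int]:
    """0-based indices of local maxima, one representative per plateau.

    A plateau (run of equal values) is a local maximum when both flanking
    values exist and are strictly smaller; runs touching the array boundary
    are never maxima (a jump cannot be established without signal on both
    sides), so monotone salience yields no peaks.

    An isolated read-start spike -- the typical dRNA-seq TSS signal, where
    every read 5' end maps to the same base -- yields an (m+1)-wide salience
    plateau, so plateau positions are not equivalent: the jump itself is
    where the read starts pile up.  The representative is therefore the
    plateau position with the largest read-start count, ties broken toward
    5' in transcription direction (a TSS is the first transcribed base).
    """
    L = len(y)
    if L == 0:
        return []
    maxima = []
    i = 0
    while i < L:
        j = i
        while j + 1 < L and y[j + 1] == y[i]:
            j += 1
        left_smaller = i > 0 and y[i - 1] < y[i]
        right_smaller = j < L - 1 and y[j + 1] < y[i]
        if left_smaller and right_smaller:
            run = read_starts[i:j + 1]
            if strand == "+":
                rep = i + int(np.argmax(run))
            else:
                rep = j - int(np.argmax(run[::-1]))
            maxima.append(rep)
        i = j + 1
    return maxima


def call_peaks(salience: np.ndarray, track: CoverageTrack,
               params: SalienceParams) -> list[Peak]:
    """Retain positive local maxima of the salience function, pruned greedily.

    Pruning keeps, among any peaks within ``prune_window`` bp of each other,
    only the largest-magnitude one; ties are broken toward 5'.
    """
    strand = track.meta.strand
    idx = [i for i in _plateau_maxima(np.asarray(salience), track.read_starts, strand)
           if salience[i] > 0]
    # greedy by descending salience, ties toward 5' in transcription direction
    def tie_key(i: int) -> int:
        return i if strand == "+" else -i
    order = sorted(idx, key=lambda i: (-salience[i], tie_key(i)))
    kept: list[int] = []
    kept_sorted: list[int] = []
    for i in order:
        if any(abs(i - k) <= params.prune_window for k in kept):
            continue
        kept.append(i)
    kept.sort()
    L = len(salience)
    peaks = []
    for i in kept:
        peaks.append(Peak(
            replicon_id=track.replicon_id, strand=strand,
            condition=track.meta.condition, treatment=track.meta.treatment,
            position=i + 1, height=float(track.read_starts[i]),
            salience=float(salience[i]),
            edge=(i < params.m or i >= L - params.m)))
    return peaks


def call_peaks_from_track(track: CoverageTrack, params: SalienceParams) -> list[Peak]:
    """Salience peaks of one library track.

    The salience input f is the per-nucleotide read count (coverage): a TSS
    is a sharp jump in coverage, and a coverage step has a unique salience
    maximum exactly at the jump.  Read-*start* counts would be degenerate
    here -- an isolated 5'-end spike yields an (m+1)-wide salience plateau
    whose argmax is decided by noise.  Tracks loaded without coverage fall
    back to read starts.  Peak height is always the read-start count at the
    peak, the quantity the downstream features need.
    """
    f = track.coverage if track.coverage is not None else track.read_starts
    sal = compute_salience(f, track.meta.strand, params.m)
    return call_peaks(sal, track, params)


def pair_peak_libraries(plus_peaks: list[Peak], minus_peaks: list[Peak],
                        params: SalienceParams) -> list[TSSCandidate]:
    """Match (+) peaks to the nearest (-) peak within max_pair_separation bp.

    Greedy nearest-first matching; each (-) peak supports at most one
    candidate; distance ties are broken toward the 3' (-) peak.  The
    candidate coordinate is the (+) peak coordinate.
    """
    if not plus_peaks or not minus_peaks:
        return []
    strand = plus_peaks[0].strand
    pairs = []
    for pi, p in enumerate(plus_peaks):
        for mi, q in enumerate(minus_peaks):
            d = abs(p.position - q.position)
            if d <= params.max_pair_separation:
                three_prime = q.position if strand == "+" else -q.position
                pairs.append((d, -three_prime, pi, mi))
    pairs.sort()
    used_plus: set[int] = set()
    used_minus: set[int] = set()
    out = []
    for _, _, pi, mi in pairs:
        if pi in used_plus or mi in used_minus:
            continue
        used_plus.add(pi)
        used_minus.add(mi)
        p, q = plus_peaks[pi], minus_peaks[mi]
        out.append(TSSCandidate(
            replicon_id=p.replicon_id, strand=p.strand, condition=p.condition,
            position=p.position, plus_peak=p, minus_peak=q))
    out.sort(key=lambda c: c.position)
    return out


def call_candidates(tracks: dict[tuple[str, str, str], CoverageTrack],
                    condition: str, strand: str,
                    params: SalienceParams) -> list[TSSCandidate]:
    """Full peak calling for one condition/strand: salience, peaks, pairing."""
    plus_track = tracks[(condition, "TEXplus", strand)]
    minus_track = tracks[(condition, "TEXminus", strand)]
    plus_peaks = call_peaks_from_track(plus_track, params)
    minus_peaks = call_peaks_from_track(minus_track, params)
    return pair_peak_libraries(plus_peaks, minus_peaks, params)
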