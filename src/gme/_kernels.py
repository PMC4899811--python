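"""Numba-compiled inner loops shared by the repeat finder and concordance code.

Sequences are encoded as uint8 arrays: A=0, C=1, G=2, T=3, anything
else (N) = 4.  Code 4 never equals itself during comparison-by-value,
so Ns behave as guaranteed mismatches where relevant; callers that need
that behaviour compare through :func:`mismatch_at`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

N_CODE = 4


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (N and unknown characters -> 4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@njit(cache=True)
def region_consensus(codes, start, end, period):
    """Per-phase majority base of codes[start:end]; ties -> smallest code."""
    counts = np.zeros((period, 4), dtype=np.int64)
    for i in range(start, end):
        c = codes[i]
        if c < 4:
            counts[(i - start) % period, c] += 1
    pattern = np.empty(period, dtype=np.uint8)
    for ph in range(period):
        best = 0
        for b in range(1, 4):
            if counts[ph, b] > counts[ph, best]:
                best = b
        pattern[ph] = best
    return pattern


@njit(cache=True)
def wraparound_align(text, pattern, match_w, mismatch_p, indel_p):
    """Best score aligning ``text`` to the cyclic repetition of ``pattern``.

    Start phase is free; every text base is consumed (match/mismatch or
    insertion); pattern bases may be skipped (deletion).  A perfect
    repeat of length L scores L*match_w.
    """
    n = text.size
    p = pattern.size
    neg = np.int64(-(10**9))
    prev = np.zeros(p, dtype=np.int64)
    cur = np.empty(p, dtype=np.int64)
    for i in range(n):
        for j in range(p):
            jm1 = j - 1 if j > 0 else p - 1
            sub = match_w if text[i] == pattern[j] else -mismatch_p
            v = prev[jm1] + sub
            ins = prev[j] - indel_p
            if ins > v:
                v = ins
            cur[j] = v
        # pattern deletions within the row; two passes handle wraparound
        for _ in range(2):
            for j in range(p):
                jm1 = j - 1 if j > 0 else p - 1
                d = cur[jm1] - indel_p
                if d > cur[j]:
                    cur[j] = d
        for j in range(p):
            prev[j] = cur[j]
    best = neg
    for j in range(p):
        if prev[j] > best:
            best = prev[j]
    return best


@njit(cache=True)
def score_region_kernel(codes, start, end, period, match_w, mismatch_p, indel_p):
    """Repeat alignment score of codes[start:end) at the given period.

    Score = (wraparound alignment vs the region's per-phase consensus)
    minus one full pattern copy, so a perfect repeat of length L scores
    (L - period) * match_w.
    """
    pattern = region_consensus(codes, start, end, period)
    total = wraparound_align(codes[start:end], pattern, match_w, mismatch_p, indel_p)
    return total - match_w * period


@njit(cache=True)
def window_candidates(
    codes, w0, w1, period, match_w, mismatch_p, indel_p, min_score, min_len, out
):
    """Score every interval [a, b) of length >= min_len inside [w0, w1).

    Consensus counts are maintained incrementally per start position.
    Qualifying (a, b, period, score) rows are written to ``out``; returns
    the row count, or -1 on buffer overflow.
    """
    cnt = 0
    counts = np.zeros((period, 4), dtype=np.int64)
    pattern = np.empty(period, dtype=np.uint8)
    for a in range(w0, w1 - min_len + 1):
        for ph in range(period):
            for x in range(4):
                counts[ph, x] = 0
        for i in range(a, a + min_len - 1):
            c = codes[i]
            if c < 4:
                counts[(i - a) % period, c] += 1
        for b in range(a + min_len, w1 + 1):
            c = codes[b - 1]
            if c < 4:
                counts[(b - 1 - a) % period, c] += 1
            for ph in range(period):
                best = 0
                for x in range(1, 4):
                    if counts[ph, x] > counts[ph, best]:
                        best = x
                pattern[ph] = best
            sc = (
                wraparound_align(codes[a:b], pattern, match_w, mismatch_p, indel_p)
                - match_w * period
            )
            if sc >= min_score:
                if cnt >= out.shape[0]:
                    return -1
                out[cnt, 0] = a
                out[cnt, 1] = b
                out[cnt, 2] = period
                out[cnt, 3] = sc
                cnt += 1
    return cnt


@njit(cache=True)
def pairwise_match_counts(codes, start, end, period):
    """(matches, total) of position-vs-position+period comparisons in the region."""
    m = 0
    total = end - start - period
    for i in range(start, end - period):
        if codes[i] == codes[i + period] and codes[i] < 4:
            m += 1
    return m, total


@njit(cache=True)
def best_ungapped_run(a, b, max_mismatches):
    """Longest ungapped alignment window between a and b with <= max_mismatches.

    Scans every diagonal with a two-pointer window.  Codes >= 4 (N)
    always count as mismatches.  Returns the maximum window length.
    """
    n = a.size
    m = b.size
    best = 0
    for diag in range(-(m - 1), n):
        if diag >= 0:
            ia0, ib0 = diag, 0
        else:
            ia0, ib0 = 0, -diag
        length = min(n - ia0, m - ib0)
        if length <= best:
            continue
        left = 0
        mism = 0
        for right in range(length):
            if a[ia0 + right] != b[ib0 + right] or a[ia0 + right] >= 4:
                mism += 1
            while mism > max_mismatches:
                if a[ia0 + left] != b[ib0 + left] or a[ia0 + left] >= 4:
                    mism -= 1
                left += 1
            if right - left + 1 > best:
                best = right - left + 1
    return best


@njit(cache=True)
def best_offset_alignment(a, b):
    """Best ungapped placement of b against a.

    Returns (offset, matches, mismatches) maximizing matches over all
    integer offsets of b relative to a (ties -> smallest offset).
    Overhanging bases are ignored.
    """
    n = a.size
    m = b.size
    best_off = 0
    best_match = -1
    best_mism = 0
    for off in range(-(m - 1), n):
        lo = max(0, off)
        hi = min(n, off + m)
        if hi - lo <= 0:
            continue
        match = 0
        mism = 0
        for i in range(lo, hi):
            if a[i] == b[i - off] and a[i] < 4:
                match += 1
            else:
                mism += 1
        if match > best_match:
            best_match = match
            best_mism = mism
            best_off = off
    return best_off, best_match, best_mism


@njit(cache=True)
def hairpin_kernel(codes, min_loop):
    """Longest perfect inverted-repeat stem with a loop of >= min_loop bases.

    codes must be ACGT-only; complement of code c is 3 - c.
    """
    n = codes.size
    best = 0
    prev = np.zeros(n, dtype=np.int64)
    cur = np.zeros(n, dtype=np.int64)
    for a in range(n - 2, -1, -1):
        for b in range(n):
            cur[b] = 0
        for b in range(a + 1, n):
            if codes[a] + codes[b] == 3 and codes[a] < 4 and codes[b] < 4:
                inner = prev[b - 1] if b - 1 > a + 1 else 0
                cur[b] = inner + 1
                usable = (b - a + 1 - min_loop) // 2
                if cur[b] < usable:
                    usable = cur[b]
                if usable > best:
                    best = usable
        for b in range(n):
            prev[b] = cur[b]
    return best


@njit(cache=True)
def hamming(a, b):
    """Mismatch count between equal-length code arrays (N always mismatches)."""
    d = 0
    for i in range(a.size):
        if a[i] != b[i] or a[i] >= 4:
            d += 1
    return d
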