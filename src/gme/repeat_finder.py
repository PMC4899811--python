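"""Tandem-repeat detection for periods 1-6.

Scoring follows the classic tandem-repeat alignment parameterization:
match +2, mismatch -7, indel -5, minimum reportable score 14, maximum
period 6.  A region is scored by wraparound alignment against its own
per-phase consensus motif, minus one motif copy, so a perfect repeat of
length L and period p scores exactly (L - p) * 2 and the shortest
reportable perfect repeat is p + 7 bases.

Detection seeds candidate windows from runs of position-vs-(position +
period) agreement and then scores every plausible interval inside each
window exhaustively; :func:`brute_force_repeats` is the unseeded full
enumeration used as a verification oracle on small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gme import _kernels
from gme.motif_families import canonical_family

__all__ = [
    "RepeatParams",
    "TandemRepeatHit",
    "score_repeat_region",
    "find_tandem_repeats",
    "brute_force_repeats",
    "hits_table",
]


@dataclass(frozen=True)
class RepeatParams:
    """Alignment weights and reporting thresholds for repeat detection."""

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 5
    # carried for record fidelity; the exhaustive scorer does not need the
    # probabilistic candidate model they parameterize
    match_probability: int = 80
    indel_probability: int = 10
    min_score: int = 14
    max_period: int = 6

    def __post_init__(self) -> None:
        for name in (
            "match_weight",
            "mismatch_penalty",
            "indel_penalty",
            "match_probability",
            "indel_probability",
            "min_score",
            "max_period",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_period > 6:
            raise ValueError("max_period must be <= 6")

    @property
    def min_extra_bases(self) -> int:
        """Bases beyond one motif copy needed to reach min_score when perfect."""
        return math.ceil(self.min_score / self.match_weight)


DEFAULT_PARAMS = RepeatParams()


@dataclass
class TandemRepeatHit:
    """A detected repeat locus (0-based half-open interval)."""

    sequence_id: str
    start: int
    end: int
    period: int
    consensus_motif: str
    family: str
    copy_number: float
    score: int
    percent_match: float
    sample_id: str | None = None
    depth: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_period(period: int, params: RepeatParams) -> None:
    if period < 1 or period > params.max_period:
        raise ValueError(f"period must be in 1..{params.max_period}, got {period}")


def score_repeat_region(
    sequence: str | np.ndarray,
    start: int,
    end: int,
    period: int,
    params: RepeatParams = DEFAULT_PARAMS,
) -> int:
    """Alignment score of sequence[start:end] as a period-``period`` repeat."""
    _check_period(period, params)
    codes = sequence if isinstance(sequence, np.ndarray) else _kernels.encode(sequence)
    if end - start <= period:
        raise ValueError("region must be longer than the period")
    return int(
        _kernels.score_region_kernel(
            codes,
            start,
            end,
            period,
            params.match_weight,
            params.mismatch_penalty,
            params.indel_penalty,
        )
    )


def _make_hit(
    sequence_id: str,
    codes: np.ndarray,
    start: int,
    end: int,
    period: int,
    score: int,
) -> TandemRepeatHit:
    pattern = _kernels.region_consensus(codes, start, end, period)
    motif = _kernels.decode(pattern)
    matches, total = _kernels.pairwise_match_counts(codes, start, end, period)
    return TandemRepeatHit(
        sequence_id=sequence_id,
        start=start,
        end=end,
        period=period,
        consensus_motif=motif,
        family=canonical_family(motif).name,
        copy_number=round((end - start) / period, 1),
        score=score,
        percent_match=round(100.0 * matches / total, 1) if total else 0.0,
    )


def _collapse(candidates: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Greedy collapse of overlapping (start, end, period, score) candidates.

    Highest score wins; ties go to the smaller period, then to the
    earlier and shorter interval.  Accepted intervals never overlap.
    """
    ordered = sorted(candidates, key=lambda c: (-c[3], c[2], c[0], c[1]))
    accepted: list[tuple[int, int, int, int]] = []
    for cand in ordered:
        s, e, _, _ = cand
        if all(e <= a[0] or a[1] <= s for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c[0])
    return accepted


def _candidate_windows(codes: np.ndarray, period: int, margin: int) -> list[tuple[int, int]]:
    """Windows likely to contain a reportable repeat of the given period.

    Seeds are maximal runs of >= 3 consecutive positions where
    codes[i] == codes[i + period]; any interval reaching min_score with
    up to 3 alignment errors contains such a run (a longer one, in
    fact), and denser error patterns cannot reach the threshold at the
    lengths involved.  Nearby seeds are merged and padded by ``margin``
    bases on each side.
    """
    n = codes.size
    eq = (codes[period:] == codes[:-period]) & (codes[:-period] < 4)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < eq.size:
        if eq[i]:
            j = i
            while j < eq.size and eq[j]:
                j += 1
            if j - i >= 3:
                runs.append((i, j + period))  # region coordinates
            i = j
        else:
            i += 1
    if not runs:
        return []
    merged: list[list[int]] = []
    for s, e in runs:
        s = max(0, s - margin)
        e = min(n, e + margin)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


_MAX_CANDIDATES = 2_000_000


def _enumerate_intervals(
    codes: np.ndarray,
    w0: int,
    w1: int,
    period: int,
    params: RepeatParams,
) -> list[tuple[int, int, int, int]]:
    """All intervals in the window scoring >= min_score (numba bulk scan)."""
    min_len = period + params.min_extra_bases
    w = w1 - w0
    rows = min(w * (w + 1) // 2 + 1, _MAX_CANDIDATES)
    buf = np.empty((rows, 4), dtype=np.int64)
    cnt = _kernels.window_candidates(
        codes,
        w0,
        w1,
        period,
        params.match_weight,
        params.mismatch_penalty,
        params.indel_penalty,
        params.min_score,
        min_len,
        buf,
    )
    if cnt < 0:
        raise RuntimeError(
            "repeat-dense window produced more than "
            f"{_MAX_CANDIDATES} candidate intervals; input is not a desk-scale contig"
        )
    return [tuple(int(x) for x in row) for row in buf[:cnt]]


def find_tandem_repeats(
    sequence: str,
    params: RepeatParams = DEFAULT_PARAMS,
    sequence_id: str = "seq",
) -> list[TandemRepeatHit]:
    """All maximal repeat loci with score >= params.min_score, sorted by start.

    Overlapping calls (within and across periods) are collapsed to the
    highest-scoring interval, ties broken toward the smaller period.
    """
    if not sequence:
        return []
    codes = _kernels.encode(sequence)
    candidates: list[tuple[int, int, int, int]] = []
    for period in range(1, params.max_period + 1):
        if codes.size < period + params.min_extra_bases:
            continue
        margin = 12 + period
        for w0, w1 in _candidate_windows(codes, period, margin):
            candidates.extend(_enumerate_intervals(codes, w0, w1, period, params))
    return [
        _make_hit(sequence_id, codes, s, e, p, sc) for s, e, p, sc in _collapse(candidates)
    ]


def brute_force_repeats(
    sequence: str,
    params: RepeatParams = DEFAULT_PARAMS,
    sequence_id: str = "seq",
) -> list[TandemRepeatHit]:
    """Unseeded exhaustive enumeration over every (start, end, period) triple.

    Verification oracle for :func:`find_tandem_repeats`; quadratic in the
    sequence length, intended for inputs of at most ~200 bases.
    """
    if not sequence:
        return []
    if len(sequence) > 200:
        raise ValueError("brute_force_repeats is a test oracle; max length 200")
    codes = _kernels.encode(sequence)
    candidates: list[tuple[int, int, int, int]] = []
    n = codes.size
    for period in range(1, params.max_period + 1):
        min_len = period + params.min_extra_bases
        for a in range(0, n - min_len + 1):
            for b in range(a + min_len, n + 1):
                sc = score_repeat_region(codes, a, b, period, params)
                if sc >= params.min_score:
                    candidates.append((a, b, period, sc))
    return [
        _make_hit(sequence_id, codes, s, e, p, sc) for s, e, p, sc in _collapse(candidates)
    ]


def hits_table(hits: list[TandemRepeatHit]) -> pd.DataFrame:
    """TSV-ready table of hits (coordinates stay 0-based half-open)."""
    rows = [
        {
            "sequence_id": h.sequence_id,
            "start": h.start,
            "end": h.end,
            "period": h.period,
            "motif": h.consensus_motif,
            "family": h.family,
            "copies": h.copy_number,
            "score": h.score,
            "percent_match": h.percent_match,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "start",
            "end",
            "period",
            "motif",
            "family",
            "copies",
            "score",
            "percent_match",
        ],
    )
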