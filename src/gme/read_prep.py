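"""Read quality trimming and N filtering.

Mirrors the standard sliding-window trimmer convention: windows are
scanned from the 5' end and the read is truncated at the start of the
first window whose mean quality falls below the threshold.  Defaults
are window 10, quality 20, post-trim length floor 70; the N filter
deletes every N and drops reads shorter than 50 afterwards.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "DROPPED",
    "phred_to_error",
    "sliding_window_trim",
    "strip_n",
    "read_fastq",
    "write_fastq",
    "trim_fastq",
    "nfilter_fastq",
]

#: sentinel returned when a read fails a length floor
DROPPED = None


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: int = 0  # 1, 2, or 0 for unpaired

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.sequence)


def phred_to_error(q: int) -> float:
    """Error probability of a Phred score: 10^(-q/10); Q20 -> 0.01."""
    if q < 0:
        raise ValueError("Phred scores are non-negative")
    return 10.0 ** (-q / 10.0)


def sliding_window_trim(
    read: Read,
    window: int = 10,
    q_threshold: int = 20,
    min_length: int = 70,
) -> Read | None:
    """Truncate at the first low-quality window; drop if too short after.

    Windows of ``window`` bases are evaluated left to right; at the first
    window whose mean quality is below ``q_threshold`` the read is cut at
    that window's start, after first retaining any leading bases of the
    window that individually meet the threshold (the sliding-window
    convention of the standard trimmers).  Reads shorter than the window
    are evaluated as a single window.  Returns ``DROPPED`` when the
    trimmed length is below ``min_length``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.qualities
    n = len(q)
    cut = n
    first_fail = None
    if n < window:
        if n and sum(q) / n < q_threshold:
            first_fail = 0
    else:
        for i in range(n - window + 1):
            if sum(q[i : i + window]) / window < q_threshold:
                first_fail = i
                break
    if first_fail is not None:
        cut = first_fail
        while cut < n and q[cut] >= q_threshold:
            cut += 1
    if cut < min_length:
        return DROPPED
    if cut == n:
        return read
    return replace(read, sequence=read.sequence[:cut], qualities=q[:cut])


def strip_n(read: Read | str, min_length: int = 50) -> Read | str | None:
    """Delete every N (qualities in lockstep); drop if shorter than min_length."""
    if isinstance(read, str):
        seq = read.replace("N", "").replace("n", "")
        return DROPPED if len(seq) < min_length else seq
    keep = [i for i, ch in enumerate(read.sequence) if ch not in "Nn"]
    if len(keep) < min_length:
        return DROPPED
    if len(keep) == len(read.sequence):
        return read
    return replace(
        read,
        sequence="".join(read.sequence[i] for i in keep),
        qualities=tuple(read.qualities[i] for i in keep),
    )


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, mate: int = 0) -> list[Read]:
    """Load a FASTQ file (Phred+33; transparently gunzips *.gz)."""
    reads = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                    mate=mate,
                )
            )
    return reads


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def trim_fastq(reads, window=10, q_threshold=20, min_length=70):
    """Apply sliding_window_trim to a read list; returns (kept, summary dict)."""
    kept = []
    for r in reads:
        t = sliding_window_trim(r, window=window, q_threshold=q_threshold, min_length=min_length)
        if t is not DROPPED:
            kept.append(t)
    return kept, {"input": len(reads), "kept": len(kept), "dropped": len(reads) - len(kept)}


def nfilter_fastq(reads, min_length=50):
    """Apply strip_n to a read list; returns (kept, summary dict)."""
    kept = []
    for r in reads:
        t = strip_n(r, min_length=min_length)
        if t is not DROPPED:
            kept.append(t)
    return kept, {"input": len(reads), "kept": len(kept), "dropped": len(reads) - len(kept)}


def drop_broken_pairs(r1, r2, keep_ids_1, keep_ids_2):
    """Keep only pairs where both mates survived (ids without /1 /2 suffixes)."""
    common = keep_ids_1 & keep_ids_2
    return (
        [r for r in r1 if _pair_key(r.id) in common],
        [r for r in r2 if _pair_key(r.id) in common],
    )


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id
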