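"""Novelty classification, cross-sample concordance and read matching.

Contigs assembled from unmapped reads are classified *known* when a
reference sequence carries a perfect ungapped match to a contig
substring strictly longer than half the contig; the rest are *novel*.
Novel contigs from different samples that align ungapped over more than
70% of the query with at most 0 or 1 mismatches form concordant groups
(connected components), each with a star-alignment consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from gme import _kernels
from gme.motif_families import reverse_complement
from gme.repeat_finder import TandemRepeatHit

__all__ = [
    "ContigRecord",
    "ConcordantGroup",
    "ExonAnnotation",
    "parse_velvet_id",
    "read_depth",
    "classify_novel",
    "add_flanks",
    "concordant_groups",
    "consensus_sequence",
    "extract_cdna",
    "match_reads",
]

_NODE_RE = re.compile(r"^NODE_(\d+)_length_(\d+)_cov_(\d+(?:\.\d+)?)$")


@dataclass
class ContigRecord:
    """An assembled contig with Velvet-style metadata."""

    sample_id: str
    node_id: int
    length: int
    kmer_coverage: float
    sequence: str
    read_kmer_length: int = 71
    status: str = "unclassified"  # known | novel | unclassified
    n_reads: int = 0  # reads assigned by the assembler (0 when unknown)

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("declared length disagrees with the sequence")
        if self.kmer_coverage < 0:
            raise ValueError("kmer coverage must be >= 0")

    @property
    def contig_id(self) -> str:
        return f"{self.sample_id}:NODE_{self.node_id}"

    @property
    def velvet_id(self) -> str:
        return f"NODE_{self.node_id}_length_{self.length}_cov_{self.kmer_coverage:.6f}"


@dataclass
class ConcordantGroup:
    group_id: str
    members: list[ContigRecord]
    mismatch_mode: int
    consensus: str = ""
    contains_mst: bool = False
    unplaced_members: list[str] = field(default_factory=list)

    @property
    def sample_count(self) -> int:
        return len({c.sample_id for c in self.members})


@dataclass
class ExonAnnotation:
    contig_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, ascending
    exon_types: list[str] = field(default_factory=list)  # initial | internal | final


def parse_velvet_id(id_string: str) -> tuple[int, int, float]:
    """Extract (node_id, length, kmer_coverage) from a Velvet contig ID."""
    parts = id_string.split("_")
    if len(parts) != 6 or parts[0] != "NODE" or parts[2] != "length" or parts[4] != "cov":
        raise ValueError(
            f"malformed Velvet ID {id_string!r}: expected NODE_<int>_length_<int>_cov_<real>"
        )
    m = _NODE_RE.match(id_string)
    if m is None:
        for name, value, caster in (
            ("node", parts[1], int),
            ("length", parts[3], int),
            ("cov", parts[5], float),
        ):
            try:
                caster(value)
            except ValueError:
                raise ValueError(
                    f"malformed Velvet ID {id_string!r}: field {name!r} is not numeric"
                ) from None
        raise ValueError(f"malformed Velvet ID {id_string!r}")
    return int(m.group(1)), int(m.group(2)), float(m.group(3))


def read_depth(ck: float, read_length: float, k: int) -> float:
    """Convert k-mer coverage to read depth: C = Ck * L / (L - k + 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if read_length < k:
        raise ValueError("average read length must be >= k")
    return ck * read_length / (read_length - k + 1)


class KnownIndex:
    """Reference sequences prepared for exact-substring novelty queries."""

    def __init__(self, reference_sets: list[list[str] | dict]):
        seqs: list[str] = []
        for ref in reference_sets:
            values = ref.values() if isinstance(ref, dict) else ref
            seqs.extend(str(s).upper() for s in values)
        # '#' separators prevent matches spanning two reference sequences
        self.haystack = "#".join(seqs)

    def __bool__(self) -> bool:
        return bool(self.haystack)

    def contains(self, fragment: str) -> bool:
        return fragment in self.haystack


def classify_novel(
    contig: ContigRecord | str,
    known_sets: list | KnownIndex,
) -> str:
    """'known' iff a reference carries a perfect match > half the contig length.

    Both strands of the contig are searched.  The match must be ungapped
    and strictly longer than length/2; equivalently, some window of
    length floor(L/2)+1 occurs verbatim in a reference.
    """
    seq = contig if isinstance(contig, str) else contig.sequence
    index = known_sets if isinstance(known_sets, KnownIndex) else KnownIndex(known_sets)
    if not index:
        return "novel"
    m = len(seq) // 2 + 1
    for candidate in (seq.upper(), reverse_complement(seq.upper())):
        if len(candidate) < m:
            continue
        for i in range(len(candidate) - m + 1):
            if index.contains(candidate[i : i + m]):
                return "known"
    return "novel"


def classify_contigs(contigs, known_sets) -> None:
    """Set status on each contig in place (empty references -> all novel)."""
    index = known_sets if isinstance(known_sets, KnownIndex) else KnownIndex(known_sets)
    if not index:
        import warnings

        warnings.warn("no known reference sequences supplied; all contigs called novel")
    for c in contigs:
        c.status = classify_novel(c, index)


def add_flanks(hit: TandemRepeatHit, contig: ContigRecord, flank: int = 30) -> str:
    """Repeat interval plus up to ``flank`` bases each side, clamped to the contig."""
    if not (0 <= hit.start < hit.end <= contig.length):
        raise ValueError("hit does not lie within the contig")
    lo = max(0, hit.start - flank)
    hi = min(contig.length, hit.end + flank)
    return contig.sequence[lo:hi]


def _qualifying_match(a: str, b: str, max_mismatches: int) -> bool:
    """True iff an ungapped alignment with <= max_mismatches covers > 70% of
    the shorter sequence (the easier of the two query directions)."""
    threshold = 0.7 * min(len(a), len(b))
    ca = _kernels.encode(a)
    for cand in (b, reverse_complement(b)):
        cb = _kernels.encode(cand)
        if _kernels.best_ungapped_run(ca, cb, max_mismatches) > threshold:
            return True
    return False


def _strand_kmers(sequence: str, k: int) -> frozenset:
    kmers = set()
    for s in (sequence, reverse_complement(sequence)):
        kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return frozenset(kmers)


def concordant_groups(
    contigs: list[ContigRecord],
    max_mismatches: int = 1,
) -> list[ConcordantGroup]:
    """Group novel contigs observed in two or more samples.

    Edges join contigs with a qualifying ungapped alignment (<=
    ``max_mismatches`` substitutions over > 70% of the query, either
    direction, either strand); groups are connected components spanning
    at least two distinct samples.  Output is order-independent.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    pool = sorted(
        (c for c in contigs if c.status == "novel"),
        key=lambda c: (c.sample_id, c.node_id),
    )
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pool)))
    k = 32
    kmer_sets = [_strand_kmers(c.sequence, k) for c in pool]
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            a, b = pool[i], pool[j]
            # an alignment > 70% of the shorter contig with <= 1 mismatch
            # implies an exact run >= 32 whenever that 70% exceeds 65 bases
            if 0.7 * min(a.length, b.length) >= 65 and kmer_sets[i].isdisjoint(
                kmer_sets[j]
            ):
                continue
            if _qualifying_match(a.sequence, b.sequence, max_mismatches):
                graph.add_edge(i, j)
    groups: list[ConcordantGroup] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for comp in components:
        members = [pool[i] for i in sorted(comp)]
        if len({c.sample_id for c in members}) < 2:
            continue
        group = ConcordantGroup(
            group_id=f"group_{len(groups) + 1:03d}",
            members=members,
            mismatch_mode=max_mismatches,
        )
        group.consensus = consensus_sequence(group)
        groups.append(group)
    return groups


def consensus_sequence(group: ConcordantGroup) -> str:
    """Star-alignment consensus anchored on the longest member.

    Each member is placed at its best ungapped offset against the anchor
    (either strand); columns are decided by majority vote with ties going
    to the anchor's base.  Members with no qualifying overlap are listed
    in ``group.unplaced_members`` and excluded from the vote.
    """
    members = sorted(group.members, key=lambda c: (-c.length, c.sample_id, c.node_id))
    anchor = members[0]
    ca = _kernels.encode(anchor.sequence)
    placements: list[tuple[int, str]] = [(0, anchor.sequence)]
    group.unplaced_members = []
    for member in members[1:]:
        best = None
        for cand in (member.sequence, reverse_complement(member.sequence)):
            off, match, mism = _kernels.best_offset_alignment(ca, _kernels.encode(cand))
            key = (-match, mism, off)
            if best is None or key < best[0]:
                best = (key, off, cand, match, mism)
        _, off, cand, match, _mism = best
        if match <= 0.7 * min(anchor.length, member.length):
            group.unplaced_members.append(member.contig_id)
            continue
        placements.append((off, cand))
    lo = min(off for off, _ in placements)
    hi = max(off + len(seq) for off, seq in placements)
    out = []
    for col in range(lo, hi):
        counts: dict[str, int] = {}
        for off, seq in placements:
            if off <= col < off + len(seq):
                base = seq[col - off]
                counts[base] = counts.get(base, 0) + 1
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if 0 <= col < anchor.length and anchor.sequence[col] in winners:
            out.append(anchor.sequence[col])
        else:
            out.append(winners[0])
    return "".join(out)


def extract_cdna(contig: ContigRecord, annotation: ExonAnnotation) -> str:
    """Concatenate exon substrings; annotations with fewer than 2 exons are rejected."""
    exons = annotation.exons
    if len(exons) < 2:
        raise ValueError("gene-like structures require more than one exon")
    prev_end = 0
    for start, end in exons:
        if start < prev_end or end <= start or end > contig.length:
            raise ValueError(f"exon ({start}, {end}) is out of range or out of order")
        prev_end = end
    return "".join(contig.sequence[s:e] for s, e in exons)


def match_reads(
    queries: dict[str, str],
    read_sets: dict[str, list[tuple[str, str]]],
) -> pd.DataFrame:
    """Per-query counts of reads with a perfect ungapped match.

    A read counts for a query when an exact (100% identity) ungapped
    match spans more than 70% of the shorter of the two sequences; both
    strands are tried.  Returns a table with one row per query, one
    column per read set, plus a total column.
    """
    names = list(read_sets)
    table = pd.DataFrame(0, index=list(queries), columns=names, dtype=int)
    for qname, qseq in queries.items():
        cq = _kernels.encode(qseq)
        for setname, reads in read_sets.items():
            count = 0
            for _rid, rseq in reads:
                threshold = 0.7 * min(len(qseq), len(rseq))
                hitlen = 0
                for cand in (rseq, reverse_complement(rseq)):
                    hitlen = max(
                        hitlen, _kernels.best_ungapped_run(cq, _kernels.encode(cand), 0)
                    )
                    if hitlen > threshold:
                        break
                if hitlen > threshold:
                    count += 1
            table.loc[qname, setname] = count
    table["total"] = table[names].sum(axis=1)
    return table
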