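"""Synthetic genomes, reads and minimal mapper/assembler stand-ins.

Generates a reference with planted repeat loci plus *extra-referential*
segments (pentamer-dominated repeat loci flanked by sequence sharing no
50-base substring with the reference), paired 150-base DNA reads and
75-base RNA-like reads, all bit-reproducible under a fixed seed.  The
50-base uniqueness guarantee makes the naive mapper's verdicts exact:
with at most 2 substitutions allowed, any mappable 150-base read must
share an exact 50-mer with the reference.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from gme import _kernels
from gme.concordance import ContigRecord
from gme.motif_families import canonical_family, reverse_complement
from gme.read_prep import Read
from gme.repeat_finder import DEFAULT_PARAMS, find_tandem_repeats

__all__ = [
    "SimulationConfig",
    "PlantedLocus",
    "GroundTruth",
    "simulate_genome",
    "simulate_reads",
    "simulate_rna_reads",
    "naive_map",
    "greedy_assemble",
]

_BASES = "ACGT"
UNIQUENESS_K = 50


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    reference_length: int = 10_000
    n_reference_mst_loci: int = 8
    n_extra_referential_loci: int = 20
    motif_pool: dict = field(
        default_factory=lambda: {
            "AATGG": 0.40,
            "GTGGA": 0.30,
            "AATAC": 0.10,
            "AAGTC": 0.10,
            "ACCTG": 0.10,
        }
    )
    n_samples: int = 6
    read_length: int = 150
    rna_read_length: int = 75
    depth: float = 30.0
    substitution_error_rate: float = 0.001
    n_rate: float = 0.001
    extra_segment_length: int = 500
    extra_tract_copies: int = 10

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "n_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PlantedLocus:
    name: str
    position: int  # within its sequence (reference or segment)
    motif: str
    family: str
    copies: float
    in_reference: bool


@dataclass
class GroundTruth:
    reference: str
    loci: list[PlantedLocus]
    extra_segments: dict[str, str]
    presence: dict[str, set]  # sample_id -> segment names carried

    def segment_for_locus(self, locus: PlantedLocus) -> str | None:
        return None if locus.in_reference else locus.name


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _aperiodic(rng: np.random.Generator, length: int, max_rounds: int = 60) -> str:
    """Random DNA with no interval reaching the repeat-score threshold."""
    seq = _random_dna(rng, length)
    for _ in range(max_rounds):
        hits = find_tandem_repeats(seq)
        if not hits:
            return seq
        chars = list(seq)
        for h in hits:
            lo, hi = max(0, h.start - 2), min(length, h.end + 2)
            chars[lo:hi] = _random_dna(rng, hi - lo)
        seq = "".join(chars)
    raise RuntimeError("could not generate an aperiodic background")


def _kmer_set(sequence: str, k: int) -> set:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def _weighted_choice(rng: np.random.Generator, pool: dict) -> str:
    names = sorted(pool)
    weights = np.array([pool[n] for n in names], dtype=float)
    weights /= weights.sum()
    return names[rng.choice(len(names), p=weights)]


def simulate_genome(config: SimulationConfig):
    """Build (reference, extra segments, ground truth), deterministic per seed.

    The reference is an aperiodic background with ``n_reference_mst_loci``
    planted repeat tracts (kept under 50 bases).  Each extra-referential
    segment carries one pentameric tract with aperiodic flanks and is
    regenerated until it shares no 50-mer with either strand of the
    reference.
    """
    rng = np.random.default_rng([config.seed, 0])
    ref_pool = {"A": 1, "AC": 1, "AAG": 1, "AATC": 1, "AATGG": 1, "AACGGT": 1}
    min_span = 60
    if config.reference_length < config.n_reference_mst_loci * (min_span + 100) + 200:
        raise ValueError("reference too short for the requested number of loci")

    background = _aperiodic(rng, config.reference_length)
    chars = list(background)
    loci: list[PlantedLocus] = []
    occupied: list[tuple[int, int]] = []
    pool_names = sorted(ref_pool)
    for i in range(config.n_reference_mst_loci):
        motif = pool_names[i % len(pool_names)]
        copies = max(math.ceil((len(motif) + 10) / len(motif)), 36 // len(motif))
        tract = motif * copies
        assert len(tract) < UNIQUENESS_K
        for _ in range(200):
            pos = int(rng.integers(50, config.reference_length - 50 - len(tract)))
            if all(pos + len(tract) + 40 < s or pos > e + 40 for s, e in occupied):
                break
        else:
            raise RuntimeError("could not place reference locus")
        chars[pos : pos + len(tract)] = tract
        occupied.append((pos, pos + len(tract)))
        loci.append(
            PlantedLocus(
                name=f"ref_locus_{i + 1}",
                position=pos,
                motif=motif,
                family=canonical_family(motif).name,
                copies=float(copies),
                in_reference=True,
            )
        )

    # clean up junction artefacts: any hit not overlapping a planted tract
    # gets re-randomized
    reference = "".join(chars)
    for _ in range(30):
        stray = [
            h
            for h in find_tandem_repeats(reference)
            if not any(h.start < e + 8 and s - 8 < h.end for s, e in occupied)
        ]
        if not stray:
            break
        chars = list(reference)
        for h in stray:
            chars[h.start : h.end] = _random_dna(rng, h.end - h.start)
        reference = "".join(chars)

    ref_kmers = _kmer_set(reference, UNIQUENESS_K) | _kmer_set(
        reverse_complement(reference), UNIQUENESS_K
    )

    extra_segments: dict[str, str] = {}
    flank_len = (config.extra_segment_length - config.extra_tract_copies * 5) // 2
    if flank_len < 30:
        raise ValueError("extra segments too short for 30-base unique flanks")
    tract_kmers: set = set()  # 31-mers of accepted tracts, both strands
    for i in range(config.n_extra_referential_loci):
        motif = _weighted_choice(rng, config.motif_pool)
        name = f"extra_{i + 1:03d}"
        half = config.extra_tract_copies // 2
        if max(half, config.extra_tract_copies - half) * len(motif) > 25:
            # a pure half-tract of >= 26 bases would let 31-mers avoid the
            # disruptor, voiding the cross-locus uniqueness guarantee
            raise ValueError(
                "extra_tract_copies too large for cross-locus tract uniqueness"
            )
        for _ in range(120):
            # a segment-specific disruptor splits the tract so that no two
            # segments share a 31-mer: cross-locus assembly joins and
            # alignment bridges are impossible by construction
            disruptor = _random_dna(rng, int(rng.integers(1, 4)))
            if disruptor[0] == motif[0] or disruptor[-1] == motif[-1]:
                continue
            tract = motif * half + disruptor + motif * (config.extra_tract_copies - half)
            new_kmers = _kmer_set(tract, 31) | _kmer_set(reverse_complement(tract), 31)
            if new_kmers & tract_kmers:
                continue
            left = _aperiodic(rng, flank_len)
            right = _aperiodic(rng, flank_len)
            segment = left + tract + right
            hits = find_tandem_repeats(segment)
            if len(hits) != 1 or hits[0].family != canonical_family(motif).name:
                continue
            if _kmer_set(segment, UNIQUENESS_K) & ref_kmers:
                continue
            tract_kmers |= new_kmers
            break
        else:
            raise RuntimeError(f"could not build extra-referential segment {name}")
        extra_segments[name] = segment
        loci.append(
            PlantedLocus(
                name=name,
                position=flank_len,
                motif=motif,
                family=canonical_family(motif).name,
                copies=float(config.extra_tract_copies),
                in_reference=False,
            )
        )

    presence = {
        f"S{j + 1}": set(extra_segments) for j in range(config.n_samples)
    }
    return reference, extra_segments, GroundTruth(
        reference=reference, loci=loci, extra_segments=extra_segments, presence=presence
    )


def _sample_rng(config: SimulationConfig, sample_id: str, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(sample_id.encode("ascii")), stream]
    )


def _mutate(rng, sequence: str, error_rate: float, n_rate: float):
    codes = _kernels.encode(sequence).copy()
    n = codes.size
    if error_rate > 0:
        hit = rng.random(n) < error_rate
        idx = np.nonzero(hit)[0]
        if idx.size:
            codes[idx] = (codes[idx] + rng.integers(1, 4, size=idx.size)) % 4
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    quals = np.full(n, q, dtype=np.int64)
    if n_rate > 0:
        mask = rng.random(n) < n_rate
        codes[mask] = _kernels.N_CODE
        quals[mask] = 2
    return _kernels.decode(codes), tuple(int(x) for x in quals)


def simulate_reads(config: SimulationConfig, truth: GroundTruth, sample_id: str):
    """Paired-end reads for one sample; returns (r1, r2, fragment_origins).

    Fragments are drawn uniformly from the reference and from every
    extra-referential segment the sample carries, at the configured fold
    coverage, on a random strand; substitution errors and N-masking are
    applied per base with Phred-consistent qualities.
    """
    rng = _sample_rng(config, sample_id, 1)
    rl = config.read_length
    sources = [("reference", truth.reference)] + [
        (name, truth.extra_segments[name])
        for name in sorted(truth.presence.get(sample_id, ()))
    ]
    r1: list[Read] = []
    r2: list[Read] = []
    origins: list[str] = []
    counter = 0
    for src_name, src in sources:
        if len(src) < rl:
            continue
        n_frags = int(round(config.depth * len(src) / (2 * rl)))
        for _ in range(n_frags):
            max_fl = min(len(src), 2 * rl + 120)
            min_fl = min(len(src), 2 * rl + 20)
            fl = int(rng.integers(min_fl, max_fl + 1)) if max_fl > min_fl else max_fl
            pos = int(rng.integers(0, len(src) - fl + 1))
            frag = src[pos : pos + fl]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            counter += 1
            for mate, raw in ((1, frag[:rl]), (2, reverse_complement(frag[-rl:]))):
                seq, quals = _mutate(
                    rng, raw, config.substitution_error_rate, config.n_rate
                )
                read = Read(
                    id=f"{sample_id}:{counter:06d}/{mate}",
                    sequence=seq,
                    qualities=quals,
                    mate=mate,
                )
                (r1 if mate == 1 else r2).append(read)
            origins.append(src_name)
    return r1, r2, origins


def simulate_rna_reads(
    config: SimulationConfig,
    truth: GroundTruth,
    segments: list[str] | None = None,
    reads_per_segment: int = 40,
):
    """Error-free 75-base RNA-like reads drawn from extra-referential segments."""
    rng = np.random.default_rng([config.seed, 7])
    rl = config.rna_read_length
    names = sorted(truth.extra_segments) if segments is None else list(segments)
    reads: list[Read] = []
    for name in names:
        src = truth.extra_segments[name]
        for i in range(reads_per_segment):
            pos = int(rng.integers(0, len(src) - rl + 1))
            seq = src[pos : pos + rl]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(
                Read(
                    id=f"rna:{name}:{i:04d}",
                    sequence=seq,
                    qualities=(40,) * rl,
                )
            )
    return reads


class _ReferenceIndex:
    """Seed-and-verify substitution mapper over one reference sequence."""

    SEED_K = 16

    def __init__(self, reference: str):
        self.codes = _kernels.encode(reference)
        self.length = len(reference)
        self.index: dict[str, list[int]] = {}
        for i in range(self.length - self.SEED_K + 1):
            self.index.setdefault(reference[i : i + self.SEED_K], []).append(i)

    def maps(self, sequence: str, max_mismatches: int) -> bool:
        for cand in (sequence, reverse_complement(sequence)):
            if self._maps_forward(cand, max_mismatches):
                return True
        return False

    def _maps_forward(self, sequence: str, max_mismatches: int) -> bool:
        n = len(sequence)
        if n > self.length or n < 3 * self.SEED_K:
            return False
        codes = _kernels.encode(sequence)
        third = n // 3
        tried: set[int] = set()
        # with <= max_mismatches substitutions one of the three thirds is
        # exact (pigeonhole for max_mismatches <= 2), so one seed is exact
        for s in (0, third, 2 * third):
            for pos in self.index.get(sequence[s : s + self.SEED_K], ()):
                off = pos - s
                if off < 0 or off + n > self.length or off in tried:
                    continue
                tried.add(off)
                if _kernels.hamming(codes, self.codes[off : off + n]) <= max_mismatches:
                    return True
        return False


def naive_map(reads: list[Read], reference: str, max_mismatches: int = 2):
    """Partition reads into (mapped, unmapped) by <=max_mismatches occurrence.

    A read maps iff it, or its reverse complement, occurs in the
    reference with at most ``max_mismatches`` substitutions (N bases
    always count as mismatches).  Deterministic.
    """
    index = reference if isinstance(reference, _ReferenceIndex) else _ReferenceIndex(reference)
    mapped, unmapped = [], []
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else read
        (mapped if index.maps(seq, max_mismatches) else unmapped).append(read)
    return mapped, unmapped


def _drop_singleton_kmer_reads(seqs, k):
    """Discard reads carrying any strand-canonical k-mer seen only once.

    The coverage-cutoff analogue of a de Bruijn assembler: at the
    simulated depths every true k-mer recurs, so a unique k-mer marks a
    sequencing error.  Error reads otherwise poison greedy extension by
    appending a wrong contig tip that no clean read can overlap.
    """
    from collections import Counter

    counts: Counter = Counter()
    canon_lists = []
    for _rid, s in seqs:
        rc = reverse_complement(s)
        n = len(s)
        canon = [
            min(s[i : i + k], rc[n - k - i : n - i]) for i in range(n - k + 1)
        ]
        canon_lists.append(canon)
        counts.update(canon)
    return [
        pair
        for pair, canon in zip(seqs, canon_lists)
        if all(counts[c] >= 2 for c in canon)
    ]


def greedy_assemble(
    reads,
    min_overlap: int = 31,
    k: int = 71,
    sample_id: str = "sample",
    drop_singleton_kmers: bool = False,
) -> list[ContigRecord]:
    """Greedy maximal-exact-overlap assembly with Velvet-style contig IDs.

    Starting from the longest unused read, contigs are extended in both
    directions by the read (either strand) with the longest exact
    suffix-prefix overlap of at least ``min_overlap`` bases.  Reads fully
    contained in a finished contig are assigned to it.  Per contig,
    k-mer coverage Ck = (total k-mers of assigned reads) / (L - k + 1).
    With ``drop_singleton_kmers`` reads carrying a k-mer observed only
    once are discarded first (error filtering at coverage >= ~10x).
    """
    seqs = [(r.id if isinstance(r, Read) else f"read_{i}",
             (r.sequence if isinstance(r, Read) else r).upper())
            for i, r in enumerate(reads)]
    seqs = [(rid, s) for rid, s in seqs if len(s) >= min_overlap]
    if drop_singleton_kmers:
        seqs = _drop_singleton_kmer_reads(seqs, min_overlap)
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i][1]), seqs[i][1], seqs[i][0]))

    prefix_index: dict[str, list[tuple[int, int]]] = {}
    oriented: list[tuple[str, str]] = []
    for i, (_rid, s) in enumerate(seqs):
        rc = reverse_complement(s)
        oriented.append((s, rc))
        prefix_index.setdefault(s[:min_overlap], []).append((i, 0))
        prefix_index.setdefault(rc[:min_overlap], []).append((i, 1))
    max_read_len = max((len(s) for _, s in seqs), default=0)

    used = [False] * len(seqs)

    def extend_right(contig: str, assigned: list[int]) -> str:
        while True:
            found = False
            top = min(max_read_len - 1, len(contig))
            for o in range(top, min_overlap - 1, -1):
                key = contig[len(contig) - o : len(contig) - o + min_overlap]
                for idx, orient in prefix_index.get(key, ()):
                    if used[idx]:
                        continue
                    r = oriented[idx][orient]
                    if len(r) <= o or not contig.endswith(r[:o]):
                        continue
                    contig += r[o:]
                    used[idx] = True
                    assigned.append(idx)
                    found = True
                    break
                if found:
                    break
            if not found:
                return contig

    contigs: list[ContigRecord] = []
    for seed in order:
        if used[seed]:
            continue
        used[seed] = True
        assigned = [seed]
        contig = seqs[seed][1]
        contig = extend_right(contig, assigned)
        contig = reverse_complement(extend_right(reverse_complement(contig), assigned))
        # sweep containments so interior reads contribute to coverage
        rc_contig = reverse_complement(contig)
        for idx in range(len(seqs)):
            if used[idx]:
                continue
            s = seqs[idx][1]
            if s in contig or s in rc_contig:
                used[idx] = True
                assigned.append(idx)
        total_kmers = sum(max(0, len(seqs[i][1]) - k + 1) for i in assigned)
        denom = len(contig) - k + 1
        ck = total_kmers / denom if denom > 0 else 0.0
        contigs.append(
            ContigRecord(
                sample_id=sample_id,
                node_id=len(contigs) + 1,
                length=len(contig),
                kmer_coverage=ck,
                sequence=contig,
                read_kmer_length=k,
                n_reads=len(assigned),
            )
        )
    return contigs
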