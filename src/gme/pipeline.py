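"""End-to-end orchestration of the unmapped-read analysis on synthetic data.

Per sample: simulate paired reads, quality-trim, map against the
reference, N-filter the unmapped fraction, assemble, classify contigs
against the reference, and annotate repeats with read depths.  Across
samples: build concordant groups and score recovery of the planted
extra-referential loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gme.concordance import (
    ConcordantGroup,
    ContigRecord,
    KnownIndex,
    classify_contigs,
    concordant_groups,
    read_depth,
)
from gme.motif_families import reverse_complement
from gme.read_prep import nfilter_fastq, trim_fastq
from gme.repeat_finder import TandemRepeatHit, find_tandem_repeats
from gme.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    _ReferenceIndex,
    greedy_assemble,
    naive_map,
    simulate_genome,
    simulate_reads,
)

__all__ = ["PipelineResult", "run_pipeline", "evaluate_recovery"]


@dataclass
class PipelineResult:
    truth: GroundTruth
    contigs: list[ContigRecord]
    novel_contigs: list[ContigRecord]
    hits_by_contig: dict[str, list[TandemRepeatHit]]
    groups: list[ConcordantGroup]
    per_sample: dict[str, dict] = field(default_factory=dict)


def _sample_names(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1}" for i in range(config.n_samples)]


def run_pipeline(
    config: SimulationConfig,
    max_mismatches: int = 1,
    min_reads_per_contig: int = 3,
    truth: GroundTruth | None = None,
) -> PipelineResult:
    """Run trim -> map -> N-filter -> assemble -> classify -> concordance."""
    if truth is None:
        _, _, truth = simulate_genome(config)
    index = _ReferenceIndex(truth.reference)
    known = KnownIndex([[truth.reference]])
    all_contigs: list[ContigRecord] = []
    per_sample: dict[str, dict] = {}
    for sample in _sample_names(config):
        r1, r2, _ = simulate_reads(config, truth, sample)
        trimmed, trim_stats = trim_fastq(r1 + r2)
        mapped, unmapped = naive_map(trimmed, index)
        filtered, n_stats = nfilter_fastq(unmapped)
        contigs = [
            c
            for c in greedy_assemble(
                filtered, sample_id=sample, drop_singleton_kmers=True
            )
            if c.n_reads >= min_reads_per_contig
        ]
        all_contigs.extend(contigs)
        per_sample[sample] = {
            "reads": len(r1) + len(r2),
            "trim": trim_stats,
            "mapped": len(mapped),
            "unmapped": len(unmapped),
            "nfilter": n_stats,
            "contigs": len(contigs),
        }
    classify_contigs(all_contigs, known)
    novel = [c for c in all_contigs if c.status == "novel"]

    hits_by_contig: dict[str, list[TandemRepeatHit]] = {}
    for contig in novel:
        hits = find_tandem_repeats(contig.sequence, sequence_id=contig.contig_id)
        depth = read_depth(contig.kmer_coverage, config.read_length, contig.read_kmer_length)
        for h in hits:
            h.sample_id = contig.sample_id
            h.depth = depth
        hits_by_contig[contig.contig_id] = hits

    groups = concordant_groups(novel, max_mismatches=max_mismatches)
    for g in groups:
        g.contains_mst = any(hits_by_contig.get(m.contig_id) for m in g.members)
    return PipelineResult(
        truth=truth,
        contigs=all_contigs,
        novel_contigs=novel,
        hits_by_contig=hits_by_contig,
        groups=groups,
        per_sample=per_sample,
    )


def _flank_kmers(truth: GroundTruth, locus, k: int = 50) -> set:
    """Segment k-mers that touch the unique flanks (both strands).

    K-mers lying entirely inside the repeat tract are excluded: same-motif
    segments share those, so only flank-anchored k-mers identify a
    specific planted locus.
    """
    segment = truth.extra_segments[locus.name]
    tract_start = locus.position
    tract_end = locus.position + int(locus.copies * len(locus.motif))
    out: set = set()
    n = len(segment)
    for i in range(n - k + 1):
        if i >= tract_start and i + k <= tract_end:
            continue
        kmer = segment[i : i + k]
        out.add(kmer)
        out.add(reverse_complement(kmer))
    return out


def _matches_segment(consensus: str, flank_kmers: set, k: int = 50) -> bool:
    return any(consensus[i : i + k] in flank_kmers for i in range(len(consensus) - k + 1))


def evaluate_recovery(result: PipelineResult) -> dict:
    """Score planted-locus recovery and false concordant groups.

    A planted extra-referential locus is recovered when some concordant
    group's consensus shares a 50-mer with its segment and a member
    contig carries a repeat hit of the planted family.  A group matching
    no extra-referential segment at all is a false group (none are
    expected from reference-derived material).
    """
    truth = result.truth
    extra_loci = [l for l in truth.loci if not l.in_reference]
    kmers_by_locus = {l.name: _flank_kmers(truth, l) for l in extra_loci}
    recovered: set[str] = set()
    false_groups: list[str] = []
    for group in result.groups:
        families = {
            h.family
            for m in group.members
            for h in result.hits_by_contig.get(m.contig_id, [])
        }
        matched = False
        for locus in extra_loci:
            if _matches_segment(group.consensus, kmers_by_locus[locus.name]):
                matched = True
                if locus.family in families:
                    recovered.add(locus.name)
        if not matched:
            false_groups.append(group.group_id)
    return {
        "n_planted": len(extra_loci),
        "n_recovered": len(recovered),
        "recovery_fraction": len(recovered) / len(extra_loci) if extra_loci else 0.0,
        "false_groups": false_groups,
        "n_false_groups": len(false_groups),
    }
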