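"""K-mer family depth tables and motif-class statistics.

Repeat hits are grouped into motif families (rotation / reverse
complement equivalence classes) and their read depths summed, giving
one depth value per family per sample.  Period-class fractions and
fold-enrichment ratios summarize the resulting profiles; the telomeric
family AACCCT (canonical name of GGGTTA) gets a named convenience
accessor because its absence is a useful sanity signal.
"""

from __future__ import annotations

import pandas as pd

from gme.motif_families import canonical_family
from gme.repeat_finder import TandemRepeatHit

__all__ = [
    "family_depth_table",
    "class_fractions",
    "fold_enrichment",
    "motif_prevalence",
    "telomeric_family_depth",
    "TELOMERIC_FAMILY",
]

#: canonical family name of the telomeric repeat GGGTTA
TELOMERIC_FAMILY = canonical_family("GGGTTA").name


def family_depth_table(hits: list[TandemRepeatHit], samples: list[str] | None = None) -> pd.DataFrame:
    """Summed read depth per (family, sample); absent combinations are 0."""
    if samples is None:
        samples = sorted({h.sample_id for h in hits if h.sample_id is not None})
    table: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.sample_id is None:
            raise ValueError(f"hit {h.sequence_id} has no sample id")
        if h.depth is None:
            raise ValueError(f"hit {h.sequence_id} has no read depth")
        key = (h.family, h.sample_id)
        table[key] = table.get(key, 0.0) + h.depth
    families = sorted({f for f, _ in table})
    df = pd.DataFrame(0.0, index=families, columns=samples)
    for (fam, sample), depth in table.items():
        if sample in df.columns:
            df.loc[fam, sample] = depth
    df.index.name = "family"
    return df


def class_fractions(
    hits: list[TandemRepeatHit],
    weighting: str = "count",
    source: str = "sample",
) -> pd.Series:
    """Fraction of repeat loci per period class 1-6, normalized to 1.

    ``weighting='count'`` weights each locus equally; ``'depth'`` weights
    by read depth.  The series carries the weighting and source label in
    its attrs.
    """
    if weighting not in ("count", "depth"):
        raise ValueError("weighting must be 'count' or 'depth'")
    if not hits:
        raise ValueError("class_fractions of an empty hit set is undefined")
    totals = {p: 0.0 for p in range(1, 7)}
    for h in hits:
        w = 1.0 if weighting == "count" else float(h.depth if h.depth is not None else 0.0)
        totals[h.period] += w
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("all weights are zero")
    out = pd.Series({p: totals[p] / grand for p in range(1, 7)}, name="fraction")
    out.index.name = "period"
    out.attrs["weighting"] = weighting
    out.attrs["source"] = source
    return out


def fold_enrichment(sample_fraction: float, baseline_fraction: float) -> float:
    """Ratio of a class fraction to a baseline fraction."""
    if baseline_fraction <= 0:
        raise ValueError("baseline fraction must be positive")
    return sample_fraction / baseline_fraction


def motif_prevalence(item_hits: dict[str, list[TandemRepeatHit]], family: str) -> float | None:
    """Fraction of repeat-bearing items (reads/contigs) carrying the family.

    ``item_hits`` maps an item id to its repeat hits.  Items without any
    hit are excluded from the denominator; returns None when no item has
    a hit at all.
    """
    with_any = [hits for hits in item_hits.values() if hits]
    if not with_any:
        return None
    with_family = sum(1 for hits in with_any if any(h.family == family for h in hits))
    return with_family / len(with_any)


def telomeric_family_depth(table: pd.DataFrame) -> pd.Series:
    """Per-sample depth of the telomeric repeat family (0 where absent)."""
    if TELOMERIC_FAMILY in table.index:
        return table.loc[TELOMERIC_FAMILY]
    return pd.Series(0.0, index=table.columns, name=TELOMERIC_FAMILY)
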