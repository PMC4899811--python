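"""Canonical representation of microsatellite motif families.

A microsatellite motif is a 1-6 base repeat unit.  Two motifs belong to
the same *family* when they are cyclic rotations of one another, or when
one is a cyclic rotation of the other's reverse complement -- a repeat
tract read on either strand, at any phase, yields the same family.  The
family is named by its lexicographically smallest member so that names
are stable across samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

ALPHABET = "ACGT"
MAX_PERIOD = 6

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: a motif is just a plain string over {A,C,G,T}; the alias documents intent
Motif = str


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> str:
    if not isinstance(motif, str) or not motif:
        raise ValueError("motif must be a non-empty string")
    if len(motif) > MAX_PERIOD:
        raise ValueError(
            f"motif {motif!r} is {len(motif)} bases long; the maximum period is {MAX_PERIOD}"
        )
    motif = motif.upper()
    for ch in motif:
        if ch not in ALPHABET:
            raise ValueError(f"invalid character {ch!r} in motif {motif!r}; alphabet is ACGT")
    return motif


@dataclass(frozen=True)
class MotifFamily:
    """An equivalence class of motifs under rotation and reverse complement."""

    name: str
    members: frozenset[str]
    period: int

    def __post_init__(self) -> None:
        if self.name not in self.members:
            raise ValueError("family name must be a member")
        if self.name != min(self.members):
            raise ValueError("family name must be the lexicographically smallest member")
        if not 1 <= self.period <= MAX_PERIOD:
            raise ValueError("period must be 1-6")


def rotations(motif: Motif) -> frozenset[str]:
    """All distinct cyclic rotations of ``motif``, including itself."""
    motif = _validate_motif(motif)
    doubled = motif + motif
    return frozenset(doubled[i : i + len(motif)] for i in range(len(motif)))


def family_members(motif: Motif) -> frozenset[str]:
    """Members of the motif's family: rotations of it and of its reverse complement."""
    motif = _validate_motif(motif)
    return rotations(motif) | rotations(reverse_complement(motif))


def canonical_family(motif: Motif) -> MotifFamily:
    """The family containing ``motif``, named by its smallest member.

    Deterministic: any member of a family maps to the identical
    :class:`MotifFamily`.
    """
    members = family_members(motif)
    return MotifFamily(name=min(members), members=members, period=len(motif))


def is_primitive(motif: Motif) -> bool:
    """True iff the motif is not a whole-number concatenation of a shorter motif."""
    motif = _validate_motif(motif)
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def enumerate_families(period: int, primitive_only: bool = False) -> list[MotifFamily]:
    """Exhaustive, duplicate-free list of motif families of the given period.

    Families are sorted by canonical name.  With ``primitive_only`` the
    families whose canonical motif is a repetition of a shorter motif
    (e.g. ``ATAT``) are excluded, so every repeat tract is attributed to
    exactly one period.
    """
    if not 1 <= period <= MAX_PERIOD:
        raise ValueError(f"period must be between 1 and {MAX_PERIOD}, got {period}")
    seen: dict[str, MotifFamily] = {}
    for tup in itertools.product(ALPHABET, repeat=period):
        motif = "".join(tup)
        fam = canonical_family(motif)
        if fam.name not in seen:
            seen[fam.name] = fam
    families = [f for f in seen.values() if not primitive_only or is_primitive(f.name)]
    return sorted(families, key=lambda f: f.name)


def all_primitive_families(max_period: int = MAX_PERIOD) -> list[MotifFamily]:
    """Primitive families for every period 1..max_period, period-major order."""
    out: list[MotifFamily] = []
    for p in range(1, max_period + 1):
        out.extend(enumerate_families(p, primitive_only=True))
    return out


def families_table(families: list[MotifFamily]) -> pd.DataFrame:
    """Tabular export: family_name, period, member_count, members (comma-joined)."""
    rows = [
        {
            "family_name": f.name,
            "period": f.period,
            "member_count": len(f.members),
            "members": ",".join(sorted(f.members)),
        }
        for f in families
    ]
    return pd.DataFrame(rows, columns=["family_name", "period", "member_count", "members"])
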