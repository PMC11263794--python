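"""In-silico construction of the observable histone peptide space.

Propionylation of free lysine amines blocks tryptic cleavage at K, so the
digest behaves like Arg-C: fully specific cleavage after arginine (never
before proline). This module builds the peptide space over a histone FASTA
database, computes monoisotopic masses with derivatization-aware deltas,
groups proteins by shared observable peptides, and filters PSM tables by
search-engine confidence thresholds.

Coordinates are 1-based inclusive on the mature sequence (initiator Met
removed), the conventional histone numbering in which H3 "K27" is residue 27.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pmass

from .errors import (
    ConsistencyError,
    InvalidModificationError,
    InvalidSequenceError,
    SchemaError,
)

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of water (peptide termini), Da.
WATER = 18.0105646837

#: Monoisotopic residue masses, Da.
RESIDUE_MASS = dict(_pmass.std_aa_mass)

#: Monoisotopic modification deltas, Da.
MOD_DELTA = {
    "ac": 42.01057,
    "me1": 14.01565,
    "me2": 28.03130,
    "me3": 42.04695,
    "ph": 79.96633,
    "prop": 56.02621,
}

#: Residues each modification may sit on.  Propionylation additionally
#: targets the peptide N-terminus, handled by ``nterm_prop``.
MOD_TARGETS = {
    "ac": set("K"),
    "me1": set("KR"),
    "me2": set("K"),
    "me3": set("K"),
    "ph": set("ST"),
    "prop": set("KSTY"),
}

PROTON = 1.00728


class Family(str, Enum):
    H2A_W = "H2A.W"
    H2A_Z = "H2A.Z"
    H2A_X = "H2A.X"
    H2A = "H2A"
    H3 = "H3"
    H4 = "H4"
    H1 = "H1"
    OTHER = "other"


@dataclass(frozen=True)
class ProteinEntry:
    """One histone database entry, with mature (Met-stripped) sequence."""

    id: str
    display_name: str
    family: Family
    sequence: str
    raw_sequence: str


@dataclass
class Peptide:
    """A proteolytic peptide located on one or more parent proteins.

    ``start``/``end`` are 1-based inclusive coordinates on the mature
    sequence of the parents.
    """

    parent_ids: frozenset[str]
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise InvalidSequenceError(
                f"coordinates {self.start}-{self.end} do not span "
                f"{len(self.sequence)} residues"
            )

    @property
    def is_unique(self) -> bool:
        return len(self.parent_ids) == 1


@dataclass(frozen=True)
class Peptidoform:
    """A peptide with site-localized modifications and derivatization state.

    ``modifications`` holds (mature-numbering position, kind) pairs. A K may
    carry ``prop`` together with ``me1`` (propionyl on monomethyl-lysine);
    otherwise one kind per site.
    """

    peptide: Peptide
    modifications: tuple[tuple[int, str], ...] = ()
    nterm_prop: bool = False
    charge: Optional[int] = None

    def validate(self) -> None:
        seen: dict[int, list[str]] = {}
        for pos, kind in self.modifications:
            if kind not in MOD_DELTA:
                raise InvalidModificationError(f"unknown modification kind {kind!r}")
            if not (self.peptide.start <= pos <= self.peptide.end):
                raise InvalidModificationError(
                    f"{kind}@{pos} outside peptide {self.peptide.start}-{self.peptide.end}"
                )
            residue = self.peptide.sequence[pos - self.peptide.start]
            if residue not in MOD_TARGETS[kind]:
                raise InvalidModificationError(
                    f"{kind} not allowed on {residue}{pos}"
                )
            seen.setdefault(pos, []).append(kind)
        for pos, kinds in seen.items():
            if len(kinds) > 1 and set(kinds) != {"prop", "me1"}:
                raise InvalidModificationError(
                    f"conflicting modifications {kinds} at position {pos}"
                )


@dataclass
class ProteinGroup:
    """Proteins indistinguishable by their observable peptide sets."""

    member_ids: frozenset[str]
    has_unique_evidence: bool
    display_name: str = ""
    family: Family = Family.OTHER


@dataclass
class PsmRecord:
    """One peptide-spectrum match with search-engine confidence scores."""

    peptidoform: Peptidoform
    ion_score: float
    expectation: float
    rank: int
    sample_id: str
    area: Optional[float] = None


def strip_initiator_met(raw_sequence: str) -> str:
    """Remove a leading initiator methionine to obtain the mature sequence.

    Histone numbering conventions (H3 K27, K36 ...) refer to the mature
    protein, so all downstream coordinates use the returned sequence.
    """
    if not raw_sequence:
        raise InvalidSequenceError("empty sequence")
    for i, aa in enumerate(raw_sequence):
        if aa not in STANDARD_AA:
            raise InvalidSequenceError(
                f"non-standard residue {aa!r} at position {i + 1}"
            )
    if raw_sequence.startswith("M"):
        return raw_sequence[1:]
    return raw_sequence


def _argc_segments(sequence: str) -> list[tuple[int, int]]:
    """0-missed-cleavage segments as (start, end) 1-based inclusive."""
    boundaries = []
    for i, aa in enumerate(sequence):
        if aa == "R" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            boundaries.append(i + 1)  # cut after residue i (1-based end)
    if not boundaries or boundaries[-1] != len(sequence):
        boundaries.append(len(sequence))
    segments = []
    prev = 0
    for b in boundaries:
        segments.append((prev + 1, b))
        prev = b
    return segments


def digest_argc(sequence: str, max_missed: int = 2) -> list[Peptide]:
    """Fully specific Arg-C digestion: cleave after R except before P.

    Lysines never cleave because their side chains are propionylated.
    Returns every peptide with at most ``max_missed`` internal missed
    cleavage sites, ordered by start then length.
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_AA:
            raise InvalidSequenceError(
                f"non-standard residue {aa!r} at position {i + 1}"
            )
    segments = _argc_segments(sequence)
    peptides = []
    for i in range(len(segments)):
        for k in range(max_missed + 1):
            j = i + k
            if j >= len(segments):
                break
            start = segments[i][0]
            end = segments[j][1]
            peptides.append(
                Peptide(
                    parent_ids=frozenset(),
                    start=start,
                    end=end,
                    sequence=sequence[start - 1 : end],
                    missed_cleavages=k,
                )
            )
    return peptides


def monoisotopic_mass(
    peptidoform: Peptidoform, assume_full_derivatization: bool = False
) -> float:
    """Monoisotopic peptidoform mass in Da.

    Sum of residue masses plus water plus modification deltas. Under
    ``assume_full_derivatization`` one propionyl group is added for the
    peptide N-terminus and for every lysine with a free amine (unmodified
    or monomethylated); acetylated, di- and trimethylated lysines are
    blocked and receive none.
    """
    peptidoform.validate()
    pep = peptidoform.peptide
    total = sum(RESIDUE_MASS[aa] for aa in pep.sequence) + WATER
    total += sum(MOD_DELTA[kind] for _, kind in peptidoform.modifications)
    if peptidoform.nterm_prop:
        total += MOD_DELTA["prop"]
    if assume_full_derivatization:
        modded = {}
        for pos, kind in peptidoform.modifications:
            modded.setdefault(pos, set()).add(kind)
        if not peptidoform.nterm_prop:
            total += MOD_DELTA["prop"]
        for offset, aa in enumerate(pep.sequence):
            if aa != "K":
                continue
            kinds = modded.get(pep.start + offset, set())
            if not kinds or kinds == {"me1"}:
                total += MOD_DELTA["prop"]
    return total


def peptide_mass_shift(form_a: Peptidoform, form_b: Peptidoform) -> float:
    """Mass difference form_b - form_a in Da (e.g. H3.3 vs H3.1 K27-R40)."""
    return monoisotopic_mass(form_b) - monoisotopic_mass(form_a)


def mz(mass_da: float, charge: int) -> float:
    """m/z of a peptidoform mass at a given positive charge state."""
    return (mass_da + charge * PROTON) / charge


def assign_protein_groups(
    db: Sequence[ProteinEntry], peptides: Sequence[Peptide]
) -> list[ProteinGroup]:
    """Group proteins by identical observable peptide sets; flag groups
    with no unique peptide.

    Proteins whose full observable peptide set coincides are merged into one
    group (they are indistinguishable in the mass spectrum). Each peptide's
    ``parent_ids`` is updated to the accessions whose mature sequence
    contains it at the stated coordinates. A group none of whose peptides is
    exclusive to it carries ``has_unique_evidence=False`` and is excluded
    from downstream variant quantification.
    """
    by_id = {p.id: p for p in db}
    for pep in peptides:
        for pid in pep.parent_ids:
            if pid and pid not in by_id:
                raise ConsistencyError(f"peptide references unknown accession {pid}")

    # Observable peptide sequences per protein.
    seqs_by_protein: dict[str, frozenset[str]] = {}
    pep_seqs = {p.sequence for p in peptides}
    for prot in db:
        owned = frozenset(s for s in pep_seqs if s in prot.sequence)
        seqs_by_protein[prot.id] = owned

    # Update parent assignments on the peptides.
    for pep in peptides:
        parents = frozenset(
            pid for pid, seqs in seqs_by_protein.items() if pep.sequence in seqs
        )
        pep.parent_ids = parents

    # Merge proteins with identical observable sets.
    groups_by_key: dict[frozenset[str], list[str]] = {}
    for prot in db:
        groups_by_key.setdefault(seqs_by_protein[prot.id], []).append(prot.id)

    groups = []
    for key, members in groups_by_key.items():
        member_set = frozenset(members)
        other = set()
        for other_key, other_members in groups_by_key.items():
            if other_key is not key:
                other |= other_key
        unique = bool(key - frozenset(other))
        name = "/".join(sorted(by_id[m].display_name for m in members))
        family = by_id[sorted(members)[0]].family
        if not unique:
            logger.warning(
                "protein group %s has no unique peptide; excluded from "
                "variant quantification",
                name,
            )
        groups.append(
            ProteinGroup(
                member_ids=member_set,
                has_unique_evidence=unique,
                display_name=name,
                family=family,
            )
        )
    groups.sort(key=lambda g: g.display_name)
    return groups


def filter_psms(
    records: Sequence[PsmRecord],
    min_score: float = 30.0,
    max_expect: float = 0.01,
    required_rank: int = 1,
) -> list[PsmRecord]:
    """Keep PSMs at the required rank with expectation < max_expect and
    ion score >= min_score (inclusive), preserving order."""
    kept = []
    for i, rec in enumerate(records):
        if rec.ion_score is None or rec.expectation is None:
            raise SchemaError(f"record {i} missing score or expectation")
        if (
            rec.rank == required_rank
            and rec.expectation < max_expect
            and rec.ion_score >= min_score
        ):
            kept.append(rec)
    logger.info("filter_psms: removed %d of %d records", len(records) - len(kept), len(records))
    return kept


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a histone FASTA database.

    The description line is parsed as ``>accession display_name ...``
    with an optional ``family=`` token; an unparseable family defaults
    to "other".
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        family = Family.OTHER
        display = rec.id
        for token in rec.description.split()[1:]:
            if token.startswith("family="):
                try:
                    family = Family(token.split("=", 1)[1])
                except ValueError:
                    family = Family.OTHER
            elif display == rec.id:
                display = token
        entries.append(
            ProteinEntry(
                id=rec.id,
                display_name=display,
                family=family,
                sequence=strip_initiator_met(raw),
                raw_sequence=raw,
            )
        )
    return entries


def build_peptide_map(
    db: Sequence[ProteinEntry], max_missed: int = 2
) -> tuple[pd.DataFrame, list[ProteinGroup], list[Peptide]]:
    """Digest every database entry and tabulate the observable peptide space.

    Returns a tidy table (one row per distinct peptide sequence), the
    protein groups, and the peptide objects with parent assignments.
    """
    seen: dict[str, Peptide] = {}
    for prot in db:
        for pep in digest_argc(prot.sequence, max_missed):
            if pep.sequence not in seen:
                pep.parent_ids = frozenset({prot.id})
                seen[pep.sequence] = pep
    peptides = list(seen.values())
    groups = assign_protein_groups(db, peptides)
    group_of = {}
    for g in groups:
        for m in g.member_ids:
            group_of[m] = g

    rows = []
    for pep in sorted(peptides, key=lambda p: (p.start, p.end, p.sequence)):
        parent_groups = {group_of[pid].display_name for pid in pep.parent_ids}
        bare = monoisotopic_mass(Peptidoform(pep))
        deriv = monoisotopic_mass(Peptidoform(pep), assume_full_derivatization=True)
        rows.append(
            {
                "accessions": ";".join(sorted(pep.parent_ids)),
                "groups": ";".join(sorted(parent_groups)),
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "missed_cleavages": pep.missed_cleavages,
                "unique": len(parent_groups) == 1,
                "bare_mass": round(bare, 4),
                "derivatized_mass": round(deriv, 4),
            }
        )
    return pd.DataFrame(rows), groups, peptides
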