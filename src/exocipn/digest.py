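"""In-silico tryptic digestion, reverse-decoy databases and peptide mapping.

Fully tryptic digestion cleaves C-terminal to K or R except when the next
residue is proline (the classical suppressed-KP convention used by common
search engines).  Decoy databases are built by reversing each target sequence
and prefixing the accession with a reserved tag, so a concatenated
target+decoy search supports target-decoy FDR estimation downstream.

Peptide-to-protein mapping first merges proteins whose digests are
indistinguishable (identical peptide sets) into deterministic groups; a
peptide is *unique* when it maps to exactly one such group.  Unique peptides
are the currency of both quantification tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 standard residues plus X for unknown.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DECOY_PREFIX = "DECOY_"

DEFAULT_MIN_LENGTH = 7


@dataclass(frozen=True)
class ProteinEntry:
    """A single FASTA entry: unique accession plus amino-acid sequence."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(
                f"protein {self.accession!r} has an empty sequence"
            )
        _validate_sequence(self.sequence)


@dataclass(frozen=True)
class PeptideMapping:
    """A peptide with its parent protein-group set and uniqueness status."""

    peptide: str
    parents: frozenset[str]
    is_unique: bool

    def __post_init__(self) -> None:
        if self.is_unique != (len(self.parents) == 1):
            raise ValueError(
                f"peptide {self.peptide!r}: is_unique inconsistent with "
                f"{len(self.parents)} parents"
            )


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(
            "sequence contains non-amino-acid symbol(s): "
            + ", ".join(repr(c) for c in sorted(bad))
        )


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cleaves (K/R not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    missed_cleavages: int = 0,
) -> list[str]:
    """Fully tryptic peptides of ``sequence`` in order of position.

    Cleaves C-terminal to K or R except before P.  Only peptides of length
    >= ``min_length`` are returned.  With ``missed_cleavages`` > 0,
    concatenations spanning up to that many internal cleavage sites are also
    produced.  Ordering is by start position, then by span.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    if not 0 <= missed_cleavages <= 2:
        raise ValueError(
            f"missed_cleavages must be in [0, 2], got {missed_cleavages}"
        )
    _validate_sequence(sequence)

    bounds = [0, *cleavage_sites(sequence), len(sequence)]
    fragments = [
        sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)
    ]
    peptides: list[str] = []
    for i in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if i + span > len(fragments):
                break
            pep = "".join(fragments[i : i + span])
            if len(pep) >= min_length:
                peptides.append(pep)
    return peptides


def reverse_decoy(
    db: Sequence[ProteinEntry], prefix: str = DECOY_PREFIX
) -> list[ProteinEntry]:
    """One reversed-sequence decoy per target, accession tagged with ``prefix``.

    The result is concatenable with the target database.  Palindromic targets
    yield decoys identical to themselves; this is allowed but logged.
    """
    if not db:
        raise ValueError("cannot build a decoy database from an empty database")
    for entry in db:
        if entry.accession.startswith(prefix):
            raise ValueError(
                f"accession {entry.accession!r} already carries the decoy "
                f"tag {prefix!r}"
            )
    decoys = []
    for entry in db:
        rev = entry.sequence[::-1]
        if rev == entry.sequence:
            logger.info(
                "palindromic sequence: decoy for %s equals its target",
                entry.accession,
            )
        decoys.append(
            ProteinEntry(
                accession=prefix + entry.accession,
                sequence=rev,
                description=f"reversed {entry.accession}",
            )
        )
    return decoys


def is_decoy_accession(accession: str, prefix: str = DECOY_PREFIX) -> bool:
    return accession.startswith(prefix)


def group_indistinguishable(
    db: Sequence[ProteinEntry],
    min_length: int = DEFAULT_MIN_LENGTH,
    missed_cleavages: int = 0,
    equate_il: bool = False,
) -> dict[str, frozenset[str]]:
    """Map each group accession to its peptide set.

    Proteins whose digests yield identical peptide sets are merged into one
    group whose accession is the sorted, ';'-joined member accessions, so the
    grouping is deterministic and reproducible.
    """
    if not db:
        raise ValueError("cannot map peptides of an empty database")
    seen: dict[str, None] = {}
    for entry in db:
        if entry.accession in seen:
            raise ValueError(f"duplicate accession {entry.accession!r}")
        seen[entry.accession] = None

    by_pepset: dict[frozenset[str], list[str]] = {}
    for entry in db:
        peps = tryptic_digest(entry.sequence, min_length, missed_cleavages)
        if equate_il:
            peps = [p.replace("I", "L") for p in peps]
        by_pepset.setdefault(frozenset(peps), []).append(entry.accession)

    return {
        ";".join(sorted(members)): pepset
        for pepset, members in by_pepset.items()
    }


def map_peptides(
    db: Sequence[ProteinEntry],
    min_length: int = DEFAULT_MIN_LENGTH,
    missed_cleavages: int = 0,
    equate_il: bool = False,
) -> list[PeptideMapping]:
    """Every distinct digest peptide with its parent groups and uniqueness.

    With ``equate_il`` the mapping treats isoleucine and leucine as the same
    residue (peptides are stored with I replaced by L); off by default,
    matching sequence-database semantics.
    """
    groups = group_indistinguishable(db, min_length, missed_cleavages, equate_il)
    parents: dict[str, set[str]] = {}
    for group_acc, pepset in groups.items():
        for pep in pepset:
            parents.setdefault(pep, set()).add(group_acc)
    return [
        PeptideMapping(
            peptide=pep,
            parents=frozenset(par),
            is_unique=len(par) == 1,
        )
        for pep, par in sorted(parents.items())
    ]


# ---------------------------------------------------------------------------
# FASTA and TSV interfaces
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[ProteinEntry]:
    entries = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate accession {record.id!r} in FASTA")
        seen.add(record.id)
        desc = record.description
        if desc.startswith(record.id):
            desc = desc[len(record.id) :].strip()
        entries.append(
            ProteinEntry(
                accession=record.id,
                sequence=str(record.seq).upper(),
                description=desc,
            )
        )
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path) -> None:
    records = [
        SeqRecord(
            Seq(e.sequence), id=e.accession, description=e.description or ""
        )
        for e in entries
    ]
    # SeqIO's fasta writer wraps sequence lines at 60 columns.
    SeqIO.write(records, str(path), "fasta")


def write_peptide_map(mappings: Sequence[PeptideMapping], path) -> None:
    """TSV with columns peptide, parents (';'-joined, sorted), is_unique (0/1)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tparents\tis_unique\n")
        for m in mappings:
            fh.write(
                f"{m.peptide}\t{';'.join(sorted(m.parents))}\t"
                f"{1 if m.is_unique else 0}\n"
            )


def read_peptide_map(path) -> list[PeptideMapping]:
    mappings = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["peptide", "parents", "is_unique"]:
            raise ValueError(f"unexpected peptide-map header: {header}")
        for line in fh:
            pep, par, uniq = line.rstrip("\n").split("\t")
            mappings.append(
                PeptideMapping(
                    peptide=pep,
                    parents=frozenset(par.split(";")),
                    is_unique=uniq == "1",
                )
            )
    return mappings
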