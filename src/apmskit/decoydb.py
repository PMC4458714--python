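"""Search-database construction: targets, contaminants, reversed decoys.

A search database is the concatenation of an organism database, a
contaminant database, and the whole-sequence reversal of every forward
entry.  Decoy entries carry a reserved accession prefix (``REV_`` by
default) so that downstream peptide-spectrum matches can be classified as
target or decoy by accession alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_DECOY_PREFIX = "REV_"

# the 20 standard residues
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DbEntry:
    """One database sequence with provenance flags."""

    accession: str
    sequence: str
    origin: str = "organism"  # "organism" | "contaminant"
    is_decoy: bool = False
    description: str = ""


@dataclass
class SequenceDatabase:
    """Ordered collection of protein entries with unique accessions."""

    entries: list[DbEntry] = field(default_factory=list)
    decoy_prefix: str = DEFAULT_DECOY_PREFIX

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DbEntry]:
        return iter(self.entries)

    @property
    def forward_entries(self) -> list[DbEntry]:
        return [e for e in self.entries if not e.is_decoy]

    @property
    def decoy_entries(self) -> list[DbEntry]:
        return [e for e in self.entries if e.is_decoy]

    def validate(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValueError(f"duplicate accession: {e.accession!r}")
            seen.add(e.accession)
            if not e.sequence:
                raise ValueError(f"empty sequence for accession {e.accession!r}")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        origin: str = "organism",
        decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    ) -> "SequenceDatabase":
        """Read a FASTA file; decoy status is inferred from the prefix."""
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            entries.append(
                DbEntry(
                    accession=rec.id,
                    sequence=str(rec.seq).upper(),
                    origin=origin,
                    is_decoy=rec.id.startswith(decoy_prefix),
                    description=desc,
                )
            )
        db = cls(entries, decoy_prefix=decoy_prefix)
        db.validate()
        return db

    def to_fasta(self, path: str | Path) -> None:
        """Write 60-column wrapped FASTA."""
        records = [
            SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
            for e in self.entries
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def build_decoy_database(
    organism_db: SequenceDatabase,
    contaminant_db: SequenceDatabase,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> SequenceDatabase:
    """Concatenate forward entries and append whole-sequence reversed decoys.

    Output order is the forward block (organism then contaminants, input
    order preserved) followed by the decoy block in the same order, so the
    result has exactly ``2 * (len(organism_db) + len(contaminant_db))``
    entries.

    Raises
    ------
    ValueError
        If an accession is duplicated across the inputs, an input entry is
        already a decoy, or a sequence is empty.
    """
    forwards: list[DbEntry] = []
    for db, origin in ((organism_db, "organism"), (contaminant_db, "contaminant")):
        for e in db.entries:
            if e.is_decoy or e.accession.startswith(decoy_prefix):
                raise ValueError(
                    f"input entry {e.accession!r} already carries the decoy prefix"
                )
            forwards.append(replace(e, origin=origin))

    seen: set[str] = set()
    for e in forwards:
        if e.accession in seen:
            raise ValueError(f"duplicate accession: {e.accession!r}")
        if not e.sequence:
            raise ValueError(f"empty sequence for accession {e.accession!r}")
        seen.add(e.accession)

    decoys = [
        DbEntry(
            accession=decoy_prefix + e.accession,
            sequence=e.sequence[::-1],
            origin=e.origin,
            is_decoy=True,
            description=e.description,
        )
        for e in forwards
    ]
    out = SequenceDatabase(forwards + decoys, decoy_prefix=decoy_prefix)
    out.validate()
    return out


def strip_decoys(db: SequenceDatabase) -> SequenceDatabase:
    """Return the forward block only (inverse of decoy construction)."""
    return SequenceDatabase(db.forward_entries, decoy_prefix=db.decoy_prefix)


# Cleavage after K or R, not before P (trypsin with the proline rule).
_TRYPTIC_SITE = re.compile(r"(?<=[KR])(?!P)")


@dataclass(frozen=True)
class TrypticPeptide:
    """A digestion product with per-terminus tryptic context."""

    peptide: str
    nterm_tryptic: bool
    cterm_tryptic: bool
    missed_cleavages: int

    @property
    def ntt(self) -> int:
        return int(self.nterm_tryptic) + int(self.cterm_tryptic)


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 2,
    proline_rule: bool = True,
    min_length: int = 1,
    on_nonstandard: str = "reject",
) -> list[TrypticPeptide]:
    """Digest a protein sequence with tryptic specificity.

    Cleavage occurs after K or R; with ``proline_rule`` a site followed by P
    is suppressed.  Protein termini count as tryptic.  Peptides containing
    up to ``missed_cleavages`` internal sites are returned.

    Parameters
    ----------
    on_nonstandard:
        ``"reject"`` raises on a residue outside the 20-letter alphabet,
        ``"skip"`` silently drops peptides containing one.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if on_nonstandard not in ("reject", "skip"):
        raise ValueError("on_nonstandard must be 'reject' or 'skip'")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad and on_nonstandard == "reject":
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")

    if proline_rule:
        fragments = _TRYPTIC_SITE.split(sequence)
    else:
        fragments = re.split(r"(?<=[KR])", sequence)
        fragments = [f for f in fragments if f]

    n = len(fragments)
    peptides: list[TrypticPeptide] = []
    for i in range(n):
        for j in range(i, min(n, i + missed_cleavages + 1)):
            pep = "".join(fragments[i : j + 1])
            if len(pep) < min_length:
                continue
            if bad and set(pep) & bad:
                continue
            peptides.append(
                TrypticPeptide(
                    peptide=pep,
                    nterm_tryptic=True,  # fully tryptic by construction
                    cterm_tryptic=True,
                    missed_cleavages=j - i,
                )
            )
    return peptides


def iter_database_peptides(
    db: SequenceDatabase,
    missed_cleavages: int = 2,
    min_length: int = 6,
    proline_rule: bool = True,
) -> Iterable[tuple[str, str]]:
    """Yield (peptide, accession) pairs over the whole database digest."""
    for entry in db.entries:
        for tp in digest_tryptic(
            entry.sequence,
            missed_cleavages=missed_cleavages,
            min_length=min_length,
            proline_rule=proline_rule,
            on_nonstandard="skip",
        ):
            yield tp.peptide, entry.accession
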