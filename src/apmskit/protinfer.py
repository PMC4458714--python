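"""Parsimonious protein inference from confident peptides.

Confident peptides are mapped back to the database, proteins sharing an
identical peptide set are merged into one group, groups whose peptide set
is a formal subset of another group's are removed, and groups lacking two
distinct at-least-half-tryptic peptides in any single sample are dropped.
Protein-level FDR is the decoy/target ratio among survivors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .decoydb import SequenceDatabase, iter_database_peptides
from .psmfilter import PSMRecord

logger = logging.getLogger(__name__)


@dataclass
class ProteinGroup:
    """Accessions sharing one confident peptide set, with per-sample evidence.

    ``evidence`` maps sample id to {peptide: max ntt observed in that
    sample}.  ``is_decoy`` is true only if every member accession is a
    decoy (mixed groups resolve to target, conservative).
    """

    accessions: list[str]
    peptide_set: frozenset[str]
    evidence: dict[str, dict[str, int]] = field(default_factory=dict)
    is_decoy: bool = False

    @property
    def group_id(self) -> str:
        return self.accessions[0]

    def distinct_peptides(self) -> int:
        return len(self.peptide_set)


@dataclass
class InferenceResult:
    groups: list[ProteinGroup]
    unmapped_peptides: list[str]
    peptide_to_groups: dict[str, list[str]] = field(default_factory=dict)


def build_peptide_index(
    database: SequenceDatabase,
    missed_cleavages: int = 2,
    min_length: int = 6,
) -> dict[str, set[str]]:
    """Peptide -> set of accessions over the tryptic digest of the database."""
    index: dict[str, set[str]] = {}
    for pep, acc in iter_database_peptides(
        database, missed_cleavages=missed_cleavages, min_length=min_length
    ):
        index.setdefault(pep, set()).add(acc)
    return index


def map_and_group(
    confident_psms: Sequence[PSMRecord],
    database: SequenceDatabase,
    peptide_index: dict[str, set[str]] | None = None,
    missed_cleavages: int = 2,
) -> InferenceResult:
    """Map confident peptides to accessions and merge identical peptide sets.

    I and L are treated as distinct residues.  Peptides absent from the
    digest index fall back to a substring scan of the database; peptides
    still unmapped are excluded and listed in the result.
    """
    if peptide_index is None:
        peptide_index = build_peptide_index(database, missed_cleavages, min_length=1)

    peptides = sorted({r.peptide for r in confident_psms})
    pep_to_acc: dict[str, set[str]] = {}
    unmapped: list[str] = []
    seq_by_acc = {e.accession: e.sequence for e in database.entries}
    for pep in peptides:
        accs = set(peptide_index.get(pep, ()))
        if not accs:
            accs = {a for a, s in seq_by_acc.items() if pep in s}
        if accs:
            pep_to_acc[pep] = accs
        else:
            unmapped.append(pep)
    if unmapped:
        logger.warning("%d confident peptides did not map to the database", len(unmapped))

    # protein -> peptide set, restricted to confident peptides
    prot_peps: dict[str, set[str]] = {}
    for pep, accs in pep_to_acc.items():
        for acc in accs:
            prot_peps.setdefault(acc, set()).add(pep)

    # merge proteins with identical peptide sets
    by_set: dict[frozenset[str], list[str]] = {}
    for acc in sorted(prot_peps):
        by_set.setdefault(frozenset(prot_peps[acc]), []).append(acc)

    prefix = database.decoy_prefix
    groups = []
    for pset, accs in sorted(by_set.items(), key=lambda kv: kv[1]):
        groups.append(
            ProteinGroup(
                accessions=accs,
                peptide_set=pset,
                is_decoy=all(a.startswith(prefix) for a in accs),
            )
        )
    attach_evidence(groups, confident_psms)
    p2g = {
        pep: sorted(g.group_id for g in groups if pep in g.peptide_set)
        for pep in pep_to_acc
    }
    return InferenceResult(groups=groups, unmapped_peptides=unmapped, peptide_to_groups=p2g)


def attach_evidence(
    groups: Iterable[ProteinGroup], confident_psms: Sequence[PSMRecord]
) -> None:
    """Fill per-sample {peptide: max ntt} evidence maps, in place."""
    for g in groups:
        g.evidence = {}
    by_pep: dict[str, list[PSMRecord]] = {}
    for r in confident_psms:
        by_pep.setdefault(r.peptide, []).append(r)
    for g in groups:
        for pep in g.peptide_set:
            for r in by_pep.get(pep, ()):
                samp = g.evidence.setdefault(r.sample_id, {})
                samp[pep] = max(samp.get(pep, -1), r.ntt)


def apply_parsimony(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Remove groups whose peptide set is a proper subset of another's.

    Order-independent: the surviving set depends only on the peptide sets.
    Every peptide of a removed group remains covered by a superset group.
    """
    survivors = []
    for g in groups:
        subsumed = any(
            g.peptide_set < other.peptide_set for other in groups if other is not g
        )
        if not subsumed:
            survivors.append(g)
    return survivors


def two_peptide_filter(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Keep groups with >=2 distinct ntt>=1 peptides in at least one sample."""
    out = []
    for g in groups:
        ok = any(
            sum(1 for ntt in peps.values() if ntt >= 1) >= 2
            for peps in g.evidence.values()
        )
        if ok:
            out.append(g)
    return out


def protein_fdr(groups: Sequence[ProteinGroup]) -> float:
    """Decoy/target group ratio; NaN (with a warning) if no target groups."""
    n_decoy = sum(1 for g in groups if g.is_decoy)
    n_target = len(groups) - n_decoy
    if n_target == 0:
        logger.warning("no target groups among survivors; protein FDR undefined")
        return math.nan
    return n_decoy / n_target


def infer_proteins(
    confident_psms: Sequence[PSMRecord],
    database: SequenceDatabase,
    missed_cleavages: int = 2,
) -> InferenceResult:
    """Full inference chain: map, group, parsimony, two-peptide rule."""
    res = map_and_group(confident_psms, database, missed_cleavages=missed_cleavages)
    groups = apply_parsimony(res.groups)
    groups = two_peptide_filter(groups)
    p2g = {
        pep: sorted(g.group_id for g in groups if pep in g.peptide_set)
        for pep in {p for g in groups for p in g.peptide_set}
    }
    return InferenceResult(
        groups=groups, unmapped_peptides=res.unmapped_peptides, peptide_to_groups=p2g
    )


def groups_to_table(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    samples = sorted({s for g in groups for s in g.evidence})
    rows = []
    for g in groups:
        row = {
            "group_id": g.group_id,
            "accessions": ";".join(g.accessions),
            "n_distinct_peptides": g.distinct_peptides(),
            "is_decoy": g.is_decoy,
        }
        for s in samples:
            row[f"n_peptides_{s}"] = len(g.evidence.get(s, {}))
        rows.append(row)
    return pd.DataFrame(rows)


def write_group_table(groups: Sequence[ProteinGroup], path: str | Path) -> None:
    groups_to_table(groups).to_csv(path, sep="\t", index=False)
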