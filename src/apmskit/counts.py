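"""Spectral-count tallies and proportional shared-peptide splitting.

Corrected counts are the sum of unique counts plus a fraction of each
shared peptide's counts, allocated to the owning groups in proportion to
their unique evidence in the same sample.  Per-sample count mass is
conserved: sum(corrected) == sum(unique) + sum(shared).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protinfer import ProteinGroup
from .psmfilter import PSMRecord

logger = logging.getLogger(__name__)

CONDITIONS = ("bait", "control_empty", "control_gfp", "bait_msl2kd", "bait_rnase")


@dataclass
class SharedPeptide:
    """Counts of one multi-group peptide, with its owning groups."""

    peptide: str
    owners: tuple[str, ...]
    counts: dict[str, int]  # sample -> spectra


@dataclass
class CountExperiment:
    """Protein-group x sample count matrices with condition labels."""

    unique_counts: pd.DataFrame  # groups x samples, int
    conditions: dict[str, str]  # sample -> condition label
    bait_accession: str = ""
    shared: list[SharedPeptide] = field(default_factory=list)
    corrected_counts: pd.DataFrame | None = None

    @property
    def proteins(self) -> list[str]:
        return list(self.unique_counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.unique_counts.columns)

    def samples_for(self, *labels: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] in labels]

    def validate(self) -> None:
        for s in self.samples:
            if s not in self.conditions:
                raise ValueError(f"sample {s!r} has no condition label")
            if self.conditions[s] not in CONDITIONS:
                raise ValueError(
                    f"unknown condition {self.conditions[s]!r} for sample {s!r}"
                )


def tally_counts(
    confident_psms: Sequence[PSMRecord],
    groups: Sequence[ProteinGroup],
    samples: Sequence[str],
    conditions: dict[str, str] | None = None,
    bait_accession: str = "",
) -> CountExperiment:
    """Tally unique spectra per group and register shared-peptide spectra.

    A spectrum is unique when its peptide belongs to exactly one surviving
    group; spectra of multi-group peptides go to the shared registry.
    Spectra whose peptide maps to no surviving group are dropped with a
    warning (their peptides were excluded upstream).
    """
    owners: dict[str, list[str]] = {}
    for g in groups:
        for pep in g.peptide_set:
            owners.setdefault(pep, []).append(g.group_id)

    gids = [g.group_id for g in groups]
    unique = pd.DataFrame(0, index=gids, columns=list(samples), dtype=int)
    shared_counts: dict[str, dict[str, int]] = {}
    n_orphan = 0
    for r in confident_psms:
        own = owners.get(r.peptide)
        if not own:
            n_orphan += 1
            continue
        if len(own) == 1:
            unique.loc[own[0], r.sample_id] += 1
        else:
            per = shared_counts.setdefault(r.peptide, {})
            per[r.sample_id] = per.get(r.sample_id, 0) + 1
    if n_orphan:
        logger.warning("%d spectra matched no surviving protein group", n_orphan)

    shared = [
        SharedPeptide(peptide=pep, owners=tuple(sorted(owners[pep])), counts=cts)
        for pep, cts in sorted(shared_counts.items())
    ]
    exp = CountExperiment(
        unique_counts=unique,
        conditions=dict(conditions or {s: "bait" for s in samples}),
        bait_accession=bait_accession,
        shared=shared,
    )
    return exp


def split_shared(
    experiment: CountExperiment, by_distinct_peptides: bool = False
) -> CountExperiment:
    """Fill corrected counts by proportional allocation of shared spectra.

    For a shared peptide with c spectra in a sample, owner g receives
    ``c * u_g / sum(u_h over owners)`` where u_g is g's unique spectral
    count in that sample (or, with ``by_distinct_peptides``, its number of
    distinct unique peptides — a sensitivity-analysis variant).  When every
    owner has zero unique evidence the spectra are split equally.
    """
    corrected = experiment.unique_counts.astype(float).copy()
    weights = experiment.unique_counts
    for sp in experiment.shared:
        missing = [o for o in sp.owners if o not in corrected.index]
        if missing:
            raise KeyError(f"shared peptide {sp.peptide!r} owned by unknown groups {missing}")
        for sample, c in sp.counts.items():
            u = weights.loc[list(sp.owners), sample].to_numpy(dtype=float)
            total = u.sum()
            if total == 0:
                logger.debug(
                    "equal split of %d spectra of %r in %s (no unique evidence)",
                    c, sp.peptide, sample,
                )
                frac = np.full(len(sp.owners), 1.0 / len(sp.owners))
            else:
                frac = u / total
            corrected.loc[list(sp.owners), sample] += c * frac
    experiment.corrected_counts = corrected
    return experiment


# ---------------------------------------------------------------------------
# I/O: matrix TSV plus a JSON sidecar with condition labels

def write_count_matrix(
    experiment: CountExperiment, matrix_path: str | Path, sidecar_path: str | Path
) -> None:
    mat = (
        experiment.corrected_counts
        if experiment.corrected_counts is not None
        else experiment.unique_counts
    )
    mat.to_csv(matrix_path, sep="\t", index_label="group_id")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "conditions": experiment.conditions,
                "bait_accession": experiment.bait_accession,
            },
            fh,
            indent=2,
        )


def read_count_matrix(
    matrix_path: str | Path, sidecar_path: str | Path
) -> CountExperiment:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="group_id")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    exp = CountExperiment(
        unique_counts=mat.round().astype(int),
        conditions=meta["conditions"],
        bait_accession=meta.get("bait_accession", ""),
        corrected_counts=mat.astype(float),
    )
    exp.validate()
    return exp
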