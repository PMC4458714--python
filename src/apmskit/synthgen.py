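"""Deterministic synthetic inputs for every pipeline stage.

Each generator draws from its own RNG stream, derived from the master seed
by a fixed offset (0 database, 1 PSMs, 2 counts, 3 intervals), so
regenerating one input never perturbs another.  Generators emit both the
standard-format file and a hidden-truth sidecar; pipeline code must never
read the sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountExperiment, write_count_matrix
from .decoydb import (
    DbEntry,
    SequenceDatabase,
    build_decoy_database,
    digest_tryptic,
)
from .psmfilter import PSMRecord, write_psm_table
from .intervals import IntervalSet, write_bed

_STREAM_DATABASE = 0
_STREAM_PSMS = 1
_STREAM_COUNTS = 2
_STREAM_INTERVALS = 3

# alphabet without KRP so cleavage structure is fully controlled by
# explicitly inserted K/R residues
_SAFE_RESIDUES = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass
class SimulationSpec:
    """Full parameterization of the synthetic experiment."""

    seed: int = 0
    # database
    n_proteins: int = 500
    n_contaminants: int = 20
    protein_length: tuple[int, int] = (120, 400)
    shared_block_fraction: float = 0.1
    # PSMs
    n_true_psms: int = 2000
    n_false_psms: int = 2000
    n_decoy_psms: int = 2000
    peptide_length: tuple[int, int] = (7, 20)
    prefilter_fail_fraction: float = 0.02
    # counts
    n_count_proteins: int = 500
    n_bait: int = 3
    n_control_empty: int = 2
    n_control_gfp: int = 2
    n_msl2kd: int = 3
    n_rnase: int = 3
    sample_total: int = 5000
    background_pi: float = 0.005
    theta: float = 0.0005
    rate_spread: float = 0.4  # lognormal sigma of per-protein base rates
    n_interactors: int = 50
    enrichment_fold: float = 5.0
    msl2kd_fold: float = 0.2
    rnase_fold: float = 0.2
    treated_fraction: float = 0.5
    # toy genome
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr2": 300_000, "chr3": 300_000}
    )
    n_intervals: int = 200
    interval_length: tuple[int, int] = (300, 1500)
    planted_overlap_fraction: float = 0.7
    jitter_width: int = 200

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # sprinkle K/R cleavage sites roughly every ~12 residues
    chars = rng.choice(_SAFE_RESIDUES, size=length).tolist()
    pos = 10
    while pos < length - 1:
        chars[pos] = "K" if rng.random() < 0.5 else "R"
        pos += int(rng.integers(8, 16))
    return "".join(chars)


def _shared_block(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(rng.choice(_SAFE_RESIDUES, size=length - 1).tolist()) + "R"


def gen_database(spec: SimulationSpec) -> tuple[SequenceDatabase, SequenceDatabase]:
    """Random forward-only organism and contaminant databases.

    A ``shared_block_fraction`` of organism proteins is organised in pairs
    carrying an identical tryptic peptide block, guaranteeing shared
    peptides downstream.
    """
    rng = spec.rng(_STREAM_DATABASE)
    lo, hi = spec.protein_length
    entries = []
    n_shared_pairs = int(spec.n_proteins * spec.shared_block_fraction / 2)
    shared_members = set(range(2 * n_shared_pairs))
    blocks = [_shared_block(rng) for _ in range(n_shared_pairs)]
    for i in range(spec.n_proteins):
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        if i in shared_members:
            block = blocks[i // 2]
            cut = len(seq) // 2
            # flank with K so the block digests out as one tryptic peptide
            seq = seq[:cut] + "K" + block + seq[cut:]
        entries.append(DbEntry(accession=f"ORG{i:05d}", sequence=seq, origin="organism"))
    organism = SequenceDatabase(entries)
    contam = SequenceDatabase(
        [
            DbEntry(
                accession=f"CONT{i:04d}",
                sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                origin="contaminant",
            )
            for i in range(spec.n_contaminants)
        ]
    )
    return organism, contam


def _candidate_peptides(
    db: SequenceDatabase, lo: int, hi: int, max_proteins: int | None = None
) -> list[tuple[str, str, int]]:
    """(peptide, accession, ntt) candidates from a digest of the database."""
    out = []
    entries = db.entries if max_proteins is None else db.entries[:max_proteins]
    for e in entries:
        for tp in digest_tryptic(e.sequence, missed_cleavages=1, min_length=lo,
                                 on_nonstandard="skip"):
            if len(tp.peptide) <= hi:
                out.append((tp.peptide, e.accession, tp.ntt))
    return out


def gen_psms(
    spec: SimulationSpec, database: SequenceDatabase
) -> tuple[list[PSMRecord], dict]:
    """Synthetic PSM table with hidden truth labels.

    True matches draw scores from a high-scoring law; false target matches
    and decoy matches draw i.i.d. from one shared low-scoring law, so the
    decoy score distribution estimates the false-match distribution exactly.
    """
    rng = spec.rng(_STREAM_PSMS)
    lo, hi = spec.peptide_length
    fw = SequenceDatabase([e for e in database.entries if not e.is_decoy],
                          decoy_prefix=database.decoy_prefix)
    dc = SequenceDatabase([e for e in database.entries if e.is_decoy],
                          decoy_prefix=database.decoy_prefix)
    fw_peps = _candidate_peptides(fw, lo, hi)
    dc_peps = _candidate_peptides(dc, lo, hi)
    if not fw_peps or not dc_peps:
        raise ValueError("database digest yielded no candidate peptides")

    records: list[PSMRecord] = []
    truth: dict[str, bool] = {}

    def _class(rng: np.random.Generator, true_match: bool) -> tuple[int, int, str]:
        charge = int(rng.choice([1, 2, 3], p=[0.15, 0.55, 0.30]))
        if true_match:
            ntt = int(rng.choice([1, 2], p=[0.15, 0.85]))
        else:
            ntt = int(rng.choice([0, 1, 2], p=[0.2, 0.3, 0.5]))
        mod = "M+16" if rng.random() < 0.1 else "unmodified"
        return charge, ntt, mod

    def _true_scores(n: int) -> np.ndarray:
        xcorr = np.clip(rng.normal(3.5, 0.6, n), 0.8, None)
        deltacn = np.clip(rng.normal(0.25, 0.08, n), 0.0, 0.6)
        sprank = rng.integers(1, 4, n)
        return np.column_stack([xcorr, deltacn, sprank])

    def _false_scores(n: int) -> np.ndarray:
        # shared by false targets and decoys
        xcorr = np.clip(rng.normal(1.3, 0.35, n), 0.3, None)
        deltacn = np.clip(rng.normal(0.04, 0.03, n), 0.0, 0.3)
        sprank = rng.integers(1, 60, n)
        return np.column_stack([xcorr, deltacn, sprank])

    def _aux(n: int) -> np.ndarray:
        ions = rng.integers(25, 90, n).astype(float)
        mh = rng.uniform(600.0, 3800.0, n)
        fail = rng.random(n) < spec.prefilter_fail_fraction
        mh[fail] = rng.choice([400.0, 4500.0], size=int(fail.sum()))
        return np.column_stack([ions, mh])

    spec_no = 0
    blocks = [
        ("true", spec.n_true_psms, fw_peps, _true_scores, False),
        ("false", spec.n_false_psms, fw_peps, _false_scores, False),
        ("decoy", spec.n_decoy_psms, dc_peps, _false_scores, True),
    ]
    for kind, n, pool, scorer, is_decoy in blocks:
        scores = scorer(n)
        aux = _aux(n)
        idx = rng.integers(0, len(pool), n)
        for i in range(n):
            pep, acc, pep_ntt = pool[idx[i]]
            charge, ntt, mod = _class(rng, kind == "true")
            ntt = min(ntt, pep_ntt)
            rec = PSMRecord(
                spectrum_id=f"sp{spec_no:06d}",
                peptide=pep,
                charge=charge,
                ntt=ntt,
                mod_state=mod,
                raw_scores={
                    "xcorr": float(scores[i, 0]),
                    "deltacn": float(scores[i, 1]),
                    "sprank": float(scores[i, 2]),
                    "ions": float(aux[i, 0]),
                    "mh": float(aux[i, 1]),
                },
                accessions=[acc],
                is_decoy=is_decoy,
                sample_id=f"S{int(rng.integers(1, 4))}",
            )
            records.append(rec)
            truth[rec.spectrum_id] = kind == "true"
            spec_no += 1
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, {"true_match": truth}


def gen_counts(spec: SimulationSpec) -> tuple[CountExperiment, dict]:
    """Overdispersed count matrix with planted interactors and treatments.

    Per sample, counts are Dirichlet-multinomial draws (concentration
    ``(1 - theta) / theta``), whose per-protein marginals are beta-binomial
    with overdispersion ``theta``; column totals equal ``sample_total``
    exactly.  Planted interactors are ``enrichment_fold`` x enriched in
    every bait-derived sample; a ``treated_fraction`` of them is attenuated
    by the treatment folds in the MSL2kd / RNase samples.  The bait protein
    carries a large count that differs across conditions to exercise
    normalization.
    """
    rng = spec.rng(_STREAM_COUNTS)
    n = spec.n_count_proteins
    proteins = [f"P{i:05d}" for i in range(n)] + ["BAIT"]

    samples: list[str] = []
    conditions: dict[str, str] = {}
    for cond, k in [
        ("bait", spec.n_bait),
        ("control_empty", spec.n_control_empty),
        ("control_gfp", spec.n_control_gfp),
        ("bait_msl2kd", spec.n_msl2kd),
        ("bait_rnase", spec.n_rnase),
    ]:
        for i in range(k):
            sid = f"{cond}_{i + 1}"
            samples.append(sid)
            conditions[sid] = cond

    interactors = [f"P{i:05d}" for i in range(spec.n_interactors)]
    n_treated = int(round(spec.n_interactors * spec.treated_fraction))
    msl2kd_sensitive = interactors[:n_treated]
    rnase_sensitive = interactors[:n_treated]

    base = rng.lognormal(0.0, spec.rate_spread, n)
    base = base / base.sum() * (n * spec.background_pi)
    bait_pi = {
        "bait": 0.15, "bait_msl2kd": 0.075, "bait_rnase": 0.10, "control_empty": 0.002,
        "control_gfp": 0.002,
    }

    conc = (1.0 - spec.theta) / spec.theta
    mat = np.zeros((n + 1, len(samples)), dtype=int)
    for j, sid in enumerate(samples):
        cond = conditions[sid]
        rates = base.copy()
        if cond.startswith("bait"):
            for gid in interactors:
                rates[int(gid[1:])] *= spec.enrichment_fold
            if cond == "bait_msl2kd":
                for gid in msl2kd_sensitive:
                    rates[int(gid[1:])] *= spec.msl2kd_fold
            if cond == "bait_rnase":
                for gid in rnase_sensitive:
                    rates[int(gid[1:])] *= spec.rnase_fold
        rates = np.append(rates, bait_pi[cond])
        props = rates / rates.sum()
        p = rng.dirichlet(np.maximum(props * conc, 1e-8))
        mat[:, j] = rng.multinomial(spec.sample_total, p)

    unique = pd.DataFrame(mat, index=proteins, columns=samples)
    exp = CountExperiment(
        unique_counts=unique,
        conditions=conditions,
        bait_accession="BAIT",
        corrected_counts=unique.astype(float),
    )
    truth = {
        "interactors": interactors,
        "msl2kd_sensitive": msl2kd_sensitive,
        "rnase_sensitive": rnase_sensitive,
    }
    return exp, truth


def gen_intervals(spec: SimulationSpec) -> tuple[IntervalSet, IntervalSet]:
    """Reference intervals uniform; query a planted-overlap mixture.

    A ``planted_overlap_fraction`` of query intervals are jittered copies
    of reference intervals (start shifted by a rounded normal of width
    ``jitter_width``); the rest are placed uniformly.
    """
    rng = spec.rng(_STREAM_INTERVALS)
    lo, hi = spec.interval_length
    chroms = list(spec.chrom_sizes)
    weights = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    def _uniform(n: int) -> list[tuple[str, int, int]]:
        out = []
        cs = rng.choice(len(chroms), size=n, p=weights)
        for ci in cs:
            chrom = chroms[ci]
            size = spec.chrom_sizes[chrom]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(size - length, 1)))
            out.append((chrom, start, start + length))
        return out

    ref_records = _uniform(spec.n_intervals)
    n_planted = int(round(spec.n_intervals * spec.planted_overlap_fraction))
    q_records = []
    picks = rng.choice(len(ref_records), size=n_planted, replace=False)
    for k in picks:
        chrom, s, e = ref_records[k]
        shift = int(round(rng.normal(0.0, spec.jitter_width))) if spec.jitter_width else 0
        size = spec.chrom_sizes[chrom]
        length = e - s
        s2 = min(max(s + shift, 0), size - length)
        q_records.append((chrom, s2, s2 + length))
    q_records += _uniform(spec.n_intervals - n_planted)

    reference = IntervalSet.from_records(ref_records, chrom_sizes=spec.chrom_sizes)
    query = IntervalSet.from_records(q_records, chrom_sizes=spec.chrom_sizes)
    return query, reference


def generate_all(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input plus the hidden-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    organism, contam = gen_database(spec)
    paths["organism_fasta"] = outdir / "organism.fasta"
    paths["contaminants_fasta"] = outdir / "contaminants.fasta"
    organism.to_fasta(paths["organism_fasta"])
    contam.to_fasta(paths["contaminants_fasta"])

    search_db = build_decoy_database(organism, contam)
    paths["search_fasta"] = outdir / "search_db.fasta"
    search_db.to_fasta(paths["search_fasta"])

    psms, psm_truth = gen_psms(spec, search_db)
    paths["psms"] = outdir / "psms.tsv"
    write_psm_table(psms, paths["psms"])

    exp, count_truth = gen_counts(spec)
    paths["counts"] = outdir / "counts.tsv"
    paths["counts_meta"] = outdir / "counts_meta.json"
    write_count_matrix(exp, paths["counts"], paths["counts_meta"])

    query, reference = gen_intervals(spec)
    paths["query_bed"] = outdir / "query.bed"
    paths["reference_bed"] = outdir / "reference.bed"
    write_bed(query, paths["query_bed"])
    write_bed(reference, paths["reference_bed"])
    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in spec.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"spec": asdict(spec), "psms": psm_truth, "counts": count_truth}, fh, indent=2
        )
    return paths
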