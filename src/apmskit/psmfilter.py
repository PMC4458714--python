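"""Discriminant scoring and class-specific FDR thresholding of PSMs.

Peptide-spectrum matches are scored with a linear discriminant combining
search-engine features, histogrammed per class (charge x tryptic-termini x
modification state, at most 18 classes), and the decoy histogram of each
class is used to place a score threshold achieving a requested peptide
false discovery rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decoydb import DEFAULT_DECOY_PREFIX

CHARGES = (1, 2, 3)
NTTS = (0, 1, 2)
MOD_STATES = ("unmodified", "M+16")

#: Default linear-discriminant weights.  The feature transforms are
#: documented in :func:`compute_discriminant`; these coefficients are
#: package defaults, reported in every filter report header so runs are
#: reproducible.
DEFAULT_WEIGHTS: dict[str, float] = {
    "xcorr": 1.0,
    "deltacn": 8.0,
    "sprank": 0.2,
}
DEFAULT_BIAS = 0.0

#: Features consumed by the spectrum prefilter.
ION_COUNT_FIELD = "ions"
MH_FIELD = "mh"


@dataclass
class PSMRecord:
    """One spectrum's candidate identification."""

    spectrum_id: str
    peptide: str
    charge: int
    ntt: int
    mod_state: str
    raw_scores: dict[str, float]
    accessions: list[str]
    is_decoy: bool = False
    sample_id: str = "S1"
    discriminant: float | None = None

    @property
    def psm_class(self) -> tuple[int, int, str]:
        return (self.charge, self.ntt, self.mod_state)


def resolve_decoy_flags(
    records: Iterable[PSMRecord], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> None:
    """Set ``is_decoy`` from accessions, in place.

    A PSM is a decoy only if *every* matched accession carries the decoy
    prefix; a mixed target/decoy match resolves to target (conservative).
    """
    for r in records:
        r.is_decoy = bool(r.accessions) and all(
            a.startswith(decoy_prefix) for a in r.accessions
        )


@dataclass
class FilterConfig:
    """Parameters of the spectrum prefilter and the FDR thresholding."""

    target_fdr: float = 0.01
    histogram_bin_width: float = 0.1
    discriminant_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    bias: float = DEFAULT_BIAS
    min_ions: int = 25
    mass_range: tuple[float, float] = (550.0, 4000.0)
    min_class_decoys: int = 50  # below this, fall back to the pooled histogram
    decoy_prefix: str = DEFAULT_DECOY_PREFIX

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fdr < 1.0:
            raise ValueError("target_fdr must be in (0, 1)")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError("mass_range.low must be < mass_range.high")


def prefilter_spectra(
    records: Sequence[PSMRecord], cfg: FilterConfig
) -> list[PSMRecord]:
    """Drop spectra failing the ion-count or precursor-mass window.

    Both bounds of the mass window are inclusive, as is the minimum ion
    count.  Input order is preserved.
    """
    lo, hi = cfg.mass_range
    out = []
    for r in records:
        for fld in (ION_COUNT_FIELD, MH_FIELD):
            if fld not in r.raw_scores:
                raise KeyError(
                    f"PSM {r.spectrum_id!r} missing required raw score {fld!r}"
                )
        if r.raw_scores[ION_COUNT_FIELD] < cfg.min_ions:
            continue
        if not lo <= r.raw_scores[MH_FIELD] <= hi:
            continue
        out.append(r)
    return out


def transform_features(record: PSMRecord) -> dict[str, float]:
    """Apply the documented discriminant feature transforms.

    * ``xcorr``   -> ln(xcorr / peptide length)
    * ``deltacn`` -> as-is
    * ``sprank``  -> -ln(rank)
    """
    feats: dict[str, float] = {}
    raw = record.raw_scores
    if "xcorr" in raw:
        if raw["xcorr"] <= 0:
            raise ValueError(f"non-positive xcorr for {record.spectrum_id!r}")
        feats["xcorr"] = math.log(raw["xcorr"] / max(len(record.peptide), 1))
    if "deltacn" in raw:
        feats["deltacn"] = raw["deltacn"]
    if "sprank" in raw:
        if raw["sprank"] <= 0:
            raise ValueError(f"non-positive sprank for {record.spectrum_id!r}")
        feats["sprank"] = -math.log(raw["sprank"])
    return feats


def compute_discriminant(
    record: PSMRecord,
    weights: Mapping[str, float] | None = None,
    bias: float = DEFAULT_BIAS,
) -> float:
    """Inner product of transformed features and weights, plus bias."""
    if weights is None:
        weights = DEFAULT_WEIGHTS
    feats = transform_features(record)
    score = bias
    for name, w in weights.items():
        if name not in feats:
            raise KeyError(
                f"PSM {record.spectrum_id!r} lacks weighted feature {name!r}"
            )
        score += w * feats[name]
    return score


def score_records(
    records: Sequence[PSMRecord], cfg: FilterConfig
) -> list[PSMRecord]:
    """Fill the discriminant field of every record (returns the same list)."""
    for r in records:
        r.discriminant = compute_discriminant(r, cfg.discriminant_weights, cfg.bias)
    return list(records)


@dataclass
class ScoreHistogram:
    """Counts over a shared uniform bin grid; ``edges`` has len(counts)+1."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def mass(self) -> int:
        return int(self.counts.sum())


def _common_grid(scores: np.ndarray, bin_width: float) -> np.ndarray:
    lo = math.floor(scores.min() / bin_width) * bin_width
    hi = math.ceil(scores.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    return lo + bin_width * np.arange(n + 1)


def class_histograms(
    records: Sequence[PSMRecord], bin_width: float = 0.1
) -> dict[tuple[int, int, str], tuple[ScoreHistogram, ScoreHistogram]]:
    """Per-class (target, decoy) discriminant histograms on a common grid.

    All histograms share one grid spanning the full score range so that
    thresholds and pooled fallbacks are directly comparable.
    """
    recs = [r for r in records if r.discriminant is not None]
    if not recs:
        return {}
    scores = np.array([r.discriminant for r in recs])
    edges = _common_grid(scores, bin_width)
    out: dict[tuple[int, int, str], tuple[ScoreHistogram, ScoreHistogram]] = {}
    classes = sorted({r.psm_class for r in recs}, key=lambda c: (c[0], c[1], c[2]))
    for cls in classes:
        t = np.array([r.discriminant for r in recs if r.psm_class == cls and not r.is_decoy])
        d = np.array([r.discriminant for r in recs if r.psm_class == cls and r.is_decoy])
        tc, _ = np.histogram(t, bins=edges) if t.size else (np.zeros(len(edges) - 1, int), None)
        dc, _ = np.histogram(d, bins=edges) if d.size else (np.zeros(len(edges) - 1, int), None)
        out[cls] = (
            ScoreHistogram(edges, tc.astype(int)),
            ScoreHistogram(edges, dc.astype(int)),
        )
    return out


def fdr_threshold(
    target_hist: ScoreHistogram,
    decoy_hist: ScoreHistogram,
    target_fdr: float,
) -> tuple[float, int, float]:
    """Smallest bin-edge threshold whose decoy/target ratio meets the FDR.

    Returns ``(threshold, kept_targets, estimated_fdr)`` where the FDR at a
    cut t is decoys>=t / targets>=t (zero targets counts as FDR 0 when there
    are no decoys either, else 1).  If no edge qualifies the class rejects
    everything: threshold is +inf and nothing is kept.
    """
    if not np.array_equal(target_hist.edges, decoy_hist.edges):
        raise ValueError("histograms must share a common grid")
    edges = target_hist.edges
    # survivors at a cut placed at edges[i]: bins i..end
    t_surv = np.concatenate([np.cumsum(target_hist.counts[::-1])[::-1], [0]])
    d_surv = np.concatenate([np.cumsum(decoy_hist.counts[::-1])[::-1], [0]])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            t_surv > 0, d_surv / np.maximum(t_surv, 1), np.where(d_surv > 0, 1.0, 0.0)
        )
    ok = np.nonzero(fdr <= target_fdr)[0]
    # ignore the trivial all-rejecting cut at the top edge unless it is the
    # only qualifying one and keeps nothing
    for i in ok:
        if t_surv[i] > 0:
            return float(edges[i]), int(t_surv[i]), float(fdr[i])
    return math.inf, 0, 0.0


def filter_psms(
    records: Sequence[PSMRecord], cfg: FilterConfig
) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Prefilter, score, threshold per class, and drop failing PSMs.

    Classes with fewer than ``cfg.min_class_decoys`` decoy matches fall back
    to a threshold computed from the pooled all-class histograms.  Returns
    the surviving records (input order preserved) and a per-class report
    with columns: charge, ntt, mod_state, threshold, targets_kept,
    decoys_kept, est_fdr, pooled_fallback.
    """
    kept_pre = prefilter_spectra(records, cfg)
    score_records(kept_pre, cfg)
    hists = class_histograms(kept_pre, cfg.histogram_bin_width)
    if not hists:
        return [], _empty_report()

    # pooled histograms for small-decoy fallback
    any_edges = next(iter(hists.values()))[0].edges
    pooled_t = ScoreHistogram(
        any_edges, sum(h[0].counts for h in hists.values())
    )
    pooled_d = ScoreHistogram(
        any_edges, sum(h[1].counts for h in hists.values())
    )
    pooled_thr, _, pooled_fdr = fdr_threshold(pooled_t, pooled_d, cfg.target_fdr)

    rows = []
    thresholds: dict[tuple[int, int, str], float] = {}
    for cls, (th, dh) in hists.items():
        if dh.mass < cfg.min_class_decoys:
            thr, est = pooled_thr, pooled_fdr
            fallback = True
        else:
            thr, _, est = fdr_threshold(th, dh, cfg.target_fdr)
            fallback = False
        thresholds[cls] = thr
        n_t = sum(
            1
            for r in kept_pre
            if r.psm_class == cls and not r.is_decoy and r.discriminant >= thr
        )
        n_d = sum(
            1
            for r in kept_pre
            if r.psm_class == cls and r.is_decoy and r.discriminant >= thr
        )
        rows.append(
            {
                "charge": cls[0],
                "ntt": cls[1],
                "mod_state": cls[2],
                "threshold": thr,
                "targets_kept": n_t,
                "decoys_kept": n_d,
                "est_fdr": est,
                "pooled_fallback": fallback,
            }
        )
    confident = [
        r for r in kept_pre if r.discriminant >= thresholds[r.psm_class]
    ]
    return confident, pd.DataFrame(rows)


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "charge",
            "ntt",
            "mod_state",
            "threshold",
            "targets_kept",
            "decoys_kept",
            "est_fdr",
            "pooled_fallback",
        ]
    )


# ---------------------------------------------------------------------------
# tabular I/O

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "charge",
    "ntt",
    "mod_state",
    "xcorr",
    "deltacn",
    "sprank",
    "ions",
    "mh",
    "accessions",
    "sample_id",
    "is_decoy",
]

_SCORE_COLUMNS = ("xcorr", "deltacn", "sprank", "ions", "mh")


def read_psm_table(
    path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[PSMRecord]:
    """Read a tab-separated PSM table.

    The ``is_decoy`` column is optional; when absent the flag is derived
    from the accession prefix (all-decoy accessions => decoy).
    """
    df = pd.read_csv(path, sep="\t", dtype={"accessions": str})
    records = []
    has_decoy_col = "is_decoy" in df.columns
    for row in df.itertuples(index=False):
        rec = PSMRecord(
            spectrum_id=str(row.spectrum_id),
            peptide=str(row.peptide),
            charge=int(row.charge),
            ntt=int(row.ntt),
            mod_state=str(row.mod_state),
            raw_scores={c: float(getattr(row, c)) for c in _SCORE_COLUMNS if hasattr(row, c)},
            accessions=str(row.accessions).split(";") if str(row.accessions) else [],
            sample_id=str(getattr(row, "sample_id", "S1")),
        )
        if has_decoy_col:
            rec.is_decoy = bool(row.is_decoy)
        records.append(rec)
    if not has_decoy_col:
        resolve_decoy_flags(records, decoy_prefix)
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "spectrum_id": r.spectrum_id,
            "peptide": r.peptide,
            "charge": r.charge,
            "ntt": r.ntt,
            "mod_state": r.mod_state,
            **{c: r.raw_scores.get(c, float("nan")) for c in _SCORE_COLUMNS},
            "accessions": ";".join(r.accessions),
            "sample_id": r.sample_id,
            "is_decoy": r.is_decoy,
        }
        if r.discriminant is not None:
            row["discriminant"] = r.discriminant
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
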