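"""Genomic interval statistics: merging, coverage, overlap and distance tests.

Intervals are 0-based half-open (BED convention), kept sorted per
chromosome.  The correlation statistics mirror the GenometriCorr family:
Jaccard and projection tests for base-level overlap, and absolute/relative
midpoint-distance statistics with relocation-permutation nulls.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Per-chromosome sorted half-open intervals with optional labels."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 2) int arrays
    labels: dict[str, list[str]] | None = None
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in list(self.intervals.items()):
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
                bad = arr[arr[:, 0] >= arr[:, 1]][0]
                raise ValueError(
                    f"invalid interval on {chrom}: start {bad[0]} >= end {bad[1]}"
                )
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self.intervals[chrom] = arr[order]
            if self.labels and chrom in self.labels:
                self.labels[chrom] = [self.labels[chrom][i] for i in order]
            size = self.chrom_sizes.get(chrom)
            if size is not None and arr.size and arr[:, 1].max() > size:
                raise ValueError(f"interval beyond chromosome {chrom} length {size}")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.intervals)

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def total_bases(self) -> int:
        return sum(int((a[:, 1] - a[:, 0]).sum()) for a in self.intervals.values())

    def midpoints(self, chrom: str) -> np.ndarray:
        arr = self.intervals.get(chrom)
        if arr is None or not arr.size:
            return np.array([], dtype=np.int64)
        return (arr[:, 0] + arr[:, 1]) // 2

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        chrom_sizes: dict[str, int] | None = None,
        labeled: bool = False,
    ) -> "IntervalSet":
        ivs: dict[str, list] = {}
        labs: dict[str, list[str]] = {}
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            ivs.setdefault(chrom, []).append((start, end))
            if labeled:
                labs.setdefault(chrom, []).append(str(rec[3]))
        return cls(
            intervals={c: np.array(v, dtype=np.int64) for c, v in ivs.items()},
            labels=labs if labeled else None,
            chrom_sizes=dict(chrom_sizes or {}),
        )


def _merge_array(arr: np.ndarray, merge_adjacent: bool = True) -> np.ndarray:
    if not arr.size:
        return arr.reshape(0, 2)
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        s, e = int(s), int(e)
        if s < cur_e or (merge_adjacent and s == cur_e):
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.array(out, dtype=np.int64)


def merge(iset: IntervalSet, merge_adjacent: bool = True) -> IntervalSet:
    """Union overlapping (and by default adjacent) intervals per chromosome."""
    return IntervalSet(
        intervals={
            c: _merge_array(a, merge_adjacent) for c, a in iset.intervals.items()
        },
        chrom_sizes=dict(iset.chrom_sizes),
    )


def concat(sets: Sequence[IntervalSet], merge_adjacent: bool = True) -> IntervalSet:
    """Concatenate several interval sets and merge into one."""
    ivs: dict[str, list[np.ndarray]] = {}
    sizes: dict[str, int] = {}
    for s in sets:
        sizes.update(s.chrom_sizes)
        for c, a in s.intervals.items():
            ivs.setdefault(c, []).append(a)
    combined = IntervalSet(
        intervals={c: np.vstack(v) for c, v in ivs.items()}, chrom_sizes=sizes
    )
    return merge(combined, merge_adjacent)


def _overlap_bases(arr: np.ndarray, s: int, e: int) -> int:
    """Bases of [s, e) covered by a merged sorted array."""
    if not arr.size:
        return 0
    lo = np.minimum(np.maximum(arr[:, 0], s), e)
    hi = np.minimum(np.maximum(arr[:, 1], s), e)
    return int(np.maximum(hi - lo, 0).sum())


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-exact intersection of two merged interval sets."""
    out: dict[str, np.ndarray] = {}
    for chrom in a.chromosomes:
        arr_a = a.intervals[chrom]
        arr_b = b.intervals.get(chrom)
        if arr_b is None or not arr_b.size or not arr_a.size:
            continue
        pieces = []
        for s, e in arr_a:
            lo = int(np.searchsorted(arr_b[:, 1], s, side="right"))
            hi = int(np.searchsorted(arr_b[:, 0], e, side="left"))
            for bs, be in arr_b[lo:hi]:
                os, oe = max(int(s), int(bs)), min(int(e), int(be))
                if os < oe:
                    pieces.append((os, oe))
        if pieces:
            out[chrom] = np.array(pieces, dtype=np.int64)
    return IntervalSet(intervals=out, chrom_sizes=dict(a.chrom_sizes) or dict(b.chrom_sizes))


def coverage_fraction(
    query: IntervalSet, reference: IntervalSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-query-interval covered fraction plus per-chromosome summaries.

    Returns (per-interval table, per-chromosome five-number summary).
    Chromosomes absent from the reference yield fractions of zero.
    """
    rows = []
    for chrom, s, e in query.iter_intervals():
        ref = reference.intervals.get(chrom, np.zeros((0, 2), dtype=np.int64))
        frac = _overlap_bases(ref, s, e) / (e - s)
        rows.append({"chrom": chrom, "start": s, "end": e, "fraction": frac})
    per_interval = pd.DataFrame(rows, columns=["chrom", "start", "end", "fraction"])
    summaries = []
    for chrom, grp in per_interval.groupby("chrom"):
        q = grp["fraction"].quantile([0, 0.25, 0.5, 0.75, 1.0])
        summaries.append(
            {
                "chrom": chrom,
                "min": q[0.0],
                "q1": q[0.25],
                "median": q[0.5],
                "q3": q[0.75],
                "max": q[1.0],
                "n": len(grp),
            }
        )
    return per_interval, pd.DataFrame(
        summaries, columns=["chrom", "min", "q1", "median", "q3", "max", "n"]
    )


def site_overlap_fraction(sites: IntervalSet, features: IntervalSet) -> float:
    """Fraction of site intervals overlapping at least one feature base."""
    n = len(sites)
    if n == 0:
        raise ValueError("no sites; overlap fraction undefined")
    hit = 0
    for chrom, s, e in sites.iter_intervals():
        feat = features.intervals.get(chrom)
        if feat is not None and _overlap_bases(feat, s, e) > 0:
            hit += 1
    return hit / n


def _jaccard_value(a: IntervalSet, b: IntervalSet) -> float:
    inter = intersect(a, b).total_bases()
    union = a.total_bases() + b.total_bases() - inter
    if union == 0:
        raise ValueError("empty union; Jaccard undefined")
    return inter / union


def _relocate(
    iset: IntervalSet, rng: np.random.Generator
) -> IntervalSet:
    """Relocation null: same interval lengths, uniform independent placement.

    Overlap within the relocated set is allowed (the set is merged only
    where the statistic requires it).
    """
    out: dict[str, np.ndarray] = {}
    for chrom, arr in iset.intervals.items():
        size = iset.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"chromosome length unknown for {chrom!r}")
        lengths = arr[:, 1] - arr[:, 0]
        max_start = size - lengths
        if np.any(max_start < 0):
            raise ValueError(f"interval longer than chromosome {chrom}")
        starts = (rng.random(len(lengths)) * (max_start + 1)).astype(np.int64)
        out[chrom] = np.column_stack([starts, starts + lengths])
    return IntervalSet(intervals=out, chrom_sizes=dict(iset.chrom_sizes))


def jaccard(
    a: IntervalSet, b: IntervalSet, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Jaccard base-overlap statistic with a relocation permutation p-value.

    p = (1 + #{null >= observed}) / (1 + n_perm); the null relocates a's
    intervals uniformly per chromosome, preserving lengths.
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation tests")
    a_m, b_m = merge(a), merge(b)
    obs = _jaccard_value(a_m, b_m)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        null = merge(_relocate(a_m, rng))
        if _jaccard_value(null, b_m) >= obs:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


def projection_test(query: IntervalSet, reference: IntervalSet) -> float:
    """Two-sided binomial test of query midpoints landing in the reference.

    With n query midpoints, k inside the merged reference, and c the
    reference's covered fraction of the shared genome, the p-value doubles
    the smaller binomial tail (capped at 1).
    """
    ref = merge(reference)
    chroms = [c for c in query.chromosomes if c in query.chrom_sizes]
    genome = sum(query.chrom_sizes[c] for c in chroms)
    if genome == 0:
        raise ValueError("zero-length genome")
    covered = sum(
        int((ref.intervals[c][:, 1] - ref.intervals[c][:, 0]).sum())
        for c in chroms
        if c in ref.intervals
    )
    c_frac = covered / genome
    n = k = 0
    for chrom in chroms:
        mids = query.midpoints(chrom)
        n += len(mids)
        arr = ref.intervals.get(chrom)
        if arr is None or not arr.size or not mids.size:
            continue
        idx = np.searchsorted(arr[:, 0], mids, side="right") - 1
        inside = (idx >= 0) & (mids < arr[np.clip(idx, 0, None), 1])
        k += int(inside.sum())
    if n == 0:
        raise ValueError("no query midpoints")
    lower = stats.binom.cdf(k, n, c_frac)
    upper = stats.binom.sf(k - 1, n, c_frac)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class CorrelationReport:
    """Distance-based correlation statistics between two interval sets."""

    relative_ks_p: float
    relative_ecdf_area_correlation: float
    absolute_area_permutation_p: float
    absolute_mean_distance: float
    jaccard_value: float
    jaccard_p: float
    projection_p: float
    n_permutations: int
    seed: int
    n_relative_distances: int
    skipped_chromosomes: list[str] = field(default_factory=list)

    def format_p(self, p: float) -> str:
        if p <= 1.0 / (self.n_permutations + 1):
            return f"< {1.0 / (self.n_permutations + 1):.4g}"
        return f"{p:.4g}"

    def to_dict(self) -> dict:
        d = {
            "relative_ks_p": self.relative_ks_p,
            "relative_ecdf_area_correlation": self.relative_ecdf_area_correlation,
            "absolute_area_permutation_p": self.format_p(
                self.absolute_area_permutation_p
            ),
            "absolute_mean_distance": self.absolute_mean_distance,
            "jaccard_value": self.jaccard_value,
            "jaccard_p": self.format_p(self.jaccard_p),
            "projection_p": self.projection_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_relative_distances": self.n_relative_distances,
            "skipped_chromosomes": self.skipped_chromosomes,
            "area_correlation_normalization": "1 at identity, 0 under independence",
        }
        return d


def relative_distances(
    query: IntervalSet, reference: IntervalSet
) -> tuple[np.ndarray, list[str]]:
    """Relative midpoint distances in [0, 0.5] plus skipped chromosomes.

    For each query midpoint strictly between the first and last reference
    midpoints of its chromosome, the distance to the nearest flanking
    reference midpoint is divided by the flanking gap.  Chromosomes with
    fewer than two reference midpoints are skipped.
    """
    dists = []
    skipped = []
    for chrom in query.chromosomes:
        q = query.midpoints(chrom)
        r = np.sort(reference.midpoints(chrom))
        if len(r) < 2:
            if len(q):
                skipped.append(chrom)
            continue
        inside = q[(q >= r[0]) & (q <= r[-1])]
        if not inside.size:
            continue
        idx = np.clip(np.searchsorted(r, inside, side="right") - 1, 0, len(r) - 2)
        left, right = r[idx], r[idx + 1]
        gap = (right - left).astype(float)
        gap[gap == 0] = 1.0
        d = np.minimum(inside - left, right - inside) / gap
        dists.append(d)
    if skipped:
        logger.info("chromosomes skipped (<2 reference midpoints): %s", skipped)
    out = np.concatenate(dists) if dists else np.array([])
    return out, skipped


def relative_ecdf_area_correlation(rel_dists: np.ndarray) -> float:
    """Area between the relative-distance ECDF and the uniform baseline.

    Normalized so identical midpoint sets (all distances 0) score 1 and
    independence (uniform on [0, 0.5]) scores approximately 0.
    """
    d = np.sort(np.asarray(rel_dists, dtype=float))
    if not d.size:
        raise ValueError("no relative distances")
    # integral of the ECDF step function over [0, 0.5]; the uniform
    # baseline integral of 2d over [0, 0.5] is 0.25
    ecdf_int = float(np.sum(0.5 - d) / d.size)
    return (ecdf_int - 0.25) / 0.25


def absolute_distances(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Distance from each query midpoint to the nearest reference midpoint."""
    dists = []
    for chrom in query.chromosomes:
        q = query.midpoints(chrom)
        r = np.sort(reference.midpoints(chrom))
        if not len(r) or not len(q):
            continue
        idx = np.searchsorted(r, q)
        left = r[np.clip(idx - 1, 0, len(r) - 1)]
        right = r[np.clip(idx, 0, len(r) - 1)]
        dists.append(np.minimum(np.abs(q - left), np.abs(right - q)).astype(float))
    return np.concatenate(dists) if dists else np.array([])


def distance_correlation(
    query: IntervalSet,
    reference: IntervalSet,
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelationReport:
    """Midpoint-distance correlation statistics with permutation nulls.

    Relative distances are tested against Uniform[0, 0.5] by KS and by the
    normalized ECDF-area statistic.  Absolute distances are tested by a
    relocation permutation: the area between the observed and null ECDFs
    over a common support reduces to the difference of mean distances, so
    the permutation compares mean nearest-midpoint distances.
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation tests")
    q_m, r_m = merge(query), merge(reference)
    rel, skipped = relative_distances(q_m, r_m)
    if not rel.size:
        raise ValueError("no usable query midpoints for relative distances")
    ks = stats.kstest(rel * 2.0, "uniform")
    area_corr = relative_ecdf_area_correlation(rel)

    obs_abs = absolute_distances(q_m, r_m)
    obs_mean = float(obs_abs.mean())
    rng = np.random.default_rng(seed)
    hits = 0
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        null_q = _relocate(q_m, rng)
        null_means[i] = absolute_distances(null_q, r_m).mean()
        if null_means[i] <= obs_mean:
            hits += 1
    abs_p = (1 + hits) / (1 + n_perm)

    jac_val, jac_p = jaccard(q_m, r_m, n_perm=n_perm, seed=seed + 1)
    proj_p = projection_test(q_m, r_m)
    return CorrelationReport(
        relative_ks_p=float(ks.pvalue),
        relative_ecdf_area_correlation=area_corr,
        absolute_area_permutation_p=abs_p,
        absolute_mean_distance=obs_mean,
        jaccard_value=jac_val,
        jaccard_p=jac_p,
        projection_p=proj_p,
        n_permutations=n_perm,
        seed=seed,
        n_relative_distances=int(rel.size),
        skipped_chromosomes=skipped,
    )


def annotate_partition(sites: IntervalSet, partition: IntervalSet) -> dict[str, float]:
    """Percent of site bases falling in each label of a genome partition.

    The partition must be non-overlapping; site bases outside every
    partition interval are reported under ``"other"``.  Percentages sum to
    100 (up to float rounding).
    """
    if partition.labels is None:
        raise ValueError("partition must carry labels")
    for chrom, arr in partition.intervals.items():
        if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError(f"partition intervals overlap on {chrom}")
    totals: dict[str, int] = {}
    grand = 0
    for chrom, s, e in sites.iter_intervals():
        grand += e - s
        arr = partition.intervals.get(chrom)
        labs = partition.labels.get(chrom, []) if arr is not None else []
        covered = 0
        if arr is not None and arr.size:
            lo = np.minimum(np.maximum(arr[:, 0], s), e)
            hi = np.minimum(np.maximum(arr[:, 1], s), e)
            ol = np.maximum(hi - lo, 0)
            for bases, lab in zip(ol, labs):
                if bases > 0:
                    totals[lab] = totals.get(lab, 0) + int(bases)
                    covered += int(bases)
        rest = (e - s) - covered
        if rest > 0:
            totals["other"] = totals.get("other", 0) + rest
    if grand == 0:
        raise ValueError("no site bases to annotate")
    return {lab: 100.0 * b / grand for lab, b in sorted(totals.items())}


# ---------------------------------------------------------------------------
# gene-model partition

@dataclass
class GeneModel:
    """Minimal gene description for region annotation."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def gene_model_partition(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    tss_window: int = 1000,
) -> IntervalSet:
    """Partition a genome into TSS/UTR/exon/intron/intergenic regions.

    Precedence (highest wins where classes overlap): TSS window (+-
    ``tss_window`` around the transcription start), 5' UTR, 3' UTR, exon,
    intron; everything else is intergenic.
    """
    layers: list[tuple[str, dict[str, list[tuple[int, int]]]]] = [
        ("tss", {}), ("utr5", {}), ("utr3", {}), ("exon", {}), ("intron", {}),
    ]
    by_name = dict(layers)
    for g in genes:
        size = chrom_sizes[g.chrom]
        lo = max(0, g.tss - tss_window)
        hi = min(size, g.tss + tss_window + 1)
        by_name["tss"].setdefault(g.chrom, []).append((lo, hi))
        for key, blocks in (("utr5", g.utr5), ("utr3", g.utr3), ("exon", g.exons)):
            for s, e in blocks:
                by_name[key].setdefault(g.chrom, []).append((s, e))
        by_name["intron"].setdefault(g.chrom, []).append((g.start, g.end))

    claimed: dict[str, np.ndarray] = {
        c: np.zeros((0, 2), dtype=np.int64) for c in chrom_sizes
    }
    ivs: dict[str, list] = {c: [] for c in chrom_sizes}
    labs: dict[str, list[str]] = {c: [] for c in chrom_sizes}

    def subtract(arr: np.ndarray, taken: np.ndarray) -> np.ndarray:
        if not arr.size:
            return arr.reshape(0, 2)
        if not taken.size:
            return arr
        pieces = []
        for s, e in arr:
            cur = int(s)
            for ts, te in taken:
                if te <= cur or ts >= e:
                    continue
                if ts > cur:
                    pieces.append((cur, int(ts)))
                cur = max(cur, int(te))
                if cur >= e:
                    break
            if cur < e:
                pieces.append((cur, int(e)))
        return np.array(pieces, dtype=np.int64) if pieces else np.zeros((0, 2), dtype=np.int64)

    for name, per_chrom in layers:
        for chrom, lst in per_chrom.items():
            if chrom not in chrom_sizes:
                continue
            arr = _merge_array(
                np.array(sorted(lst), dtype=np.int64).reshape(-1, 2)
            )
            arr = subtract(arr, claimed[chrom])
            for s, e in arr:
                ivs[chrom].append((int(s), int(e)))
                labs[chrom].append(name)
            claimed[chrom] = _merge_array(
                np.vstack([claimed[chrom], arr])[
                    np.lexsort((np.vstack([claimed[chrom], arr])[:, 1],
                                np.vstack([claimed[chrom], arr])[:, 0]))
                ]
            ) if arr.size else claimed[chrom]

    for chrom, size in chrom_sizes.items():
        rest = subtract(np.array([[0, size]], dtype=np.int64), claimed[chrom])
        for s, e in rest:
            ivs[chrom].append((int(s), int(e)))
            labs[chrom].append("intergenic")

    return IntervalSet(
        intervals={c: np.array(v, dtype=np.int64) for c, v in ivs.items() if v},
        labels={c: l for c, l in labs.items() if l},
        chrom_sizes=dict(chrom_sizes),
    )


# ---------------------------------------------------------------------------
# I/O

def read_bed(
    path: str | Path,
    chrom_sizes: dict[str, int] | None = None,
    labeled: bool | None = None,
) -> IntervalSet:
    """Read 3- or 4-column BED; the 4th column becomes the label if present."""
    records = []
    ncols = 3
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            ncols = max(ncols, len(parts))
            records.append(parts)
    use_labels = labeled if labeled is not None else ncols >= 4
    recs = [
        (p[0], int(p[1]), int(p[2]), p[3] if use_labels and len(p) > 3 else "")
        for p in records
    ]
    return IntervalSet.from_records(recs, chrom_sizes=chrom_sizes, labeled=use_labels)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in iset.chromosomes:
            labs = (iset.labels or {}).get(chrom)
            for i, (s, e) in enumerate(iset.intervals[chrom]):
                if labs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{labs[i]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split("\t")[:2]
            out[name] = int(size)
    return out


def write_report(report: CorrelationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
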