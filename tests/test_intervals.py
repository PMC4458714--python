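import json
import math

import numpy as np
import pytest
from scipy import stats

from apmskit.intervals import (
    CorrelationReport,
    GeneModel,
    IntervalSet,
    absolute_distances,
    annotate_partition,
    coverage_fraction,
    distance_correlation,
    gene_model_partition,
    intersect,
    jaccard,
    merge,
    projection_test,
    read_bed,
    read_chrom_sizes,
    relative_distances,
    relative_ecdf_area_correlation,
    site_overlap_fraction,
    write_bed,
    _relocate,
)
from apmskit.synthgen import SimulationSpec, gen_intervals


def iset(ivs, size=1000, labels=None, chrom="c"):
    return IntervalSet(
        intervals={chrom: np.array(ivs, dtype=np.int64).reshape(-1, 2)},
        labels={chrom: labels} if labels else None,
        chrom_sizes={chrom: size},
    )


# ---------------------------------------------------------------------------
# per-base bit-vector oracle

class BitGenome:
    def __init__(self, iset: IntervalSet):
        self.masks = {}
        for chrom, size in iset.chrom_sizes.items():
            mask = np.zeros(size, dtype=bool)
            for s, e in iset.intervals.get(chrom, []):
                mask[s:e] = True
            self.masks[chrom] = mask

    def bases(self):
        return sum(int(m.sum()) for m in self.masks.values())

    def jaccard(self, other):
        inter = union = 0
        for chrom in self.masks:
            a, b = self.masks[chrom], other.masks[chrom]
            inter += int((a & b).sum())
            union += int((a | b).sum())
        return inter / union

    def intersect_bases(self, other):
        return sum(
            int((self.masks[c] & other.masks[c]).sum()) for c in self.masks
        )

    def covered_fraction_of(self, chrom, s, e, ):
        return float(self.masks[chrom][s:e].sum()) / (e - s)


def random_toy_sets(rng, size=None, n_chroms=2, max_iv=12):
    sizes = {
        f"chr{i}": int(size or rng.integers(200, 10_000)) for i in range(n_chroms)
    }
    def one():
        ivs = {}
        for chrom, L in sizes.items():
            n = int(rng.integers(1, max_iv))
            starts = rng.integers(0, L - 1, n)
            lens = rng.integers(1, max(L // 10, 2), n)
            ends = np.minimum(starts + lens, L)
            ivs[chrom] = np.column_stack([starts, ends])
        return merge(IntervalSet(intervals=ivs, chrom_sizes=sizes))
    return one(), one()


class TestMerge:
    def test_overlapping_union(self):
        m = merge(iset([[0, 10], [5, 20]]))
        np.testing.assert_array_equal(m.intervals["c"], [[0, 20]])

    def test_disjoint_identity(self):
        m = merge(iset([[0, 10], [30, 40]]))
        np.testing.assert_array_equal(m.intervals["c"], [[0, 10], [30, 40]])

    def test_adjacent_merged(self):
        m = merge(iset([[0, 10], [10, 20]]))
        np.testing.assert_array_equal(m.intervals["c"], [[0, 20]])

    def test_adjacent_merge_can_be_disabled(self):
        m = merge(iset([[0, 10], [10, 20]]), merge_adjacent=False)
        assert len(m.intervals["c"]) == 2

    def test_covered_bases_preserved(self, rng):
        for _ in range(20):
            a, _ = random_toy_sets(rng)
            assert merge(a).total_bases() == BitGenome(a).bases()

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start"):
            iset([[10, 10]])


class TestCoverageFraction:
    def test_half_covered(self):
        per, _ = coverage_fraction(iset([[0, 100]]), iset([[50, 150]]))
        assert per["fraction"].tolist() == [0.5]

    def test_fully_covered(self):
        per, _ = coverage_fraction(iset([[10, 20]]), iset([[0, 100]]))
        assert per["fraction"].tolist() == [1.0]

    def test_disjoint(self):
        per, _ = coverage_fraction(iset([[0, 10]]), iset([[50, 60]]))
        assert per["fraction"].tolist() == [0.0]

    def test_missing_chromosome_zero(self):
        q = iset([[0, 10]], chrom="cA")
        r = iset([[0, 10]], chrom="cB")
        per, _ = coverage_fraction(q, r)
        assert per["fraction"].tolist() == [0.0]

    def test_summary_median(self):
        q = iset([[0, 10], [20, 30], [40, 50]])
        r = iset([[0, 5], [20, 30]])
        _, summary = coverage_fraction(q, r)
        assert summary.loc[0, "median"] == pytest.approx(0.5)

    def test_against_bit_oracle(self, rng):
        for _ in range(30):
            q, r = random_toy_sets(rng)
            oracle = BitGenome(r)
            per, _ = coverage_fraction(q, r)
            for row in per.itertuples():
                want = oracle.covered_fraction_of(row.chrom, row.start, row.end)
                assert row.fraction == pytest.approx(want)


class TestJaccard:
    def test_hand_value(self):
        v, _ = jaccard(iset([[0, 100]]), iset([[50, 150]]), n_perm=9, seed=0)
        assert v == pytest.approx(1 / 3)

    def test_identical_sets(self):
        v, _ = jaccard(iset([[0, 100]]), iset([[0, 100]]), n_perm=9, seed=0)
        assert v == 1.0

    def test_disjoint_sets(self):
        v, _ = jaccard(iset([[0, 100]]), iset([[200, 300]]), n_perm=9, seed=0)
        assert v == 0.0

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            jaccard(iset([[0, 100]]), iset([[50, 150]]), n_perm=9)

    def test_against_bit_oracle(self, rng):
        for _ in range(30):
            a, b = random_toy_sets(rng)
            v, _ = jaccard(a, b, n_perm=1, seed=1)
            assert v == pytest.approx(BitGenome(a).jaccard(BitGenome(b)))


class TestIntersect:
    def test_hand_intersection(self):
        out = intersect(iset([[0, 100]]), iset([[50, 150]]))
        np.testing.assert_array_equal(out.intervals["c"], [[50, 100]])

    def test_identity(self):
        out = intersect(iset([[0, 100]]), iset([[0, 100]]))
        np.testing.assert_array_equal(out.intervals["c"], [[0, 100]])

    def test_disjoint_empty(self):
        out = intersect(iset([[0, 10]]), iset([[20, 30]]))
        assert len(out) == 0

    def test_against_bit_oracle(self, rng):
        for _ in range(30):
            a, b = random_toy_sets(rng)
            got = intersect(a, b).total_bases()
            assert got == BitGenome(a).intersect_bases(BitGenome(b))


class TestProjection:
    def test_closed_form_all_inside(self):
        # 10 midpoints inside a reference covering half the genome
        q = iset([[i * 100, i * 100 + 10] for i in range(10)], size=2000)
        r = iset([[0, 1000]], size=2000)
        p = projection_test(q, r)
        assert p == pytest.approx(2 * 0.5 ** 10)

    def test_central_case(self):
        q = iset([[i * 100, i * 100 + 2] for i in range(10)], size=1000)
        # 5 of 10 midpoints inside; reference covers half the genome
        r = iset([[0, 500]], size=1000)
        p = projection_test(q, r)
        assert p >= 0.5

    def test_reference_covers_everything(self):
        q = iset([[10, 20], [50, 60]], size=100)
        r = iset([[0, 100]], size=100)
        assert projection_test(q, r) == pytest.approx(1.0)

    def test_zero_genome_rejected(self):
        q = IntervalSet(intervals={"c": np.array([[0, 5]])}, chrom_sizes={})
        with pytest.raises(ValueError):
            projection_test(q, q)


class TestRelativeDistances:
    def test_coincident_midpoints(self):
        q = iset([[10, 20], [50, 60], [90, 100]])
        d, _ = relative_distances(q, q)
        assert np.all(d == 0.0)
        assert relative_ecdf_area_correlation(d) == pytest.approx(1.0)

    def test_hand_value(self):
        # query midpoint 25 between reference midpoints 0 and 100
        q = iset([[25, 26]], size=200)
        r = iset([[0, 1], [100, 101]], size=200)
        d, _ = relative_distances(q, r)
        assert d.tolist() == [0.25]

    def test_chromosome_with_few_midpoints_skipped(self):
        q = iset([[25, 26]], chrom="cX")
        r = iset([[0, 1]], chrom="cX")
        d, skipped = relative_distances(q, r)
        assert d.size == 0
        assert skipped == ["cX"]

    def test_independent_uniform_near_zero(self, rng):
        # 1000 points: area correlation within +-0.05 of 0, KS non-extreme
        L = 1_000_000
        q = np.sort(rng.integers(0, L, 1000))
        r = np.sort(rng.integers(0, L, 1000))
        qs = IntervalSet(intervals={"c": np.column_stack([q, q + 1])},
                         chrom_sizes={"c": L})
        rs = IntervalSet(intervals={"c": np.column_stack([r, r + 1])},
                         chrom_sizes={"c": L})
        d, _ = relative_distances(qs, rs)
        assert abs(relative_ecdf_area_correlation(d)) < 0.05
        assert stats.kstest(d * 2, "uniform").pvalue > 1e-4


class TestDistanceCorrelation:
    def test_planted_correlation_detected(self):
        spec = SimulationSpec(seed=5, n_intervals=200, planted_overlap_fraction=0.8)
        q, r = gen_intervals(spec)
        rep = distance_correlation(q, r, n_perm=99, seed=3)
        assert rep.relative_ecdf_area_correlation > 0.3
        assert rep.projection_p < 0.01
        assert rep.absolute_area_permutation_p <= 0.05
        assert rep.jaccard_p <= 0.05

    def test_independent_not_detected(self):
        spec = SimulationSpec(seed=6, n_intervals=200, planted_overlap_fraction=0.0)
        q, r = gen_intervals(spec)
        rep = distance_correlation(q, r, n_perm=99, seed=3)
        assert abs(rep.relative_ecdf_area_correlation) < 0.2
        assert rep.jaccard_p > 0.05

    def test_zero_p_never_printed(self):
        rep = CorrelationReport(
            relative_ks_p=0.0, relative_ecdf_area_correlation=1.0,
            absolute_area_permutation_p=1 / 100, absolute_mean_distance=0.0,
            jaccard_value=1.0, jaccard_p=1 / 100, projection_p=0.0,
            n_permutations=99, seed=1, n_relative_distances=10,
        )
        d = rep.to_dict()
        assert d["absolute_area_permutation_p"].startswith("<")
        assert d["jaccard_p"].startswith("<")

    def test_relocation_preserves_lengths(self, rng):
        a, _ = random_toy_sets(rng)
        null = _relocate(a, rng)
        for chrom in a.intervals:
            want = np.sort(a.intervals[chrom][:, 1] - a.intervals[chrom][:, 0])
            got = np.sort(null.intervals[chrom][:, 1] - null.intervals[chrom][:, 0])
            np.testing.assert_array_equal(want, got)
            assert null.intervals[chrom][:, 0].min() >= 0
            assert null.intervals[chrom][:, 1].max() <= a.chrom_sizes[chrom]


class TestAnnotatePartition:
    def test_hand_split(self):
        part = iset([[0, 50], [50, 100]], labels=["A", "B"], size=100)
        sites = iset([[40, 60]], size=100)
        pct = annotate_partition(sites, part)
        assert pct == {"A": 50.0, "B": 50.0}

    def test_single_state(self):
        part = iset([[0, 100]], labels=["A"], size=100)
        pct = annotate_partition(iset([[10, 30]], size=100), part)
        assert pct == {"A": 100.0}

    def test_residual_other(self):
        part = iset([[0, 10]], labels=["A"], size=100)
        pct = annotate_partition(iset([[0, 20]], size=100), part)
        assert pct == {"A": 50.0, "other": 50.0}

    def test_overlapping_partition_rejected(self):
        part = iset([[0, 50], [40, 100]], labels=["A", "B"], size=100)
        with pytest.raises(ValueError, match="overlap"):
            annotate_partition(iset([[0, 10]], size=100), part)

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            sites, _ = random_toy_sets(rng, size=2000)
            cuts = np.sort(rng.choice(np.arange(1, 2000), 3, replace=False))
            bounds = [0, *cuts.tolist(), 2000]
            part = IntervalSet(
                intervals={c: np.array([[bounds[i], bounds[i + 1]]
                                        for i in range(4)])
                           for c in sites.chrom_sizes},
                labels={c: ["s1", "s2", "s3", "s4"] for c in sites.chrom_sizes},
                chrom_sizes=dict(sites.chrom_sizes),
            )
            if sites.total_bases() == 0:
                continue
            pct = annotate_partition(sites, part)
            assert sum(pct.values()) == pytest.approx(100.0)

    def test_against_bit_oracle(self, rng):
        sizes = {"chr0": 5000}
        sites = merge(IntervalSet(
            intervals={"chr0": np.sort(rng.integers(0, 5000, (6, 2)), axis=1)},
            chrom_sizes=sizes,
        ))
        sites = IntervalSet(
            intervals={"chr0": sites.intervals["chr0"][
                sites.intervals["chr0"][:, 0] < sites.intervals["chr0"][:, 1]
            ]},
            chrom_sizes=sizes,
        )
        part = iset([[0, 2000], [2000, 5000]], labels=["A", "B"], size=5000,
                    chrom="chr0")
        if sites.total_bases():
            pct = annotate_partition(sites, part)
            mask = BitGenome(sites).masks["chr0"]
            a_bases = int(mask[:2000].sum())
            b_bases = int(mask[2000:].sum())
            tot = a_bases + b_bases
            assert pct.get("A", 0.0) == pytest.approx(100 * a_bases / tot)


class TestSiteOverlapFraction:
    def test_hand_count(self):
        sites = iset([[0, 10], [20, 30], [40, 50], [60, 70]])
        feats = iset([[5, 8], [45, 46]])
        assert site_overlap_fraction(sites, feats) == pytest.approx(0.5)

    def test_all_covered(self):
        sites = iset([[0, 10], [20, 30]])
        feats = iset([[0, 100]])
        assert site_overlap_fraction(sites, feats) == 1.0

    def test_disjoint(self):
        sites = iset([[0, 10]])
        feats = iset([[50, 60]])
        assert site_overlap_fraction(sites, feats) == 0.0

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            site_overlap_fraction(IntervalSet(chrom_sizes={"c": 10}), iset([[0, 5]]))


class TestGeneModelPartition:
    def test_precedence_and_cover(self):
        genes = [GeneModel(chrom="c", start=3000, end=7000, strand="+",
                           exons=[(3000, 3500), (6500, 7000)],
                           utr5=[(3000, 3100)], utr3=[(6900, 7000)])]
        part = gene_model_partition(genes, {"c": 10_000}, tss_window=1000)
        pct = annotate_partition(iset([[0, 10_000]], size=10_000), part)
        assert sum(pct.values()) == pytest.approx(100.0)
        # TSS window [2000, 4001) wins over exon/UTR inside it
        labels_at = dict()
        for (s, e), lab in zip(part.intervals["c"], part.labels["c"]):
            for pos in (2500, 3050, 6600, 6950, 5000, 500):
                if s <= pos < e:
                    labels_at[pos] = lab
        assert labels_at[2500] == "tss"
        assert labels_at[3050] == "tss"      # inside window despite utr5
        assert labels_at[6600] == "exon"
        assert labels_at[6950] == "utr3"
        assert labels_at[5000] == "intron"
        assert labels_at[500] == "intergenic"


class TestIO:
    def test_bed_round_trip(self, tmp_path, rng):
        a, _ = random_toy_sets(rng)
        path = tmp_path / "a.bed"
        write_bed(a, path)
        back = read_bed(path, chrom_sizes=a.chrom_sizes)
        for chrom in a.intervals:
            np.testing.assert_array_equal(a.intervals[chrom], back.intervals[chrom])

    def test_labeled_bed(self, tmp_path):
        part = iset([[0, 50], [50, 100]], labels=["A", "B"], size=100)
        path = tmp_path / "p.bed"
        write_bed(part, path)
        back = read_bed(path)
        assert back.labels["c"] == ["A", "B"]

    def test_chrom_sizes(self, tmp_path):
        path = tmp_path / "sizes.tsv"
        path.write_text("chr1\t100\nchr2\t200\n")
        assert read_chrom_sizes(path) == {"chr1": 100, "chr2": 200}
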