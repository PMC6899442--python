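"""Interaction calling: background model, binomial test, differential test,
binning, and compartments."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from chicnet import interactions as ia
from chicnet.formats_io import GenomicInterval, InteractionRecord, PeakRecord
from chicnet.synthetic_data import simulate_compartment_matrix


def upper_tail_pmf_sum(count: int, n: int, p0: float) -> float:
    """Independent oracle: P(X >= count) by direct pmf summation."""
    if count <= 0:
        return 1.0
    i = np.arange(count, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
              + i * np.log(p0) + (n - i) * np.log1p(-p0))
    return float(np.exp(logpmf).sum())


def two_sided_pmf_sum(k: int, n: int, p0: float) -> float:
    """Oracle: sum of all outcome probabilities <= pmf(k) (minlike rule)."""
    i = np.arange(0, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
              + i * np.log(p0) + (n - i) * np.log1p(-p0))
    pmf = np.exp(logpmf)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())


def make_records(counts, positions, chrom="chr1", width=100):
    """Pairs of one bait (id 0) against others, at given midpoint spacings."""
    records = []
    for i, (c, pos) in enumerate(zip(counts, positions), start=1):
        records.append(InteractionRecord(
            bait_id=0, other_id=i, count=int(c), distance=int(pos),
            bait_interval=GenomicInterval(chrom, 0, width),
            other_interval=GenomicInterval(chrom, pos, pos + width),
            bait_gene="GENE1"))
    return records


class TestExpectedCounts:
    def test_uniform_coverage_gives_equal_expected(self):
        """4 fragments, 6 pairs, 100 reads each: expected = 100 per pair."""
        records = []
        for i in range(4):
            for j in range(i + 1, 4):
                records.append(InteractionRecord(
                    bait_id=i, other_id=j, count=100, distance=50_000))
        out = ia.expected_counts(records, model="coverage_product")
        assert all(math.isclose(r.expected, 100.0) for r in out)

    def test_single_pair_gets_total(self):
        records = [InteractionRecord(bait_id=0, other_id=1, count=600,
                                     distance=50_000)]
        (out,) = ia.expected_counts(records, model="coverage_product")
        assert math.isclose(out.expected, 600.0)

    def test_matches_brute_force_coverage_products(self, rng):
        """Random 20-fragment instance against a from-scratch recomputation."""
        n = 20
        records = []
        for i in range(n):
            for j in range(i + 1, n):
                records.append(InteractionRecord(
                    bait_id=i, other_id=j,
                    count=int(rng.integers(0, 30)),
                    distance=int(abs(i - j) * 4000)))
        out = ia.expected_counts(records, model="coverage_product")
        total = sum(r.count for r in records)
        cov = {i: 0.0 for i in range(n)}
        for r in records:
            cov[r.bait_id] += r.count
            cov[r.other_id] += r.count
        wsum = sum(cov[r.bait_id] * cov[r.other_id] for r in records)
        assert abs(sum(r.expected for r in out) - total) <= 1e-9 * total
        for r in out:
            brute = total * cov[r.bait_id] * cov[r.other_id] / wsum
            assert abs(r.expected - brute) <= 1e-9 * max(brute, 1.0)

    def test_decay_model_conserves_total(self, rng):
        """Expected counts sum to the read total over fitted (testable)
        pairs; self-ligation-range pairs are left unmodelled (NaN)."""
        records = make_records(rng.integers(0, 40, size=200),
                               rng.integers(1000, 900_000, size=200))
        out = ia.expected_counts(records, model="coverage_product_decay")
        fitted = [r for r in out if r.distance >= 10_000]
        near = [r for r in out if r.distance < 10_000]
        total = sum(r.count for r in fitted)
        assert abs(sum(r.expected for r in fitted) - total) <= 1e-6 * total
        assert near and all(math.isnan(r.expected) for r in near)

    def test_all_zero_coverage_rejected(self):
        records = [InteractionRecord(bait_id=0, other_id=1, count=0),
                   InteractionRecord(bait_id=0, other_id=2, count=0)]
        with pytest.raises(ValueError):
            ia.expected_counts(records, model="coverage_product")

    def test_empty_pair_set_rejected(self):
        with pytest.raises(ValueError):
            ia.expected_counts([], model="coverage_product")


class TestCallSignificant:
    def test_zero_count_has_p_one(self):
        recs = make_records([0, 10], [50_000, 60_000])
        recs = ia.expected_counts(recs, model="coverage_product")
        out = ia.call_significant_interactions(recs, alpha=0.05)
        by_pair = {r.pair: r for r in out}
        assert by_pair[(0, 1)].p_value == 1.0

    def test_single_trial_closed_form(self):
        rec = InteractionRecord(bait_id=0, other_id=1, count=1,
                                distance=50_000, expected=0.5)
        (out,) = ia.call_significant_interactions([rec], alpha=0.05)
        assert math.isclose(out.p_value, 0.5, abs_tol=1e-12)

    @pytest.mark.parametrize("n,expected,count", [
        (10_000, 2.0, 8),
        (1_000, 5.0, 20),
        (100_000, 50.0, 100),
        (100, 0.5, 3),
    ])
    def test_matches_pmf_summation_oracle(self, n, expected, count):
        recs = [InteractionRecord(bait_id=0, other_id=1, count=count,
                                  distance=50_000, expected=expected),
                InteractionRecord(bait_id=0, other_id=2, count=n - count,
                                  distance=60_000, expected=n - expected)]
        out = ia.call_significant_interactions(recs, alpha=0.05)
        p = {r.pair: r.p_value for r in out}[(0, 1)]
        assert abs(p - upper_tail_pmf_sum(count, n, expected / n)) <= 1e-10

    def test_min_distance_excludes_pairs_from_testing(self):
        recs = make_records([5, 5], [2_000, 50_000])
        recs = ia.expected_counts(recs, model="coverage_product")
        out = ia.call_significant_interactions(recs, min_distance=10_000)
        by_pair = {r.pair: r for r in out}
        assert math.isnan(by_pair[(0, 1)].p_value)
        assert not math.isnan(by_pair[(0, 2)].p_value)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ia.call_significant_interactions([], alpha=1.5)


class TestMergeAndOverlap:
    def test_counts_sum_pairwise(self):
        r1 = make_records([3, 1], [50_000, 60_000])
        r2 = make_records([5, 0], [50_000, 60_000])
        pooled = ia.merge_replicates(r1, r2)
        assert [r.count for r in pooled] == [8, 1]
        assert sum(r.count for r in pooled) == \
            sum(r.count for r in r1) + sum(r.count for r in r2)

    def test_empty_replicate_is_identity(self):
        r1 = make_records([3, 4], [50_000, 60_000])
        r2 = make_records([0, 0], [50_000, 60_000])
        pooled = ia.merge_replicates(r1, r2)
        assert [r.count for r in pooled] == [3, 4]

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            ia.merge_replicates(make_records([1], [50_000]),
                                make_records([1, 2], [50_000, 60_000]))

    def test_overlap_fractions(self):
        a = {("c", 1), ("c", 2), ("c", 3), ("c", 4)}
        b = {("c", 3), ("c", 4), ("c", 5)}
        fa, fb, mean = ia.replicate_overlap(a, b)
        assert (fa, fb) == (0.5, 2 / 3)
        assert math.isclose(mean, 7 / 12)
        assert ia.replicate_overlap(a, a)[2] == 1.0
        assert ia.replicate_overlap(a, {("c", 9)})[2] == 0.0

    def test_empty_set_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ia.replicate_overlap(set(), {("c", 1)}) == (0.0, 0.0, 0.0)


class TestDifferential:
    def test_symmetric_counts_equal_libraries(self):
        a = make_records([5, 95], [50_000, 60_000])
        b = make_records([5, 95], [50_000, 60_000])
        res = ia.differential_interactions(a, b)
        assert math.isclose(res[0]["p_value"], 1.0)

    def test_extreme_split_closed_form(self):
        """Counts (0, 10) at equal depth: two-sided p = 2 * (1/2)^10."""
        a = make_records([0, 100], [50_000, 60_000])
        b = make_records([10, 90], [50_000, 60_000])
        res = {r["pair"]: r for r in ia.differential_interactions(a, b)}
        assert math.isclose(res[(0, 1)]["p_value"], 2 * 0.5 ** 10,
                            abs_tol=1e-12)
        assert res[(0, 1)]["direction"] == "gained"
        assert res[(0, 1)]["differential"]

    def test_matches_two_sided_pmf_oracle(self):
        a = make_records([20, 80], [50_000, 60_000])
        b = make_records([2, 98], [50_000, 60_000])
        res = {r["pair"]: r for r in ia.differential_interactions(a, b)}
        assert abs(res[(0, 1)]["p_value"] - two_sided_pmf_sum(20, 22, 0.5)) \
            <= 1e-10

    def test_antisymmetry_is_exact(self, rng):
        a = make_records(rng.integers(0, 40, size=50),
                         np.arange(50) * 10_000 + 50_000)
        b = make_records(rng.integers(0, 60, size=50),
                         np.arange(50) * 10_000 + 50_000)
        fwd = ia.differential_interactions(a, b)
        rev = ia.differential_interactions(b, a)
        flip = {"gained": "lost", "lost": "gained",
                "none": "none", "untested": "untested"}
        for f, r in zip(fwd, rev):
            assert f["p_value"] == r["p_value"] or (
                math.isnan(f["p_value"]) and math.isnan(r["p_value"]))
            assert r["direction"] == flip[f["direction"]]

    def test_zero_total_reported_untested(self):
        a = make_records([0, 50], [50_000, 60_000])
        b = make_records([0, 50], [50_000, 60_000])
        res = {r["pair"]: r for r in ia.differential_interactions(a, b)}
        assert res[(0, 1)]["direction"] == "untested"
        assert math.isnan(res[(0, 1)]["p_value"])


class TestBinContacts:
    def test_same_bin_and_symmetry(self):
        recs = make_records([1], [350_000])
        mat = ia.bin_contacts(recs, bin_size=100_000, chrom="chr1",
                              chrom_length=1_000_000)
        assert mat.counts[0, 3] == 1 and mat.counts[3, 0] == 1
        assert mat.counts.sum() == 2  # mirrored once

    def test_total_conservation_cis(self, rng):
        recs = make_records(rng.integers(0, 5, size=30),
                            rng.integers(1_000, 900_000, size=30))
        mat = ia.bin_contacts(recs, bin_size=50_000, chrom="chr1",
                              chrom_length=1_000_000)
        total = sum(r.count for r in recs)
        off_diag = np.triu(mat.counts, 1).sum()
        diag = np.trace(mat.counts)
        assert diag + off_diag == total


class TestCompartments:
    def test_recovers_planted_blocks(self):
        mat, labels, dhs = simulate_compartment_matrix(n_bins=40, seed=3)
        pc1, called, kept = ia.compartment_pc1(mat, dhs)
        agree = np.mean([c == t for c, t in zip(called, labels)])
        assert agree == 1.0

    def test_pc1_satisfies_eigen_equation(self):
        """PC1 solves corr @ v = lambda v for the brute-force O/E correlation."""
        mat, _, dhs = simulate_compartment_matrix(n_bins=20, seed=5)
        pc1, _, kept = ia.compartment_pc1(mat, dhs)
        counts = mat.counts[np.ix_(kept, kept)]
        sep = np.abs(np.subtract.outer(kept, kept))
        oe = counts.astype(float).copy()
        for d in np.unique(sep):
            sel = sep == d
            if counts[sel].mean() > 0:
                oe[sel] = counts[sel] / counts[sel].mean()
        corr = np.corrcoef(oe)
        v = pc1[kept]
        lam = v @ corr @ v / (v @ v)
        resid = corr @ v - lam * v
        assert np.max(np.abs(resid)) <= 1e-8

    def test_orientation_follows_dhs_density(self):
        mat, labels, dhs = simulate_compartment_matrix(n_bins=30, seed=7)
        pc1, called, kept = ia.compartment_pc1(mat, dhs)
        a_bins = [i for i in kept if called[i] == "A"]
        assert np.nanmean(pc1[a_bins]) > 0

    def test_constant_matrix_rejected(self):
        mat = ia.ContactMatrix(bin_size=10, chrom="chr1", n_bins=5,
                               counts=np.ones((5, 5)))
        with pytest.raises(ValueError):
            ia.compartment_pc1(mat, [])

    def test_dhs_fraction_sums_to_one(self):
        labels = ["A", "A", "B", "dropped"]
        dhs = [PeakRecord(interval=GenomicInterval("chr1", i * 100 + 10,
                                                   i * 100 + 90))
               for i in range(4)]
        frac = ia.dhs_compartment_fraction(dhs, labels, bin_size=100,
                                           chrom="chr1")
        assert math.isclose(sum(frac.values()), 1.0)
        assert frac["A"] == 0.5 and frac["B"] == 0.25
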