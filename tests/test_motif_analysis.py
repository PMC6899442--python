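"""PWM scanning, occupancy, enrichment, and co-localization statistics."""

import itertools
import math

import numpy as np
import pytest

from chicnet import motif_analysis as ma
from chicnet.formats_io import (
    Footprint,
    GenomicInterval,
    MotifModel,
    MotifOccurrence,
    PeakRecord,
)


def make_motif(consensus, major=0.85, motif_id="M", family="FAM"):
    minor = (1 - major) / 3
    matrix = np.full((4, len(consensus)), minor)
    for j, base in enumerate(consensus):
        matrix["ACGT".index(base), j] = major
    return MotifModel(motif_id=motif_id, family=family, matrix=matrix)


def occ(center, motif_id="A", chrom="chr1", occupied=True, strand="+"):
    return MotifOccurrence(
        interval=GenomicInterval(chrom, center - 5, center + 5, strand),
        motif_id=motif_id, strand=strand, llr_score=1.0, occupied=occupied)


def fp(start, end, chrom="chr1"):
    return Footprint(interval=GenomicInterval(chrom, start, end),
                     score=5.0, p_value=1e-5)


def brute_force_hits(sequence, motif, threshold):
    """Enumerate every window on both strands and apply the LLR cutoff."""
    sm = motif.score_matrix
    cutoff = threshold * motif.max_llr
    hits = set()
    L = len(motif)
    for strand, seq in (("+", sequence),
                        ("-", ma.reverse_complement(sequence))):
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            if "N" in window:
                continue
            llr = sum(sm["ACGT".index(b), j] for j, b in enumerate(window))
            if llr >= cutoff:
                start = i if strand == "+" else len(seq) - i - L
                hits.add((start, strand, round(llr, 9)))
    return hits


class TestScanPwm:
    def test_consensus_scores_max_llr(self):
        motif = make_motif("ACGTAC")
        (hit,) = [o for o in ma.scan_pwm("ACGTAC", motif, "chr1")
                  if o.strand == "+"]
        assert math.isclose(hit.llr_score, motif.max_llr)

    def test_reverse_complement_hits_minus_strand(self):
        motif = make_motif("AACGTC")
        seq = "GACGTT"  # reverse complement of the consensus
        hits = ma.scan_pwm(seq, motif, "chr1")
        minus = [o for o in hits if o.strand == "-"]
        assert len(minus) == 1
        assert math.isclose(minus[0].llr_score, motif.max_llr)

    def test_genome_offset_applied(self):
        motif = make_motif("ACGT")
        hits = ma.scan_pwm("TTACGTTT", motif, "chr5", offset=1000)
        plus = [o for o in hits if o.strand == "+"]
        assert plus[0].interval.start == 1002

    @pytest.mark.parametrize("consensus", ["ACGT", "GATA"])
    def test_equals_full_enumeration_on_all_4mers(self, consensus):
        motif = make_motif(consensus)
        seq = "".join("".join(p) for p in
                      itertools.product("ACGT", repeat=4))
        ours = {(o.interval.start, o.strand, round(o.llr_score, 9))
                for o in ma.scan_pwm(seq, motif, "chr1")}
        assert ours == brute_force_hits(seq, motif, 0.8)

    def test_n_windows_skipped(self):
        motif = make_motif("ACGT")
        assert ma.scan_pwm("ACNT", motif, "chr1") == []

    def test_motif_longer_than_sequence(self):
        assert ma.scan_pwm("ACG", make_motif("ACGTAC"), "chr1") == []

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            ma.scan_pwm("ACXT", make_motif("ACGT"), "chr1")


class TestOccupiedMotifs:
    def test_overlap_and_halfopen_boundary(self):
        occs = [
            MotifOccurrence(interval=GenomicInterval("chr1", 100, 112),
                            motif_id="M", strand="+", llr_score=1.0),
            MotifOccurrence(interval=GenomicInterval("chr1", 200, 212),
                            motif_id="M", strand="+", llr_score=1.0),
        ]
        out = ma.occupied_motifs(occs, [fp(105, 125), fp(212, 230)])
        assert out[0].occupied is True      # [100,112) vs [105,125) overlap
        assert out[1].occupied is False     # [200,212) vs [212,230) abut only

    def test_no_footprints_means_unoccupied(self):
        occs = [occ(100, occupied=True)]
        assert all(not o.occupied for o in ma.occupied_motifs(occs, []))


class TestEnrichmentScore:
    def _peaks(self, n, with_occ_at=()):
        return [PeakRecord(interval=GenomicInterval("chr1", i * 1000,
                                                    i * 1000 + 200))
                for i in range(n)], \
               [occ(i * 1000 + 100) for i in with_occ_at]

    def test_equal_fractions_give_zero(self):
        spec, occs = self._peaks(4, with_occ_at=(0, 1))
        ref = [PeakRecord(interval=p.interval) for p in spec[:4]]
        assert ma.enrichment_score(spec, ref, occs, pseudo=0.5) == 0.0

    def test_four_fold_without_pseudo(self):
        spec = [PeakRecord(interval=GenomicInterval("chr1", i * 1000,
                                                    i * 1000 + 200))
                for i in range(10)]
        ref = [PeakRecord(interval=GenomicInterval("chr2", i * 1000,
                                                   i * 1000 + 200))
               for i in range(10)]
        occs = [occ(i * 1000 + 100) for i in range(4)] \
            + [occ(100, chrom="chr2")]
        assert math.isclose(
            ma.enrichment_score(spec, ref, occs, pseudo=0.0), 2.0)

    def test_zero_specific_fraction(self):
        ref = [PeakRecord(interval=GenomicInterval("chr2", i * 1000,
                                                   i * 1000 + 200))
               for i in range(2)]
        spec = [PeakRecord(interval=GenomicInterval("chr1", 0, 200))]
        occs = [occ(100, chrom="chr2")]
        es = ma.enrichment_score(spec, ref, occs, pseudo=0.01)
        assert math.isclose(es, math.log2(0.01 / 0.51))

    def test_antisymmetric_without_pseudo(self):
        spec, occs_a = self._peaks(4, with_occ_at=(0,))
        ref = [PeakRecord(interval=GenomicInterval("chr2", i * 1000,
                                                   i * 1000 + 200))
               for i in range(4)]
        occs = occs_a + [occ(i * 1000 + 100, chrom="chr2") for i in (0, 1)]
        fwd = ma.enrichment_score(spec, ref, occs, pseudo=0.0)
        rev = ma.enrichment_score(ref, spec, occs, pseudo=0.0)
        assert math.isclose(fwd, -rev)

    def test_empty_peak_set_rejected(self):
        with pytest.raises(ValueError):
            ma.enrichment_score([], [], [])


class TestColocalizationCounts:
    def test_boundary_inclusive_at_gap(self):
        assert ma.colocalization_counts([occ(100)], [occ(150, "B")], 50) == 1
        assert ma.colocalization_counts([occ(100)], [occ(151, "B")], 50) == 0

    def test_a_occurrence_counted_once(self):
        a = [occ(100)]
        b = [occ(90, "B"), occ(110, "B")]
        assert ma.colocalization_counts(a, b, 50) == 1

    def test_self_pair_convention(self):
        """An occurrence is never its own partner; a co-located distinct
        occurrence at distance 0 does count."""
        shared = [occ(100)]
        assert ma.colocalization_counts(shared, shared, 50) == 0
        twin = [MotifOccurrence(interval=GenomicInterval("chr1", 95, 105, "-"),
                                motif_id="A", strand="-", llr_score=1.0,
                                occupied=True)]
        assert ma.colocalization_counts(shared, shared + twin, 50) == 1

    def test_matches_brute_force(self, rng):
        a = [occ(int(c)) for c in rng.integers(100, 5000, size=100)]
        b = [occ(int(c), "B") for c in rng.integers(100, 5000, size=100)]
        brute = sum(
            1 for x in a
            if any(abs(x.center - y.center) <= 50 for y in b))
        assert ma.colocalization_counts(a, b, 50) == brute

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            ma.colocalization_counts([], [], -1)


def build_coloc_universe(rng, m=8, width=200, spacing=1000, occupied_k=4):
    """Small universe: one A and one B occurrence per footprint."""
    universe = [fp(i * spacing, i * spacing + width) for i in range(m)]
    chosen = set(rng.choice(m, size=occupied_k, replace=False).tolist())
    occ_a, occ_b = [], []
    for i in range(m):
        base = i * spacing
        ca = base + int(rng.integers(10, width - 10))
        cb = base + int(rng.integers(10, width - 10))
        occ_a.append(occ(ca, "A", occupied=i in chosen))
        occ_b.append(occ(cb, "B", occupied=i in chosen))
    return universe, occ_a, occ_b


def enumerate_null_moments(universe, occ_a, occ_b, k, max_gap=50):
    """Exact mean/sd of the subset co-localization count over all C(m,k)
    subsets of the footprint universe."""
    m = len(universe)
    counts = []
    for subset in itertools.combinations(range(m), k):
        chosen = set(subset)
        n = 0
        for a in occ_a:
            fa = a.center // 1000
            if fa not in chosen:
                continue
            if any(abs(a.center - b.center) <= max_gap
                   and (b.center // 1000) in chosen for b in occ_b):
                n += 1
        counts.append(n)
    counts = np.array(counts, dtype=float)
    return counts.mean(), counts.std(ddof=1)


class TestColocalizationZscore:
    def test_bootstrap_matches_enumeration(self, rng):
        universe, occ_a, occ_b = build_coloc_universe(rng, m=8, occupied_k=4)
        res = ma.colocalization_zscore(occ_a, occ_b, universe, n_boot=40_000,
                                       seed=5)
        exact_mean, exact_sd = enumerate_null_moments(universe, occ_a, occ_b,
                                                      k=4)
        mc_se = exact_sd / math.sqrt(res["n_boot"])
        assert abs(res["mean_null"] - exact_mean) <= 3 * mc_se
        assert abs(res["sd_null"] - exact_sd) <= 0.05 * max(exact_sd, 0.1)

    def test_fixed_seed_is_bit_identical(self, rng):
        universe, occ_a, occ_b = build_coloc_universe(rng)
        r1 = ma.colocalization_zscore(occ_a, occ_b, universe, n_boot=500,
                                      seed=7)
        r2 = ma.colocalization_zscore(occ_a, occ_b, universe, n_boot=500,
                                      seed=7)
        assert r1 == r2

    def test_degenerate_sd_flagged(self):
        universe = [fp(0, 200)]
        a = [occ(50, "A")]
        b = [occ(60, "B")]
        res = ma.colocalization_zscore(a, b, universe, n_boot=50, seed=1)
        assert res["defined"] is False and math.isnan(res["z"])


class TestPeakDistances:
    def _peaks(self, summits, chrom="chr1"):
        return [PeakRecord(interval=GenomicInterval(chrom, s - 10, s + 10),
                           summit_offset=10) for s in summits]

    def test_identity_gives_zero_distances(self):
        peaks = self._peaks([100, 500])
        hist, dists, unmatched = ma.peak_distance_distribution(
            peaks, peaks, np.array([0, 1, 10]))
        assert list(dists) == [0, 0] and unmatched == 0

    def test_nearest_distances(self):
        a = self._peaks([100, 700])
        b = self._peaks([120, 900])
        _, dists, _ = ma.peak_distance_distribution(a, b,
                                                    np.array([0, 1000]))
        assert sorted(dists) == [20, 200]

    def test_histogram_conserves_matched_count(self, rng):
        a = self._peaks(sorted(rng.integers(100, 10_000, size=30)))
        b = self._peaks(sorted(rng.integers(100, 10_000, size=10)))
        edges = np.array([0, 10, 100, 1000, 100_000])
        hist, dists, unmatched = ma.peak_distance_distribution(a, b, edges)
        assert hist.sum() == len(dists) == 30 - unmatched

    def test_missing_chromosome_unmatched(self):
        a = self._peaks([100], chrom="chr9")
        _, dists, unmatched = ma.peak_distance_distribution(
            a, self._peaks([100]), np.array([0, 10]))
        assert unmatched == 1 and len(dists) == 0


class TestPairwiseMatrix:
    def test_planted_adjacent_pair_ranks_highest(self, rng):
        """Families planted always within 50 bp beat independent background."""
        m = 120
        universe = [fp(i * 1000, i * 1000 + 400) for i in range(m)]
        fams = {"X": [], "Y": [], "Z": []}
        for i in range(m):
            base = i * 1000
            cx = base + int(rng.integers(20, 380))
            fams["X"].append(occ(cx, "X"))
            fams["Y"].append(occ(cx + int(rng.integers(0, 40)), "Y"))
            fams["Z"].append(occ(base + int(rng.integers(20, 380)), "Z"))
        # occupied subset: half the universe
        for lst in fams.values():
            for i, o in enumerate(lst):
                o.occupied = i < m // 2
        mat = ma.pairwise_coloc_matrix(fams, universe, n_boot=300, seed=3)
        assert mat.shape == (3, 3)
        off_diag = [(a, b) for a in mat.index for b in mat.columns if a != b]
        best = max(off_diag, key=lambda p: mat.loc[p])
        assert set(best) == {"X", "Y"}

    def test_requires_two_families(self):
        with pytest.raises(ValueError):
            ma.pairwise_coloc_matrix({"X": []}, [], n_boot=10)
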