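"""Promoter capture Hi-C interaction calling and compartment analysis.

Significant bait--other-end interactions are detected with a cumulative
binomial test against a random-ligation background: with N total read
pairs over the tested pair universe and an expected count e_ij per pair,
the upper-tail probability P(X >= k_ij) with X ~ Binomial(N, e_ij / N)
scores how strongly a pair exceeds the background. The background itself
is the normalized product of fragment coverages, optionally modulated by
an empirical distance-decay factor estimated from the data.

Differential interactions between two conditions use an exact two-sided
binomial proportion test on the per-pair count split, with the expected
proportion set by the two library sizes.

A/B compartments come from the leading eigenvector of the Pearson
correlation matrix of the distance-normalized (observed/expected) binned
contact matrix, with the sign oriented by DHS density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression
from statsmodels.stats.multitest import multipletests

from .formats_io import (  # noqa: F401  (re-exported domain types)
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
    RestrictionFragment,
)

__all__ = [
    "InteractionRecord",
    "ContactMatrix",
    "expected_counts",
    "call_significant_interactions",
    "merge_replicates",
    "replicate_overlap",
    "differential_interactions",
    "bin_contacts",
    "compartment_pc1",
    "dhs_compartment_fraction",
]


@dataclass
class ContactMatrix:
    """A symmetric binned contact-count matrix for one chromosome."""

    bin_size: int
    chrom: str
    n_bins: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_bins, self.n_bins):
            raise ValueError("matrix shape does not match bin count")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be nonnegative")


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------

def expected_counts(
    records: list[InteractionRecord],
    model: str = "coverage_product_decay",
    n_distance_bins: int = 60,
    n_iter: int = 20,
    min_fit_distance: int = 10_000,
) -> list[InteractionRecord]:
    """Fill the expected count of every pair under the background model.

    Under ``coverage_product``, coverage c_i is the marginal read count
    of fragment i over the pair universe and expected_ij =
    N * (c_i * c_j) / sum over pairs of (c_k * c_l).

    ``coverage_product_decay`` factorizes the background as
    c_i * c_j * f(d_ij) with f a monotone distance-decay factor over
    log2-spaced distance bins (trans pairs share one unconstrained bin).
    Raw marginals conflate a fragment's intrinsic visibility with its
    proximity to high-contact partners, so the factors are fitted
    jointly by iterative proportional fitting: each round rescales the
    decay by the (observed / expected) bin totals -- pooled by weighted
    isotonic regression so f is non-increasing in distance, which keeps
    the fine binning needed near the steep short-range end from
    overfitting -- then rescales each coverage by its
    (observed / expected) marginal. Pairs closer than
    ``min_fit_distance`` are self-ligation-range: they are excluded
    from the fit entirely (their huge counts would otherwise dominate
    the marginals of their fragments and poison the coverage
    estimates) and get no expected value (NaN); they are never tested.
    Expected counts sum to N, the total read pairs over fitted pairs.
    """
    if model not in ("coverage_product", "coverage_product_decay"):
        raise ValueError(f"unknown background model {model!r}")
    if not records:
        raise ValueError("empty pair set")
    counts = np.array([r.count for r in records], dtype=float)
    total = counts.sum()

    ids = sorted({r.bait_id for r in records} | {r.other_id for r in records})
    if len(ids) < 2:
        raise ValueError("need at least 2 fragments")
    idx = {fid: i for i, fid in enumerate(ids)}
    bi = np.array([idx[r.bait_id] for r in records])
    oi = np.array([idx[r.other_id] for r in records])

    if model == "coverage_product":
        cov = np.zeros(len(ids))
        np.add.at(cov, bi, counts)
        np.add.at(cov, oi, counts)
        if cov.sum() == 0:
            raise ValueError("all-zero coverage")
        weights = cov[bi] * cov[oi]
        wsum = weights.sum()
        if wsum <= 0:
            raise ValueError("degenerate background: all weights zero")
        expected = total * weights / wsum
        return [replace(r, expected=float(e))
                for r, e in zip(records, expected)]

    all_dist = np.array(
        [r.distance if r.distance is not None else -1 for r in records],
        dtype=float,
    )
    fit_mask = (all_dist < 0) | (all_dist >= min_fit_distance)
    fit_records = [r for r, m in zip(records, fit_mask) if m]
    if not fit_records:
        raise ValueError("no pairs beyond min_fit_distance to fit")
    counts = counts[fit_mask]
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero coverage")
    ids = sorted({r.bait_id for r in fit_records}
                 | {r.other_id for r in fit_records})
    idx = {fid: i for i, fid in enumerate(ids)}
    bi = np.array([idx[r.bait_id] for r in fit_records])
    oi = np.array([idx[r.other_id] for r in fit_records])
    dist = all_dist[fit_mask]
    cis = dist >= 0
    which = np.zeros(len(fit_records), dtype=np.int64)
    n_bins = 1
    centers = np.zeros(1)
    if cis.any():
        d = np.maximum(dist[cis], 1.0)
        lo, hi = np.log2(d.min()), np.log2(d.max())
        edges = np.linspace(lo, hi + 1e-9, n_distance_bins + 1)
        which[cis] = np.clip(np.digitize(np.log2(d), edges) - 1, 0,
                             n_distance_bins - 1)
        which[~cis] = n_distance_bins  # trans bin, outside the monotone fit
        n_bins = n_distance_bins + 1
        centers = 0.5 * (edges[:-1] + edges[1:])

    # both-ends-baited pairs sit almost outside the marginal constraints
    # (there are no nonbait-nonbait pairs), so the bait/non-bait coverage
    # split is weakly identified; an explicit class factor absorbs it
    bait_set = {r.bait_id for r in fit_records}
    both_bait = np.array([r.other_id in bait_set for r in fit_records])
    log_g = 0.0

    cov = np.ones(len(ids))
    log_f = np.zeros(n_bins)
    marg_obs = np.zeros(len(ids))
    np.add.at(marg_obs, bi, counts)
    np.add.at(marg_obs, oi, counts)
    bin_obs = np.bincount(which, weights=counts, minlength=n_bins)
    n_cis_bins = n_bins - 1 if cis.any() else 0
    for _ in range(max(1, n_iter)):
        e = cov[bi] * cov[oi] * np.exp(log_f[which] + log_g * both_bait)
        e *= total / e.sum()
        if both_bait.any() and (~both_bait).any():
            obs_bb = counts[both_bait].sum()
            exp_bb = e[both_bait].sum()
            if obs_bb > 0 and exp_bb > 0:
                log_g += np.log(obs_bb / exp_bb)
        e = cov[bi] * cov[oi] * np.exp(log_f[which] + log_g * both_bait)
        e *= total / e.sum()
        bin_e = np.bincount(which, weights=e, minlength=n_bins)
        ok = (bin_e > 0) & (bin_obs > 0)
        raw = log_f.copy()
        raw[ok] = log_f[ok] + np.log(bin_obs[ok] / bin_e[ok])
        if n_cis_bins:
            ok_cis = ok[:n_cis_bins]
            if ok_cis.any():
                fit = isotonic_regression(
                    raw[:n_cis_bins][ok_cis],
                    weights=bin_obs[:n_cis_bins][ok_cis],
                    increasing=False).x
                log_f[:n_cis_bins] = np.interp(
                    centers[:n_cis_bins], centers[:n_cis_bins][ok_cis], fit)
            log_f[n_cis_bins:] = raw[n_cis_bins:]
        else:
            log_f = raw
        e = cov[bi] * cov[oi] * np.exp(log_f[which] + log_g * both_bait)
        e *= total / e.sum()
        marg_e = np.zeros(len(ids))
        np.add.at(marg_e, bi, e)
        np.add.at(marg_e, oi, e)
        # sqrt damping: the ratio hits both endpoints of every pair, so a
        # full-step symmetric update squares the correction and oscillates
        cov *= np.where(marg_e > 0,
                        np.sqrt(marg_obs / np.maximum(marg_e, 1e-300)), 1.0)
    weights = cov[bi] * cov[oi] * np.exp(log_f[which] + log_g * both_bait)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("degenerate background: all weights zero")
    expected = total * weights / wsum
    fitted = iter(expected)
    return [replace(r, expected=float(next(fitted)) if m else float("nan"))
            for r, m in zip(records, fit_mask)]


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def binomial_tail_p(count: np.ndarray, n: int, p0: np.ndarray) -> np.ndarray:
    """Upper-tail P(X >= count) with X ~ Binomial(n, p0), vectorized."""
    count = np.asarray(count)
    p0 = np.clip(np.asarray(p0, dtype=float), 0.0, 1.0)
    return stats.binom.sf(count - 1, n, p0)


def call_significant_interactions(
    records: list[InteractionRecord],
    alpha: float = 0.05,
    min_distance: int = 10_000,
) -> list[InteractionRecord]:
    """Assign binomial p-values and BH q-values; flag q <= alpha.

    Pairs closer than ``min_distance`` (fragment midpoints) are excluded
    from testing (self-ligation range); trans pairs are tested. Output is
    sorted by (bait_id, other_id) for deterministic downstream behaviour.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    tested = [r for r in records
              if r.distance is None or r.distance >= min_distance]
    skipped = [r for r in records
               if r.distance is not None and r.distance < min_distance]
    if not tested:
        return sorted(skipped, key=lambda r: r.pair)
    counts = np.array([r.count for r in tested])
    expected = np.array([r.expected for r in tested], dtype=float)
    if np.isnan(expected).any():
        raise ValueError("expected counts missing; run expected_counts first")
    n_total = int(round(counts.sum()))
    if n_total < 1:
        raise ValueError("no read pairs in tested universe")
    if (expected > n_total).any():
        raise ValueError("expected count exceeds library size")
    pvals = binomial_tail_p(counts, n_total, expected / n_total)
    # deterministic BH: rank ties broken by descending count then pair id
    order = sorted(
        range(len(tested)),
        key=lambda i: (pvals[i], -counts[i], tested[i].pair),
    )
    reject, qvals_ord, _, _ = multipletests(pvals[order], alpha=alpha,
                                            method="fdr_bh")
    out = []
    for rank, i in enumerate(order):
        out.append(replace(tested[i], p_value=float(pvals[i]),
                           q_value=float(qvals_ord[rank]),
                           significant=bool(reject[rank])))
    out.extend(replace(r, p_value=float("nan"), q_value=float("nan"),
                       significant=False) for r in skipped)
    return sorted(out, key=lambda r: r.pair)


def merge_replicates(*replicates: list[InteractionRecord]) -> list[InteractionRecord]:
    """Pool replicate read counts pairwise over an identical pair universe."""
    if not replicates:
        raise ValueError("no replicates given")
    maps = [{r.pair: r for r in rep} for rep in replicates]
    universe = set(maps[0])
    for m in maps[1:]:
        if set(m) != universe:
            raise ValueError("replicates have mismatched pair universes")
    return [
        replace(maps[0][pair], count=sum(m[pair].count for m in maps),
                expected=float("nan"), p_value=float("nan"),
                q_value=float("nan"), significant=False)
        for pair in sorted(universe)
    ]


def replicate_overlap(
    called_rep1: set | list,
    called_rep2: set | list,
) -> tuple[float, float, float]:
    """Fraction of each replicate's significant pairs shared, and the mean."""
    a = {r.pair if isinstance(r, InteractionRecord) else r for r in called_rep1}
    b = {r.pair if isinstance(r, InteractionRecord) else r for r in called_rep2}
    if not a or not b:
        warnings.warn("empty significant set; overlap defined as 0")
        return 0.0, 0.0, 0.0
    shared = len(a & b)
    fa, fb = shared / len(a), shared / len(b)
    return fa, fb, (fa + fb) / 2


# ---------------------------------------------------------------------------
# Differential interactions
# ---------------------------------------------------------------------------

def _two_sided_binom_p(k: int, n: int, p0: float) -> float:
    return stats.binomtest(k, n, p0, alternative="two-sided").pvalue


def differential_interactions(
    records_a: list[InteractionRecord],
    records_b: list[InteractionRecord],
    p_cutoff: float = 0.01,
) -> list[dict]:
    """Exact two-sided binomial test of the per-pair count split.

    For each pair, count_a out of (count_a + count_b) successes are tested
    against the expected proportion N_A / (N_A + N_B) set by the library
    sizes. Direction is ``gained`` when the depth-scaled count rises in
    condition B. Pairs with zero total count are reported untested.

    The test is evaluated in a canonical condition order internally, so
    swapping the two inputs flips every direction label and reproduces
    the p-values exactly.
    """
    map_a = {r.pair: r for r in records_a}
    map_b = {r.pair: r for r in records_b}
    if set(map_a) != set(map_b):
        raise ValueError("conditions have mismatched pair universes")
    n_a = sum(r.count for r in records_a)
    n_b = sum(r.count for r in records_b)
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both conditions need positive library size")

    # canonical orientation: test the lexicographically smaller
    # (library size, count vector) side so A<->B swaps are exact mirrors
    pairs = sorted(map_a)
    vec_a = (n_a, tuple(map_a[p].count for p in pairs))
    vec_b = (n_b, tuple(map_b[p].count for p in pairs))
    flip = vec_b < vec_a
    first, second = (map_b, map_a) if flip else (map_a, map_b)
    n_first, n_second = (n_b, n_a) if flip else (n_a, n_b)
    p0 = n_first / (n_first + n_second)

    results = []
    for pair in pairs:
        k1, k2 = first[pair].count, second[pair].count
        n = k1 + k2
        if n == 0:
            results.append({"pair": pair, "count_a": map_a[pair].count,
                            "count_b": map_b[pair].count, "p_value": float("nan"),
                            "direction": "untested", "differential": False})
            continue
        p = _two_sided_binom_p(k1, n, p0)
        rate1, rate2 = k1 / n_first, k2 / n_second
        # direction is reported relative to the original (A, B) order
        if flip:
            gained = rate1 > rate2  # first=B: B above A means gained
        else:
            gained = rate2 > rate1
        direction = "gained" if gained else ("lost" if rate1 != rate2 else "none")
        results.append({"pair": pair, "count_a": map_a[pair].count,
                        "count_b": map_b[pair].count, "p_value": float(p),
                        "direction": direction,
                        "differential": bool(p <= p_cutoff)})
    return results


# ---------------------------------------------------------------------------
# Binned matrices and compartments
# ---------------------------------------------------------------------------

def bin_contacts(
    records: list[InteractionRecord],
    bin_size: int,
    chrom: str,
    chrom_length: int,
) -> ContactMatrix:
    """Aggregate cis pair counts into a symmetric binned matrix.

    Each pair contributes its count at the (midpoint bin, midpoint bin)
    cell, mirrored across the diagonal.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.ceil(chrom_length / bin_size))
    mat = np.zeros((n_bins, n_bins))
    for r in records:
        if r.bait_interval is None or r.other_interval is None:
            raise ValueError("records need intervals for binning")
        if r.bait_interval.chrom != chrom or r.other_interval.chrom != chrom:
            continue
        i = r.bait_interval.midpoint // bin_size
        j = r.other_interval.midpoint // bin_size
        mat[i, j] += r.count
        if i != j:
            mat[j, i] += r.count
    return ContactMatrix(bin_size=bin_size, chrom=chrom, n_bins=n_bins,
                         counts=mat)


def compartment_pc1(
    matrix: ContactMatrix,
    dhs: list[PeakRecord],
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """A/B compartments from the leading eigenvector of the O/E correlation.

    The observed matrix is normalized by the mean count at each bin
    separation (observed/expected), the Pearson correlation matrix of the
    O/E matrix is eigendecomposed, and the leading eigenvector is oriented
    so that bins with above-median DHS density have positive mean PC1.
    Bins with zero marginal are dropped (label ``dropped``, PC1 NaN).

    Returns (pc1 per bin, labels per bin in {A, B, dropped}, kept bin idx).
    """
    counts = matrix.counts
    n = matrix.n_bins
    keep = counts.sum(axis=0) > 0
    if keep.sum() < 4:
        raise ValueError("need >= 4 non-empty bins")
    sub = counts[np.ix_(keep, keep)]
    m = sub.shape[0]
    # observed / expected by bin separation
    kept_pos = np.flatnonzero(keep)
    sep = np.abs(kept_pos[:, None] - kept_pos[None, :])
    oe = np.array(sub, dtype=float)
    for d in np.unique(sep):
        sel = sep == d
        mean = sub[sel].mean()
        if mean > 0:
            oe[sel] = sub[sel] / mean
    if np.allclose(oe.std(axis=0), 0):
        raise ValueError("constant O/E matrix: no principal direction")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    pc1_kept = evecs[:, -1]

    # orient: above-median DHS density bins get positive mean PC1
    density = np.zeros(n)
    for peak in dhs:
        if peak.interval.chrom != matrix.chrom:
            continue
        b = peak.summit // matrix.bin_size
        if 0 <= b < n:
            density[b] += 1
    dens_kept = density[keep]
    high = dens_kept > np.median(dens_kept)
    if high.any() and pc1_kept[high].mean() < 0:
        pc1_kept = -pc1_kept

    pc1 = np.full(n, np.nan)
    pc1[keep] = pc1_kept
    labels = ["dropped"] * n
    for i, b in enumerate(kept_pos):
        labels[b] = "A" if pc1_kept[i] > 0 else "B"
    return pc1, labels, kept_pos


def dhs_compartment_fraction(
    dhs: list[PeakRecord],
    labels: list[str],
    bin_size: int,
    chrom: str,
) -> dict[str, float]:
    """Fractions of DHSs in A (active) / B (inactive) / unassigned bins."""
    tally = {"A": 0, "B": 0, "unassigned": 0}
    for peak in dhs:
        if peak.interval.chrom != chrom:
            tally["unassigned"] += 1
            continue
        b = peak.summit // bin_size
        if 0 <= b < len(labels) and labels[b] in ("A", "B"):
            tally[labels[b]] += 1
        else:
            tally["unassigned"] += 1
    total = sum(tally.values())
    if total == 0:
        return {k: 0.0 for k in tally}
    return {k: v / total for k, v in tally.items()}
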