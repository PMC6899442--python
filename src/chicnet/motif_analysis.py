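"""PWM scanning, occupied motifs, enrichment, and co-localization statistics.

An "occupied" motif is a PWM match that overlaps a called digital
footprint by at least one base -- the footprint provides evidence that
the motif is actually bound. Co-localization between two motif sets is
counted center-to-center within a 50-bp window, and its significance is
assessed with a bootstrap Z-score: random footprint sets of the same
size as the observed footprinted set are drawn without replacement from
the footprint universe, the co-localization count is recomputed in each,
and Z = (observed - mean_null) / sd_null.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .formats_io import (  # noqa: F401
    Footprint,
    GenomicInterval,
    MotifModel,
    MotifOccurrence,
    PeakRecord,
)

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "scan_pwm",
    "occupied_motifs",
    "enrichment_score",
    "colocalization_counts",
    "colocalization_zscore",
    "peak_distance_distribution",
    "pairwise_coloc_matrix",
    "cluster_scores",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MAX_GAP = 50


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid sequence character {exc.args[0]!r}") from exc


def _strand_scores(enc: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    """LLR at every offset of one strand; NaN where the window contains N."""
    length = score_matrix.shape[1]
    n_off = len(enc) - length + 1
    if n_off <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, length)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_off, np.nan)
    if valid.any():
        w = windows[valid]
        scores[valid] = score_matrix[w, np.arange(length)].sum(axis=1)
    return scores


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    chrom: str,
    offset: int = 0,
    threshold: float = 0.8,
) -> list[MotifOccurrence]:
    """Scan both strands for PWM matches above a fraction of the maximal LLR.

    ``offset`` places the sequence in genome space: reported intervals are
    ``[offset + i, offset + i + L)``. Windows containing N are skipped.
    """
    sequence = sequence.upper()
    length = len(motif)
    if length > len(sequence):
        return []
    enc_fwd = _encode(sequence)
    enc_rev = _encode(reverse_complement(sequence))
    sm = motif.score_matrix
    cutoff = threshold * motif.max_llr

    occs: list[MotifOccurrence] = []
    fwd = _strand_scores(enc_fwd, sm)
    for i in np.flatnonzero(~np.isnan(fwd) & (fwd >= cutoff)):
        occs.append(MotifOccurrence(
            interval=GenomicInterval(chrom, offset + int(i),
                                     offset + int(i) + length, "+"),
            motif_id=motif.motif_id, strand="+", llr_score=float(fwd[i])))
    rev = _strand_scores(enc_rev, sm)
    n = len(sequence)
    for i in np.flatnonzero(~np.isnan(rev) & (rev >= cutoff)):
        start = n - int(i) - length  # map back to forward coordinates
        occs.append(MotifOccurrence(
            interval=GenomicInterval(chrom, offset + start,
                                     offset + start + length, "-"),
            motif_id=motif.motif_id, strand="-", llr_score=float(rev[i])))
    occs.sort(key=lambda o: (o.interval.start, o.strand))
    return occs


def occupied_motifs(
    occurrences: list[MotifOccurrence],
    footprints: list[Footprint],
) -> list[MotifOccurrence]:
    """Flag occurrences that overlap a called footprint by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for fp in footprints:
        by_chrom.setdefault(fp.interval.chrom, []).append(
            (fp.interval.start, fp.interval.end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        # running max of ends lets a single bisect answer overlap queries
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        starts_ends[chrom] = (starts, ends)

    out = []
    for occ in occurrences:
        iv = occ.interval
        hit = False
        if iv.chrom in starts_ends:
            starts, ends = starts_ends[iv.chrom]
            j = np.searchsorted(starts, iv.end, side="left")
            hit = j > 0 and ends[j - 1] > iv.start
        out.append(replace(occ, occupied=bool(hit)))
    return out


def _peaks_with_occurrence(peaks: list[PeakRecord],
                           occurrences: list[MotifOccurrence]) -> int:
    count = 0
    for peak in peaks:
        if any(o.interval.overlaps(peak.interval) for o in occurrences):
            count += 1
    return count


def enrichment_score(
    specific_peaks: list[PeakRecord],
    reference_peaks: list[PeakRecord],
    occupied_occurrences: list[MotifOccurrence],
    pseudo: float = 0.01,
) -> float:
    """log2 enrichment of occupied-motif-bearing peaks versus a reference.

    ES = log2((f_spec + pseudo) / (f_ref + pseudo)) where f is the
    fraction of peaks containing at least one occupied occurrence of the
    motif (or motif family) under study.
    """
    if not specific_peaks or not reference_peaks:
        raise ValueError("both peak sets must be non-empty")
    occ = [o for o in occupied_occurrences if o.occupied]
    f_spec = _peaks_with_occurrence(specific_peaks, occ) / len(specific_peaks)
    f_ref = _peaks_with_occurrence(reference_peaks, occ) / len(reference_peaks)
    return float(np.log2((f_spec + pseudo) / (f_ref + pseudo)))


def colocalization_counts(
    occurrences_a: list[MotifOccurrence],
    occurrences_b: list[MotifOccurrence],
    max_gap: int = DEFAULT_MAX_GAP,
) -> int:
    """Number of A occurrences with a B partner within ``max_gap`` bases.

    Distances are center-to-center on the same chromosome, inclusive at
    the boundary; each A occurrence counts at most once. An occurrence is
    never its own partner (relevant when A and B are the same set), but
    distinct co-located occurrences at distance 0 do count.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    b_centers: dict[str, np.ndarray] = {}
    b_keys: dict[str, list[tuple]] = {}
    for chrom in {o.interval.chrom for o in occurrences_b}:
        obs = [o for o in occurrences_b if o.interval.chrom == chrom]
        obs.sort(key=lambda o: o.center)
        b_centers[chrom] = np.array([o.center for o in obs])
        b_keys[chrom] = [_occ_key(o) for o in obs]
    count = 0
    for occ in occurrences_a:
        chrom = occ.interval.chrom
        if chrom not in b_centers:
            continue
        centers = b_centers[chrom]
        lo = np.searchsorted(centers, occ.center - max_gap, side="left")
        hi = np.searchsorted(centers, occ.center + max_gap, side="right")
        me = _occ_key(occ)
        if any(b_keys[chrom][j] != me for j in range(lo, hi)):
            count += 1
    return count


def _occ_key(o: MotifOccurrence) -> tuple:
    return (o.interval.chrom, o.interval.start, o.interval.end,
            o.motif_id, o.strand)


def _footprint_index(footprints: list[Footprint]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom in {f.interval.chrom for f in footprints}:
        items = [(i, f) for i, f in enumerate(footprints)
                 if f.interval.chrom == chrom]
        items.sort(key=lambda t: t[1].interval.start)
        out[chrom] = (
            np.array([f.interval.start for _, f in items]),
            np.array([f.interval.end for _, f in items]),
            np.array([i for i, _ in items]),
        )
    return out


def _assign_to_footprints(occurrences: list[MotifOccurrence],
                          footprints: list[Footprint]) -> np.ndarray:
    """Index of the universe footprint containing each occurrence center (-1 if none)."""
    index = _footprint_index(footprints)
    assigned = np.full(len(occurrences), -1, dtype=np.int64)
    for i, occ in enumerate(occurrences):
        chrom = occ.interval.chrom
        if chrom not in index:
            continue
        starts, ends, ids = index[chrom]
        j = np.searchsorted(starts, occ.center, side="right") - 1
        if j >= 0 and occ.center < ends[j]:
            assigned[i] = ids[j]
    return assigned


def colocalization_zscore(
    occurrences_a: list[MotifOccurrence],
    occurrences_b: list[MotifOccurrence],
    footprint_universe: list[Footprint],
    n_boot: int = 1000,
    seed: int = 0,
    max_gap: int = DEFAULT_MAX_GAP,
    rng: np.random.Generator | None = None,
) -> dict:
    """Bootstrap Z-score for motif A/B co-localization.

    The observed count is the co-localization of the *occupied* A and B
    occurrences. Each null replicate draws, without replacement, a random
    footprint subset of the universe with the same size as the observed
    footprinted set (footprints holding an occupied A or B occurrence)
    and recounts co-localization among the occurrences whose centers fall
    in the drawn footprints.

    Returns a dict with observed, mean_null, sd_null, z, n_boot and a
    ``defined`` flag (False when sd_null is 0).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    m = len(footprint_universe)
    fa = _assign_to_footprints(occurrences_a, footprint_universe)
    fb = _assign_to_footprints(occurrences_b, footprint_universe)

    occ_a = [o for o in occurrences_a if o.occupied]
    occ_b = [o for o in occurrences_b if o.occupied]
    occ_fa = fa[[o.occupied for o in occurrences_a]]
    occ_fb = fb[[o.occupied for o in occurrences_b]]
    observed_set = sorted(set(occ_fa[occ_fa >= 0]) | set(occ_fb[occ_fb >= 0]))
    k = len(observed_set)
    if k > m:
        raise ValueError("observed footprint set larger than universe")
    observed = colocalization_counts(occ_a, occ_b, max_gap)
    if k == 0:
        return {"observed": observed, "mean_null": 0.0, "sd_null": 0.0,
                "z": float("nan"), "defined": False, "n_boot": n_boot}

    # precompute, per A occurrence in the universe, its footprint and the
    # footprints of its candidate B partners (within max_gap, not itself)
    in_a = np.flatnonzero(fa >= 0)
    pairs_fp: list[tuple[int, np.ndarray]] = []
    b_in = [(occurrences_b[i], fb[i]) for i in np.flatnonzero(fb >= 0)]
    by_chrom: dict[str, list[tuple[int, int, tuple]]] = {}
    for occ, f in b_in:
        by_chrom.setdefault(occ.interval.chrom, []).append(
            (occ.center, int(f), _occ_key(occ)))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for ia in in_a:
        occ = occurrences_a[ia]
        cands = by_chrom.get(occ.interval.chrom, [])
        centers = np.array([c for c, _, _ in cands])
        me = _occ_key(occ)
        lo = np.searchsorted(centers, occ.center - max_gap, side="left")
        hi = np.searchsorted(centers, occ.center + max_gap, side="right")
        partners = np.array(sorted({cands[j][1] for j in range(lo, hi)
                                    if cands[j][2] != me}), dtype=np.int64)
        if partners.size:
            pairs_fp.append((int(fa[ia]), partners))

    null_counts = np.zeros(n_boot, dtype=np.int64)
    if pairs_fp:
        # draw all subsets at once; count by footprint membership
        masks = np.zeros((n_boot, m), dtype=bool)
        for b in range(n_boot):
            masks[b, rng.choice(m, size=k, replace=False)] = True
        for f_own, partners in pairs_fp:
            hit = masks[:, f_own] & masks[:, partners].any(axis=1)
            null_counts += hit
    mean_null = float(null_counts.mean())
    sd_null = float(null_counts.std(ddof=1)) if n_boot > 1 else 0.0
    if sd_null == 0.0:
        return {"observed": observed, "mean_null": mean_null, "sd_null": 0.0,
                "z": float("nan"), "defined": False, "n_boot": n_boot}
    z = (observed - mean_null) / sd_null
    return {"observed": observed, "mean_null": mean_null, "sd_null": sd_null,
            "z": float(z), "defined": True, "n_boot": n_boot}


def peak_distance_distribution(
    peaks_a: list[PeakRecord],
    peaks_b: list[PeakRecord],
    bin_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of each A summit's distance to the nearest B summit.

    Returns (histogram counts, distances for matched A peaks, n_unmatched).
    A peaks on chromosomes with no B peak are unmatched.
    """
    b_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.interval.chrom for p in peaks_b}:
        b_by_chrom[chrom] = np.sort(np.array(
            [p.summit for p in peaks_b if p.interval.chrom == chrom]))
    dists = []
    unmatched = 0
    for peak in peaks_a:
        chrom = peak.interval.chrom
        if chrom not in b_by_chrom or len(b_by_chrom[chrom]) == 0:
            unmatched += 1
            continue
        summits = b_by_chrom[chrom]
        j = np.searchsorted(summits, peak.summit)
        best = min(
            (abs(peak.summit - summits[i]) for i in (j - 1, j)
             if 0 <= i < len(summits)),
        )
        dists.append(best)
    dists_arr = np.array(dists)
    hist, _ = np.histogram(dists_arr, bins=bin_edges)
    return hist, dists_arr, unmatched


def pairwise_coloc_matrix(
    occurrences_by_family: dict[str, list[MotifOccurrence]],
    footprint_universe: list[Footprint],
    n_boot: int = 1000,
    seed: int = 0,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Z-score matrix of co-localization over all ordered family pairs.

    Deterministic given ``seed``: every pair gets its own child generator
    spawned from the same seed sequence, so the matrix does not depend on
    evaluation order.
    """
    families = sorted(occurrences_by_family)
    if len(families) < 2:
        raise ValueError("need >= 2 motif families")
    mat = pd.DataFrame(np.nan, index=families, columns=families)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(families) ** 2)
    for i, fam_a in enumerate(families):
        for j, fam_b in enumerate(families):
            rng = np.random.default_rng(children[i * len(families) + j])
            res = colocalization_zscore(
                occurrences_by_family[fam_a], occurrences_by_family[fam_b],
                footprint_universe, n_boot=n_boot, max_gap=max_gap, rng=rng)
            mat.loc[fam_a, fam_b] = res["z"]
    return mat


def cluster_scores(score_matrix: pd.DataFrame) -> np.ndarray:
    """Hierarchical clustering (Euclidean, complete linkage) of score rows."""
    return linkage(score_matrix.to_numpy(), method="complete",
                   metric="euclidean")
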