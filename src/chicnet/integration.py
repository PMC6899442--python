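"""Linking distal DHSs to promoters and differential filtering.

A DHS is assigned to a gene when its summit falls inside the other-end
fragment of a significant bait--other-end interaction whose bait is that
gene's promoter fragment (plus self-assignment for DHSs sitting in a
bait fragment). The nearest promoter is determined by summit-to-TSS
distance, where the TSS is the 5' end of the bait fragment on the
annotated strand (fragment midpoint when the strand is unknown).

Also here: DHS count normalization (median-of-ratios size factors over a
400-bp summit window), sample Pearson correlation, fold-change ranking
of DHSs, and the 2-fold / p <= 0.01 differential-expression filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (  # noqa: F401
    ExpressionRecord,
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
    RestrictionFragment,
)

__all__ = [
    "DHSAssignment",
    "ExpressionRecord",
    "assign_dhs_to_promoters",
    "nearest_promoter_fraction",
    "interaction_participation_fraction",
    "interval_set_overlap_fraction",
    "normalize_dhs_counts",
    "sample_correlation",
    "differential_dhs",
    "filter_degs",
]


@dataclass
class DHSAssignment:
    """A DHS linked to promoters through significant interactions."""

    dhs: PeakRecord
    assigned_genes: list[tuple[str, str, float]] = field(default_factory=list)
    nearest_gene: str = ""
    nearest_is_assigned: bool = False

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.assigned_genes}


def _tss(fragment: RestrictionFragment, strand: str = ".") -> int:
    iv = fragment.interval
    if strand == "+":
        return iv.start
    if strand == "-":
        return iv.end - 1
    return iv.midpoint


def _locate_fragment(fragments_by_chrom: dict[str, tuple[np.ndarray, list]],
                     chrom: str, pos: int) -> RestrictionFragment | None:
    if chrom not in fragments_by_chrom:
        return None
    starts, frags = fragments_by_chrom[chrom]
    j = int(np.searchsorted(starts, pos, side="right")) - 1
    if j >= 0 and pos < frags[j].interval.end:
        return frags[j]
    return None


def assign_dhs_to_promoters(
    dhs_list: list[PeakRecord],
    interactions: list[InteractionRecord],
    fragments: list[RestrictionFragment],
    promoter_strands: dict[str, str] | None = None,
) -> list[DHSAssignment]:
    """Assign each DHS to the promoters it contacts.

    A DHS is assigned to gene G iff its summit lies within the other-end
    fragment of a significant interaction whose bait is G's promoter
    fragment; a DHS whose summit sits in a bait fragment is additionally
    self-assigned to that bait's gene. The summit (not any-overlap) rule
    avoids double-assigning boundary-spanning DHSs.
    """
    frag_by_id = {f.fragment_id: f for f in fragments}
    by_chrom: dict[str, tuple[np.ndarray, list]] = {}
    for chrom in {f.interval.chrom for f in fragments}:
        fs = sorted((f for f in fragments if f.interval.chrom == chrom),
                    key=lambda f: f.interval.start)
        by_chrom[chrom] = (np.array([f.interval.start for f in fs]), fs)

    # other-end fragment id -> [(gene, interaction id, q)]
    links: dict[int, list[tuple[str, str, float]]] = {}
    for rec in interactions:
        if not rec.significant:
            continue
        bait = frag_by_id.get(rec.bait_id)
        gene = rec.bait_gene or (bait.bait_gene if bait else "")
        if not gene:
            continue
        links.setdefault(rec.other_id, []).append(
            (gene, f"{rec.bait_id}:{rec.other_id}", rec.q_value))

    baits = [f for f in fragments if f.is_bait]
    strands = promoter_strands or {}

    out = []
    for dhs in dhs_list:
        chrom = dhs.interval.chrom
        frag = _locate_fragment(by_chrom, chrom, dhs.summit)
        if frag is None:
            warnings.warn(f"DHS at {chrom}:{dhs.summit} outside fragment map")
            out.append(DHSAssignment(dhs=dhs))
            continue
        assigned = list(links.get(frag.fragment_id, []))
        if frag.is_bait:
            assigned.append((frag.bait_gene, f"self:{frag.fragment_id}",
                             float("nan")))
        # deduplicate per gene, keeping the best (lowest) q
        best: dict[str, tuple[str, float]] = {}
        for gene, iid, q in assigned:
            if gene not in best or (q == q and q < best[gene][1]):
                best[gene] = (iid, q if q == q else float("inf"))
        assigned = sorted((g, iid, q) for g, (iid, q) in best.items())

        nearest_gene = ""
        if baits:
            assigned_set = {g for g, _, _ in assigned}
            same_chrom = [b for b in baits if b.interval.chrom == chrom]
            if same_chrom:
                def key(b: RestrictionFragment):
                    d = abs(dhs.summit - _tss(b, strands.get(b.bait_gene, ".")))
                    # ties broken toward an assigned gene, then lexicographic
                    return (d, b.bait_gene not in assigned_set, b.bait_gene)
                nearest_gene = min(same_chrom, key=key).bait_gene
        out.append(DHSAssignment(
            dhs=dhs,
            assigned_genes=assigned,
            nearest_gene=nearest_gene,
            nearest_is_assigned=bool(
                nearest_gene and nearest_gene in {g for g, _, _ in assigned}),
        ))
    return out


def nearest_promoter_fraction(assignments: list[DHSAssignment]) -> float:
    """Fraction of assigned DHSs whose nearest promoter is among the
    promoters they interact with."""
    assigned = [a for a in assignments if a.assigned_genes]
    if not assigned:
        raise ValueError("no assigned DHSs")
    if not any(a.nearest_gene for a in assigned):
        raise ValueError("no promoters available for nearest computation")
    return sum(a.nearest_is_assigned for a in assigned) / len(assigned)


def interaction_participation_fraction(
    dhs_list: list[PeakRecord],
    assignments: list[DHSAssignment],
) -> float:
    """Fraction of DHSs linked to >= 1 promoter by a significant interaction."""
    if not dhs_list:
        raise ValueError("empty DHS set")
    def ident(p: PeakRecord):
        return (p.interval.chrom, p.interval.start, p.interval.end)
    linked = {ident(a.dhs) for a in assignments
              if any(not i.startswith("self:") for _, i, _ in a.assigned_genes)}
    return sum(ident(d) in linked for d in dhs_list) / len(dhs_list)


def interval_set_overlap_fraction(
    set_a: list[PeakRecord],
    set_b: list[PeakRecord],
    min_overlap: int = 1,
) -> float:
    """Fraction of A intervals overlapped by >= min_overlap bases of B."""
    if not set_a:
        raise ValueError("empty A set")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in set_b:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    hits = 0
    for p in set_a:
        ivs = by_chrom.get(p.interval.chrom, [])
        if any(p.interval.overlap_len(iv) >= min_overlap for iv in ivs):
            hits += 1
    return hits / len(set_a)


def normalize_dhs_counts(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization of a DHS x sample count table.

    Size factor per sample = median over features of count / geometric
    mean across samples; features whose geometric mean is zero are
    excluded from the median. Returns (normalized counts, size factors).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    with np.errstate(divide="ignore"):
        log_gm = np.log(arr).mean(axis=1)
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no feature has nonzero counts in every sample")
    gm = np.exp(log_gm[usable])
    ratios = arr[usable] / gm[:, None]
    size_factors = pd.Series(np.median(ratios, axis=0), index=counts.columns)
    normalized = counts / size_factors
    return normalized, size_factors


def sample_correlation(normalized: pd.DataFrame,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Pairwise sample Pearson correlation of log2 normalized counts.

    Zero-variance samples yield NaN entries (reported missing).
    """
    if normalized.shape[1] < 2 or normalized.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 features")
    logged = np.log2(normalized + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return logged.corr(method="pearson")


def differential_dhs(
    normalized: pd.DataFrame,
    cond_a_samples: list[str],
    cond_b_samples: list[str],
    fold_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Fold-change ranking of DHSs between two conditions.

    log2fc = log2((mean_B + 1) / (mean_A + 1)); flagged ``increased`` when
    log2fc >= log2(fold_cutoff), ``decreased`` when <= -log2(fold_cutoff).
    Every DHS appears in the returned ranking.
    """
    if not cond_a_samples or not cond_b_samples:
        raise ValueError("need >= 1 sample per condition")
    mean_a = normalized[cond_a_samples].mean(axis=1)
    mean_b = normalized[cond_b_samples].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    cut = np.log2(fold_cutoff)
    direction = np.where(log2fc >= cut, "increased",
                         np.where(log2fc <= -cut, "decreased", "unchanged"))
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b,
        "log2fc": log2fc, "direction": direction,
        "flagged": direction != "unchanged",
    })
    return out.sort_values("log2fc", ascending=False, kind="mergesort")


def filter_degs(
    records: list[ExpressionRecord],
    fold_cutoff: float = 2.0,
    p_cutoff: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Differentially expressed genes at >= fold_cutoff and p <= p_cutoff.

    Boundary values are included on both thresholds. Returns (up, down).
    """
    lfc = np.log2(fold_cutoff)
    up = {r.gene for r in records if r.log2fc >= lfc and r.p_value <= p_cutoff}
    down = {r.gene for r in records if r.log2fc <= -lfc and r.p_value <= p_cutoff}
    return up, down
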