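"""Synthetic multi-omics data with known ground truth.

Generates every input the pipeline consumes -- a fragment-tiled genome
with bait (promoter) annotation, capture Hi-C ligation counts for two
conditions x two replicates, per-base DNaseI cut profiles over DHS
windows, ChIP peak sets, a PWM library, and an expression table --
while recording the planted truth (loops, footprints, regulatory edges)
for calibration and recovery tests.

The statistical structure emulates promoter-capture data: pair counts
are Poisson around a coverage-product background with power-law distance
decay (coverages log-normal), planted loops multiply selected pair
weights by an enrichment fold in chosen conditions; cut profiles are
uniform-rate Poisson with planted protected footprints at motif
instances; differential genes carry >= 2-fold changes at small p.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import (
    CutProfile,
    ExpressionRecord,
    GenomicInterval,
    InteractionRecord,
    MotifModel,
    PeakRecord,
    RestrictionFragment,
)
from .interactions import ContactMatrix

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SyntheticDataset",
    "default_motif_library",
    "default_family_map",
    "simulate_genome_and_fragments",
    "simulate_interaction_counts",
    "simulate_cut_profiles",
    "simulate_peaks_and_expression",
    "simulate_dataset",
    "simulate_compartment_matrix",
    "write_dataset",
]

CONTROL, DEPLETED = "siMM", "siRE"

# fixed per-stage stream identifiers so stages are independently reproducible
_STAGE_GENOME, _STAGE_SEQ, _STAGE_LOOPS = 11, 12, 13
_STAGE_COUNTS, _STAGE_CUTS, _STAGE_PEAKS = 14, 15, 16


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the test-bed conditions.

    ``read_depth`` is ligation pairs per condition, split evenly over
    replicates. ``decay_exponent`` is alpha in the d^(-alpha) contact
    decay; coverages are log-normal(sigma). Planted loops multiply their
    pair weight by ``loop_enrichment`` in the conditions implied by their
    class (shared / gained-on-depletion / lost-on-depletion) and are only
    planted on pairs whose baseline expected count is at least
    ``loop_min_expected`` (and whose other-end fragment can hold a DHS
    window). At most one loop is planted per bait so planted regulatory
    edges stay unambiguous.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    mean_fragment_length: int = 4096
    n_baits: int = 40
    read_depth: int = 500_000
    n_replicates: int = 2
    decay_exponent: float = 1.0
    coverage_sigma: float = 0.5
    overdispersion: float | None = None  # NB shape; None = pure Poisson
    n_loops_shared: int = 10
    n_loops_gained: int = 15
    n_loops_lost: int = 10
    loop_enrichment: float = 5.0
    loop_min_expected: float = 5.0
    loop_min_distance: int = 25_000
    window_size: int = 200
    footprint_width: int = 20
    footprint_protection: float = 0.9
    shoulder_cut_rate: float = 0.5
    n_background_dhs: int = 60
    n_planted_edges: int = 20
    gained_family: str = "CEBP"
    n_chip_peaks: int = 40
    peak_gain_fraction: float = 0.2
    peak_loss_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if not (0.0 <= self.footprint_protection <= 1.0):
            raise ValueError("footprint_protection must be in [0, 1]")
        if self.loop_enrichment < 1.0:
            raise ValueError("loop_enrichment must be >= 1")
        if self.chrom_length < self.mean_fragment_length:
            raise ValueError("chrom_length below mean fragment length")
        if self.footprint_width > self.window_size:
            raise ValueError("footprint wider than DHS window")

    @property
    def n_loops(self) -> int:
        return self.n_loops_shared + self.n_loops_gained + self.n_loops_lost

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside the synthetic inputs."""

    true_interactions: set[tuple[int, int, str]] = field(default_factory=set)
    true_footprints: list[tuple[GenomicInterval, str, str]] = field(
        default_factory=list)  # (interval, motif_id, condition)
    true_edges: set[tuple[str, str, str]] = field(default_factory=set)
    true_compartment: list[str] = field(default_factory=list)
    runx1_eto_targets: set[str] = field(default_factory=set)

    def interactions_in(self, condition: str) -> set[tuple[int, int]]:
        return {(b, o) for b, o, c in self.true_interactions
                if c in ("both", condition)}


# ---------------------------------------------------------------------------
# Motif library
# ---------------------------------------------------------------------------

_CONSENSI = {
    "CEBP": "ATTGCGCAAT",
    "AP1": "ATGACTCATC",
    "ETS": "ACAGGAAGTG",
    "RUNX": "CTGTGGTTTC",
    "GATA": "CAGATAAGAC",
    "NFKB": "GGGACTTTCC",
    "MYB": "TAACGGTTGC",
    "EBOX": "GTCACGTGAC",
}


def default_motif_counts() -> list[tuple[str, str, np.ndarray]]:
    """Sharp count matrices (85 consensus / 5 off) for eight TF families."""
    out = []
    for family, consensus in _CONSENSI.items():
        counts = np.full((4, len(consensus)), 5.0)
        for j, base in enumerate(consensus):
            counts["ACGT".index(base), j] = 85.0
        out.append((f"M_{family}", family, counts))
    return out


def default_motif_library(pseudocount: float = 1.0) -> list[MotifModel]:
    motifs = []
    for motif_id, family, counts in default_motif_counts():
        counts = counts + pseudocount
        motifs.append(MotifModel(
            motif_id=motif_id, family=family,
            matrix=counts / counts.sum(axis=0, keepdims=True)))
    return motifs


def default_family_map() -> dict[str, str]:
    return {f"M_{family}": family for family in _CONSENSI}


# ---------------------------------------------------------------------------
# Genome and fragments
# ---------------------------------------------------------------------------

def simulate_genome_and_fragments(
    config: SimulationConfig,
) -> tuple[list[RestrictionFragment], list[PeakRecord]]:
    """Fragment-tiled genome with bait annotation.

    Fragment lengths are geometric with the configured mean (a six-cutter
    leaves ~4 kb fragments); each chromosome is tiled exactly, the last
    fragment truncated to fit. ``n_baits`` fragments become baits with
    synthetic gene names ordered along the genome; the returned promoter
    records mark each gene's TSS (5' fragment end on a random strand).
    """
    rng = config.rng(_STAGE_GENOME)
    fragments: list[RestrictionFragment] = []
    fid = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        pos = 0
        while pos < config.chrom_length:
            length = int(rng.geometric(1.0 / config.mean_fragment_length))
            end = min(pos + length, config.chrom_length)
            fragments.append(RestrictionFragment(
                interval=GenomicInterval(chrom, pos, end), fragment_id=fid))
            fid += 1
            pos = end
    if config.n_baits > len(fragments):
        raise ValueError("more baits requested than fragments")
    bait_ids = np.sort(rng.choice(len(fragments), size=config.n_baits,
                                  replace=False))
    strands = rng.choice(["+", "-"], size=config.n_baits)
    promoters: list[PeakRecord] = []
    for rank, (fi, strand) in enumerate(zip(bait_ids, strands)):
        gene = f"GENE{rank + 1:04d}"
        frag = fragments[fi]
        fragments[fi] = replace(frag, is_bait=True, bait_gene=gene)
        iv = frag.interval
        promoters.append(PeakRecord(
            interval=GenomicInterval(iv.chrom, iv.start, iv.end, str(strand)),
            summit_offset=0 if strand == "+" else len(iv) - 1,
            name=gene))
    return fragments, promoters


def simulate_genome_sequence(
    config: SimulationConfig,
) -> dict[str, bytearray]:
    """Random ACGT sequence per chromosome (mutable, for motif planting)."""
    rng = config.rng(_STAGE_SEQ)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for c in range(config.n_chroms):
        idx = rng.integers(0, 4, size=config.chrom_length)
        seqs[f"chr{c + 1}"] = bytearray(bases[idx].tobytes())
    return seqs


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

def _pair_universe(fragments: list[RestrictionFragment]) -> list[tuple[int, int]]:
    """All cis bait--fragment pairs; bait-bait pairs deduplicated."""
    by_chrom: dict[str, list[RestrictionFragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    pairs = []
    for frags in by_chrom.values():
        baits = [f for f in frags if f.is_bait]
        for b in baits:
            for o in frags:
                if o.fragment_id == b.fragment_id:
                    continue
                if o.is_bait and o.fragment_id < b.fragment_id:
                    continue  # counted from the other bait's side
                pairs.append((b.fragment_id, o.fragment_id))
    return sorted(pairs)


def _pair_weights(
    pairs: list[tuple[int, int]],
    fragments: list[RestrictionFragment],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(normalized weights, distances); coverage log-normal, decay d^-alpha."""
    coverage = rng.lognormal(mean=0.0, sigma=config.coverage_sigma,
                             size=len(fragments))
    frag_by_id = {f.fragment_id: f for f in fragments}
    mid = {fid: frag_by_id[fid].interval.midpoint for fid in frag_by_id}
    b = np.array([p[0] for p in pairs])
    o = np.array([p[1] for p in pairs])
    dist = np.abs(np.array([mid[x] for x in b]) - np.array([mid[x] for x in o]))
    dist = np.maximum(dist, 1)
    w = coverage[b] * coverage[o] * dist.astype(float) ** (-config.decay_exponent)
    return w / w.sum(), dist


def plant_loops(
    pairs: list[tuple[int, int]],
    weights: np.ndarray,
    dist: np.ndarray,
    fragments: list[RestrictionFragment],
    config: SimulationConfig,
) -> list[tuple[int, int, str]]:
    """Choose planted loops: (bait, other, class) with unique baits.

    Candidates must have baseline expected count >= loop_min_expected,
    distance >= loop_min_distance, and an other-end fragment wide enough
    to hold a DHS window. Classes in order: shared, gained, lost.
    """
    if config.n_loops == 0:
        return []
    rng = config.rng(_STAGE_LOOPS)
    frag_by_id = {f.fragment_id: f for f in fragments}
    expected = config.read_depth * weights
    ok = ((expected >= config.loop_min_expected)
          & (dist >= config.loop_min_distance))
    cand = [i for i in np.flatnonzero(ok)
            if len(frag_by_id[pairs[i][1]].interval) >= config.window_size
            and not frag_by_id[pairs[i][1]].is_bait]
    rng.shuffle(cand)
    chosen: list[int] = []
    used_baits: set[int] = set()
    used_others: set[int] = set()
    for i in cand:
        b, o = pairs[i]
        if b in used_baits or o in used_others:
            continue
        chosen.append(i)
        used_baits.add(b)
        used_others.add(o)
        if len(chosen) == config.n_loops:
            break
    if len(chosen) < config.n_loops:
        raise ValueError(
            f"only {len(chosen)} eligible loop sites for {config.n_loops} "
            "requested loops; enlarge the genome or lower loop_min_expected")
    classes = (["both"] * config.n_loops_shared
               + [DEPLETED] * config.n_loops_gained
               + [CONTROL] * config.n_loops_lost)
    return [(pairs[i][0], pairs[i][1], cls)
            for i, cls in zip(chosen, classes)]


def simulate_interaction_counts(
    fragments: list[RestrictionFragment],
    config: SimulationConfig,
    loops: list[tuple[int, int, str]] | None = None,
) -> tuple[dict[str, list[list[InteractionRecord]]], TruthSet]:
    """Poisson ligation counts per condition and replicate.

    Counts are Poisson(depth_rep * w_ij) with w the normalized
    coverage-product-decay weights; planted loops multiply their weight
    by the enrichment fold in their condition(s) before renormalization.
    With ``overdispersion`` theta set, counts are gamma-Poisson
    (negative binomial) with that shape. Returns the truth set listing
    every planted pair.
    """
    pairs = _pair_universe(fragments)
    if not pairs:
        raise ValueError("no bait pairs (no baits annotated?)")
    rng_w = config.rng(_STAGE_LOOPS + 100)
    weights, dist = _pair_weights(pairs, fragments, config, rng_w)
    if loops is None:
        loops = plant_loops(pairs, weights, dist, fragments, config)
    pair_index = {p: i for i, p in enumerate(pairs)}
    for b, o, _cls in loops:
        if (b, o) not in pair_index:
            raise ValueError(f"planted loop {b}-{o} not in cis pair universe")

    truth = TruthSet(true_interactions={(b, o, cls) for b, o, cls in loops})
    frag_by_id = {f.fragment_id: f for f in fragments}
    rng = config.rng(_STAGE_COUNTS)
    out: dict[str, list[list[InteractionRecord]]] = {}
    for condition in (CONTROL, DEPLETED):
        w = weights.copy()
        for b, o, cls in loops:
            if cls in ("both", condition):
                w[pair_index[(b, o)]] *= config.loop_enrichment
        w = w / w.sum()
        depth_rep = config.read_depth / config.n_replicates
        reps = []
        for _rep in range(config.n_replicates):
            lam = depth_rep * w
            if config.overdispersion is not None:
                theta = config.overdispersion
                lam = rng.gamma(shape=theta, scale=lam / theta)
            counts = rng.poisson(lam)
            records = []
            for (bfid, ofid), cnt, d in zip(pairs, counts, dist):
                bait = frag_by_id[bfid]
                records.append(InteractionRecord(
                    bait_id=bfid, other_id=ofid, count=int(cnt),
                    distance=int(d),
                    bait_interval=bait.interval,
                    other_interval=frag_by_id[ofid].interval,
                    bait_gene=bait.bait_gene))
            reps.append(records)
        out[condition] = reps
    return out, truth


# ---------------------------------------------------------------------------
# Cut profiles
# ---------------------------------------------------------------------------

def simulate_cut_profiles(
    windows: list[GenomicInterval],
    planted: list[tuple[int, int, int, str]],
    config: SimulationConfig,
    seed_offset: int = 0,
) -> tuple[list[CutProfile], TruthSet]:
    """Per-base strand-specific cut counts with planted protected footprints.

    ``planted`` holds (window index, footprint offset, footprint length,
    motif id). Cuts are Poisson(shoulder_cut_rate) per base per strand;
    inside a planted footprint each cut is independently removed with
    probability ``footprint_protection``.
    """
    rng = config.rng(_STAGE_CUTS + seed_offset)
    planted_by_window: dict[int, list[tuple[int, int, str]]] = {}
    for wi, off, length, motif_id in planted:
        if length > len(windows[wi]):
            raise ValueError("planted footprint wider than its window")
        if off < 0 or off + length > len(windows[wi]):
            raise ValueError("planted footprint outside its window")
        planted_by_window.setdefault(wi, []).append((off, length, motif_id))

    profiles = []
    truth = TruthSet()
    for wi, window in enumerate(windows):
        width = len(window)
        plus = rng.poisson(config.shoulder_cut_rate, size=width)
        minus = rng.poisson(config.shoulder_cut_rate, size=width)
        for off, length, motif_id in planted_by_window.get(wi, []):
            for arr in (plus, minus):
                seg = arr[off:off + length]
                kept = rng.binomial(seg, 1.0 - config.footprint_protection)
                arr[off:off + length] = kept
            truth.true_footprints.append((
                GenomicInterval(window.chrom, window.start + off,
                                window.start + off + length),
                motif_id, ""))
        profiles.append(CutProfile(window=window, cuts_plus=plus,
                                   cuts_minus=minus))
    return profiles, truth


# ---------------------------------------------------------------------------
# Peaks and expression
# ---------------------------------------------------------------------------

def simulate_peaks_and_expression(
    config: SimulationConfig,
    genes: list[str],
    planted_edges: list[tuple[str, str, str]],
    fragments: list[RestrictionFragment],
) -> tuple[dict[str, dict[str, list[PeakRecord]]], list[ExpressionRecord]]:
    """Condition-specific ChIP peak sets and the expression table.

    Each TF family gets a shared peak set plus peaks gained or lost on
    depletion at the configured fractions. Genes targeted by planted
    edges are >= 2-fold differential at small p in the stated direction;
    all other genes sit near log2fc 0 with p > 0.01.
    """
    de_genes = {g for _f, g, _d in planted_edges}
    if len(de_genes) > len(genes):
        raise ValueError("more planted edges than genes")
    rng = config.rng(_STAGE_PEAKS)

    direction_of = {g: d for _f, g, d in planted_edges}
    expression = []
    for gene in genes:
        base = float(2.0 ** rng.uniform(2, 8))
        if gene in direction_of:
            sign = 1.0 if direction_of[gene] == "up" else -1.0
            lfc = float(sign * rng.uniform(1.0, 3.0))
            p = float(10.0 ** (-rng.uniform(2.5, 8.0)))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.25), -0.9, 0.9))
            p = float(rng.uniform(0.02, 1.0))
        expression.append(ExpressionRecord(
            gene=gene, value_a=base, value_b=float(base * 2.0 ** lfc),
            log2fc=lfc, p_value=p))

    genome_len = config.n_chroms * config.chrom_length
    peak_width = 200

    def random_peaks(n: int, tf: str, condition: str) -> list[PeakRecord]:
        out = []
        pos = rng.integers(0, genome_len - peak_width, size=n)
        for p in np.sort(pos):
            chrom = f"chr{int(p // config.chrom_length) + 1}"
            start = int(p % config.chrom_length)
            out.append(PeakRecord(
                interval=GenomicInterval(chrom, start, start + peak_width),
                tf_name=tf, condition=condition,
                score=float(rng.uniform(5, 100))))
        return out

    chip: dict[str, dict[str, list[PeakRecord]]] = {}
    n_gain = int(round(config.n_chip_peaks * config.peak_gain_fraction))
    n_loss = int(round(config.n_chip_peaks * config.peak_loss_fraction))
    n_shared = config.n_chip_peaks - n_gain - n_loss
    for family in _CONSENSI:
        shared = random_peaks(n_shared, family, "both")
        gained = random_peaks(n_gain, family, DEPLETED)
        lost = random_peaks(n_loss, family, CONTROL)
        chip[family] = {
            CONTROL: [replace(p, condition=CONTROL) for p in shared + lost],
            DEPLETED: [replace(p, condition=DEPLETED) for p in shared + gained],
        }
    return chip, expression


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    fragments: list[RestrictionFragment]
    promoters: list[PeakRecord]
    sequences: dict[str, str]
    motifs: list[MotifModel]
    family_map: dict[str, str]
    interactions: dict[str, list[list[InteractionRecord]]]
    dhs: list[PeakRecord]
    cut_profiles: dict[str, list[CutProfile]]
    chip_peaks: dict[str, dict[str, list[PeakRecord]]]
    runx1_eto_peaks: list[PeakRecord]
    expression: list[ExpressionRecord]
    truth: TruthSet

    @property
    def promoter_strands(self) -> dict[str, str]:
        return {p.name: p.interval.strand for p in self.promoters}


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full coherent two-condition study.

    Planted regulatory edges ride on planted loops (one loop per bait):
    edges on depletion-gained loops use the configured ``gained_family``
    and an upregulated target gene; the remainder sit on shared loops
    with the other families cycling and downregulated targets. The DHS at
    each edge's loop other-end carries a planted motif instance (written
    into the genome sequence) protected by a footprint in the conditions
    where the loop is active.
    """
    fragments, promoters = simulate_genome_and_fragments(config)
    sequences = simulate_genome_sequence(config)
    interactions, truth = simulate_interaction_counts(fragments, config)
    frag_by_id = {f.fragment_id: f for f in fragments}
    motifs = default_motif_library()
    motif_by_family = {m.family: m for m in motifs}
    family_map = default_family_map()

    # order loops: gained first (they carry the gained-family edges)
    loops = sorted(truth.true_interactions,
                   key=lambda t: (t[2] != DEPLETED, t[2] != "both", t[:2]))
    other_families = [f for f in _CONSENSI if f != config.gained_family]

    dhs: list[PeakRecord] = []
    edge_specs = []  # (dhs index, family, gene, direction, loop condition)
    half = config.window_size // 2
    for li, (bait_id, other_id, cls) in enumerate(loops):
        frag = frag_by_id[other_id]
        center = frag.interval.midpoint
        start = max(0, min(center - half,
                           config.chrom_length - config.window_size))
        window = GenomicInterval(frag.interval.chrom, start,
                                 start + config.window_size)
        dhs.append(PeakRecord(interval=window, summit_offset=half,
                              name=f"DHS{len(dhs) + 1:04d}"))
        if len(edge_specs) >= config.n_planted_edges or cls == CONTROL:
            continue
        gene = frag_by_id[bait_id].bait_gene
        if cls == DEPLETED:
            family, direction = config.gained_family, "up"
        else:
            family = other_families[len(edge_specs) % len(other_families)]
            direction = "down"
        edge_specs.append((len(dhs) - 1, family, gene, direction, cls))

    # background DHSs on fragments without loops
    rng_bg = config.rng(_STAGE_CUTS + 900)
    loop_frags = {o for _b, o, _c in loops}
    eligible = [f for f in fragments
                if f.fragment_id not in loop_frags and not f.is_bait
                and len(f.interval) >= config.window_size]
    picks = rng_bg.choice(len(eligible),
                          size=min(config.n_background_dhs, len(eligible)),
                          replace=False)
    for i in np.sort(picks):
        frag = eligible[i]
        center = frag.interval.midpoint
        start = max(0, min(center - half,
                           config.chrom_length - config.window_size))
        dhs.append(PeakRecord(
            interval=GenomicInterval(frag.interval.chrom, start,
                                     start + config.window_size),
            summit_offset=half, name=f"DHS{len(dhs) + 1:04d}"))

    # plant motif instances into the genome at edge DHS centers
    fp_by_condition: dict[str, list[tuple[int, int, int, str]]] = {
        CONTROL: [], DEPLETED: []}
    for dhs_i, family, _gene, _direction, cls in edge_specs:
        motif = motif_by_family[family]
        window = dhs[dhs_i].interval
        m_off = (config.window_size - len(motif)) // 2
        gstart = window.start + m_off
        sequences[window.chrom][gstart:gstart + len(motif)] = \
            motif.consensus.encode()
        fp_len = max(len(motif), config.footprint_width)
        fp_off = m_off - (fp_len - len(motif)) // 2
        for condition in (CONTROL, DEPLETED):
            if cls in ("both", condition):
                fp_by_condition[condition].append(
                    (dhs_i, fp_off, fp_len, motif.motif_id))

    windows = [d.interval for d in dhs]
    cut_profiles = {}
    for k, condition in enumerate((CONTROL, DEPLETED)):
        profiles, fp_truth = simulate_cut_profiles(
            windows, fp_by_condition[condition], config, seed_offset=k)
        cut_profiles[condition] = profiles
        truth.true_footprints.extend(
            (iv, mid, condition) for iv, mid, _ in fp_truth.true_footprints)

    planted_edges = [(family, gene, direction)
                     for _i, family, gene, direction, _c in edge_specs]
    truth.true_edges = set(planted_edges)

    genes = sorted(f.bait_gene for f in fragments if f.is_bait)
    chip, expression = simulate_peaks_and_expression(
        config, genes, planted_edges, fragments)

    # RUNX1-ETO ChIP peaks on every other edge DHS
    runx_peaks = []
    for j, (dhs_i, _f, gene, _d, _c) in enumerate(edge_specs):
        if j % 2 == 0:
            runx_peaks.append(replace(dhs[dhs_i], tf_name="RUNX1-ETO",
                                      condition=CONTROL))
            truth.runx1_eto_targets.add(gene)

    return SyntheticDataset(
        config=config, fragments=fragments, promoters=promoters,
        sequences={c: s.decode() if isinstance(s, (bytes, bytearray)) else s
                   for c, s in sequences.items()},
        motifs=motifs, family_map=family_map, interactions=interactions,
        dhs=dhs, cut_profiles=cut_profiles, chip_peaks=chip,
        runx1_eto_peaks=runx_peaks, expression=expression, truth=truth)


# ---------------------------------------------------------------------------
# Compartment matrix
# ---------------------------------------------------------------------------

def simulate_compartment_matrix(
    n_bins: int = 40,
    bin_size: int = 10_000_000,
    chrom: str = "chr1",
    base_count: float = 500.0,
    contrast: float = 0.4,
    seed: int = 0,
) -> tuple[ContactMatrix, list[str], list[PeakRecord]]:
    """Block-structured contact matrix with planted A/B labels.

    Counts are Poisson(mu_ij) with mu_ij = base * d^-0.5 * (1 + contrast
    * s_i * s_j), s = +1 in A bins and -1 in B bins. DHS density is high
    in A bins and low in B bins so the orientation rule can resolve the
    eigenvector sign. Returns (matrix, labels, dhs records).
    """
    rng = np.random.default_rng(seed)
    s = np.where(rng.random(n_bins) < 0.5, 1.0, -1.0)
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins))) + 1.0
    mu = base_count * d ** -0.5 * (1.0 + contrast * np.outer(s, s))
    counts = rng.poisson(mu)
    counts = np.triu(counts) + np.triu(counts, 1).T  # symmetrize
    matrix = ContactMatrix(bin_size=bin_size, chrom=chrom, n_bins=n_bins,
                           counts=counts.astype(float))
    labels = ["A" if x > 0 else "B" for x in s]
    dhs = []
    for b in range(n_bins):
        n_d = int(rng.poisson(12 if s[b] > 0 else 2))
        for pos in rng.integers(0, bin_size, size=n_d):
            start = b * bin_size + int(pos)
            dhs.append(PeakRecord(
                interval=GenomicInterval(chrom, start, start + 200),
                summit_offset=100))
    return matrix, labels, dhs


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit every input file the CLI pipeline consumes, plus truth tables."""
    from pathlib import Path

    from . import formats_io as fio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fio.dump_config(dataset.config, out / "config.yaml")
    fio.write_fragments_bed(dataset.fragments, out / "fragments.bed")
    fio.write_bed(dataset.promoters, out / "promoters.bed", dialect="bed6")
    fio.write_bed(dataset.dhs, out / "dhs.narrowPeak", dialect="narrowPeak")
    fio.write_fasta(dataset.sequences, out / "genome.fa")
    fio.write_pwm_counts(default_motif_counts(), out / "motifs.pwm")
    fio.write_expression_tsv(dataset.expression, out / "expression.tsv")
    fio.write_bed(dataset.runx1_eto_peaks, out / "runx1_eto.narrowPeak",
                  dialect="narrowPeak")
    for condition, reps in dataset.interactions.items():
        for r, records in enumerate(reps, 1):
            fio.write_interactions_bedpe(
                records, out / f"interactions_{condition}_rep{r}.bedpe")
    for condition, profiles in dataset.cut_profiles.items():
        fio.write_cut_profiles(profiles, out / f"cuts_{condition}.tsv")
    for family, per_cond in dataset.chip_peaks.items():
        for condition, peaks in per_cond.items():
            fio.write_bed(peaks, out / f"chip_{family}_{condition}.narrowPeak",
                          dialect="narrowPeak")
    with open(out / "family_map.tsv", "w") as fh:
        for motif_id, family in sorted(dataset.family_map.items()):
            fh.write(f"{motif_id}\t{family}\n")
    truth = dataset.truth
    with open(out / "truth_interactions.tsv", "w") as fh:
        fh.write("bait_id\tother_id\tcondition\n")
        for b, o, c in sorted(truth.true_interactions):
            fh.write(f"{b}\t{o}\t{c}\n")
    with open(out / "truth_footprints.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tmotif_id\tcondition\n")
        for iv, mid, cond in truth.true_footprints:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{mid}\t{cond}\n")
    with open(out / "truth_edges.tsv", "w") as fh:
        fh.write("family\tgene\tdirection\n")
        for fam, gene, d in sorted(truth.true_edges):
            fh.write(f"{fam}\t{gene}\t{d}\n")
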