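"""End-to-end orchestration: simulate -> call -> footprint -> scan ->
assign -> network, with truth-recovery metrics.

Thin plumbing over the stage modules; every scientific step lives in its
own module. Used by the acceptance machinery and as a worked example of
chaining the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import (
    footprints as fp_mod,
    integration as integ,
    interactions as ia,
    motif_analysis as ma,
    network as net_mod,
    synthetic_data as sd,
)
from .formats_io import Footprint, MotifOccurrence, PeakRecord


@dataclass
class PipelineResult:
    dataset: sd.SyntheticDataset
    called: dict[str, list]                 # condition -> interaction records
    footprints: dict[str, list[Footprint]]
    occurrences: dict[str, list[MotifOccurrence]]  # occupied-flagged, per cond
    assignments: dict[str, list[integ.DHSAssignment]]
    deg_up: set[str] = field(default_factory=set)
    deg_down: set[str] = field(default_factory=set)
    networks: dict[str, net_mod.RegulatoryNetwork] = field(default_factory=dict)


def run_standard_analysis(
    config: sd.SimulationConfig,
    alpha: float = 0.05,
    min_distance: int = 10_000,
    footprint_fdr: float = 0.01,
    n_shuffles: int = 5,
    scan_threshold: float = 0.8,
) -> PipelineResult:
    """Run the full two-condition analysis on a synthetic dataset."""
    ds = sd.simulate_dataset(config)
    called, fps, occs, assigns, nets = {}, {}, {}, {}, {}
    up, down = integ.filter_degs(ds.expression)

    # motif occurrences over DHS sequences are condition-independent
    raw_occs: list[MotifOccurrence] = []
    for dhs in ds.dhs:
        iv = dhs.interval
        seq = ds.sequences[iv.chrom][iv.start:iv.end]
        for motif in ds.motifs:
            raw_occs.extend(ma.scan_pwm(seq, motif, iv.chrom, offset=iv.start,
                                        threshold=scan_threshold))

    for condition in (sd.CONTROL, sd.DEPLETED):
        pooled = ia.merge_replicates(*ds.interactions[condition])
        pooled = ia.expected_counts(pooled)
        called[condition] = ia.call_significant_interactions(
            pooled, alpha=alpha, min_distance=min_distance)
        fps[condition] = fp_mod.call_footprints(
            ds.cut_profiles[condition], fdr=footprint_fdr,
            n_shuffles=n_shuffles, seed=config.seed)
        occs[condition] = ma.occupied_motifs(raw_occs, fps[condition])
        assigns[condition] = integ.assign_dhs_to_promoters(
            ds.dhs, called[condition], ds.fragments,
            promoter_strands=ds.promoter_strands)
        nets[condition] = net_mod.build_network(
            occs[condition], assigns[condition], up, down, ds.family_map,
            runx1_eto_peaks=ds.runx1_eto_peaks, fragments=ds.fragments,
            condition=condition)

    return PipelineResult(dataset=ds, called=called, footprints=fps,
                          occurrences=occs, assignments=assigns,
                          deg_up=up, deg_down=down, networks=nets)


def edge_recovery(result: PipelineResult, condition: str = sd.DEPLETED,
                  ) -> dict[str, float]:
    """Recall/precision of recovered network edges against planted truth."""
    truth_pairs = {(f, g) for f, g, _d in result.dataset.truth.true_edges}
    found = result.networks[condition].edge_keys()
    tp = len(truth_pairs & found)
    return {
        "recall": tp / len(truth_pairs) if truth_pairs else float("nan"),
        "precision": tp / len(found) if found else float("nan"),
        "n_truth": len(truth_pairs),
        "n_found": len(found),
    }


def gained_family_enrichment(result: PipelineResult,
                             p_cutoff: float = 0.01) -> dict[str, float]:
    """Per-family enrichment scores in DHSs at depletion-gained interactions.

    Gained interactions come from the exact differential test between the
    pooled condition libraries; the reference peak set is the DHSs linked
    in the control condition.
    """
    ds = result.dataset
    diff = ia.differential_interactions(
        [r for r in result.called[sd.CONTROL]],
        [r for r in result.called[sd.DEPLETED]], p_cutoff=p_cutoff)
    sig_depleted = {r.pair for r in result.called[sd.DEPLETED] if r.significant}
    gained_others = {pair[1] for d in diff for pair in [d["pair"]]
                     if d["differential"] and d["direction"] == "gained"
                     and pair in sig_depleted}

    frag_by_id = {f.fragment_id: f for f in ds.fragments}
    def dhs_in(other_ids: set[int]) -> list[PeakRecord]:
        out = []
        for dhs in ds.dhs:
            for oid in other_ids:
                if frag_by_id[oid].interval.contains_point(
                        dhs.interval.chrom, dhs.summit):
                    out.append(dhs)
                    break
        return out

    control_others = {r.other_id for r in result.called[sd.CONTROL]
                      if r.significant}
    specific = dhs_in(gained_others)
    reference = dhs_in(control_others - gained_others)
    if not specific or not reference:
        return {}
    by_family: dict[str, list[MotifOccurrence]] = {}
    for occ in result.occurrences[sd.DEPLETED]:
        by_family.setdefault(ds.family_map[occ.motif_id], []).append(occ)
    return {family: ma.enrichment_score(specific, reference, occ_list)
            for family, occ_list in sorted(by_family.items())}
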