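# chicnet

Integrative analysis of promoter capture Hi-C (CHi-C), digital DNaseI
footprinting, ChIP peaks, PWM motifs, and expression changes, assembled
into a transcription-factor-family → gene regulatory network. The
setting is a two-condition knockdown study (an oncogenic fusion TF
depleted by siRNA, `siRE`, versus a mismatch control, `siMM`), but every
stage is generic. A first-class synthetic-data generator emulates the
statistical structure of the sequencing libraries with known ground
truth, so every stage is testable for calibration and recovery.

Intended users: regulatory-genomics analysts who have fragment-level
CHi-C counts, per-base DNaseI cut profiles, peak sets, and expression
tables, and want promoter–enhancer links and an evidence-annotated
regulatory network.

## Methods at a glance

- **Interaction calling.** With N total ligation pairs over the tested
  bait–other-end universe, each pair is scored by the cumulative
  binomial tail `p_ij = P(X ≥ k_ij)`, `X ~ Binomial(N, e_ij/N)`,
  against a random-ligation background `e_ij ∝ c_i·c_j·f(d_ij)`
  (fragment coverages times a monotone empirical distance decay, fitted
  jointly by iterative proportional fitting). BH-FDR across tested
  pairs; pairs closer than 10 kb are excluded.
- **Differential interactions.** Exact two-sided binomial test of the
  per-pair count split `k_A` out of `k_A + k_B` against the library
  proportion `N_A/(N_A+N_B)`, flagged at p ≤ 0.01.
- **A/B compartments.** Leading eigenvector of the Pearson correlation
  of the distance-normalized (O/E) binned contact matrix, sign oriented
  by DHS density (A = open).
- **Digital footprints.** Strand-aware two-shoulder binomial depletion
  test: plus-strand cuts in the candidate footprint versus its upstream
  shoulder, minus-strand versus downstream,
  `score = −log10 p₊ − log10 p₋`, scanned over footprint lengths
  11–25 bp; calls are greedy non-overlapping maxima thresholded at an
  empirical FDR from within-window shuffles.
- **Motifs.** Log-likelihood-ratio PWM scanning of both strands at 80%
  of the maximal score; a motif is *occupied* when it overlaps a called
  footprint. Enrichment `log2((f_spec+ψ)/(f_ref+ψ))` on the fraction of
  peaks carrying an occupied motif; motif-pair co-localization counted
  center-to-center within 50 bp and tested by a bootstrap Z-score over
  equal-size random footprint sets drawn from the footprint universe.
- **Integration and network.** DHSs are assigned to genes whose bait
  fragment they contact through significant interactions (summit-in-
  fragment rule); genes with ≥ 2-fold expression change at p ≤ 0.01
  gate the network: an edge family → gene requires an occupied motif of
  that family in a DHS assigned to the gene. Edges carry their
  (dhs, interaction, occurrence) evidence chain; exports are GraphML,
  TSV, and dot.

## Worked example

```python
from chicnet.pipeline import run_standard_analysis, edge_recovery
from chicnet.synthetic_data import SimulationConfig, CONTROL, DEPLETED

res = run_standard_analysis(SimulationConfig(seed=42))
for cond in (CONTROL, DEPLETED):
    n = sum(r.significant for r in res.called[cond])
    tested = sum(1 for r in res.called[cond] if r.p_value == r.p_value)
    print(f"{cond}: {n} significant interactions (of {tested} tested pairs)")
print(f"footprints called (siRE, FDR 0.01): {len(res.footprints[DEPLETED])}")
print(f"occupied motif occurrences (siRE): "
      f"{sum(o.occupied for o in res.occurrences[DEPLETED])}")
print(f"differentially expressed genes: "
      f"{len(res.deg_up)} up, {len(res.deg_down)} down")
net = res.networks[DEPLETED]
print(f"network (siRE): {len(net.nodes)} nodes, {len(net.edges)} edges")
rec = edge_recovery(res)
print(f"planted-edge recovery: recall {rec['recall']:.2f}, "
      f"precision {rec['precision']:.2f}")
```

prints:

```
siMM: 23 significant interactions (of 18673 tested pairs)
siRE: 31 significant interactions (of 18673 tested pairs)
footprints called (siRE, FDR 0.01): 15
occupied motif occurrences (siRE): 24
differentially expressed genes: 15 up, 5 down
network (siRE): 19 nodes, 14 edges
planted-edge recovery: recall 0.70, precision 1.00
```

The 35 planted loops (10 shared, 15 gained on depletion, 10 lost)
dominate the significant sets; the siRE network recovers planted
regulatory edges with perfect precision, while recall is bounded by
footprint detection power at the simulated cut depth. Every edge can be
traced back through its DHS, interaction, and motif-occurrence ids.

The same stages are exposed as a CLI:

```
chicnet simulate --seed 1 --out sim/
chicnet call-interactions --bedpe sim/interactions_siMM_rep1.bedpe \
    --bedpe sim/interactions_siMM_rep2.bedpe --out called_siMM.bedpe
chicnet footprint --cuts sim/cuts_siRE.tsv --fdr 0.01 --out fp.bed
chicnet assign --dhs sim/dhs.narrowPeak --bedpe called_siMM.bedpe \
    --fragments sim/fragments.bed --out assignments.tsv
```

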