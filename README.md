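# regmaster

Master-regulator discovery from transcriptomic case-control studies, and
drug repositioning against the dysregulated regulons.

Complex diseases rarely reduce to single-gene effects: a transcription
factor (TF) whose activity shifts drags dozens of target genes with it.
`regmaster` is built for analysts who want to work at that regulon level.
From a healthy reference cohort it infers a TF-centric transcriptional
network; against a panel of case-control studies it asks which regulons
are consistently enriched with differentially expressed genes (master
regulators, MRs); it calls each MR's activation state, models how regulon
activity relates to patient survival, and finally screens a
drug-perturbation reference for compounds whose signatures *revert* the
disease expression profile.

## The method in brief

- **Network inference** (ARACNe-style): mutual information
  `MI(x, y)` between each TF and every gene (equal-frequency binned ranks,
  Miller-Madow corrected), a pooled permutation null with BH-adjusted
  p < .001, 100-bootstrap consensus, data-processing-inequality pruning of
  the weakest edge in every TF-TF-target triangle, and a mode of action
  per edge, `sign(r_Pearson(TF, target))`.
- **Master regulators**: per study, DEGs (fdr < .05, |log2FC| > 1) are
  tested for overrepresentation in each regulon (hypergeometric upper
  tail, BH across regulons). A *common* MR has regulon size > 50 and is
  enriched in >= 80% of studies; *consensus* MRs are common in both
  reference networks.
- **Activation state** (two-tailed GSEA): split a regulon into positive
  (A) and negative (B) mode targets, compute weighted KS enrichment
  scores on the logFC ranking, and test `dES = ES_A - ES_B` against a
  gene-label permutation null — dES > 0 means activated in cases.
- **Survival**: per-sample regulon activity via a GSVA-style kernel-CDF
  rank statistic, multivariable Cox models per study (stratified when the
  proportional-hazards test fails), a >= 50%-of-studies consensus with
  consistent hazard direction, and quartile-discretised Kaplan-Meier
  curves on z-merged scores.
- **Connectivity map**: merged regulon genes split into up/down tags by
  logFC; each drug scored by the classic rank-based KS composite in
  [-1, 1]; *reverters* (score < 0, fdr < .05 in **all** studies) are
  intersected across three query presets and both networks.

Everything is testable without external data: `regmaster.synthetic`
plants a linear-Gaussian ground truth (regulons with signed couplings,
disease MRs with shifted activity, survival MRs with a hazard
coefficient, reverter drugs) whose recovery the test suite measures.

## Worked example

Simulate a small benchmark bundle and run the full pipeline:

```bash
regmaster simulate --preset mini --outdir bundle --seed 7
regmaster run --config bundle/config.yaml --outdir bundle/results
```

which prints (seed 7):

```
bundle written to bundle (config: bundle/config.yaml)
3 case-control studies, 2 survival studies
wrote outputs to bundle/results
consensus MRs: TF000, TF001, TF004
```

`bundle/truth.json` lists the planted disease MRs — for this seed exactly
`TF000, TF001, TF004` — so the consensus stage recovered all three with no
false positives; `report.json` shows `"final_drugs": ["DRUG005",
"DRUG015"]`, which are precisely the two planted reverter drugs. `bundle/results/` then holds, per reference network, the
edge list (`network_TN*.tsv`), signed regulons (`regulons_TN*.gmt`),
per-study DEG and MRA tables, GSEA2 activation calls, Cox and
survival-consensus tables, Kaplan-Meier curve data, and the CMap score and
reverter tables; `report.json` summarises the run. The same stages are
available individually (`regmaster infer-network`, `diffexp`, `mra`,
`gsea2`, `survival`, `cmap`) and as library functions.

The library surface mirrors the stages: `regmaster.network.infer_edges`,
`apply_dpi`, `assign_modes`; `regmaster.diffexp.fit_differential`,
`select_degs`; `regmaster.mra.mra_study`, `study_consensus`,
`network_consensus`; `regmaster.enrichment.two_tailed_gsea`,
`gsva_scores`; `regmaster.survival.fit_cox_regulon`,
`merge_and_discretize`, `km_logrank`; `regmaster.cmap.build_query`,
`score_reference`, `repositioning_consensus`.

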