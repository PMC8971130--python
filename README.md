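# cfrna

Analysis toolkit for **cell-free RNA (cfRNA) liquid biopsies in
pregnancy**: plasma cfRNA mixes transcripts shed by tissues across the
body, so serial blood draws can track maternal organ health and detect
signatures of preeclampsia — a hypertensive multi-organ syndrome and a
leading cause of maternal death — months before clinical symptoms.

The package implements the full statistical pipeline for a longitudinal
case/control cfRNA study, together with a synthetic cohort generator so
every stage runs and is tested without any sequencing data:

- **Sample QC** — three per-sample metrics (RNA degradation as the
  fraction of detected genes with all reads in their 3′-most exon, DNA
  contamination as the intron:exon read ratio, reads assigned) with the
  pooled empirical 95th-percentile exclusion rule.
- **Normalization** — TMM scaling factors (doubly trimmed,
  precision-weighted mean of M-values against an upper-quartile
  reference), moderated log₂CPM, a 0.5-CPM/75% detection filter, and
  least-squares batch-offset removal.
- **Differential signal** — per-gene Mann–Whitney rank tests with
  Benjamini–Hochberg correction; per-window log₂ fold change
  log₂FC = median(case logCPM) − median(control logCPM) over one sample
  per participant; and a bootstrap stability statistic
  CV = ∂ / |log₂FC|, where ∂ is the one-sided 95% bootstrap error bound
  toward zero fold change (CV ≥ 1 ⇔ the sign itself is uncertain).
- **Longitudinal trends** — k-means over per-window fold-change
  profiles with kneedle elbow selection (k = 1…16), a within-gene
  column-permutation control, and two-cluster heatmap segregation of
  samples with sensitivity/specificity readout.
- **Tissue / cell-type signatures** — Gini-coefficient gene specificity
  (G = Σᵢⱼ|xᵢ−xⱼ| / 2T·Σx; cut 0.6 for tissues, 0.8 for cell types),
  one-sided hypergeometric enrichment of differential gene sets, and
  signature scores (sum of logCPM over profile genes) anchored to each
  participant's post-partum sample and scaled by the category IQR.
- **Risk classifier** — an elastic-net logistic model on samples
  collected at 5–16 weeks of gestation, with per-cohort median
  centering, discovery-IQR scaling, internal-control-gene sample
  normalization, |log₂FC|/CV feature pre-selection, 80/20 + 5-fold
  grouped CV hyperparameter tuning, and a probability threshold tuned
  at a 10% false-positive-rate target, rounded to the nearest 0.05.
- **Performance metrics** — sensitivity/specificity/PPV/NPV with 90%
  Jeffreys (Beta(x+½, n−x+½)) intervals and AUROC with a
  Hanley–McNeil binormal CI.

## Worked example

`examples/06_risk_model.py` simulates a discovery cohort (61 controls,
24 cases) and an independent validation cohort, trains the risk model
and evaluates it held-out:

```
57 internal-control genes (adjusted p > 0.99)
panel of 27 genes; tuned threshold P = 0.5
held-out AUROC 1.00 [1.00-1.00]
held-out sensitivity: 100% [79-100%] (90% Jeffreys interval)
held-out specificity: 100% [95-100%] (90% Jeffreys interval)
```

The internal controls are genes whose levels do not differ between
outcomes (BH-adjusted p > 0.99); their per-sample median anchors each
sample like housekeeping genes in RT-qPCR. The panel is the gene set the
tuned model consumes, and a sample is called at risk when P(case) ≥ the
tuned threshold. On clean synthetic signal the held-out metrics are
near-perfect; the brackets are 90% Jeffreys intervals reflecting the
validation cohort's size. The other `examples/` scripts walk through
each capability (simulation, QC, differential signal, trends,
signatures, full pipeline) in the same style, and
`cfrna.run_pipeline(AnalysisConfig(...))` chains everything, writing TSV
tables plus a JSON manifest carrying the seed and config hash.

## Layout

```
src/cfrna/       io, simulate, qc, normalize, degs, trends,
                 profiles, classifier, metrics, pipeline
examples/        one narrative script per capability
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, assumptions, parameter choices, limitations
```
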