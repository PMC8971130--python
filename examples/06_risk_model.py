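"""Early-gestation preeclampsia risk model, end to end.

Trains the elastic-net logistic model on a simulated discovery cohort
(bespoke centering/IQR-scaling/control-gene normalization, fold-change
and CV feature pre-selection, 80/20 tuning), tunes the probability
threshold at a 10% FPR target, and evaluates on a held-out cohort.
"""

import warnings

warnings.filterwarnings("ignore")

from cfrna import classifier as clf
from cfrna import degs, metrics, normalize, pipeline, simulate
from cfrna.io import OUTCOME_PE

design = simulate.SimulationDesign(
    cohorts={"discovery": (61, 24), "validation": (35, 8)},
    n_genes=800, frac_deg=0.05, seed=6,
)
cm, meta, truth = simulate.simulate_cohort(design)
kept = normalize.filter_genes(cm, meta.loc[meta["cohort"] == "discovery", "sample_id"])
cm = cm.subset(genes=kept)
cm = normalize.logcpm(cm, normalize.tmm_factors(cm))

cohorts = meta.set_index("sample_id")["cohort"]
disc = meta[meta["cohort"] == "discovery"]
early = pipeline._early_first_samples(disc, ga_max=16.0)
em = disc.set_index("sample_id").loc[early]
pe = early[(em["outcome"] == OUTCOME_PE).to_numpy()]
nt = early[(em["outcome"] != OUTCOME_PE).to_numpy()]
deg = degs.rank_test_degs(cm.logcpm, pe, nt)

scheme = clf.fit_normalization(cm.logcpm, cohorts, "discovery", deg["bh_adjusted_p"])
print(f"{len(scheme.control_genes)} internal-control genes (adjusted p > 0.99)")
normalized = clf.apply_normalization(scheme, cm.logcpm, cohorts)

y = meta.set_index("sample_id")["outcome"].eq(OUTCOME_PE)
parts = meta.set_index("sample_id")["participant_id"]
model = clf.train(normalized[early].T, y.loc[early], parts.loc[early],
                  deg.index[deg["significant"]].tolist(), seed=6)
threshold = clf.tune_threshold(model, normalized[early].T, y.loc[early])
print(f"panel of {len(model.genes)} genes; tuned threshold P = {threshold}")
print("hyperparameters:", model.hyperparameters)

val_early = pipeline._early_first_samples(meta[meta["cohort"] == "validation"], 16.0)
pred = clf.predict(model, normalized[val_early].T, meta)
auc = metrics.auroc(pred["probability"], y.loc[pred["sample_id"]])
cmx = metrics.ConfusionMatrix.from_labels(y.loc[pred["sample_id"]], pred["predicted"])
perf = metrics.confusion_metrics(cmx)
print(f"held-out AUROC {auc.estimate:.2f} [{auc.ci_low:.2f}-{auc.ci_high:.2f}]")
for name in ("sensitivity", "specificity"):
    est, lo, hi = perf[name].as_percent()
    print(f"held-out {name}: {est}% [{lo}-{hi}%] (90% Jeffreys interval)")
# A sample is called at risk when P(case) >= the tuned threshold; a
# participant with two eligible samples is scored by their maximum.
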