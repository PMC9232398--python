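"""Classify short vs long survival from gene-pair interactions (JDINAC).

One gene pair is correlated +0.8 in the short-survival class and -0.8 in the
long-survival class; every marginal distribution is identical, so only the
pairwise dependence carries signal. JDINAC's log density-ratio features find
it, and the repeated-split edge counts rank that pair first.
"""

from diffomics import SimulationConfig, simulate_cohort
from diffomics.evaluate import cross_validate, evaluate_predictions
from diffomics.ingest import LabeledDataset
from diffomics.jdinac import run_jdinac

cfg = SimulationConfig(
    n_samples=400,
    p_genes=6,
    class_fraction=0.5,
    differential_pairs=[(0, 1, 0.8, -0.8)],
    seed=11,
)
cohort = simulate_cohort(cfg)
dataset = LabeledDataset(cohort.expression, cohort.true_class, horizon_years=5.0)

model = run_jdinac(dataset, n_splits=25, seed=1)
print("edge counts over 25 data splits (top 3 of 15 pairs):")
print(model.edge_report().head(3).to_string(index=False))

runner = lambda train, test: run_jdinac(train, n_splits=25, seed=2).predict(test)
preds = cross_validate(dataset, runner, k=5, seed=3)
ev = evaluate_predictions(preds)
print(f"\n5-fold CV AUC: {ev.auc:.3f}  (Youden cutoff {ev.cutoff:.3f})")
print(f"accuracy {ev.confusion['accuracy']:.3f}, "
      f"sensitivity {ev.confusion['sensitivity']:.3f}, "
      f"specificity {ev.confusion['specificity']:.3f}")
# the planted pair is selected in (almost) every split; AUC approaches the
# Bayes limit (~0.90) for this configuration.
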