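"""End-to-end run: simulate -> screen -> JDINAC + LGCDG -> network -> evaluate.

The same gene pair is made differential in all three omics layers, so it
should survive the "supported by at least two omics" rule and appear in the
combined differential network. Survival hazards differ 100-fold between the
classes, so the cross-validated classifier separates the dichotomized groups
and the Kaplan-Meier log-rank test is strongly significant.
"""

import pandas as pd

from diffomics import PipelineConfig, SimulationConfig, run_pipeline
from diffomics.network import read_network

sim = SimulationConfig(
    n_samples=240,
    p_genes=8,
    class_fraction=0.4,
    differential_pairs=[(0, 1, 0.8, -0.8)],
    cnv_pairs=[(0, 1, 0.7, -0.5)],
    mutation_pairs=[(0, 1, 0.7, -0.5)],
    cnv_quantile=0.6,
    mutation_quantile=0.7,
    hazard_class1=2.0,
    hazard_class0=0.02,
)
config = PipelineConfig(
    simulation=sim,
    horizons=(5.0,),
    jdinac_n_splits=25,
    seed=1,
    outdir="scratch/example_run",
)
outdir = run_pipeline(config)

metrics = pd.read_csv(outdir / "metrics_5yr.tsv", sep="\t")
print("5-year evaluation:")
print(metrics.to_string(index=False))
net = read_network(outdir / "network_5yr.graphml")
print(f"\ncombined differential network: {len(net)} edges")
print(f"planted pair present: {('G0', 'G1') in net.edges} "
      f"(layers: {net.edges.get(('G0', 'G1'))})")
hubs = pd.read_csv(outdir / "hubs_5yr.tsv", sep="\t")
print(f"hub genes (degree >= 3): {hubs['gene'].tolist()}")
# AUC is limited by dichotomization label noise (long-hazard patients can
# still die within 5 years); the log-rank p-value shows the risk groups
# separate sharply all the same.
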