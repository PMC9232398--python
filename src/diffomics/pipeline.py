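"""End-to-end orchestration: cohort -> preprocessing -> screening ->
per-layer differential models -> combined network -> evaluation.

For every survival horizon t the pipeline dichotomizes the cohort, screens
each omics layer by distance correlation with survival time, intersects the
screened sets, runs JDINAC on the expression layer and the latent copula
differential graph on each binary layer over the common genes, combines the
per-layer edges ("supported by >= 2 omics"), calls degree->=3 hub genes, and
evaluates the classifier by stratified cross-validation with ROC/Youden/
Kaplan-Meier outputs. A manifest (config, seed, per-stage counts) makes the
run reproducible; outputs carry no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import cross_validate, evaluate_predictions
from .ingest import (
    ClinicalTable,
    LabeledDataset,
    binarize_cnv,
    collapse_duplicates,
    dichotomize,
    filter_and_impute,
    fpkm_to_tpm,
    read_clinical,
    read_expression,
    read_mutations_to_matrix,
)
from .jdinac import jdinac_edges, run_jdinac
from .lgcdg import (
    delta_edges,
    estimate_delta,
    latent_correlation,
    low_prevalence_genes,
    select_lambda,
)
from .network import call_hubs, combine_layers, export_network, hub_consensus
from .screening import dcsis_screen, intersect_screened
from .simulate import MultiOmicsCohort, SimulationConfig, simulate_cohort

log = logging.getLogger("diffomics")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_cohort"]


def stage_seed(seed: int, tag: str) -> int:
    """Derive a per-stage sub-seed deterministically from the global seed."""
    return (int(seed) ^ zlib.crc32(tag.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run; every field mirrors a CLI flag."""

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    cnv_path: str | None = None
    mutation_path: str | None = None
    clinical_path: str | None = None
    expression_is_fpkm: bool = False
    clinical_time_divisor: float = 1.0
    horizons: tuple[float, ...] = (5.0,)
    screening_d: int | None = None
    jdinac_n_splits: int = 100
    jdinac_min_count: int | None = None
    lgcdg_lambda: float | None = None
    lgcdg_grid: tuple[float, ...] | None = None
    hub_degree: int = 3
    min_layers: int = 2
    cv_folds: int = 5
    seed: int = 0
    outdir: str = "runs/run0"

    def validate(self) -> None:
        if not self.horizons:
            raise ValueError("horizons must be nonempty")
        if self.simulation is None:
            for name in ("expression_path", "cnv_path", "clinical_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"real-data mode requires {name}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: {path}")
            if self.mutation_path is not None and not Path(self.mutation_path).exists():
                raise FileNotFoundError(f"mutation_path: {self.mutation_path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d


def load_cohort(config: PipelineConfig) -> MultiOmicsCohort:
    """Simulate, or read and preprocess, the input cohort."""
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        return simulate_cohort(sim)

    expr = read_expression(config.expression_path)
    expr = collapse_duplicates(expr)
    expr, n_removed = filter_and_impute(expr)
    log.info("expression: %d genes removed by missingness filter", n_removed)
    if config.expression_is_fpkm:
        expr = fpkm_to_tpm(expr)
    cnv_raw = read_expression(config.cnv_path)
    cnv_raw = collapse_duplicates(cnv_raw)
    cnv_raw, _ = filter_and_impute(cnv_raw)
    clinical = read_clinical(
        config.clinical_path, time_divisor=config.clinical_time_divisor
    )

    samples = sorted(
        set(expr.index) & set(cnv_raw.index) & set(clinical.table["sample_id"])
    )
    genes = sorted(set(expr.columns) & set(cnv_raw.columns))
    expr = expr.loc[samples, genes]
    cnv = binarize_cnv(cnv_raw.loc[samples, genes])
    if config.mutation_path is not None:
        mutation = read_mutations_to_matrix(config.mutation_path, genes, samples)
    else:
        mutation = pd.DataFrame(0, index=samples, columns=genes)
    clin = clinical.table.set_index("sample_id").loc[samples]
    return MultiOmicsCohort(
        sample_ids=samples,
        gene_ids=genes,
        expression=expr,
        cnv=cnv,
        mutation=mutation,
        os_time_years=clin["os_time_years"],
        os_event=clin["os_event"],
    )


def _jdinac_runner(n_splits: int, seed: int):
    def runner(train: LabeledDataset, test_matrix: pd.DataFrame) -> np.ndarray:
        model = run_jdinac(train, n_splits=n_splits, seed=seed)
        return model.predict(test_matrix)

    return runner


def _lgcdg_layer(
    matrix: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig,
    layer: str,
):
    """Differential-precision edges for one binary layer."""
    d1 = matrix.loc[labels.index[labels == 1]]
    d0 = matrix.loc[labels.index[labels == 0]]
    drop = set(low_prevalence_genes(d1.to_numpy())) | set(
        low_prevalence_genes(d0.to_numpy())
    )
    keep = [g for k, g in enumerate(matrix.columns) if k not in drop]
    if drop:
        log.info("%s: dropped %d low-prevalence genes", layer, len(drop))
    if len(keep) < 2:
        log.warning("%s: fewer than 2 usable genes; empty layer", layer)
        from .network import EdgeSet

        return EdgeSet(layer=layer), None
    est1 = latent_correlation(d1[keep].to_numpy(), gene_ids=keep)
    est0 = latent_correlation(d0[keep].to_numpy(), gene_ids=keep)
    if config.lgcdg_lambda is not None:
        lam = config.lgcdg_lambda
    else:
        lam = select_lambda(
            est1.sigma_hat,
            est0.sigma_hat,
            len(d1),
            len(d0),
            grid=list(config.lgcdg_grid) if config.lgcdg_grid else None,
        )
    dm = estimate_delta(est1.sigma_hat, est0.sigma_hat, lam, gene_ids=keep)
    return delta_edges(dm, layer=layer), dm


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config)
    clinical = ClinicalTable(cohort.clinical())
    counts: dict[str, object] = {
        "n_samples": len(cohort.sample_ids),
        "n_genes": len(cohort.gene_ids),
    }

    layers = {"mrna": cohort.expression, "cnv": cohort.cnv, "mutation": cohort.mutation}
    # a binary layer with no alterations at all carries no signal; drop it
    layers = {
        name: m
        for name, m in layers.items()
        if name == "mrna" or m.to_numpy().sum() > 0
    }

    hubs_by_horizon: dict[float, list[str]] = {}
    for t in config.horizons:
        tag = f"{t:g}yr"
        labels, excluded = dichotomize(clinical, t, horizons=tuple(config.horizons))
        counts[f"{tag}_labeled"] = int(labels.size)
        counts[f"{tag}_excluded"] = len(excluded)
        log.info("%s: %d labeled (%d short), %d censored-excluded",
                 tag, labels.size, int(labels.sum()), len(excluded))
        if labels.nunique() < 2 or labels.value_counts().min() < 10:
            log.warning("%s: class counts too small; horizon skipped", tag)
            continue

        # DC-SIS per layer against observed survival time, then intersection
        screened = []
        for name, matrix in layers.items():
            res = dcsis_screen(
                matrix,
                cohort.os_time_years.to_numpy(),
                d=config.screening_d,
                layer=name,
            )
            res.to_frame().to_csv(
                outdir / f"screening_{name}_{tag}.tsv", sep="\t", index=False
            )
            screened.append(res)
        common = intersect_screened(screened) if len(screened) >= 2 else screened[0].selected
        counts[f"{tag}_common_genes"] = len(common)
        pd.Series(common, name="gene").to_csv(
            outdir / f"common_genes_{tag}.tsv", sep="\t", index=False
        )
        if len(common) < 2:
            log.warning("%s: <2 common genes; horizon skipped", tag)
            continue

        # per-layer differential models
        edge_sets = []
        expr_ds = LabeledDataset(
            matrix=cohort.expression.loc[labels.index, common],
            labels=labels,
            horizon_years=t,
            excluded_samples=excluded,
        )
        jd = run_jdinac(
            expr_ds,
            n_splits=config.jdinac_n_splits,
            seed=stage_seed(config.seed, f"jdinac_{tag}"),
        )
        jd.edge_report().to_csv(outdir / f"edges_mrna_{tag}.tsv", sep="\t", index=False)
        edge_sets.append(jdinac_edges(jd, min_count=config.jdinac_min_count))
        for name in ("cnv", "mutation"):
            if name not in layers:
                continue
            es, dm = _lgcdg_layer(
                layers[name].loc[labels.index, common], labels, config, name
            )
            edge_sets.append(es)
            rows = sorted(
                ({"gene_i": a, "gene_j": b, "delta": w} for (a, b), w in es.edges.items()),
                key=lambda r: (r["gene_i"], r["gene_j"]),
            )
            pd.DataFrame(rows, columns=["gene_i", "gene_j", "delta"]).to_csv(
                outdir / f"edges_{name}_{tag}.tsv", sep="\t", index=False
            )
        for es in edge_sets:
            es.horizon_years = t
            counts[f"{tag}_edges_{es.layer}"] = len(es)

        network = combine_layers(edge_sets, min_layers=config.min_layers)
        hubs = call_hubs(network, hub_degree=config.hub_degree)
        hubs_by_horizon[t] = hubs
        counts[f"{tag}_network_edges"] = len(network)
        counts[f"{tag}_hubs"] = len(hubs)
        export_network(network, outdir / f"network_{tag}.graphml", "graphml")
        export_network(network, outdir / f"network_{tag}.sif", "sif")
        deg = network.degree()
        pd.DataFrame(
            [{"gene": g, "degree": deg.get(g, 0)} for g in hubs],
            columns=["gene", "degree"],
        ).to_csv(outdir / f"hubs_{tag}.tsv", sep="\t", index=False)

        # cross-validated evaluation of the expression classifier
        preds = cross_validate(
            expr_ds,
            _jdinac_runner(config.jdinac_n_splits, stage_seed(config.seed, f"cv_{tag}")),
            k=config.cv_folds,
            seed=stage_seed(config.seed, f"folds_{tag}"),
        )
        labeled_clin = ClinicalTable(
            clinical.table[clinical.table["sample_id"].isin(labels.index)].reset_index(
                drop=True
            )
        )
        ev = evaluate_predictions(preds, labeled_clin)
        preds.to_csv(outdir / f"predictions_{tag}.tsv", sep="\t", index=False)
        ev.roc.to_csv(outdir / f"roc_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame([ev.metrics_row()]).to_csv(
            outdir / f"metrics_{tag}.tsv", sep="\t", index=False
        )
        if ev.km_curves:
            pd.concat(
                [c.assign(group=name) for name, c in sorted(ev.km_curves.items())]
            ).to_csv(outdir / f"km_{tag}.tsv", sep="\t", index=False)
        counts[f"{tag}_auc"] = round(ev.auc, 6)

    consensus = hub_consensus(hubs_by_horizon) if len(hubs_by_horizon) >= 2 else {}
    pd.DataFrame(
        [
            {"gene": g, "horizons": ",".join(f"{t:g}" for t in ts)}
            for g, ts in consensus.items()
        ],
        columns=["gene", "horizons"],
    ).to_csv(outdir / "hub_consensus.tsv", sep="\t", index=False)

    manifest = {
        "package": "diffomics",
        "version": __version__,
        "config": config.to_dict(),
        "counts": counts,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
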