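"""Synthetic multi-omics cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without downloading a real cohort:

* a positive continuous expression matrix with class-dependent pairwise
  dependence — per class a multivariate Gaussian with unit variances and
  configured pairwise correlations, exponentiated to a TPM-like positive
  scale (log-normal marginals; the density-ratio classifier is rank/density
  based, so the monotone map is harmless);
* sparse 0/1 CNV and mutation matrices obtained by thresholding a latent
  Gaussian whose class-specific covariance is the inverse of a configured
  precision matrix, so the differential-precision ground truth is exact by
  construction;
* survival times in years: per-class exponential event times (short-survival
  class 1 has the larger hazard) with independent exponential censoring.

The same cohort can be written to disk in the ingest module's on-disk
formats, so the full pipeline runs on synthetic data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import EdgeSet

__all__ = [
    "SimulationConfig",
    "MultiOmicsCohort",
    "simulate_cohort",
    "true_differential_edges",
    "write_cohort",
]

Pair = tuple[int, int, float, float]


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    ``differential_pairs`` configures the continuous expression layer as
    ``(gene_i, gene_j, rho_class1, rho_class0)`` pairwise correlations of the
    latent Gaussian. ``cnv_pairs`` / ``mutation_pairs`` configure the binary
    layers as ``(gene_i, gene_j, omega1_off, omega0_off)`` off-diagonal
    entries of the class precision matrices (diagonal fixed at 1).
    ``*_quantile`` q sets the per-gene latent threshold so that a fraction
    1 - q of samples carries an alteration. Hazards are per-class exponential
    event rates in 1/years; censoring is an independent exponential.
    """

    n_samples: int = 200
    p_genes: int = 20
    class_fraction: float = 0.3
    differential_pairs: list[Pair] = field(default_factory=list)
    cnv_pairs: list[Pair] = field(default_factory=list)
    mutation_pairs: list[Pair] = field(default_factory=list)
    cnv_quantile: float = 0.7
    mutation_quantile: float = 0.9
    hazard_class1: float = 0.7
    hazard_class0: float = 0.1
    censoring_rate: float = 0.05
    horizon_years: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must be in (0, 1)")
        if self.hazard_class1 <= 0 or self.hazard_class0 <= 0:
            raise ValueError("hazards must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        for name, pairs in (
            ("differential_pairs", self.differential_pairs),
            ("cnv_pairs", self.cnv_pairs),
            ("mutation_pairs", self.mutation_pairs),
        ):
            for i, j, a, b in pairs:
                if max(i, j) >= self.p_genes or min(i, j) < 0:
                    raise ValueError(
                        f"{name}: gene index ({i},{j}) outside 0..{self.p_genes - 1}"
                    )
                if i == j:
                    raise ValueError(f"{name}: self-pair on gene {i}")
        for i, j, r1, r0 in self.differential_pairs:
            for r in (r1, r0):
                if not -1.0 < r < 1.0:
                    raise ValueError(
                        f"correlation {r} for pair ({i},{j}) outside (-1, 1)"
                    )
        for layer, pairs in (("cnv", self.cnv_pairs), ("mutation", self.mutation_pairs)):
            for cls in (0, 1):
                _assemble_precision(self.p_genes, pairs, cls, layer)  # PD check

    def gene_ids(self) -> list[str]:
        width = len(str(self.p_genes))
        return [f"G{k:0{width}d}" for k in range(self.p_genes)]

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{k:0{width}d}" for k in range(self.n_samples)]


@dataclass
class MultiOmicsCohort:
    """Aligned expression/CNV/mutation matrices plus clinical outcomes.

    All matrices are samples x genes with identical indexes. ``true_class``
    is known for synthetic cohorts only (1 = short survival).
    """

    sample_ids: list[str]
    gene_ids: list[str]
    expression: pd.DataFrame
    cnv: pd.DataFrame
    mutation: pd.DataFrame
    os_time_years: pd.Series
    os_event: pd.Series
    true_class: pd.Series | None = None

    def clinical(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "os_time_years": self.os_time_years.to_numpy(),
                "os_event": self.os_event.to_numpy(dtype=int),
            }
        )


def _assemble_correlation(p: int, pairs: list[Pair], cls: int) -> np.ndarray:
    r = np.eye(p)
    for i, j, rho1, rho0 in pairs:
        rho = rho1 if cls == 1 else rho0
        r[i, j] = r[j, i] = rho
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"expression correlation matrix for class {cls} is not positive definite"
        ) from exc
    return r


def _assemble_precision(p: int, pairs: list[Pair], cls: int, layer: str) -> np.ndarray:
    omega = np.eye(p)
    for i, j, o1, o0 in pairs:
        o = o1 if cls == 1 else o0
        omega[i, j] = omega[j, i] = o
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"{layer} precision matrix for class {cls} is not positive definite"
        ) from exc
    return omega


def _sample_binary_layer(
    rng: np.random.Generator,
    labels: np.ndarray,
    p: int,
    pairs: list[Pair],
    quantile: float,
    layer: str,
) -> np.ndarray:
    """Threshold a class-specific latent Gaussian at its marginal quantile."""
    n = labels.shape[0]
    out = np.zeros((n, p), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        omega = _assemble_precision(p, pairs, cls, layer)
        sigma = np.linalg.inv(omega)
        chol = np.linalg.cholesky(sigma)
        latent = rng.standard_normal((idx.size, p)) @ chol.T
        # cutoff per gene on the latent marginal scale: P(X_j > C_j) = 1 - q
        cutoff = stats.norm.ppf(quantile) * np.sqrt(np.diag(sigma))
        out[idx] = (latent > cutoff[None, :]).astype(int)
    return out


def simulate_cohort(config: SimulationConfig) -> MultiOmicsCohort:
    """Draw one cohort; the seed fully determines the output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.p_genes

    n1 = int(round(n * config.class_fraction))
    n1 = min(max(n1, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    expr = np.zeros((n, p))
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        r = _assemble_correlation(p, config.differential_pairs, cls)
        chol = np.linalg.cholesky(r)
        expr[idx] = np.exp(rng.standard_normal((idx.size, p)) @ chol.T)

    cnv = _sample_binary_layer(
        rng, labels, p, config.cnv_pairs, config.cnv_quantile, "cnv"
    )
    mutation = _sample_binary_layer(
        rng, labels, p, config.mutation_pairs, config.mutation_quantile, "mutation"
    )

    hazard = np.where(labels == 1, config.hazard_class1, config.hazard_class0)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    samples, genes = config.sample_ids(), config.gene_ids()
    return MultiOmicsCohort(
        sample_ids=samples,
        gene_ids=genes,
        expression=pd.DataFrame(expr, index=samples, columns=genes),
        cnv=pd.DataFrame(cnv, index=samples, columns=genes),
        mutation=pd.DataFrame(mutation, index=samples, columns=genes),
        os_time_years=pd.Series(os_time, index=samples, name="os_time_years"),
        os_event=pd.Series(os_event, index=samples, name="os_event"),
        true_class=pd.Series(labels, index=samples, name="true_class"),
    )


def true_differential_edges(config: SimulationConfig) -> dict[str, EdgeSet]:
    """Ground-truth differential pairs per layer (class parameters differ)."""
    genes = config.gene_ids()
    out: dict[str, EdgeSet] = {}
    for layer, pairs in (
        ("mrna", config.differential_pairs),
        ("cnv", config.cnv_pairs),
        ("mutation", config.mutation_pairs),
    ):
        es = EdgeSet(layer=layer, horizon_years=config.horizon_years)
        for i, j, a, b in pairs:
            if a != b:
                es.add(genes[i], genes[j], abs(a - b))
        out[layer] = es
    return out


def write_cohort(cohort: MultiOmicsCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the ingest module's on-disk formats.

    Expression and CNV as genes-in-rows TSV, mutations as a MAF-like table
    (one row per mutated sample/gene), clinical as sample/time/event TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "cnv": outdir / "cnv.tsv",
        "mutation": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    cohort.expression.T.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    cohort.cnv.T.to_csv(paths["cnv"], sep="\t", index_label="gene_id")
    rows = [
        {"Hugo_Symbol": g, "Tumor_Sample_Barcode": s}
        for s in cohort.sample_ids
        for g in cohort.gene_ids
        if cohort.mutation.at[s, g] == 1
    ]
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode"]).to_csv(
        paths["mutation"], sep="\t", index=False
    )
    cohort.clinical().to_csv(paths["clinical"], sep="\t", index=False)
    return paths
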