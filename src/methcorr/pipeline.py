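"""End-to-end training and inference.

``train`` turns a matched methylation/expression cohort into a
:class:`~methcorr.types.ModelStore`: split the samples 40/40/20, screen
CpG–gene Spearman correlations in the two discovery sets, select each
gene's top expression-correlated CpG sites, compute and impute MethCORR
scores, fit cross-validated polynomial models on the discovery samples and
validate them on the held-out set.  Only genes clearing the dual R² > 0.16
gate enter the store; everything else lands in a rejected-genes audit
table with a reason code.

``infer`` applies a store to a new β-value matrix — tolerating missing
probes, as when an EPIC profile meets a 450K-trained store — and returns
inferred expression (iRNA) plus a per-sample coverage report.
``evaluate_concordance`` scores inferred against observed expression
sample by sample.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MethcorrConfig
from .discovery import combine_rank_sum, select_top_cpgs, spearman_screen, split_samples
from .mcs import MCSMatrix, compute_mcs, impute_missing_mcs
from .models import fit_gene_model, gene_seed, predict, validate_gene_model
from .types import (
    ExpressionMatrix,
    MethCORRMatrix,
    MethylationMatrix,
    ModelStore,
    ProbeSets,
)

__all__ = ["InferenceReport", "train", "infer", "evaluate_concordance"]

logger = logging.getLogger(__name__)

#: reason codes used in the rejected-genes audit table
REASON_TOO_FEW_CPGS = "too-few-CpGs"
REASON_LOW_DISCOVERY_R2 = "low-discovery-R2"
REASON_LOW_VALIDATION_R2 = "low-validation-R2"
REASON_FIT_FAILED = "fit-failed"


@dataclass
class InferenceReport:
    """Per-sample accounting of an inference (or concordance) run."""

    per_sample: pd.DataFrame
    summary: dict = field(default_factory=dict)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.2fs (%s)", self.name, dt, exc)
        return False


def train(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    config: MethcorrConfig | None = None,
    *,
    cancer_type: str = "unspecified",
    platform: str = "450K",
) -> ModelStore:
    """Train a MethCORR model store from matched methylation + expression.

    Returns a store holding, for every MethCORR gene (dual R² > 0.16), its
    selected CpG sites and fitted polynomial model, plus training metadata
    and a sidecar table of rejected genes with reasons.
    """
    config = config or MethcorrConfig()

    shared = sorted(set(meth.sample_ids) & set(expr.sample_ids))
    if len(shared) < config.min_train_samples:
        raise ValueError(
            f"need >= {config.min_train_samples} shared samples, got {len(shared)}"
        )
    meth = meth.subset_samples(shared)
    expr = expr.subset_samples(shared)

    with _Stage("split"):
        split = split_samples(shared, config.seed)

    with _Stage("spearman-screen"):
        rec1 = spearman_screen(
            expr, meth, split.discovery1, 1,
            p_threshold=config.p_threshold, min_pair_n=config.min_pair_n,
        )
        rec2 = spearman_screen(
            expr, meth, split.discovery2, 2,
            p_threshold=config.p_threshold, min_pair_n=config.min_pair_n,
        )

    with _Stage("rank-sum-selection"):
        ranked = combine_rank_sum(rec1, rec2)
        matrix = select_top_cpgs(
            ranked, config.max_per_side, min_cpg_total=config.min_cpg_total
        )

    rejected: list[tuple[str, str]] = []
    for gene in expr.gene_ids:
        if gene not in matrix:
            rejected.append((gene, REASON_TOO_FEW_CPGS))

    with _Stage("mcs"):
        mcs = compute_mcs(meth, matrix, min_probe_coverage=config.min_probe_coverage)
        if np.isnan(mcs.mcs).any():
            mcs = impute_missing_mcs(mcs, k=config.knn_k)

    with _Stage("modeling"):
        mcs_df = mcs.to_frame()
        expr_df = expr.to_frame()
        disc = list(split.discovery)
        val = list(split.validation)
        kept_models = {}
        kept_probes: dict[str, ProbeSets] = {}
        for gene in mcs.gene_ids:
            x_disc = mcs_df.loc[gene, disc].to_numpy()
            y_disc = expr_df.loc[gene, disc].to_numpy()
            try:
                model = fit_gene_model(
                    x_disc, y_disc, gene_seed(config.seed, gene),
                    sample_ids=disc, gene=gene,
                    cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
                    rmse_improvement=config.rmse_improvement,
                    min_fit_samples=config.min_fit_samples,
                )
            except ValueError as err:
                logger.warning("gene %s: fit failed (%s)", gene, err)
                rejected.append((gene, REASON_FIT_FAILED))
                continue
            model = validate_gene_model(
                model,
                mcs_df.loc[gene, val].to_numpy(),
                expr_df.loc[gene, val].to_numpy(),
                r2_gate=config.r2_gate,
                min_validation_samples=config.min_validation_samples,
            )
            if model.methcorr_flag:
                kept_models[gene] = model
                kept_probes[gene] = matrix.genes[gene]
            elif model.r2_discovery <= config.r2_gate:
                rejected.append((gene, REASON_LOW_DISCOVERY_R2))
            else:
                rejected.append((gene, REASON_LOW_VALIDATION_R2))

    logger.info(
        "training done: %d MethCORR genes, %d rejected", len(kept_models), len(rejected)
    )
    metadata = {
        "cancer_type": cancer_type,
        "platform": platform,
        "split_seed": config.seed,
        "n_samples": len(shared),
        "n_discovery1": len(split.discovery1),
        "n_discovery2": len(split.discovery2),
        "n_validation": len(split.validation),
        "config": config.to_dict(),
    }
    return ModelStore(
        methcorr_matrix=MethCORRMatrix(kept_probes, max_per_side=config.max_per_side),
        models=kept_models,
        metadata=metadata,
        rejected=pd.DataFrame(rejected, columns=["gene", "reason"]),
    )


def infer(
    store: ModelStore,
    meth: MethylationMatrix,
) -> tuple[ExpressionMatrix, InferenceReport]:
    """Apply a trained store to a new methylation matrix.

    The matrix may cover only a subset of the store's probes (the EPIC
    case): each gene's MCS is averaged over the probes present, genes below
    the coverage threshold get their MCS imputed from neighbour genes, and
    expression is inferred from the per-gene polynomial models.  Raises
    when fewer than the configured fraction of store probes overlap (a
    platform mismatch rather than a probe subset).
    """
    cfg = store.metadata.get("config", {})
    min_cov = float(cfg.get("min_probe_coverage", 0.5))
    knn_k = int(cfg.get("knn_k", 10))
    min_overlap = float(cfg.get("min_probe_overlap", 0.1))

    genes = store.genes
    if not meth.sample_ids or not genes:
        empty = ExpressionMatrix(genes, list(meth.sample_ids),
                                 np.empty((len(genes), meth.n_samples)))
        return empty, InferenceReport(
            per_sample=pd.DataFrame(
                columns=["sample", "n_genes_inferred", "probe_coverage"]
            ),
            summary={"n_samples": 0, "n_genes": len(genes)},
        )

    store_probes = store.probes
    present = set(meth.probe_ids)
    overlap = sum(p in present for p in store_probes) / len(store_probes)
    if overlap < min_overlap:
        raise ValueError(
            f"platform mismatch: only {overlap:.1%} of the store's "
            f"{len(store_probes)} probes are present in the methylation matrix"
        )

    with _Stage("mcs"):
        mcs = compute_mcs(meth, store.methcorr_matrix, min_probe_coverage=min_cov)
        if np.isnan(mcs.mcs).any():
            mcs = impute_missing_mcs(mcs, k=knn_k)

    with _Stage("predict"):
        irna = np.empty((len(genes), meth.n_samples))
        gene_row = {g: i for i, g in enumerate(mcs.gene_ids)}
        for i, gene in enumerate(genes):
            irna[i] = predict(store.models[gene], mcs.mcs[gene_row[gene]])

    # per-sample coverage: fraction of the store's probe universe observed
    probe_pos = {p: i for i, p in enumerate(meth.probe_ids)}
    rows = [probe_pos[p] for p in store_probes if p in probe_pos]
    observed = ~np.isnan(meth.beta[rows]) if rows else np.zeros((0, meth.n_samples), bool)
    coverage = observed.sum(axis=0) / len(store_probes)
    n_inferred = (~np.isnan(irna)).sum(axis=0)
    report = InferenceReport(
        per_sample=pd.DataFrame(
            {
                "sample": list(meth.sample_ids),
                "n_genes_inferred": n_inferred,
                "probe_coverage": coverage,
            }
        ),
        summary={
            "n_samples": meth.n_samples,
            "n_genes": len(genes),
            "median_probe_coverage": float(np.median(coverage)),
        },
    )
    return ExpressionMatrix(genes, list(meth.sample_ids), irna), report


def evaluate_concordance(
    inferred: ExpressionMatrix,
    observed: ExpressionMatrix,
) -> InferenceReport:
    """Intra-sample concordance between inferred and observed expression.

    For every shared sample, computes R² (squared Pearson correlation over
    the shared genes) and RMSE between inferred and observed values, plus
    cohort medians.
    """
    shared_genes = [g for g in inferred.gene_ids if g in set(observed.gene_ids)]
    shared_samples = [s for s in inferred.sample_ids if s in set(observed.sample_ids)]
    if not shared_genes:
        raise ValueError("no shared genes between inferred and observed matrices")
    if not shared_samples:
        raise ValueError("no shared samples between inferred and observed matrices")

    inf_df = inferred.to_frame().loc[shared_genes, shared_samples]
    obs_df = observed.to_frame().loc[shared_genes, shared_samples]
    from .models import squared_pearson

    rows = []
    for s in shared_samples:
        a = inf_df[s].to_numpy()
        b = obs_df[s].to_numpy()
        ok = ~np.isnan(a) & ~np.isnan(b)
        r2 = squared_pearson(a[ok], b[ok])
        rmse = float(np.sqrt(np.mean((a[ok] - b[ok]) ** 2))) if ok.any() else float("nan")
        rows.append((s, int(ok.sum()), r2, rmse))
    per_sample = pd.DataFrame(rows, columns=["sample", "n_genes", "r2", "rmse"])
    return InferenceReport(
        per_sample=per_sample,
        summary={
            "n_samples": len(shared_samples),
            "n_genes": len(shared_genes),
            "median_r2": float(per_sample["r2"].median()),
            "median_rmse": float(per_sample["rmse"].median()),
        },
    )
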