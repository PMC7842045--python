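"""Per-gene polynomial regression from MethCORR score to expression.

For every gene, ordinary least squares models of the form

    RNA = B0 + B1*MCS + B2*MCS^2 + ... + Bn*MCS^n        (n = 1..4)

are scored by repeated cross-validation (10 repeats of 10 folds by
default).  The best polynomial (degree 2-4 with the lowest mean held-out
RMSE) replaces the simple linear model only when it lowers the linear
model's CV RMSE by at least 5% — most genes are effectively linear in
their MCS and the rule avoids overfitting curvature to noise.  Discovery
R² is the squared Pearson correlation between the cross-validated
out-of-fold predictions and the observed expression (zeroed when the
correlation is negative; see :func:`model_r2`); validation R² is the same
statistic on the held-out validation samples.  A gene is a "MethCORR
gene" when both exceed 0.16.

Fold assignment is keyed to sample identifiers (not array positions), so
reordering samples cannot change any cross-validation result.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np

from .types import GeneModel

__all__ = [
    "fit_gene_model",
    "model_r2",
    "validate_gene_model",
    "predict",
    "squared_pearson",
    "gene_seed",
]

DEGREES = (1, 2, 3, 4)


def squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when either vector is degenerate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r * r)


def model_r2(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Model-performance R²: squared Pearson, but 0 for anticorrelation.

    Cross-validated out-of-fold predictions of an uninformative gene are
    systematically *anti*-correlated with the held-out observations (each
    fold's training mean excludes the fold's own values), and a plain
    square would turn that artifact into a spuriously high R².  A model
    whose predictions decrease when expression increases has no predictive
    value, so negative correlations score 0.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(observed, dtype=float)
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    if not np.isfinite(r) or r <= 0.0:
        return 0.0
    return float(r * r)


def gene_seed(seed: int, gene: str) -> np.random.SeedSequence:
    """Deterministic per-gene seed, stable across gene iteration order."""
    return np.random.SeedSequence([int(seed), zlib.crc32(gene.encode())])


def _fold_labels(sample_ids: list[str], n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold label per position, keyed to sample IDs.

    IDs are sorted before shuffling so that permuting the input order
    permutes the labels identically: each sample keeps its fold.
    """
    order = sorted(range(len(sample_ids)), key=lambda i: sample_ids[i])
    perm = rng.permutation(len(sample_ids))
    labels = np.empty(len(sample_ids), dtype=int)
    # sorted sample j gets fold perm[j] % n_folds -> near-equal fold sizes
    sizes = np.full(n_folds, len(sample_ids) // n_folds)
    sizes[: len(sample_ids) % n_folds] += 1
    fold_of_slot = np.repeat(np.arange(n_folds), sizes)
    for j, i in enumerate(order):
        labels[i] = fold_of_slot[perm[j]]
    return labels


def _polyfit(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """OLS monomial coefficients (B0..B_degree)."""
    V = np.vander(x, N=degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    return coef


def predict(model: GeneModel, mcs: np.ndarray) -> np.ndarray:
    """Evaluate the gene's polynomial at the given MCS values.

    Missing (NaN) scores yield missing predictions; impute scores first if
    complete output is needed.
    """
    x = np.asarray(mcs, dtype=float)
    return np.polynomial.polynomial.polyval(x, np.asarray(model.coefficients))


def fit_gene_model(
    mcs: np.ndarray,
    expr: np.ndarray,
    seed: int | np.random.SeedSequence,
    *,
    sample_ids: list[str] | None = None,
    gene: str = "",
    cv_folds: int = 10,
    cv_repeats: int = 10,
    rmse_improvement: float = 0.05,
    min_fit_samples: int = 30,
) -> GeneModel:
    """Fit and select a polynomial MCS→expression model for one gene.

    Parameters
    ----------
    mcs, expr
        Aligned per-sample vectors over the discovery samples.  Samples
        with missing MCS are ignored.
    seed
        Seeds the repeated-CV fold assignment.
    sample_ids
        Identifiers the fold assignment is keyed to; defaults to the
        positional order.

    Returns a :class:`GeneModel` with ``r2_validation`` unset; pass it to
    :func:`validate_gene_model` to score it on held-out samples.
    """
    x = np.asarray(mcs, dtype=float)
    y = np.asarray(expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("mcs and expr must be aligned 1-D vectors")
    if sample_ids is None:
        sample_ids = [f"{i:06d}" for i in range(len(x))]
    obs = ~np.isnan(x)
    x, y = x[obs], y[obs]
    ids = [s for s, o in zip(sample_ids, obs) if o]
    # canonical sample order: results are bit-identical under permutation
    order = sorted(range(len(ids)), key=ids.__getitem__)
    x, y = x[order], y[order]
    ids = [ids[i] for i in order]
    n = len(x)
    if n < min_fit_samples:
        raise ValueError(f"need >= {min_fit_samples} discovery samples with an MCS, got {n}")

    if np.std(x) == 0.0:
        # constant MCS carries no information: degenerate intercept model
        return GeneModel(
            gene=gene,
            degree=1,
            coefficients=(float(np.mean(y)), 0.0),
            cv_rmse=float(np.std(y)),
            r2_discovery=0.0,
        )

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    repeat_seeds = ss.spawn(cv_repeats)

    max_deg = max(DEGREES)
    V = np.vander(x, N=max_deg + 1, increasing=True)
    fold_rmses = {d: [] for d in DEGREES}
    oof_sum = {d: np.zeros(n) for d in DEGREES}
    for rep_ss in repeat_seeds:
        rng = np.random.default_rng(rep_ss)
        labels = _fold_labels(ids, cv_folds, rng)
        for fold in range(cv_folds):
            test = labels == fold
            if not test.any():
                continue
            train = ~test
            for d in DEGREES:
                coef, *_ = np.linalg.lstsq(V[train, : d + 1], y[train], rcond=None)
                pred = V[test, : d + 1] @ coef
                fold_rmses[d].append(float(np.sqrt(np.mean((pred - y[test]) ** 2))))
                oof_sum[d][test] += pred
    cv_rmse = {d: float(np.mean(fold_rmses[d])) for d in DEGREES}

    poly_degrees = [d for d in DEGREES if d >= 2]
    best_poly = min(poly_degrees, key=lambda d: (cv_rmse[d], d))
    rmse_lin = cv_rmse[1]
    if rmse_lin > 0 and (rmse_lin - cv_rmse[best_poly]) / rmse_lin >= rmse_improvement:
        final_degree = best_poly
    else:
        final_degree = 1

    coef = _polyfit(x, y, final_degree)
    oof_mean = oof_sum[final_degree] / cv_repeats
    return GeneModel(
        gene=gene,
        degree=final_degree,
        coefficients=tuple(float(c) for c in coef),
        cv_rmse=cv_rmse[final_degree],
        r2_discovery=model_r2(oof_mean, y),
    )


def validate_gene_model(
    model: GeneModel,
    mcs_validation: np.ndarray,
    expr_validation: np.ndarray,
    *,
    r2_gate: float = 0.16,
    min_validation_samples: int = 10,
) -> GeneModel:
    """Score a fitted model on independent validation samples.

    Sets ``r2_validation`` (squared Pearson between predicted and observed
    expression) and the MethCORR flag: true iff both discovery and
    validation R² exceed ``r2_gate``.  With fewer than
    ``min_validation_samples`` usable samples the flag is forced false.
    """
    x = np.asarray(mcs_validation, dtype=float)
    y = np.asarray(expr_validation, dtype=float)
    obs = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[obs], y[obs]
    pred = predict(model, x)
    r2_val = model_r2(pred, y) if len(x) >= 2 else 0.0
    flag = model.r2_discovery > r2_gate and r2_val > r2_gate
    if len(x) < min_validation_samples:
        warnings.warn(
            f"gene {model.gene!r}: only {len(x)} validation samples; "
            "MethCORR flag forced false",
            stacklevel=2,
        )
        flag = False
    return GeneModel(
        gene=model.gene,
        degree=model.degree,
        coefficients=model.coefficients,
        cv_rmse=model.cv_rmse,
        r2_discovery=model.r2_discovery,
        r2_validation=r2_val,
        methcorr_flag=flag,
    )
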