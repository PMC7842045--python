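"""Discovery of expression-correlated CpG sites.

The sample cohort is partitioned 40/40/20 into two discovery sets and one
held-out validation set.  Within each discovery set, every (gene, CpG) pair
is screened by Spearman correlation between expression and β-value;
non-significant pairs (two-sided P ≥ 0.01) are discarded.  Candidates that
are significant with a concordant sign in both discovery sets are ranked by
rho within each set and then by the rank-sum across the two sets, and the
top ≤100 positively and ≤100 negatively correlated probes per gene form the
MethCORR matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, MethCORRMatrix, MethylationMatrix, ProbeSets

__all__ = [
    "SplitSpec",
    "split_samples",
    "spearman_screen",
    "combine_rank_sum",
    "select_top_cpgs",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["gene", "probe", "rho", "p", "set_label"]


@dataclass(frozen=True)
class SplitSpec:
    """40/40/20 partition of a cohort into discovery and validation sets."""

    discovery1: tuple[str, ...]
    discovery2: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        all_ids = self.discovery1 + self.discovery2 + self.validation
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split sets are not pairwise disjoint")

    @property
    def discovery(self) -> tuple[str, ...]:
        """Union of both discovery sets (modeling samples)."""
        return self.discovery1 + self.discovery2

    @property
    def n_samples(self) -> int:
        return len(self.discovery1) + len(self.discovery2) + len(self.validation)


def split_samples(sample_ids, seed: int) -> SplitSpec:
    """Randomly partition samples into two 40% discovery sets + 20% validation.

    The assignment is uniform given the seed and independent of the input
    order (IDs are sorted before shuffling), so every downstream statistic
    is invariant to sample permutation.
    """
    ids = sorted(str(s) for s in sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs")
    n = len(ids)
    if n < 15:
        raise ValueError(f"need at least 15 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_d = round(0.4 * n)
    shuffled = [ids[i] for i in perm]
    return SplitSpec(
        discovery1=tuple(shuffled[:n_d]),
        discovery2=tuple(shuffled[n_d : 2 * n_d]),
        validation=tuple(shuffled[2 * n_d :]),
        seed=seed,
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rhos = (rx_c[perms] * ry_c).sum(axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t(n-2) approximation on rho."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def _standardized_ranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise mid-ranks, centred and L2-normalised; flags zero variance."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    ok = norms > 0
    ranks[ok] = ranks[ok] / norms[ok, None]
    return ranks, ok


def _screen_block(
    gene_ids: list[str],
    expr: np.ndarray,
    probe_ids: list[str],
    beta: np.ndarray,
    set_label: int,
    p_threshold: float,
) -> pd.DataFrame:
    """All-pairs Spearman screen on complete (NaN-free) blocks."""
    n = expr.shape[1]
    rg, gene_ok = _standardized_ranks(expr)
    rp, probe_ok = _standardized_ranks(beta)
    for idx in np.nonzero(~gene_ok)[0]:
        logger.debug("set %d: zero-variance expression for %s, skipped", set_label, gene_ids[idx])
    for idx in np.nonzero(~probe_ok)[0]:
        logger.debug("set %d: zero-variance β for %s, skipped", set_label, probe_ids[idx])
    rho = rg[gene_ok] @ rp[probe_ok].T  # Pearson correlation of mid-ranks
    if n >= 10:
        p = _t_approx_p(rho, n)
    else:
        p = np.empty_like(rho)
        rk_g = stats.rankdata(expr[gene_ok], axis=1)
        rk_p = stats.rankdata(beta[probe_ok], axis=1)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                p[i, j] = _exact_spearman_p(rk_g[i], rk_p[j], rho[i, j])
    keep = p < p_threshold
    gi, pj = np.nonzero(keep)
    genes_kept = np.asarray(gene_ids, dtype=object)[gene_ok]
    probes_kept = np.asarray(probe_ids, dtype=object)[probe_ok]
    return pd.DataFrame(
        {
            "gene": genes_kept[gi],
            "probe": probes_kept[pj],
            "rho": np.clip(rho[keep], -1.0, 1.0),
            "p": p[keep],
            "set_label": set_label,
        }
    )


def spearman_screen(
    expr: ExpressionMatrix,
    meth: MethylationMatrix,
    samples,
    set_label: int,
    *,
    p_threshold: float = 0.01,
    min_pair_n: int = 15,
) -> pd.DataFrame:
    """Genome-wide Spearman screen of every (gene, CpG probe) pair.

    Correlations use the samples in ``samples`` where the probe's β-value is
    observed; pairs with fewer than ``min_pair_n`` complete observations or
    with a zero-variance vector are skipped.  Only significant pairs
    (two-sided p < ``p_threshold``) are returned.

    Returns a DataFrame with columns ``gene, probe, rho, p, set_label``.
    """
    samples = [str(s) for s in samples]
    missing = [s for s in samples if s not in expr.sample_ids or s not in meth.sample_ids]
    if missing:
        raise KeyError(f"samples absent from one of the matrices: {missing[:5]}")
    if len(samples) < min_pair_n:
        logger.warning(
            "set %d: only %d samples (< min_pair_n=%d), no pairs screened",
            set_label, len(samples), min_pair_n,
        )
        return pd.DataFrame(columns=RECORD_COLUMNS)
    e = expr.subset_samples(samples)
    m = meth.subset_samples(samples)

    nan_mask = np.isnan(m.beta)
    complete = ~nan_mask.any(axis=1)
    blocks: list[pd.DataFrame] = []
    if complete.any():
        blocks.append(
            _screen_block(
                e.gene_ids,
                e.expr,
                [p for p, c in zip(m.probe_ids, complete) if c],
                m.beta[complete],
                set_label,
                p_threshold,
            )
        )
    # probes with missing β: group by identical missingness pattern so the
    # expression ranks can be recomputed once per pattern
    incomplete_idx = np.nonzero(~complete)[0]
    if incomplete_idx.size:
        patterns: dict[bytes, list[int]] = {}
        for i in incomplete_idx:
            patterns.setdefault(nan_mask[i].tobytes(), []).append(i)
        for key, probe_rows in patterns.items():
            obs = ~np.frombuffer(key, dtype=bool)
            if obs.sum() < min_pair_n:
                logger.debug(
                    "set %d: %d probes with only %d complete observations, skipped",
                    set_label, len(probe_rows), int(obs.sum()),
                )
                continue
            blocks.append(
                _screen_block(
                    e.gene_ids,
                    e.expr[:, obs],
                    [m.probe_ids[i] for i in probe_rows],
                    m.beta[np.ix_(probe_rows, np.nonzero(obs)[0])],
                    set_label,
                    p_threshold,
                )
            )
    if not blocks:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(blocks, ignore_index=True)
    return out[RECORD_COLUMNS]


def combine_rank_sum(records_set1: pd.DataFrame, records_set2: pd.DataFrame) -> pd.DataFrame:
    """Combine the two discovery screens into per-gene ranked candidate lists.

    A candidate must be significant with the same correlation sign in both
    discovery sets.  Within each gene, sign and set, candidates receive
    mid-ranks (rank 1 = strongest: largest rho for positive candidates,
    smallest rho for negative ones); the final order is ascending rank-sum
    across the two sets, ties broken by larger mean \\|rho\\| and then by
    probe ID.

    Returns a DataFrame with columns ``gene, direction, probe, rho_set1,
    rho_set2, rank_set1, rank_set2, ranksum``, sorted in final per-gene,
    per-direction order.
    """
    cols = ["gene", "probe", "rho"]
    r1 = records_set1[cols].rename(columns={"rho": "rho_set1"})
    r2 = records_set2[cols].rename(columns={"rho": "rho_set2"})
    merged = r1.merge(r2, on=["gene", "probe"], how="inner")
    merged = merged[merged["rho_set1"] * merged["rho_set2"] > 0].copy()
    if merged.empty:
        return pd.DataFrame(
            columns=["gene", "direction", "probe", "rho_set1", "rho_set2",
                     "rank_set1", "rank_set2", "ranksum"]
        )
    merged["direction"] = np.where(merged["rho_set1"] > 0, "pos", "neg")
    # rank key: ascending in (-rho) for positive candidates, ascending in rho
    # for negative ones, i.e. strongest correlation first in both cases
    sign = np.where(merged["direction"] == "pos", -1.0, 1.0)
    merged["_key1"] = sign * merged["rho_set1"]
    merged["_key2"] = sign * merged["rho_set2"]
    grp = merged.groupby(["gene", "direction"], sort=False)
    merged["rank_set1"] = grp["_key1"].rank(method="average")
    merged["rank_set2"] = grp["_key2"].rank(method="average")
    merged["ranksum"] = merged["rank_set1"] + merged["rank_set2"]
    merged["_mean_abs_rho"] = (merged["rho_set1"].abs() + merged["rho_set2"].abs()) / 2.0
    merged["_neg_mean_abs"] = -merged["_mean_abs_rho"]
    merged = merged.sort_values(
        ["gene", "direction", "ranksum", "_neg_mean_abs", "probe"],
        kind="mergesort",
    ).reset_index(drop=True)
    return merged[
        ["gene", "direction", "probe", "rho_set1", "rho_set2",
         "rank_set1", "rank_set2", "ranksum"]
    ]


def select_top_cpgs(
    ranked_candidates: pd.DataFrame,
    max_per_side: int = 100,
    *,
    min_cpg_total: int = 10,
) -> MethCORRMatrix:
    """Keep each gene's top ``max_per_side`` probes per correlation sign.

    Genes whose retained positive + negative probes total fewer than
    ``min_cpg_total`` are dropped (and logged): too few CpG sites give an
    unstable MethCORR score.
    """
    genes: dict[str, ProbeSets] = {}
    if len(ranked_candidates):
        top = ranked_candidates.groupby(["gene", "direction"], sort=False).head(max_per_side)
        for gene, sub in top.groupby("gene", sort=False):
            pos = sub.loc[sub["direction"] == "pos", "probe"].tolist()
            neg = sub.loc[sub["direction"] == "neg", "probe"].tolist()
            if len(pos) + len(neg) < min_cpg_total:
                logger.info(
                    "gene %s dropped: %d CpG sites < min_cpg_total=%d",
                    gene, len(pos) + len(neg), min_cpg_total,
                )
                continue
            genes[str(gene)] = ProbeSets(pos, neg)
    return MethCORRMatrix(genes, max_per_side=max_per_side)
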