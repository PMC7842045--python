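"""MethCORR scores: per-gene methylation summaries and their imputation.

The MethCORR score (MCS) of a gene in a sample averages the β-values of
its positively expression-correlated CpG sites together with (1 − β) of
its negatively correlated sites:

    MCS = ( Σ β_pos + Σ (1 − β_neg) ) / (number of available probes)

The denominator adapts to the probes actually observed, which is what
makes the score robust to platform differences (450K vs EPIC probe
subsets) and sporadic missing β-values.  A score is only emitted when at
least ``min_probe_coverage`` of the gene's listed probes are observed;
otherwise it is left missing and later filled in by gene-wise k-nearest-
neighbour imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MethCORRMatrix, MethylationMatrix

__all__ = ["MCSMatrix", "compute_mcs", "impute_missing_mcs"]


@dataclass
class MCSMatrix:
    """MethCORR scores per (gene, sample); values in [0, 1], NaN = missing."""

    gene_ids: list[str]
    sample_ids: list[str]
    mcs: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.mcs = np.asarray(self.mcs, dtype=float)
        if self.mcs.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("mcs shape does not match gene/sample IDs")
        vals = self.mcs[~np.isnan(self.mcs)]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("MCS values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mcs, index=self.gene_ids, columns=self.sample_ids)

    def select(self, gene: str) -> np.ndarray:
        return self.mcs[self.gene_ids.index(gene)]


def compute_mcs(
    meth: MethylationMatrix,
    matrix: MethCORRMatrix,
    *,
    min_probe_coverage: float = 0.5,
) -> MCSMatrix:
    """Compute the MethCORR score for every (gene, sample).

    Probes listed for a gene but absent from ``meth`` (or with a missing
    β-value in a sample) simply drop out of the average.  When fewer than
    ``min_probe_coverage`` of the gene's listed probes contribute in a
    sample, that score is set to missing instead.
    """
    probe_pos = {p: i for i, p in enumerate(meth.probe_ids)}
    n_samples = meth.n_samples
    genes = list(matrix.genes)
    scores = np.full((len(genes), n_samples), np.nan)
    for gi, gene in enumerate(genes):
        sets = matrix.genes[gene]
        n_listed = sets.n_probes
        if n_listed == 0:
            raise ValueError(f"gene {gene} has no CpG probes in the MethCORR matrix")
        ip = [probe_pos[p] for p in sets.pos if p in probe_pos]
        im = [probe_pos[p] for p in sets.neg if p in probe_pos]
        contrib = np.full((len(ip) + len(im), n_samples), np.nan)
        if ip:
            contrib[: len(ip)] = meth.beta[ip]
        if im:
            contrib[len(ip) :] = 1.0 - meth.beta[im]
        available = (~np.isnan(contrib)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nansum(contrib, axis=0) / np.where(available > 0, available, 1)
        ok = available / n_listed >= min_probe_coverage
        scores[gi, ok & (available > 0)] = mean[ok & (available > 0)]
    return MCSMatrix(genes, list(meth.sample_ids), scores)


def _gene_knn_distances(values: np.ndarray, g: int) -> np.ndarray:
    """Euclidean distance from gene ``g`` to every gene, computed over the
    samples where both genes are observed; NaN when there is no overlap."""
    diff = values - values[g]
    obs = ~np.isnan(diff)
    n_obs = obs.sum(axis=1)
    sq = np.where(obs, diff, 0.0) ** 2
    with np.errstate(invalid="ignore"):
        d = np.sqrt(sq.sum(axis=1))
    d[n_obs == 0] = np.nan
    return d


def impute_missing_mcs(mcs: MCSMatrix, k: int = 10) -> MCSMatrix:
    """Fill missing MethCORR scores by gene-wise kNN averaging.

    For a missing (gene g, sample s), the neighbours are the ``k`` genes
    closest to g in Euclidean distance over mutually observed samples that
    are themselves observed in s; the imputed value is their mean in s,
    clipped to [0, 1].  Requires every sample to have at least half of its
    genes observed.
    """
    values = mcs.mcs.copy()
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return MCSMatrix(list(mcs.gene_ids), list(mcs.sample_ids), values)

    frac_missing = nan_mask.mean(axis=0)
    bad = np.nonzero(frac_missing > 0.5)[0]
    if bad.size:
        raise ValueError(
            f"samples with more than 50% missing MCSs cannot be imputed: "
            f"{[mcs.sample_ids[j] for j in bad[:5]]}"
        )

    original = mcs.mcs  # neighbour search uses pre-imputation values only
    for g in np.nonzero(nan_mask.any(axis=1))[0]:
        d = _gene_knn_distances(original, g)
        d[g] = np.nan
        for s in np.nonzero(nan_mask[g])[0]:
            eligible = ~np.isnan(d) & ~np.isnan(original[:, s])
            idx = np.nonzero(eligible)[0]
            if idx.size == 0:
                raise ValueError(
                    f"no neighbour genes available to impute gene "
                    f"{mcs.gene_ids[g]!r} in sample {mcs.sample_ids[s]!r}"
                )
            if idx.size < k:
                warnings.warn(
                    f"only {idx.size} neighbour genes available for "
                    f"{mcs.gene_ids[g]!r} (k={k}); using all of them",
                    stacklevel=2,
                )
                chosen = idx
            else:
                # stable nearest-k: sort by distance, then gene index
                order = np.lexsort((idx, d[idx]))
                chosen = idx[order[:k]]
            values[g, s] = float(np.clip(original[chosen, s].mean(), 0.0, 1.0))
    return MCSMatrix(list(mcs.gene_ids), list(mcs.sample_ids), values)
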