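"""Core in-memory containers for methylation-based expression inference.

Matrices are thin wrappers around a numpy array plus ordered row/column
identifiers.  β-values live in [0, 1] with NaN for missing entries;
expression values are continuous (typically log2(FPKM+1)) and must be
finite.  The trained artifact is a :class:`ModelStore`: the per-gene CpG
probe lists plus the per-gene regression models and training metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ExpressionMatrix",
    "ProbeSets",
    "MethCORRMatrix",
    "GeneModel",
    "ModelStore",
]


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class MethylationMatrix:
    """β-values per (CpG probe, sample); NaN marks a missing measurement."""

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray  # shape (n_probes, n_samples), float, NaN = missing

    def __post_init__(self) -> None:
        self.probe_ids = _check_unique(self.probe_ids, "probe IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        vals = self.beta[~np.isnan(self.beta)]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("β-values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MethylationMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        sample_ids = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MethylationMatrix(list(self.probe_ids), sample_ids, self.beta[:, idx])


@dataclass
class ExpressionMatrix:
    """Continuous expression per (gene, sample) on a log scale; no missing."""

    gene_ids: list[str]
    sample_ids: list[str]
    expr: np.ndarray  # shape (n_genes, n_samples), float, finite

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        self.expr = np.asarray(self.expr, dtype=float)
        if self.expr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expr shape {self.expr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.expr.size and not np.isfinite(self.expr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), sample_ids, self.expr[:, idx])


@dataclass
class ProbeSets:
    """Ordered CpG probe lists for one gene, strongest correlation first."""

    pos: list[str]
    neg: list[str]

    def __post_init__(self) -> None:
        if set(self.pos) & set(self.neg):
            raise ValueError("positive and negative probe lists overlap")

    @property
    def n_probes(self) -> int:
        return len(self.pos) + len(self.neg)


@dataclass
class MethCORRMatrix:
    """Per-gene lists of the top expression-correlated CpG sites.

    Each gene maps to at most ``max_per_side`` positively and
    ``max_per_side`` negatively correlated probes (≤200 in total with the
    default of 100 per side), ordered by combined rank across the two
    discovery sets.
    """

    genes: dict[str, ProbeSets]
    max_per_side: int = 100

    def __post_init__(self) -> None:
        for gene, sets in self.genes.items():
            if len(sets.pos) > self.max_per_side or len(sets.neg) > self.max_per_side:
                raise ValueError(
                    f"gene {gene}: more than {self.max_per_side} probes on one side"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            sets = self.genes[gene]
            for direction, probes in (("pos", sets.pos), ("neg", sets.neg)):
                for rank, probe in enumerate(probes, start=1):
                    rows.append((gene, direction, rank, probe))
        return pd.DataFrame(rows, columns=["gene", "direction", "rank", "probe"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, max_per_side: int = 100) -> "MethCORRMatrix":
        genes: dict[str, ProbeSets] = {}
        for gene, sub in df.groupby("gene", sort=False):
            pos = sub[sub["direction"] == "pos"].sort_values("rank")["probe"].tolist()
            neg = sub[sub["direction"] == "neg"].sort_values("rank")["probe"].tolist()
            genes[str(gene)] = ProbeSets([str(p) for p in pos], [str(p) for p in neg])
        return cls(genes, max_per_side=max_per_side)


@dataclass
class GeneModel:
    """Polynomial regression model mapping MCS to expression for one gene.

    ``coefficients`` are the monomial coefficients (B0, B1, ..., B_degree)
    so predicted expression is ``sum(B_k * MCS**k)``.  ``methcorr_flag`` is
    true iff the model clears R² > 0.16 in both the cross-validated
    discovery fit and the independent validation set.
    """

    gene: str
    degree: int
    coefficients: tuple[float, ...]
    cv_rmse: float
    r2_discovery: float
    r2_validation: float | None = None
    methcorr_flag: bool = False

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3, 4):
            raise ValueError(f"degree must be 1-4, got {self.degree}")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError(
                f"expected {self.degree + 1} coefficients, got {len(self.coefficients)}"
            )
        if self.cv_rmse < 0:
            raise ValueError("cv_rmse must be non-negative")


@dataclass
class ModelStore:
    """Serializable training artifact: CpG lists + gene models + metadata.

    ``rejected`` is an audit sidecar listing genes excluded from the store
    and why (too few CpG sites, R² gate failures); it is not needed for
    inference.
    """

    methcorr_matrix: MethCORRMatrix
    models: dict[str, GeneModel]
    metadata: dict
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reason"])
    )

    def __post_init__(self) -> None:
        matrix_genes = set(self.methcorr_matrix.genes)
        model_genes = set(self.models)
        if matrix_genes != model_genes:
            missing = sorted(matrix_genes ^ model_genes)
            raise ValueError(
                f"model and CpG tables list different genes (e.g. {missing[:5]})"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.models)

    @property
    def probes(self) -> list[str]:
        seen: dict[str, None] = {}
        for sets in self.methcorr_matrix.genes.values():
            for p in sets.pos:
                seen.setdefault(p)
            for p in sets.neg:
                seen.setdefault(p)
        return list(seen)
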