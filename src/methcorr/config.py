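"""Training/inference configuration with the published defaults.

Every threshold that the method prints is the default here: the P < 0.01
Spearman screen, ≤100 CpG sites per correlation sign, the R² > 0.16
MethCORR-gene gate, the ≥5% relative RMSE-decrease rule for accepting a
polynomial over the linear model, and 10 repeats of 10-fold
cross-validation.  The remaining knobs (minimum pairwise observations,
minimum CpG count per gene, MCS probe-coverage fraction, kNN imputation
neighbours) are implementation parameters the method leaves open.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["MethcorrConfig"]


@dataclass
class MethcorrConfig:
    seed: int = 0
    #: two-sided p-value threshold for the per-set Spearman screen
    p_threshold: float = 0.01
    #: maximum CpG sites kept per correlation sign per gene
    max_per_side: int = 100
    #: squared-correlation gate a gene must clear in discovery AND validation
    r2_gate: float = 0.16
    #: minimum relative CV-RMSE decrease for a polynomial to beat linear
    rmse_improvement: float = 0.05
    #: cross-validation layout
    cv_folds: int = 10
    cv_repeats: int = 10
    #: minimum complete (expression, β) observations for one correlation
    min_pair_n: int = 15
    #: genes with fewer selected CpG sites in total are dropped
    min_cpg_total: int = 10
    #: fraction of a gene's listed probes that must be observed for an MCS
    min_probe_coverage: float = 0.5
    #: neighbour genes used for kNN imputation of missing MCSs
    knn_k: int = 10
    #: minimum shared samples to train at all
    min_train_samples: int = 50
    #: minimum discovery samples with an observed MCS to fit one gene
    min_fit_samples: int = 30
    #: minimum validation samples for a trustworthy validation R²
    min_validation_samples: int = 10
    #: minimum fraction of store probes present in a new methylation matrix
    min_probe_overlap: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.max_per_side < 1:
            raise ValueError("max_per_side must be positive")
        if not 0 < self.min_probe_coverage <= 1:
            raise ValueError("min_probe_coverage must be in (0, 1]")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("cross-validation needs >= 2 folds and >= 1 repeat")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MethcorrConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
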