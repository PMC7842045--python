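"""Readers and writers for matrices and the trained model store.

Matrices travel as plain tab-separated tables (first column = row IDs,
first row = sample IDs).  Methylation tables may also arrive in the GEO
series-matrix dialect: ``!``-prefixed header lines with the numeric table
enclosed by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
markers.

A trained :class:`~methcorr.types.ModelStore` is a directory of three
diff-able text files (``cpg_sites.tsv``, ``models.tsv``, ``metadata.yaml``)
plus an optional ``rejected_genes.tsv`` audit table.  Floats are written
with 17 significant digits, so save/load round-trips every IEEE double
bit-for-bit and inference is stable across serialization.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneModel,
    MethCORRMatrix,
    MethylationMatrix,
    ModelStore,
)

__all__ = [
    "NA_TOKENS",
    "read_matrix",
    "write_methylation_matrix",
    "write_expression_matrix",
    "write_model_store",
    "read_model_store",
]

#: tokens accepted as "missing" in methylation input (XENA and GEO exports)
NA_TOKENS = frozenset({"NA", "NaN", "null", ""})

#: on-disk layout version of the model store
STORE_FORMAT_VERSION = "1"

_SERIES_BEGIN = "!series_matrix_table_begin"
_SERIES_END = "!series_matrix_table_end"


def _fmt(x: float) -> str:
    """17-significant-digit decimal text; round-trips any finite double."""
    return format(float(x), ".17g")


def _parse_cell(token: str, *, where: str) -> float:
    token = token.strip().strip('"')
    if token in NA_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric cell {token!r} at {where}") from None


def _read_table_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    lines = text.splitlines()
    if any(ln.startswith("!") for ln in lines[:1]):
        # GEO series-matrix dialect: keep only the delimited table body
        try:
            start = next(i for i, ln in enumerate(lines) if ln.strip().lower() == _SERIES_BEGIN)
            end = next(i for i, ln in enumerate(lines) if ln.strip().lower() == _SERIES_END)
        except StopIteration:
            raise ValueError(
                f"{path}: '!'-style header found but no "
                f"{_SERIES_BEGIN}/{_SERIES_END} markers"
            ) from None
        lines = lines[start + 1 : end]
    return [ln for ln in lines if ln.strip()]


def read_matrix(path: str | Path, kind: str) -> MethylationMatrix | ExpressionMatrix:
    """Read a methylation or expression matrix from a TSV file.

    Parameters
    ----------
    path
        Tab-separated table; row IDs in the first column, sample IDs in the
        first row.  For ``kind="methylation"`` the GEO series-matrix dialect
        is also accepted.
    kind
        ``"methylation"`` (β-values in [0, 1], NA tokens become missing) or
        ``"expression"`` (finite values required; an NA token is an error).
    """
    if kind not in ("methylation", "expression"):
        raise ValueError(f"kind must be 'methylation' or 'expression', got {kind!r}")
    lines = _read_table_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty table")
    header = [t.strip().strip('"') for t in lines[0].split("\t")]
    sample_ids = header[1:]
    row_ids: list[str] = []
    values = np.empty((len(lines) - 1, len(sample_ids)), dtype=float)
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split("\t")
        if len(parts) != len(sample_ids) + 1:
            raise ValueError(
                f"{path}: line {i + 1} has {len(parts)} fields, expected "
                f"{len(sample_ids) + 1}"
            )
        rid = parts[0].strip().strip('"')
        row_ids.append(rid)
        for j, token in enumerate(parts[1:]):
            values[i - 1, j] = _parse_cell(token, where=f"row {rid!r}, column {sample_ids[j]!r}")
    if kind == "methylation":
        return MethylationMatrix(row_ids, sample_ids, values)
    if values.size and np.isnan(values).any():
        bad = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value for gene {row_ids[bad[0]]!r}, "
            f"sample {sample_ids[bad[1]]!r}; expression input must be complete"
        )
    return ExpressionMatrix(row_ids, sample_ids, values)


def _write_matrix(ids: list[str], sample_ids: list[str], values: np.ndarray,
                  path: str | Path, id_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(id_label + "".join("\t" + s for s in sample_ids) + "\n")
        for rid, row in zip(ids, values):
            cells = "".join(
                "\tNA" if math.isnan(v) else "\t" + _fmt(v) for v in row
            )
            fh.write(rid + cells + "\n")


def write_methylation_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    _write_matrix(matrix.probe_ids, matrix.sample_ids, matrix.beta, path, "probe")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    _write_matrix(matrix.gene_ids, matrix.sample_ids, matrix.expr, path, "gene")


# ---------------------------------------------------------------------------
# model store
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = [
    "gene", "degree", "b0", "b1", "b2", "b3", "b4",
    "cv_rmse", "r2_discovery", "r2_validation", "methcorr_flag",
]


def write_model_store(store: ModelStore, dir: str | Path) -> None:
    """Write a model store to ``dir`` (created if needed)."""
    import yaml

    from . import __version__

    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)

    cpg = store.methcorr_matrix.to_frame()
    cpg.to_csv(out / "cpg_sites.tsv", sep="\t", index=False)

    with open(out / "models.tsv", "w") as fh:
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for model in store.models.values():
            coefs = list(model.coefficients) + [None] * (4 - model.degree)
            row = [
                model.gene,
                str(model.degree),
                *("" if c is None else _fmt(c) for c in coefs),
                _fmt(model.cv_rmse),
                _fmt(model.r2_discovery),
                "" if model.r2_validation is None else _fmt(model.r2_validation),
                "true" if model.methcorr_flag else "false",
            ]
            fh.write("\t".join(row) + "\n")

    metadata = dict(store.metadata)
    metadata.setdefault("software_version", __version__)
    metadata["format_version"] = STORE_FORMAT_VERSION
    metadata["max_per_side"] = store.methcorr_matrix.max_per_side
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)

    store.rejected.to_csv(out / "rejected_genes.tsv", sep="\t", index=False)


def read_model_store(dir: str | Path) -> ModelStore:
    """Read a model store written by :func:`write_model_store`."""
    import yaml

    src = Path(dir)
    for required in ("cpg_sites.tsv", "models.tsv", "metadata.yaml"):
        if not (src / required).exists():
            raise FileNotFoundError(f"model store at {src} is missing {required}")

    with open(src / "metadata.yaml") as fh:
        metadata = yaml.safe_load(fh) or {}
    found = str(metadata.get("format_version"))
    if found != STORE_FORMAT_VERSION:
        raise ValueError(
            f"model store format version mismatch: store has {found!r}, "
            f"this software reads {STORE_FORMAT_VERSION!r}"
        )
    metadata.pop("format_version", None)
    max_per_side = int(metadata.pop("max_per_side", 100))

    cpg = pd.read_csv(src / "cpg_sites.tsv", sep="\t", dtype={"gene": str, "probe": str})
    matrix = MethCORRMatrix.from_frame(cpg, max_per_side=max_per_side) if len(cpg) else \
        MethCORRMatrix({}, max_per_side=max_per_side)

    models: dict[str, GeneModel] = {}
    with open(src / "models.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MODEL_COLUMNS:
            raise ValueError(f"unexpected models.tsv columns: {header}")
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            rec = dict(zip(_MODEL_COLUMNS, parts))
            degree = int(rec["degree"])
            coefs = tuple(float(rec[f"b{k}"]) for k in range(degree + 1))
            models[rec["gene"]] = GeneModel(
                gene=rec["gene"],
                degree=degree,
                coefficients=coefs,
                cv_rmse=float(rec["cv_rmse"]),
                r2_discovery=float(rec["r2_discovery"]),
                r2_validation=None if rec["r2_validation"] == "" else float(rec["r2_validation"]),
                methcorr_flag=rec["methcorr_flag"] == "true",
            )

    rejected_path = src / "rejected_genes.tsv"
    if rejected_path.exists():
        rejected = pd.read_csv(rejected_path, sep="\t", dtype=str)
        if rejected.empty:
            rejected = pd.DataFrame(columns=["gene", "reason"])
    else:
        rejected = pd.DataFrame(columns=["gene", "reason"])

    return ModelStore(matrix, models, metadata, rejected)
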