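"""Tabular input/output and normalization for the eQTL pipeline.

All tables are plain UTF-8 TSV files with a header row; the first column is
the row identifier.  In-memory containers are plain :class:`pandas.DataFrame`
objects with a fixed layout:

* **marker map** — index ``marker``, columns ``chromosome`` (str) and
  ``position_bp`` (int, 1-based); sorted by (chromosome, position).
* **genotype matrix** — index line/sample id, one column per marker, values
  ``A``/``B`` (homozygous RIL alleles) or missing (``NA``).
* **expression matrix** — index gene id, one column per sample, float log2
  intensities.
* **gene annotation** — index ``gene``, columns ``chromosome``, ``start_bp``,
  ``end_bp``.

Files written by the pipeline may carry leading ``#`` comment lines (version
and configuration hash); all readers skip them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENOTYPE_CODES = {"A": -1.0, "B": 1.0}

__all__ = [
    "DataValidationError",
    "read_marker_map",
    "read_genotypes",
    "read_expression",
    "read_gene_annotation",
    "write_table",
    "encode_genotypes",
    "quantile_normalize",
    "log2_transform",
    "validate_marker_map",
    "validate_genotypes",
    "validate_expression",
    "validate_gene_annotation",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the format contract."""


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicated row identifiers: {dups[:5]}")
    return df


def validate_marker_map(mmap: pd.DataFrame) -> pd.DataFrame:
    missing = {"chromosome", "position_bp"} - set(mmap.columns)
    if missing:
        raise DataValidationError(f"marker map missing columns: {sorted(missing)}")
    if mmap.index.has_duplicates:
        raise DataValidationError("duplicated marker names")
    if (mmap["position_bp"] < 0).any():
        raise DataValidationError("negative marker positions")
    out = mmap.copy()
    out["chromosome"] = out["chromosome"].astype(str)
    out["position_bp"] = out["position_bp"].astype(np.int64)
    return out.sort_values(["chromosome", "position_bp"], kind="stable")


def read_marker_map(path) -> pd.DataFrame:
    mmap = _read_tsv(path)
    mmap.index.name = "marker"
    return validate_marker_map(mmap)


def validate_genotypes(geno: pd.DataFrame, marker_map: pd.DataFrame | None = None) -> pd.DataFrame:
    codes = set(pd.unique(geno.values.ravel()))
    bad = {c for c in codes if not (pd.isna(c) or c in GENOTYPE_CODES)}
    if bad:
        raise DataValidationError(
            f"unknown genotype codes {sorted(map(str, bad))}; RILs are homozygous (A/B/NA)"
        )
    if marker_map is not None:
        if set(geno.columns) != set(marker_map.index):
            raise DataValidationError("genotype markers do not match the marker map")
        geno = geno.loc[:, marker_map.index]  # map order
    return geno


def read_genotypes(path, marker_map: pd.DataFrame | None = None) -> pd.DataFrame:
    geno = _read_tsv(path)
    geno.index.name = "line"
    return validate_genotypes(geno, marker_map)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        raise DataValidationError("duplicated gene identifiers")
    return expr.astype(float)


def read_expression(path) -> pd.DataFrame:
    expr = _read_tsv(path)
    expr.index.name = "gene"
    return validate_expression(expr)


def validate_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    missing = {"chromosome", "start_bp", "end_bp"} - set(genes.columns)
    if missing:
        raise DataValidationError(f"gene annotation missing columns: {sorted(missing)}")
    if genes.index.has_duplicates:
        raise DataValidationError("duplicated gene identifiers")
    if (genes["start_bp"] > genes["end_bp"]).any():
        raise DataValidationError("gene start_bp > end_bp")
    out = genes.copy()
    out["chromosome"] = out["chromosome"].astype(str)
    out["start_bp"] = out["start_bp"].astype(np.int64)
    out["end_bp"] = out["end_bp"].astype(np.int64)
    return out


def read_gene_annotation(path) -> pd.DataFrame:
    genes = _read_tsv(path)
    genes.index.name = "gene"
    return validate_gene_annotation(genes)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a TSV, optionally preceded by a ``#`` comment header line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep="NA")


def encode_genotypes(geno: pd.DataFrame) -> np.ndarray:
    """A/B genotype codes to a float matrix: A -> -1, B -> +1, missing -> NaN."""
    arr = geno.to_numpy(dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "A"] = -1.0
    out[arr == "B"] = 1.0
    return out


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column is mapped onto the vector of per-rank column means (the
    limma ``normalizeQuantiles`` convention): tied values receive the mean of
    the normalized values of their tied ranks.

    Parameters
    ----------
    expr : DataFrame, genes x samples, no missing values, >= 2 samples.
    """
    if expr.shape[1] < 2:
        raise DataValidationError("quantile normalization needs >= 2 samples")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataValidationError("missing values not supported in quantile normalization")
    n = values.shape[0]
    ref = np.sort(values, axis=0).mean(axis=1)
    from scipy.stats import rankdata

    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        # interpolation at half-ranks == mean of the two tied positions
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def log2_transform(expr: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise ``log2(value + offset)``; rejects non-positive arguments."""
    shifted = expr.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        raise DataValidationError("log2 transform requires all values + offset > 0")
    return pd.DataFrame(np.log2(shifted), index=expr.index, columns=expr.columns)
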