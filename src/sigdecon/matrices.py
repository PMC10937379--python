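"""Core matrix containers and elementary spectrum operations.

Three typed wrappers around dense numpy arrays carry the data through the
pipeline:

* :class:`CountMatrix` — nonnegative integer mutation counts X (p channels
  by n samples), with a :class:`~sigdecon.schemas.ChannelSchema`.
* :class:`SignatureMatrix` — column-stochastic spectra W (p by r); each
  column is a probability distribution over channels.
* :class:`ExposureMatrix` — nonnegative activities H (r signatures by
  n samples).

All matrices are dense: p <= ~100 channels and cohorts of at most a few
thousand samples make sparsity pointless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schemas import ChannelSchema, SchemaError, infer_schema


class MatrixValidationError(ValueError):
    """Raised when a matrix violates its type's invariants."""


_NORM_TOL = 0.01  # accept signature columns within 1% of unit sum (file rounding)
_COLSUM_TOL = 1e-8


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise MatrixValidationError(f"duplicate {what} ids")
    return ids


@dataclass
class CountMatrix:
    """Mutation count matrix X (channels x samples)."""

    schema: ChannelSchema
    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != self.schema.size:
            raise MatrixValidationError(
                f"count matrix must be {self.schema.size} x n, got {v.shape}"
            )
        if v.shape[1] < 1:
            raise MatrixValidationError("count matrix needs at least one sample")
        if np.any(v < 0):
            raise MatrixValidationError("negative entry in count matrix")
        if not np.allclose(v, np.round(v)):
            raise MatrixValidationError("non-integral entry in count matrix")
        self.values = np.asarray(np.round(v), dtype=float)
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != v.shape[1]:
            raise MatrixValidationError("sample_ids length does not match n")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.schema.labels), columns=list(self.sample_ids)
        )


@dataclass
class SignatureMatrix:
    """Signature spectra W (channels x signatures); columns sum to one."""

    schema: ChannelSchema
    values: np.ndarray
    signature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != self.schema.size:
            raise MatrixValidationError(
                f"signature matrix must be {self.schema.size} x r, got {v.shape}"
            )
        if np.any(v < 0):
            raise MatrixValidationError("negative entry in signature matrix")
        sums = v.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _NORM_TOL):
            bad = np.where(np.abs(sums - 1.0) > _NORM_TOL)[0]
            raise MatrixValidationError(
                f"signature column(s) {bad.tolist()} not normalized (sum off by >1%)"
            )
        self.values = v / sums  # exact L1 normalization internally
        self.signature_ids = _check_unique(self.signature_ids, "signature")
        if len(self.signature_ids) != v.shape[1]:
            raise MatrixValidationError("signature_ids length does not match r")

    @property
    def n_signatures(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.schema.labels), columns=list(self.signature_ids)
        )

    def subset(self, ids) -> "SignatureMatrix":
        ids = list(ids)
        pos = {s: j for j, s in enumerate(self.signature_ids)}
        cols = [pos[i] for i in ids]
        return SignatureMatrix(self.schema, self.values[:, cols], tuple(ids))


@dataclass
class ExposureMatrix:
    """Signature activities H (signatures x samples)."""

    values: np.ndarray
    signature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise MatrixValidationError("exposure matrix must be 2-D")
        if np.any(v < 0):
            raise MatrixValidationError("negative entry in exposure matrix")
        self.values = v
        self.signature_ids = _check_unique(self.signature_ids, "signature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if v.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise MatrixValidationError("exposure matrix shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.signature_ids), columns=list(self.sample_ids)
        )


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two spectra; in [0, 1] for nonnegative input.

    Cosine distance is defined as ``1 - cosine_similarity``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between columns of A and columns of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return np.clip(1.0 - An.T @ Bn, 0.0, 2.0)


def l1_normalize_columns(M) -> np.ndarray:
    """Scale each column of a nonnegative matrix to unit sum."""
    M = np.asarray(M, dtype=float)
    sums = M.sum(axis=0)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise ValueError(f"cannot normalize all-zero column(s) {zero.tolist()}")
    return M / sums


# ---------------------------------------------------------------------------
# TSV I/O.  Dialect: tab-separated, UTF-8, header row of column ids, first
# column of row labels.  COSMIC signature files (channels x signatures) read
# directly; channel rows are canonicalized to schema order on read.
# ---------------------------------------------------------------------------


def read_matrix(path, kind: str, schema: ChannelSchema | None = None):
    """Read a counts / signatures / exposures TSV into its typed container.

    For counts and signatures the row labels must form a known channel schema
    (or match the ``schema`` argument); rows are reordered to canonical schema
    order. Signature columns are L1-normalized if within 1% of unit sum.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise MatrixValidationError(f"duplicate row or column ids in {path}")
    if kind == "exposures":
        return ExposureMatrix(
            df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns))
        )
    if kind not in ("counts", "signatures"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    labels = [str(x) for x in df.index]
    if schema is None:
        schema = infer_schema(labels)
    elif set(labels) != set(schema.labels):
        raise SchemaError(f"row labels of {path} do not match schema {schema.name}")
    df = df.loc[list(schema.labels)]
    vals = df.to_numpy(dtype=float)
    ids = tuple(map(str, df.columns))
    if kind == "counts":
        return CountMatrix(schema, vals, ids)
    return SignatureMatrix(schema, vals, ids)


def write_matrix(matrix, path) -> None:
    """Write any typed matrix as TSV (10 significant digits, lossless round-trip)."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.10g")
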