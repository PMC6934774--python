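"""Connectivity-matrix I/O, prevalence-based edge filtering and confound removal.

The preparation stage mirrors common practice for FA-weighted structural
connectomes: edges are kept only if present in more than a threshold fraction
of the healthy reference group (group-consensus mask), and age/sex effects
are removed from each retained edge by ordinary least squares, re-centred at
the covariate means so the FA scale is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthcohort import ConnectivityMatrix, SubjectRecord

__all__ = [
    "EdgeMask",
    "MatrixFormatError",
    "MatrixLabelError",
    "MatrixAsymmetryError",
    "MatrixValueError",
    "ConfoundError",
    "read_matrix",
    "write_matrix",
    "prevalence_mask",
    "apply_mask",
    "regress_confounds",
    "covariates_from_subjects",
]


class MatrixFormatError(ValueError):
    """File is not a parseable square matrix TSV."""


class MatrixLabelError(ValueError):
    """Row and column node labels disagree."""


class MatrixAsymmetryError(ValueError):
    """Matrix is asymmetric beyond tolerance."""


class MatrixValueError(ValueError):
    """Weights outside [0, 1] or nonzero diagonal."""


class ConfoundError(ValueError):
    """Degenerate covariate design."""


@dataclass
class EdgeMask:
    """Retained/dropped indicator over unordered node pairs (upper triangle)."""

    n_nodes: int
    retained: np.ndarray  # boolean, length n_nodes*(n_nodes-1)//2

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        expect = self.n_nodes * (self.n_nodes - 1) // 2
        if self.retained.shape != (expect,):
            raise ValueError(
                f"mask length {self.retained.size} != {expect} pairs for "
                f"{self.n_nodes} nodes"
            )

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def indicator(self) -> np.ndarray:
        """Full symmetric 0/1 matrix with zero diagonal."""
        n = self.n_nodes
        ind = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        ind[iu, ju] = self.retained
        return ind + ind.T

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        df = pd.DataFrame(
            {"i": iu[self.retained], "j": ju[self.retained]}
        )
        with open(path, "w") as fh:
            fh.write(f"# n_nodes={self.n_nodes}\n")
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EdgeMask":
        n_nodes = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# n_nodes="):
                    n_nodes = int(line.strip().split("=", 1)[1])
                if not line.startswith("#"):
                    break
        if n_nodes is None:
            raise MatrixFormatError(f"{path}: missing '# n_nodes=' header")
        df = pd.read_csv(path, sep="\t", comment="#")
        iu, ju = np.triu_indices(n_nodes, k=1)
        flat = np.zeros(iu.size, dtype=bool)
        pos = {(a, b): k for k, (a, b) in enumerate(zip(iu, ju))}
        for a, b in zip(df["i"], df["j"]):
            a, b = int(min(a, b)), int(max(a, b))
            flat[pos[(a, b)]] = True
        return cls(n_nodes, flat)


# -- matrix I/O -------------------------------------------------------------


def write_matrix(
    matrix: ConnectivityMatrix, path, header_comment: str | None = None
) -> None:
    """Write a matrix as TSV with node labels on both axes."""
    df = pd.DataFrame(
        matrix.weights, index=matrix.node_labels, columns=matrix.node_labels
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_matrix(path, atol: float = 1e-8) -> ConnectivityMatrix:
    """Read and validate a matrix TSV (leading ``#`` comment lines allowed)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MatrixFormatError(f"{path}: cannot parse matrix TSV: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise MatrixLabelError(f"{path}: row and column labels differ")
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entries: {exc}") from exc
    if not np.allclose(w, w.T, atol=atol):
        raise MatrixAsymmetryError(f"{path}: asymmetry beyond {atol}")
    if np.any(np.diag(w) != 0):
        raise MatrixValueError(f"{path}: nonzero diagonal")
    if np.any(w < 0) or np.any(w > 1):
        raise MatrixValueError(f"{path}: weights outside [0, 1]")
    sid = str(path).rsplit("/", 1)[-1].removesuffix(".tsv")
    return ConnectivityMatrix(sid, row_labels, w)


# -- prevalence filter ------------------------------------------------------


def prevalence_mask(
    hv_matrices: Sequence[ConnectivityMatrix],
    threshold: float = 0.6,
    presence_eps: float = 0.0,
) -> EdgeMask:
    """Group-consensus edge mask from the healthy reference group.

    A node pair is retained iff the fraction of HV subjects in which the edge
    is present (weight strictly greater than ``presence_eps``) is strictly
    greater than ``threshold``.
    """
    if len(hv_matrices) == 0:
        raise ValueError("prevalence_mask requires at least one HV matrix")
    labels = hv_matrices[0].node_labels
    n = hv_matrices[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    counts = np.zeros(iu.size)
    for mat in hv_matrices:
        if mat.node_labels != labels:
            raise MatrixLabelError(
                f"{mat.subject_id}: node labels differ across HV matrices"
            )
        counts += mat.weights[iu, ju] > presence_eps
    retained = counts / len(hv_matrices) > threshold
    return EdgeMask(n, retained)


def apply_mask(matrix: ConnectivityMatrix, mask: EdgeMask) -> ConnectivityMatrix:
    """Zero out every non-retained pair; retained pairs pass unchanged."""
    if matrix.n_nodes != mask.n_nodes:
        raise ValueError(
            f"matrix has {matrix.n_nodes} nodes, mask {mask.n_nodes}"
        )
    w = matrix.weights * mask.indicator()
    return ConnectivityMatrix(matrix.subject_id, list(matrix.node_labels), w)


# -- confound regression ----------------------------------------------------


def covariates_from_subjects(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Age/sex covariate table aligned to subject order (sex coded F=1, M=0)."""
    return pd.DataFrame(
        {
            "age": [s.age for s in subjects],
            "sex": [1.0 if s.sex == "F" else 0.0 for s in subjects],
        },
        index=[s.subject_id for s in subjects],
    )


def regress_confounds(
    matrices: Sequence[ConnectivityMatrix], covariates: pd.DataFrame
) -> list[ConnectivityMatrix]:
    """Remove linear age/sex effects from each edge across subjects.

    For every edge that is nonzero in at least one subject, fits OLS
    ``weight ~ 1 + age + sex`` pooling all subjects, and replaces each weight
    with its residual plus the fitted value at the covariate means. This
    preserves the edge-wise mean (and hence the FA scale); results are clipped
    to [0, 1]. Edges that are zero in every subject stay exactly zero.
    """
    n_subj = len(matrices)
    if n_subj != len(covariates):
        raise ValueError("need exactly one covariate row per matrix")
    if n_subj < 4:
        raise ValueError("confound regression requires at least 4 subjects")
    for col in ("age", "sex"):
        if col not in covariates.columns:
            raise ConfoundError(f"covariate table lacks column '{col}'")
        if np.ptp(covariates[col].to_numpy(dtype=float)) == 0:
            raise ConfoundError(
                f"covariate '{col}' is constant: design is rank-deficient"
            )

    labels = matrices[0].node_labels
    n = matrices[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    W = np.stack([m.weights[iu, ju] for m in matrices])  # subjects x edges

    X = covariates[["age", "sex"]].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)  # centred: fitted value at means == intercept
    design = np.column_stack([np.ones(n_subj), Xc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfoundError("covariate design is rank-deficient")

    active = np.any(W != 0, axis=0)
    beta, *_ = np.linalg.lstsq(design, W[:, active], rcond=None)
    adjusted = W.copy()
    # subtract only the covariate part; the intercept is the edge-wise mean
    adjusted[:, active] = W[:, active] - Xc @ beta[1:, :]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    adjusted[:, ~active] = 0.0

    out = []
    for k, mat in enumerate(matrices):
        full = np.zeros((n, n))
        full[iu, ju] = adjusted[k]
        full += full.T
        out.append(ConnectivityMatrix(mat.subject_id, list(labels), full))
    return out
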