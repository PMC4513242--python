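"""Connectivity-matrix data model, file I/O, normalization and vectorization.

A structural connectome is represented as a symmetric, zero-diagonal,
nonnegative square matrix whose entry (i, j) weights the connection between
brain regions i and j (typically a streamline count from tractography).
Cohorts are stacked into a three-way tensor whose first mode indexes
subjects; that tensor is the input to the HO-SVD feature-reduction step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_LABELS = ("AD", "MCI", "NC")

#: Relative tolerance below which small numeric asymmetry (e.g. from text
#: round-tripping) is silently repaired by averaging; larger asymmetry is an
#: error because it signals an upstream bug rather than print noise.
ASYMMETRY_RTOL = 1e-8


class MatrixFormatError(ValueError):
    """Raised when a connectivity-matrix file is not a square numeric matrix."""


class MatrixValidationError(ValueError):
    """Raised when a parsed matrix violates the connectome invariants."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric, zero-diagonal, nonnegative edge-weight matrix."""

    weights: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        _validate_square(w)
        if w.shape[0] < 2:
            raise MatrixValidationError("connectivity matrix needs at least 2 nodes")
        if np.any(w < 0):
            i, j = np.unravel_index(int(np.argmin(w)), w.shape)
            raise MatrixValidationError(
                f"negative entry {w[i, j]:g} at ({i}, {j}); connectivity weights must be >= 0"
            )
        _check_symmetry(w)
        object.__setattr__(self, "weights", _symmetrize(w))
        if self.node_labels is not None and len(self.node_labels) != w.shape[0]:
            raise MatrixValidationError("node_labels length must equal node count")

    @property
    def node_count(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class AdjustedMatrix:
    """A residualized (confound-adjusted) network; entries may be negative."""

    residuals: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.residuals, dtype=float)
        _validate_square(r)
        _check_symmetry(r)
        object.__setattr__(self, "residuals", _symmetrize(r))

    @property
    def node_count(self) -> int:
        return self.residuals.shape[0]


@dataclass(frozen=True)
class PhenotypeRecord:
    """Subject id, diagnostic label (AD / MCI / NC), age in years, sex (M/F)."""

    subject_id: str
    label: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label {self.label!r} not in {VALID_LABELS}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex {self.sex!r} must be 'M' or 'F'")
        if not self.age > 0:
            raise ValueError("age must be positive (years)")


@dataclass
class CohortTensor:
    """n subjects x p x p array with aligned phenotype records.

    Mode 1 (axis 0) is the sample mode; every slice ``data[i]`` is symmetric
    with zero diagonal.  ``adjusted`` marks confound-residualized cohorts,
    whose entries may be negative.
    """

    data: np.ndarray
    phenotypes: list[PhenotypeRecord]
    adjusted: bool = False
    node_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError(f"cohort tensor must be n x p x p, got {self.data.shape}")
        if len(self.phenotypes) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.phenotypes)} phenotype records for {self.data.shape[0]} matrices"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def node_count(self) -> int:
        return self.data.shape[1]

    @property
    def mode_sizes(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.phenotypes])

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.phenotypes], dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.phenotypes])

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.phenotypes],
                "label": [r.label for r in self.phenotypes],
                "age": [r.age for r in self.phenotypes],
                "sex": [r.sex for r in self.phenotypes],
            }
        )


def _validate_square(w: np.ndarray) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MatrixFormatError(f"expected a square matrix, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise MatrixValidationError("matrix contains non-finite entries")


def _check_symmetry(w: np.ndarray) -> None:
    scale = float(np.max(np.abs(w))) if w.size else 0.0
    asym = np.abs(w - w.T)
    worst = float(asym.max()) if asym.size else 0.0
    if scale > 0 and worst > ASYMMETRY_RTOL * scale:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise MatrixValidationError(
            f"matrix asymmetric beyond tolerance: |w[{i},{j}] - w[{j},{i}]| = {worst:g} "
            f"(max entry {scale:g})"
        )


def _symmetrize(w: np.ndarray) -> np.ndarray:
    out = 0.5 * (w + w.T)
    np.fill_diagonal(out, 0.0)
    return out


def read_connectivity_matrix(
    path: str | Path, delimiter: str | None = None
) -> ConnectivityMatrix:
    """Read one subject's matrix from a delimited text file.

    The delimiter is auto-detected (comma vs. whitespace) unless given. An
    optional first line of non-numeric tokens is taken as node labels.
    Small numeric asymmetry (<= 1e-8 relative) is repaired by averaging;
    anything larger is an error naming the worst cell.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "," if "," in lines[0] else None  # None = any whitespace
    labels: tuple[str, ...] | None = None
    first = lines[0].split(delimiter)
    if not _all_numeric(first):
        labels = tuple(tok.strip() for tok in first)
        lines = lines[1:]
    rows = []
    for ln in lines:
        toks = ln.split(delimiter)
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: non-numeric entry: {exc}") from None
    lengths = {len(r) for r in rows}
    if len(lengths) != 1 or len(rows) != lengths.pop():
        raise MatrixFormatError(
            f"{path}: not a square matrix ({len(rows)} rows, widths {sorted({len(r) for r in rows})})"
        )
    return ConnectivityMatrix(np.array(rows, dtype=float), node_labels=labels)


def write_connectivity_matrix(
    m: ConnectivityMatrix | AdjustedMatrix | np.ndarray, path: str | Path
) -> None:
    """Write a matrix as whitespace-delimited text with 17 significant digits."""
    w = m if isinstance(m, np.ndarray) else getattr(m, "weights", None)
    if w is None:
        w = m.residuals  # type: ignore[union-attr]
    np.savetxt(path, np.asarray(w, dtype=float), fmt="%.17g")


def _all_numeric(tokens: Sequence[str]) -> bool:
    try:
        for t in tokens:
            float(t)
    except ValueError:
        return False
    return True


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype CSV/TSV with columns subject_id, label, age, sex."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = {"subject_id", "label", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return [
        PhenotypeRecord(str(r.subject_id), str(r.label), float(r.age), str(r.sex))
        for r in df.itertuples()
    ]


def normalize_by_max(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every entry by the matrix's maximum entry.

    Puts subjects with different tractography scales onto a common [0, 1]
    range.  An all-zero matrix (degenerate subject) passes through unchanged
    with a warning rather than erroring, so batch runs survive.
    """
    top = float(m.weights.max())
    if top == 0.0:
        warnings.warn("all-zero connectivity matrix; normalize_by_max is a no-op")
        return m
    return ConnectivityMatrix(m.weights / top, node_labels=m.node_labels)


def stack_cohort(
    matrices: Sequence[ConnectivityMatrix | np.ndarray],
    phenotypes: Sequence[PhenotypeRecord],
) -> CohortTensor:
    """Stack per-subject matrices into an n x p x p tensor, order preserved."""
    if len(matrices) != len(phenotypes):
        raise ValueError(
            f"{len(matrices)} matrices but {len(phenotypes)} phenotype records"
        )
    arrays = [
        m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
        for m in matrices
    ]
    sizes = {a.shape for a in arrays}
    if len(sizes) > 1:
        raise ValueError(f"matrices disagree on node count: {sorted(sizes)}")
    labels = next(
        (m.node_labels for m in matrices if isinstance(m, ConnectivityMatrix) and m.node_labels),
        None,
    )
    return CohortTensor(np.stack(arrays), list(phenotypes), node_labels=labels)


def load_cohort(matrix_dir: str | Path, phenotype_path: str | Path) -> CohortTensor:
    """Load a cohort from a directory of ``<subject_id>.txt`` matrix files.

    Subjects are taken in phenotype-table order; every listed subject must
    have a matrix file.
    """
    matrix_dir = Path(matrix_dir)
    phenotypes = read_phenotypes(phenotype_path)
    matrices = []
    for rec in phenotypes:
        candidates = [matrix_dir / f"{rec.subject_id}{ext}" for ext in (".txt", ".csv", ".tsv")]
        found = next((c for c in candidates if c.exists()), None)
        if found is None:
            raise FileNotFoundError(f"no matrix file for subject {rec.subject_id} in {matrix_dir}")
        matrices.append(read_connectivity_matrix(found))
    return stack_cohort(matrices, phenotypes)


def save_cohort(t: CohortTensor, out_dir: str | Path) -> None:
    """Serialize a cohort as matrix text files plus ``phenotypes.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(t.phenotypes):
        np.savetxt(out_dir / f"{rec.subject_id}.txt", t.data[i], fmt="%.17g")
    t.phenotype_frame().to_csv(out_dir / "phenotypes.csv", index=False)


def vectorize_upper_triangle(m: ConnectivityMatrix | AdjustedMatrix | np.ndarray) -> np.ndarray:
    """Stack the strict upper triangle row-major: entries (i, j), i < j.

    For p nodes the result has length p(p-1)/2 (6328 for the 113-region
    atlas).  The ordering (i ascending, then j) is fixed so features are
    reproducible across runs and implementations.
    """
    w = _as_array(m)
    p = w.shape[0]
    iu = np.triu_indices(p, k=1)
    return w[iu]


def matrix_from_upper_triangle(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    v = np.asarray(v, dtype=float)
    if v.size != p * (p - 1) // 2:
        raise ValueError(f"vector length {v.size} != p(p-1)/2 for p={p}")
    out = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    out[iu] = v
    return out + out.T


def _as_array(m: ConnectivityMatrix | AdjustedMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return m.weights
    if isinstance(m, AdjustedMatrix):
        return m.residuals
    a = np.asarray(m, dtype=float)
    _validate_square(a)
    return a
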