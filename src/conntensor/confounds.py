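"""Linear-model residualization of age and sex effects.

Confounds are removed across subjects by ordinary least squares on the
design [1, age, sex] (a Gaussian identity-link GLM): each edge weight, or
each global network measure, is replaced by its residual y - X @ beta_hat.
Residuals are exactly orthogonal to the design columns, so downstream group
contrasts cannot be driven by age or sex imbalance between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from conntensor.data import CohortTensor, matrix_from_upper_triangle, vectorize_upper_triangle


@dataclass(frozen=True)
class CovariateDesign:
    """Design matrix [intercept, age (years), sex indicator (M=1, F=0)]."""

    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        sex = np.asarray(self.sex, dtype=float)
        if age.ndim != 1 or sex.shape != age.shape:
            raise ValueError("age and sex must be 1-D vectors of equal length")
        if age.size < 4:
            raise ValueError("need at least 4 subjects to fit a 3-column design")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "sex", sex)

    @classmethod
    def from_cohort(cls, t: CohortTensor) -> "CovariateDesign":
        return cls(age=t.ages, sex=(t.sexes == "M").astype(float))

    @property
    def n(self) -> int:
        return self.age.size

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self.age, self.sex])

    def hat_complement(self) -> np.ndarray:
        """Return I - X pinv(X), the residual-maker (annihilator) matrix.

        Uses the pseudoinverse so a rank-deficient design (all ages equal,
        or a single-sex cohort) still yields well-defined residuals; such
        designs trigger a warning.
        """
        X = self.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("rank-deficient covariate design; using pseudoinverse")
        return np.eye(self.n) - X @ np.linalg.pinv(X)


def residualize(y: np.ndarray, design: CovariateDesign) -> np.ndarray:
    """Return y - X @ beta_hat with beta_hat the OLS fit on [1, age, sex]."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n:
        raise ValueError(f"y has {y.shape[0]} rows but design has {design.n}")
    return design.hat_complement() @ y


def adjust_cohort(t: CohortTensor, design: CovariateDesign | None = None) -> CohortTensor:
    """Residualize every edge of a cohort tensor against age and sex.

    Each unordered edge (i < j) is treated as an n-vector across subjects,
    residualized, and written back symmetrically; the diagonal stays zero.
    The result is flagged ``adjusted`` because entries may be negative.
    """
    if design is None:
        design = CovariateDesign.from_cohort(t)
    edges = np.stack([vectorize_upper_triangle(t.data[i]) for i in range(t.n_subjects)])
    resid = residualize(edges, design)  # annihilator applied to all edges at once
    p = t.node_count
    adjusted = np.stack([matrix_from_upper_triangle(resid[i], p) for i in range(t.n_subjects)])
    return CohortTensor(adjusted, list(t.phenotypes), adjusted=True, node_labels=t.node_labels)


def adjust_metrics(metric_table: np.ndarray, design: CovariateDesign) -> np.ndarray:
    """Residualize each column of an n x k table of global network measures."""
    table = np.atleast_2d(np.asarray(metric_table, dtype=float))
    return residualize(table, design)
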