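"""Higher-order SVD, mode-wise truncation, and the three feature extractors.

The HO-SVD (Tucker form) of an N-way tensor X writes

    X = S x_1 U(1) x_2 U(2) ... x_N U(N)

where each factor U(k) is the orthogonal matrix of left singular vectors of
the mode-k unfolding of X, and the core S = X x_1 U(1)^T ... x_N U(N)^T is
all-orthogonal with mode-k subtensor norms (the k-mode singular values)
in descending order.  Truncating the trailing indices of each feature mode
and multiplying the truncated core back along the sample mode only yields a
reduced subjects x R2 x R3 tensor whose per-subject slices are the HO-SVD
features.

Conventions fixed here for reproducibility:

* mode-k unfolding orders the remaining modes cyclically k+1, ..., N, 1,
  ..., k-1 (any fixed convention yields identical singular values);
* each singular vector's sign is flipped so its largest-magnitude component
  is positive, ties broken by the first index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from conntensor.data import CohortTensor, vectorize_upper_triangle


def _cyclic_axes(ndim: int, mode: int) -> list[int]:
    return [mode] + [(mode + 1 + i) % ndim for i in range(ndim - 1)]


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k unfolding: mode-k fibers become columns of an I_k x prod(I_j) matrix."""
    t = np.asarray(t)
    if not 0 <= mode < t.ndim:
        raise ValueError(f"mode {mode} invalid for a {t.ndim}-way tensor")
    return np.transpose(t, _cyclic_axes(t.ndim, mode)).reshape(t.shape[mode], -1)


def fold(m: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    shape = tuple(shape)
    axes = _cyclic_axes(len(shape), mode)
    permuted_shape = [shape[a] for a in axes]
    inverse = np.argsort(axes)
    return np.transpose(np.asarray(m).reshape(permuted_shape), inverse)


def mode_multiply(t: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k product t x_k matrix (matrix rows index the new mode size)."""
    t = np.asarray(t)
    out = np.tensordot(matrix, t, axes=([1], [mode]))
    # tensordot puts the new axis first; move it back to `mode`
    return np.moveaxis(out, 0, mode)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip singular-vector signs so each column's largest-|.| entry is positive.

    Ties on magnitude are broken by the first (lowest) index, making the
    factor matrices — and hence all extracted features — deterministic.
    """
    u = u.copy()
    for j in range(u.shape[1]):
        col = u[:, j]
        idx = int(np.argmax(np.abs(col)))  # argmax takes the first index on ties
        if col[idx] < 0:
            u[:, j] = -col
    return u


@dataclass(frozen=True)
class HosvdResult:
    """Factors U(k), k-mode singular values, and the all-orthogonal core."""

    factors: tuple[np.ndarray, ...]
    mode_singular_values: tuple[np.ndarray, ...]
    core: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.core.shape

    def reconstruct(self) -> np.ndarray:
        out = self.core
        for k, u in enumerate(self.factors):
            out = mode_multiply(out, u, k)
        return out


def hosvd(t: np.ndarray) -> HosvdResult:
    """Full higher-order SVD of an N-way tensor.

    Each factor is the left singular matrix of the corresponding unfolding;
    the core is the tensor multiplied by every factor transpose.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor contains non-finite entries")
    factors: list[np.ndarray] = []
    singvals: list[np.ndarray] = []
    for k in range(t.ndim):
        unf = unfold(t, k)
        u, s, _ = np.linalg.svd(unf, full_matrices=True)
        factors.append(_fix_signs(u))
        sv = np.zeros(t.shape[k])
        sv[: s.size] = s
        singvals.append(sv)
    core = t
    for k, u in enumerate(factors):
        core = mode_multiply(core, u.T, k)
    return HosvdResult(tuple(factors), tuple(singvals), core)


@dataclass(frozen=True)
class TruncationSpec:
    """Per-mode ranks (R_1, ..., R_N); the sample mode is normally kept full."""

    ranks: tuple[int, ...]

    def validate(self, shape: tuple[int, ...]) -> None:
        if len(self.ranks) != len(shape):
            raise ValueError(f"{len(self.ranks)} ranks for a {len(shape)}-way tensor")
        for r, size in zip(self.ranks, shape):
            if not 1 <= r <= size:
                raise ValueError(f"rank {r} out of range [1, {size}]")


def reduce_tensor(
    t: np.ndarray, spec: TruncationSpec, decomposition: HosvdResult | None = None
) -> tuple[np.ndarray, HosvdResult]:
    """Truncate the HO-SVD core and map back along the sample mode only.

    Keeping the leading R_k indices of the core per mode and multiplying by
    the (truncated) mode-1 factor yields a reduced tensor of size
    R_1 x R_2 x ... x R_N expressed in the original sample basis — for a
    cohort, one R_2 x R_3 matrix per subject.
    """
    t = np.asarray(t, dtype=float)
    spec.validate(t.shape)
    result = decomposition if decomposition is not None else hosvd(t)
    core_trunc = result.core[tuple(slice(0, r) for r in spec.ranks)]
    u1 = result.factors[0][:, : spec.ranks[0]]
    reduced = mode_multiply(core_trunc, u1, 0)
    return reduced, result


@dataclass
class FeatureMatrix:
    """n x m feature matrix (rows aligned with cohort phenotypes)."""

    values: np.ndarray
    method: Literal["raw", "svd", "hosvd"]
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def extract_raw(t: CohortTensor) -> FeatureMatrix:
    """Upper-triangle vectorization: n x p(p-1)/2 features (6328 for p=113)."""
    values = np.stack([vectorize_upper_triangle(t.data[i]) for i in range(t.n_subjects)])
    return FeatureMatrix(values, "raw", [r.subject_id for r in t.phenotypes])


def extract_svd(t: CohortTensor, k: int = 15) -> FeatureMatrix:
    """PCA scores of the raw feature matrix: top-k components after centering.

    The raw n x p(p-1)/2 matrix is column-centered and projected onto its
    top-k right singular directions (equivalently, principal components of
    the edge features).  Component signs follow the deterministic
    largest-entry-positive rule.
    """
    raw = extract_raw(t).values
    max_k = min(raw.shape)
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} out of range [1, {max_k}]")
    centered = raw - raw.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = _fix_signs(vt.T)[:, :k]
    return FeatureMatrix(centered @ v, "svd", [r.subject_id for r in t.phenotypes])


def extract_hosvd(t: CohortTensor, k: int = 15, center: bool = False) -> FeatureMatrix:
    """HO-SVD features: each subject's k x k reduced slice, stacked row-major.

    The cohort tensor is decomposed with the sample mode kept full and both
    region modes truncated to rank k, giving m = k^2 features per subject.
    ``center`` optionally removes the mean matrix across subjects first
    (off by default; the raw tensor is decomposed as-is).
    """
    if not 1 <= k <= t.node_count:
        raise ValueError(f"k={k} out of range [1, {t.node_count}]")
    data = t.data
    if center:
        data = data - data.mean(axis=0, keepdims=True)
    spec = TruncationSpec((t.n_subjects, k, k))
    reduced, _ = reduce_tensor(data, spec)
    values = reduced.reshape(t.n_subjects, k * k)
    return FeatureMatrix(values, "hosvd", [r.subject_id for r in t.phenotypes])
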