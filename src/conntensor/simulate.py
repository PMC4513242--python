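"""Synthetic connectome cohorts with planted, known ground truth.

Every subject's matrix is built as

    W = | M + group_shift + age_slope * (age - mean age) + sex_offset * sex + noise |

where M is a shared symmetric nonnegative low-rank mean structure (so that
tensor truncation genuinely concentrates signal), the group shift adds an
ordered effect NC < MCI < AD of delta * noise_sd on a chosen set of edges,
and the noise is i.i.d. Gaussian.  The absolute value keeps weights
nonnegative without creating a point mass at zero; the diagonal is zeroed
and each matrix max-normalized, mirroring how real fiber-count networks are
preprocessed.

By default the effect edges form a *block* — all edges among a small node
subset — which makes the group contrast low-rank; ``effect_pattern="random"``
scatters them uniformly instead (a sparse contrast that favours edge-wise
methods).  Group sizes default to the 39 / 112 / 51 (AD / MCI / NC) split of
a typical elderly diffusion-MRI cohort; ages are uniform on 60-85 years and
sex is Bernoulli(1/2) unless per-group age ranges are given (to construct
deliberate age confounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from conntensor.data import CohortTensor, PhenotypeRecord

GROUP_ORDER = ("NC", "MCI", "AD")
#: Ordered severity levels driving the planted effect magnitude per group.
GROUP_LEVEL = {"NC": 0.0, "MCI": 0.5, "AD": 1.0}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a simulated cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AD": 39, "MCI": 112, "NC": 51}
    )
    p: int = 113
    base_rank: int = 5
    effect_edges: int = 20
    effect_size: float = 1.0  # delta, in units of noise_sd
    effect_pattern: Literal["block", "random"] = "block"
    age_slope: float = 0.0  # per-year additive edge effect
    sex_offset: float = 0.0
    noise_sd: float = 0.1  # relative to the max-normalized mean structure
    age_range: tuple[float, float] = (60.0, 85.0)
    age_range_by_group: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if unknown := set(self.n_per_group) - set(GROUP_ORDER):
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        if self.p < 2 or self.base_rank < 1:
            raise ValueError("p >= 2 and base_rank >= 1 required")
        max_edges = self.p * (self.p - 1) // 2
        if not 0 <= self.effect_edges <= max_edges:
            raise ValueError(f"effect_edges must be in [0, {max_edges}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortTruth:
    """Planted effect edges and the per-group mean on each of them."""

    effect_edges: tuple[tuple[int, int], ...]
    group_edge_means: dict[str, np.ndarray]  # label -> mean value per effect edge
    mean_structure: np.ndarray  # the shared M


def _effect_edge_set(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    if spec.effect_pattern == "random":
        all_edges = [(i, j) for i in range(spec.p) for j in range(i + 1, spec.p)]
        idx = rng.choice(len(all_edges), size=spec.effect_edges, replace=False)
        return [all_edges[k] for k in sorted(idx)]
    # block: smallest node subset whose clique holds effect_edges edges
    q = 2
    while q * (q - 1) // 2 < spec.effect_edges:
        q += 1
    nodes = np.sort(rng.choice(spec.p, size=q, replace=False))
    clique = [(int(a), int(b)) for ai, a in enumerate(nodes) for b in nodes[ai + 1:]]
    return clique[: spec.effect_edges]


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTensor, CohortTruth]:
    """Draw one cohort; a fixed spec (including seed) is bitwise reproducible."""
    rng = np.random.default_rng(spec.seed)
    p = spec.p

    # shared symmetric nonnegative low-rank mean, scaled to max 1
    A = np.abs(rng.normal(size=(p, spec.base_rank))) / np.sqrt(spec.base_rank)
    M = A @ A.T
    np.fill_diagonal(M, 0.0)
    M /= M.max()

    edges = _effect_edge_set(spec, rng)
    shift_template = np.zeros((p, p))
    for i, j in edges:
        shift_template[i, j] = shift_template[j, i] = spec.effect_size * spec.noise_sd

    labels: list[str] = []
    for g in GROUP_ORDER:
        labels += [g] * spec.n_per_group.get(g, 0)
    n = len(labels)

    ages = np.empty(n)
    for idx, g in enumerate(labels):
        lo, hi = (spec.age_range_by_group or {}).get(g, spec.age_range)
        ages[idx] = rng.uniform(lo, hi)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    mean_age = ages.mean()

    data = np.empty((n, p, p))
    iu = np.triu_indices(p, k=1)
    for idx, g in enumerate(labels):
        w = M + GROUP_LEVEL[g] * shift_template
        w = w + spec.age_slope * (ages[idx] - mean_age) + spec.sex_offset * (sexes[idx] == "M")
        noise = np.zeros((p, p))
        noise[iu] = rng.normal(scale=spec.noise_sd, size=iu[0].size)
        noise = noise + noise.T
        w = np.abs(w + noise)
        np.fill_diagonal(w, 0.0)
        top = w.max()
        if top > 0:
            w /= top
        data[idx] = w

    phenotypes = [
        PhenotypeRecord(f"S{idx:04d}", labels[idx], float(ages[idx]), str(sexes[idx]))
        for idx in range(n)
    ]
    group_edge_means = {
        g: np.array([M[i, j] + GROUP_LEVEL[g] * shift_template[i, j] for i, j in edges])
        for g in GROUP_ORDER
    }
    truth = CohortTruth(tuple(edges), group_edge_means, M)
    return CohortTensor(data, phenotypes), truth


def worked_fixture() -> tuple[CohortTensor, CohortTruth]:
    """Tiny deterministic cohort (n=12, p=6) for unit tests and documentation."""
    spec = SyntheticSpec(
        n_per_group={"AD": 4, "MCI": 4, "NC": 4},
        p=6,
        base_rank=2,
        effect_edges=3,
        effect_size=2.0,
        noise_sd=0.1,
        seed=7,
    )
    return generate_cohort(spec)
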