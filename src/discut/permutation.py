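"""Permutation null: relabeled datasets and their recomputed attributes.

The FDR estimator needs the distribution of every attribute under the
no-signal hypothesis.  It is obtained by reassigning the condition
labels (preserving group sizes) and re-running the full attribute
pipeline on each relabeling — never by shuffling the original statistic
vector, which would not capture the attributes' joint null behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .attributes import build_attribute_matrix
from .dataset import ExpressionDataset

__all__ = ["PermutationNull", "generate_permutations", "attributes_on_permutations"]


@dataclass
class PermutationNull:
    """B permuted label vectors and their recomputed M x K attribute matrices."""

    permuted_labels: list[np.ndarray]
    perm_stats: list[np.ndarray]  # B matrices, M x K each
    seed: int | None = None
    purpose: str = "search"
    exhaustive: bool = False
    settings: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return len(self.permuted_labels)

    def stacked(self) -> np.ndarray:
        """All permutation attribute matrices as a (B, M, K) array."""
        return np.stack(self.perm_stats, axis=0)


def _n_assignments(n: int, n2: int) -> int:
    return math.comb(n, n2)


def generate_permutations(labels: np.ndarray, B: int, seed: int) -> list[np.ndarray]:
    """Draw B group-size-preserving relabelings, excluding the original.

    Label vectors are sampled without replacement from the C(N, n2)
    distinct assignments of samples to groups.  When B or more covers
    every distinct non-identity assignment, all of them are returned
    (exhaustive mode) and the effective B is the returned length.
    Complementary assignments (a plain group swap) count as distinct.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    labels = np.asarray(labels)
    values = sorted(np.unique(labels).tolist())
    if len(values) != 2:
        raise ValueError("labels must take exactly two values")
    mask = labels == values[1]
    n = labels.size
    n2 = int(mask.sum())
    if n2 == 0 or n2 == n:
        raise ValueError("both groups must be non-empty")
    total = _n_assignments(n, n2)
    if total - 1 < 2:
        raise ValueError("too few distinct relabelings for a permutation null")

    identity = frozenset(np.flatnonzero(mask).tolist())

    def build(idx_set) -> np.ndarray:
        out = np.full(n, values[0], dtype=labels.dtype)
        out[list(idx_set)] = values[1]
        return out

    if total - 1 <= B:
        # exhaustive: every distinct non-identity assignment
        return [
            build(c)
            for c in combinations(range(n), n2)
            if frozenset(c) != identity
        ]

    rng = np.random.default_rng(seed)
    chosen: list[frozenset] = []
    seen = {identity}
    while len(chosen) < B:
        c = frozenset(rng.choice(n, size=n2, replace=False).tolist())
        if c not in seen:
            seen.add(c)
            chosen.append(c)
    return [build(c) for c in chosen]


def attributes_on_permutations(
    data: ExpressionDataset,
    perms: list[np.ndarray],
    spec,
    seed: int | None = None,
    purpose: str = "search",
) -> PermutationNull:
    """Re-run the attribute pipeline on each permuted label vector.

    Every extractor is refit from scratch per permutation (voom weights,
    SAM fudge factor, NB dispersions, ...), with the same spec and
    settings as the original run.
    """
    import warnings

    stats = []
    for labels in perms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            am = build_attribute_matrix(data.with_labels(labels), spec)
        stats.append(am.stats)
    return PermutationNull(
        permuted_labels=[np.asarray(p) for p in perms],
        perm_stats=stats,
        seed=seed,
        purpose=purpose,
        exhaustive=len(perms) == _n_assignments(*_sizes(data)) - 1,
        settings={"spec": spec},
    )


def _sizes(data: ExpressionDataset) -> tuple[int, int]:
    n1, n2 = data.group_sizes
    return n1 + n2, n2
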