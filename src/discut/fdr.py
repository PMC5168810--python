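"""Non-parametric permutation FDR estimator for a discriminant function.

For a fixed discriminant f with values d_i on the original data and
d*_{i,b} on B permuted datasets, the estimator composes three pieces:

* P(D_f > 0 | NULL)  ~  (median over b of #{d*_{i,b} > 0}) / M
* P(NULL)            ~  #{d_i <= d_lambda} / ((1 - lambda) M), truncated
                        at 1, where d_lambda is the lambda-quantile of
                        the pooled permutation values
* P(D_f > 0 | R > 0) ~  (r v 1) / M, with r = #{d_i > 0}

giving

    FDR_hat = #{d_i <= d_lambda} * E_b(#{d* > 0}) / ((1-lambda) (r v 1) M)

This is the classic Storey-style pi0-corrected permutation estimator,
applied to discriminant values instead of a single statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscriminantModel",
    "FdrEstimate",
    "discriminant_values",
    "estimate_p_pos_null",
    "estimate_d_lambda",
    "estimate_p_null",
    "estimate_fdr",
]


@dataclass
class DiscriminantModel:
    """Linear discriminant f(s) = sum_k w_k s_k - tau.

    Weights satisfy the L1 constraint sum |w_k| = 1 with all w_k >= 0
    for an up-regulation model and all w_k <= 0 for a down-regulation
    model; features with f(s) > 0 (strictly) are called.
    """

    weights: np.ndarray
    tau: float
    direction: str = "up"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ValueError("weights must be a non-empty vector")
        if abs(np.abs(self.weights).sum() - 1.0) > 1e-9:
            raise ValueError("weights must satisfy sum |w_k| = 1")
        if self.direction == "up":
            if np.any(self.weights < 0):
                raise ValueError("up-regulation model requires w_k >= 0")
        elif self.direction == "down":
            if np.any(self.weights > 0):
                raise ValueError("down-regulation model requires w_k <= 0")
        else:
            raise ValueError("direction must be 'up' or 'down'")
        self.tau = float(self.tau)


@dataclass
class FdrEstimate:
    """One FDR estimate with its intermediate quantities."""

    fdr_hat: float
    r: int
    p_null_hat: float
    p_pos_null_hat: float
    d_lambda: float
    lam: float
    e_b_mode: str
    p_null_floored: bool = False


def discriminant_values(stats: np.ndarray, model: DiscriminantModel) -> np.ndarray:
    """d_i = sum_k w_k s_i^(k) - tau for every feature."""
    stats = np.asarray(stats, dtype=float)
    if stats.ndim != 2 or stats.shape[1] != model.weights.size:
        raise ValueError("stats must be M x K with K matching the model")
    if not np.all(np.isfinite(stats)):
        i = int(np.flatnonzero(~np.isfinite(stats).all(axis=1))[0])
        raise ValueError(f"non-finite statistic at feature index {i}")
    return stats @ model.weights - model.tau


def _e_b(counts: np.ndarray, e_b_mode: str) -> float:
    if e_b_mode == "median":
        return float(np.median(counts))
    if e_b_mode == "mean":
        return float(np.mean(counts))
    raise ValueError("e_b_mode must be 'median' or 'mean'")


def estimate_p_pos_null(perm_d: list[np.ndarray], e_b_mode: str = "median") -> float:
    """Expected fraction of null features with positive discriminant value."""
    if len(perm_d) < 1:
        raise ValueError("need at least one permutation")
    m = len(perm_d[0])
    counts = np.array([int((np.asarray(d) > 0).sum()) for d in perm_d])
    return _e_b(counts, e_b_mode) / m


def estimate_d_lambda(pooled_perm_d: np.ndarray, lam: float = 0.5) -> float:
    """lambda-quantile (lower interpolation) of the pooled permutation values."""
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    pooled = np.asarray(pooled_perm_d, dtype=float).ravel()
    if pooled.size == 0:
        raise ValueError("pooled permutation set is empty")
    return float(np.quantile(pooled, lam, method="lower"))


def _n_le(d: np.ndarray, d_lambda: float) -> tuple[int, bool]:
    n = int((np.asarray(d) <= d_lambda).sum())
    floored = n == 0
    return (1 if floored else n), floored


def estimate_p_null(d: np.ndarray, d_lambda: float, lam: float = 0.5) -> float:
    """Conservative pi0 estimate #{d_i <= d_lambda} / ((1-lambda) M), truncated at 1.

    A vacuous numerator (no d_i at or below d_lambda) is floored at one
    count so the estimator cannot certify FDR = 0 from it.
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    d = np.asarray(d, dtype=float)
    n_le, _ = _n_le(d, d_lambda)
    return min(n_le / ((1.0 - lam) * d.size), 1.0)


def estimate_fdr(
    d: np.ndarray,
    perm_d: list[np.ndarray],
    lam: float = 0.5,
    e_b_mode: str = "median",
) -> FdrEstimate:
    """Full FDR estimate for one discriminant value configuration.

    ``d`` are the M original discriminant values; ``perm_d`` the B
    permutation value vectors of the same f.  The estimate is clipped
    to [0, 1] for reporting.
    """
    d = np.asarray(d, dtype=float)
    m = d.size
    counts = np.array([int((np.asarray(v) > 0).sum()) for v in perm_d])
    e_b = _e_b(counts, e_b_mode)
    pooled = np.concatenate([np.asarray(v, dtype=float).ravel() for v in perm_d])
    d_lambda = estimate_d_lambda(pooled, lam)
    n_le, floored = _n_le(d, d_lambda)
    r = int((d > 0).sum())
    fdr = n_le * e_b / ((1.0 - lam) * max(r, 1) * m)
    return FdrEstimate(
        fdr_hat=float(min(max(fdr, 0.0), 1.0)),
        r=r,
        p_null_hat=min(n_le / ((1.0 - lam) * m), 1.0),
        p_pos_null_hat=e_b / m,
        d_lambda=d_lambda,
        lam=lam,
        e_b_mode=e_b_mode,
        p_null_floored=floored,
    )
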