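"""Discriminant-Cut: maximize detections under a permutation-FDR bound.

The search family is linear, f(s) = sum_k w_k s_k - tau, with the L1
constraint sum |w_k| = 1 and sign constraints w_k >= 0 (up-regulation)
or w_k <= 0 (down-regulation).  The algorithm enumerates a weight grid
at a fixed resolution; for each weight vector it tunes tau to call as
many features as possible while keeping the estimated FDR below the
target psi; the best weight vector is then recalibrated — tau re-tuned
only — on an independent permutation set to remove the selection bias
of searching and estimating FDR on the same permutations.

Up- and down-regulation are searched with separate discriminant
functions, since the two tails of the joint attribute distribution may
have different shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .attributes import AttributeMatrix, build_attribute_matrix
from .dataset import ExpressionDataset
from .fdr import DiscriminantModel, FdrEstimate, estimate_fdr
from .permutation import PermutationNull, attributes_on_permutations, generate_permutations

__all__ = [
    "SearchConfig",
    "DetectionResult",
    "weight_grid",
    "tune_tau",
    "fit_direction",
    "detect",
    "detect_from_matrices",
]


@dataclass
class SearchConfig:
    """Settings of one Discriminant-Cut run.

    psi
        Target FDR bound in (0, 1).
    resolution
        Weight-grid step delta; 1/delta must be an integer.  ``None``
        picks 0.05 for K <= 3 and 0.1 for larger K.
    lam
        Quantile tuning parameter lambda of the pi0 estimator.
    e_b_mode
        "median" (default) or "mean" aggregation of the per-permutation
        positive counts.
    B, B_cal
        Permutation counts for the search set and the independent
        calibration set.
    direction
        "up", "down" or "both".
    """

    psi: float = 0.05
    resolution: float | None = None
    lam: float = 0.5
    e_b_mode: str = "median"
    B: int = 100
    B_cal: int = 500
    seed: int = 0
    direction: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.psi < 1:
            raise ValueError("psi must be in (0, 1)")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must be in (0, 1)")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be 'up', 'down' or 'both'")
        if self.resolution is not None:
            _check_resolution(self.resolution)

    def resolved_resolution(self, k: int) -> float:
        if self.resolution is not None:
            return self.resolution
        return 0.05 if k <= 3 else 0.1


def _check_resolution(delta: float) -> int:
    steps = 1.0 / delta
    if abs(steps - round(steps)) > 1e-9 or delta <= 0 or delta > 1:
        raise ValueError("resolution must be a unit fraction 1/n in (0, 1]")
    return int(round(steps))


@dataclass
class DirectionFit:
    """Outcome of the search for one regulation direction."""

    model: DiscriminantModel | None
    calls: np.ndarray  # boolean mask over features
    d_values: np.ndarray
    fdr_search: FdrEstimate | None
    fdr_calibrated: FdrEstimate | None
    status: str  # "ok" | "no detections at psi" | "no detections at psi (calibration)"
    n_grid: int = 0


@dataclass
class DetectionResult:
    """Final calls plus the per-direction models and FDR estimates."""

    calls: np.ndarray  # per feature: "none" | "up" | "down"
    fits: dict = field(default_factory=dict)  # direction -> DirectionFit
    feature_ids: list[str] = field(default_factory=list)
    effective_B: dict = field(default_factory=dict)
    config: SearchConfig | None = None

    @property
    def n_called(self) -> int:
        return int((self.calls != "none").sum())


# ---------------------------------------------------------------------------
# grid


def weight_grid(k: int, resolution: float, direction: str = "up") -> np.ndarray:
    """All weight vectors with entries in delta steps summing (in |.|) to 1.

    For "up" these are the non-negative lattice points of the simplex at
    step delta (C(1/delta + K - 1, K - 1) of them); for "down" the same
    vectors negated.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    steps = _check_resolution(resolution)

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first, *rest)

    grid = np.array(list(compositions(steps, k)), dtype=float) / steps
    assert len(grid) == math.comb(steps + k - 1, k - 1)
    if direction == "down":
        return -grid
    if direction != "up":
        raise ValueError("direction must be 'up' or 'down'")
    return grid


# ---------------------------------------------------------------------------
# tau tuning


def tune_tau(
    d0: np.ndarray,
    perm_d0: np.ndarray,
    psi: float,
    lam: float = 0.5,
    e_b_mode: str = "median",
):
    """Best cutoff for fixed weights: max detections with FDR_hat < psi.

    ``d0`` are the M projected values at tau = 0, ``perm_d0`` the B x M
    permutation projections.  Candidate cutoffs are the distinct values
    of ``d0`` (each calls the features strictly above it) plus one
    cutoff just below the minimum (calling everything).  All candidates
    are evaluated against sorted arrays, since the estimated FDR need
    not be monotone in tau; ties on the detection count go to the larger
    (more conservative) tau.  Returns ``(tau, r, FdrEstimate)`` or
    ``None`` when no candidate satisfies the bound.
    """
    d0 = np.asarray(d0, dtype=float)
    perm = np.asarray(perm_d0, dtype=float)
    if perm.ndim != 2 or perm.shape[1] != d0.size:
        raise ValueError("perm_d0 must be B x M")
    m = d0.size
    b = perm.shape[0]

    # d_lambda of the pooled permutation values; both it and the original
    # values shift by tau together, so the pi0 numerator is tau-free
    q = np.quantile(perm, lam, method="lower")
    n_le = int((d0 <= q).sum())
    n_le_eff = max(n_le, 1)

    u_sorted = np.sort(d0)
    candidates = np.unique(d0)
    tau_all = np.nextafter(candidates[0], -np.inf)
    candidates = np.concatenate([[tau_all], candidates])

    r = m - np.searchsorted(u_sorted, candidates, side="right")
    perm_sorted = np.sort(perm, axis=1)
    counts = np.empty((b, candidates.size))
    for j in range(b):
        counts[j] = m - np.searchsorted(perm_sorted[j], candidates, side="right")
    if e_b_mode == "median":
        e_b = np.median(counts, axis=0)
    elif e_b_mode == "mean":
        e_b = np.mean(counts, axis=0)
    else:
        raise ValueError("e_b_mode must be 'median' or 'mean'")

    fdr = n_le_eff * e_b / ((1.0 - lam) * np.maximum(r, 1) * m)
    feasible = (fdr < psi) & (r > 0)  # r = 0 is a vacuous solution, not a fit
    if not np.any(feasible):
        return None
    best_r = r[feasible].max()
    # ties on r -> larger tau; candidates are sorted ascending
    idx = np.flatnonzero(feasible & (r == best_r))[-1]
    tau = float(candidates[idx])
    est = estimate_fdr(d0 - tau, list(perm - tau), lam=lam, e_b_mode=e_b_mode)
    return tau, int(r[idx]), est


# ---------------------------------------------------------------------------
# direction fit


def _better(cand: tuple, best: tuple) -> bool:
    """Grid tie-breaking: max r, then min search FDR_hat, then fewer
    nonzero weights, then lexicographically smallest weight vector."""
    r_c, fdr_c, nnz_c, w_c = cand
    r_b, fdr_b, nnz_b, w_b = best
    if r_c != r_b:
        return r_c > r_b
    if fdr_c != fdr_b:
        return fdr_c < fdr_b
    if nnz_c != nnz_b:
        return nnz_c < nnz_b
    return tuple(w_c) < tuple(w_b)


def fit_direction(
    stats: np.ndarray,
    perm_stats: np.ndarray,
    calib_stats: np.ndarray,
    cfg: SearchConfig,
    direction: str,
) -> DirectionFit:
    """Grid-search the weights on the search null, recalibrate tau on the
    independent calibration null, and produce final calls.

    ``stats`` is M x K; ``perm_stats`` and ``calib_stats`` are
    (B, M, K) and (B_cal, M, K) permutation attribute arrays computed
    with the identical pipeline.
    """
    s = np.asarray(stats, dtype=float)
    p = np.asarray(perm_stats, dtype=float)
    c = np.asarray(calib_stats, dtype=float)
    m, k = s.shape
    sign = 1.0 if direction == "up" else -1.0
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    grid = weight_grid(k, cfg.resolved_resolution(k), "up")
    best = None
    best_key = None
    for w in grid:
        u = sign * (s @ w)
        v = sign * np.einsum("bmk,k->bm", p, w)
        res = tune_tau(u, v, cfg.psi, cfg.lam, cfg.e_b_mode)
        if res is None:
            continue
        tau, r, est = res
        key = (r, est.fdr_hat, int((w > 0).sum()), w)
        if best is None or _better(key, best_key):
            best = (w, tau, r, est)
            best_key = key

    empty = DirectionFit(
        model=None,
        calls=np.zeros(m, dtype=bool),
        d_values=np.full(m, -np.inf),
        fdr_search=None,
        fdr_calibrated=None,
        status="no detections at psi",
        n_grid=len(grid),
    )
    if best is None:
        return empty

    w, _, _, est_search = best
    u = sign * (s @ w)
    v_cal = sign * np.einsum("bmk,k->bm", c, w)
    res_cal = tune_tau(u, v_cal, cfg.psi, cfg.lam, cfg.e_b_mode)
    if res_cal is None:
        empty.status = "no detections at psi (calibration)"
        empty.fdr_search = est_search
        return empty
    tau_cal, _, est_cal = res_cal

    model = DiscriminantModel(weights=sign * w, tau=tau_cal, direction=direction)
    d = u - tau_cal
    return DirectionFit(
        model=model,
        calls=d > 0,
        d_values=d,
        fdr_search=est_search,
        fdr_calibrated=est_cal,
        status="ok",
        n_grid=len(grid),
    )


# ---------------------------------------------------------------------------
# full detection


def detect_from_matrices(
    stats: np.ndarray,
    perm_stats: np.ndarray,
    calib_stats: np.ndarray,
    cfg: SearchConfig,
    feature_ids: list[str] | None = None,
) -> DetectionResult:
    """Run the per-direction searches on precomputed attribute arrays.

    Useful when several configurations (attribute subsets, psi values)
    share one set of permutation recomputations.
    """
    m = stats.shape[0]
    directions = ("up", "down") if cfg.direction == "both" else (cfg.direction,)
    fits = {}
    for direction in directions:
        fits[direction] = fit_direction(stats, perm_stats, calib_stats, cfg, direction)

    calls = np.full(m, "none", dtype=object)
    if "up" in fits:
        calls[fits["up"].calls] = "up"
    if "down" in fits:
        down = fits["down"].calls
        if "up" in fits:
            # a feature above both boundaries keeps the larger margin
            clash = down & fits["up"].calls
            down = down & (~clash | (fits["down"].d_values > fits["up"].d_values))
        calls[down] = "down"
    return DetectionResult(
        calls=calls,
        fits=fits,
        feature_ids=feature_ids or [f"feature_{i}" for i in range(m)],
        effective_B={"search": perm_stats.shape[0], "calibration": calib_stats.shape[0]},
        config=cfg,
    )


def detect(data: ExpressionDataset, spec, cfg: SearchConfig) -> DetectionResult:
    """End-to-end Discriminant-Cut on an expression dataset.

    Computes the attribute matrix, generates disjoint-seeded search and
    calibration permutation nulls, and fits the requested directions.
    """
    am = build_attribute_matrix(data, spec)
    null_search, null_calib = build_nulls(data, spec, cfg)
    result = detect_from_matrices(
        am.stats,
        null_search.stacked(),
        null_calib.stacked(),
        cfg,
        feature_ids=am.feature_ids,
    )
    return result


def build_nulls(
    data: ExpressionDataset, spec, cfg: SearchConfig
) -> tuple[PermutationNull, PermutationNull]:
    """Search and calibration permutation nulls from disjoint seed streams."""
    ss = np.random.SeedSequence(cfg.seed)
    seed_search, seed_calib = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    perms_search = generate_permutations(data.labels, cfg.B, seed_search)
    perms_calib = generate_permutations(data.labels, cfg.B_cal, seed_calib)
    null_search = attributes_on_permutations(
        data, perms_search, spec, seed=seed_search, purpose="search"
    )
    null_calib = attributes_on_permutations(
        data, perms_calib, spec, seed=seed_calib, purpose="calibration"
    )
    return null_search, null_calib
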