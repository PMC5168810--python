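"""Scoring detection results against simulated ground truth.

True FDR here is direction-aware: a gene whose truth is "up" but which
was called "down" counts as a false positive.  A configuration is said
to fail FDR control when its mean true FDR exceeds the target by more
than 10% (i.e. > 1.1 psi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .discriminant_cut import SearchConfig, detect_from_matrices

__all__ = [
    "EvaluationReport",
    "true_fdr",
    "evaluate_calls",
    "sweep_psi",
    "aggregate_replicates",
    "paired_comparison",
    "fdr_control_ok",
]

FDR_CONTROL_SLACK = 1.1  # "does not exceed the target FDR by 10%"


@dataclass
class EvaluationReport:
    """Confusion summary of one detection run against the truth table."""

    calls: int
    true_positives: int
    false_positives: int
    true_fdr: float
    psi: float | None = None


def true_fdr(calls: np.ndarray, truth: np.ndarray) -> float:
    """False calls / max(#calls, 1); direction mismatches are false."""
    calls = np.asarray(calls, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must align feature-wise")
    called = calls != "none"
    false = called & (truth != calls)
    return float(false.sum()) / max(int(called.sum()), 1)


def evaluate_calls(calls: np.ndarray, truth: np.ndarray, psi: float | None = None):
    calls = np.asarray(calls, dtype=object)
    truth = np.asarray(truth, dtype=object)
    called = calls != "none"
    tp = int((called & (truth == calls)).sum())
    fp = int(called.sum()) - tp
    return EvaluationReport(
        calls=int(called.sum()),
        true_positives=tp,
        false_positives=fp,
        true_fdr=fp / max(int(called.sum()), 1),
        psi=psi,
    )


def fdr_control_ok(mean_true_fdr: float, psi: float) -> bool:
    return mean_true_fdr <= FDR_CONTROL_SLACK * psi


def sweep_psi(
    stats: np.ndarray,
    perm_stats: np.ndarray,
    calib_stats: np.ndarray,
    cfg: SearchConfig,
    truth: np.ndarray | None = None,
    psi_grid=None,
) -> pd.DataFrame:
    """One detection run per target FDR, sharing the permutation arrays.

    Default grid: 0.01 to 0.10 in steps of 0.01.  Returns a table with
    one row per psi (calls; plus true FDR and true positives when the
    truth is known), from which the false-discovery curve — true FDR as
    a function of the number of calls — reads off directly.
    """
    if psi_grid is None:
        psi_grid = np.round(np.arange(0.01, 0.101, 0.01), 3)
    rows = []
    for psi in psi_grid:
        cfg_psi = SearchConfig(
            psi=float(psi),
            resolution=cfg.resolution,
            lam=cfg.lam,
            e_b_mode=cfg.e_b_mode,
            B=cfg.B,
            B_cal=cfg.B_cal,
            seed=cfg.seed,
            direction=cfg.direction,
        )
        result = detect_from_matrices(stats, perm_stats, calib_stats, cfg_psi)
        row = {"psi": float(psi), "calls": result.n_called}
        if truth is not None:
            rep = evaluate_calls(result.calls, truth, psi=float(psi))
            row.update(true_fdr=rep.true_fdr, true_positives=rep.true_positives)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_replicates(reports_by_config: dict[str, list[EvaluationReport]]) -> dict:
    """Replicate-matched means and pairwise paired-t comparisons.

    ``reports_by_config`` maps a configuration name to its per-replicate
    reports; all configurations must cover the same replicates in the
    same order.  Returns mean true FDR / true positives / calls per
    configuration plus paired comparisons of true positives between
    every configuration pair.
    """
    names = list(reports_by_config)
    if len(names) < 1:
        raise ValueError("no reports given")
    n_rep = len(reports_by_config[names[0]])
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    for name in names:
        if len(reports_by_config[name]) != n_rep:
            raise ValueError("replicate sets are mismatched across configurations")

    summary = {
        name: {
            "mean_true_fdr": float(np.mean([r.true_fdr for r in reps])),
            "mean_true_positives": float(np.mean([r.true_positives for r in reps])),
            "mean_calls": float(np.mean([r.calls for r in reps])),
            "n_replicates": n_rep,
        }
        for name, reps in reports_by_config.items()
    }
    comparisons = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comparisons[(a, b)] = paired_comparison(
                [r.true_positives for r in reports_by_config[a]],
                [r.true_positives for r in reports_by_config[b]],
            )
    return {"summary": summary, "paired_true_positives": comparisons}


def paired_comparison(xs, ys) -> dict:
    """Mean difference and paired t-test between replicate-matched runs."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("paired comparison needs matched replicates")
    diff = xs - ys
    if np.allclose(diff, diff[0]):
        t_stat, p = (np.nan, np.nan) if np.isclose(diff[0], 0) else (np.inf, 0.0)
    else:
        t_stat, p = sps.ttest_rel(xs, ys)
    return {
        "mean_difference": float(diff.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p),
    }
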