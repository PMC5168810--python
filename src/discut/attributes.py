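"""Per-feature test statistics ("basic attributes").

Each extractor maps an :class:`~discut.dataset.ExpressionDataset` to one
signed statistic per feature, oriented so that a larger value means
stronger evidence of up-regulation in group 2 relative to group 1.  The
K columns produced by :func:`build_attribute_matrix` form the space in
which the discriminant boundary is searched.

All extractors are fully vectorized across features because the
permutation null requires recomputing every statistic B times.  They are
deliberately self-contained re-implementations of the familiar designs
(SAM corrected t / ranksum, limma-style moderated t, voom-style
precision-weighted moderated t, DESeq2-style NB Wald); numerical
equality with the corresponding R packages is not a goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import digamma, gammaln, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataset import ExpressionDataset

__all__ = [
    "AttributeMatrix",
    "compute_sam_t",
    "compute_sam_ranksum",
    "compute_moderated_t",
    "compute_voom_t",
    "compute_nb_wald",
    "size_factors",
    "build_attribute_matrix",
    "SUPPORTED_ATTRIBUTES",
]

_INTEGER_TOL = 1e-6


@dataclass
class AttributeMatrix:
    """M x K matrix of oriented basic-attribute values.

    ``stats[i, k]`` is the k-th statistic of feature i, signed
    group-2 minus group-1.  ``settings`` records the extractor options
    so the identical pipeline can be re-run on permuted labels.
    """

    stats: np.ndarray
    attribute_names: list[str]
    feature_ids: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.ndim != 2 or self.stats.shape[1] != len(self.attribute_names):
            raise ValueError("stats shape does not match attribute_names")
        if self.stats.shape[1] < 1:
            raise ValueError("need at least one attribute")
        if not np.all(np.isfinite(self.stats)):
            i, k = np.argwhere(~np.isfinite(self.stats))[0]
            name = self.feature_ids[i] if self.feature_ids else str(i)
            raise ValueError(
                f"non-finite attribute value: feature {name}, "
                f"attribute {self.attribute_names[k]}"
            )

    @property
    def n_features(self) -> int:
        return self.stats.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.stats.shape[1]


# ---------------------------------------------------------------------------
# helpers


def _group_split(data: ExpressionDataset):
    mask = data.group_mask
    x1 = data.values[:, ~mask]
    x2 = data.values[:, mask]
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return x1, x2


def _pooled_se(x1: np.ndarray, x2: np.ndarray):
    """Per-feature mean difference and pooled-SD standard error."""
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    pooled_var = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return diff, se


def _require_counts(data: ExpressionDataset, who: str) -> np.ndarray:
    if np.any(data.values < 0):
        raise ValueError(f"{who} requires non-negative counts")
    if not data.is_integer_valued(_INTEGER_TOL):
        raise ValueError(
            f"{who} requires integer counts; scale and round continuous values "
            "first (e.g. scale_round with factor 1000)"
        )
    return np.round(data.values)


# ---------------------------------------------------------------------------
# SAM-style statistics


def compute_sam_t(data: ExpressionDataset, s0_mode="median") -> np.ndarray:
    """SAM corrected t-statistic: (mean2 - mean1) / (s_g + s0).

    ``s0`` is a single data-wide fudge constant stabilizing features with
    small standard errors.  ``s0_mode`` is either ``"median"`` (the median
    of the per-feature standard errors, the default), a float in [0, 1)
    interpreted as a quantile of the standard errors, or a non-negative
    fixed value passed as ``("fixed", value)``.
    """
    x1, x2 = _group_split(data)
    diff, se = _pooled_se(x1, x2)
    if s0_mode == "median":
        s0 = float(np.median(se))
    elif isinstance(s0_mode, tuple) and s0_mode[0] == "fixed":
        s0 = float(s0_mode[1])
        if s0 < 0:
            raise ValueError("fixed s0 must be non-negative")
    elif isinstance(s0_mode, (int, float)):
        if not 0 <= s0_mode < 1:
            raise ValueError("quantile s0_mode must be in [0, 1)")
        s0 = float(np.quantile(se, s0_mode))
    else:
        raise ValueError(f"unrecognized s0_mode: {s0_mode!r}")

    denom = se + s0
    out = np.zeros(data.n_features)
    ok = denom > 0
    if not np.all(ok):
        # zero variance in both groups with s0 = 0: no evidence either way
        warnings.warn(
            f"{int((~ok).sum())} zero-variance feature(s) with s0 = 0; "
            "statistic set to 0",
            stacklevel=2,
        )
    out[ok] = diff[ok] / denom[ok]
    return out


def compute_sam_ranksum(data: ExpressionDataset) -> np.ndarray:
    """Centered rank-sum statistic W - E0[W] with mid-ranks for ties.

    W is the sum of the ranks of the group-2 samples among all N samples
    of the feature; under the null its expectation is n2 (N + 1) / 2.
    """
    x1, x2 = _group_split(data)
    mask = data.group_mask
    n2 = int(mask.sum())
    n = data.n_samples
    ranks = sps.rankdata(data.values, axis=1)
    w = ranks[:, mask].sum(axis=1)
    return w - n2 * (n + 1) / 2.0


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes shrunk variance)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Given per-feature residual variances ``s2`` on ``df`` degrees of
    freedom, estimates the prior degrees of freedom d0 and prior variance
    s0^2 from the mean and variance of log(s2), using the digamma /
    trigamma moments of the log of a chi-square variate.  Returns
    ``(d0, s0_sq)`` with d0 capped at 1e6 (representing "infinite", i.e.
    all features share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 3:
        raise ValueError(
            "variance-prior estimation needs at least 3 features with positive variance"
        )
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    target = evar - float(polygamma(1, df / 2.0))
    if target <= 0:
        d0 = 1e6
        s0_sq = float(np.exp(emean))
    else:
        d0 = float(2.0 * _trigamma_inverse(np.array(target)))
        d0 = min(d0, 1e6)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def compute_moderated_t(
    data: ExpressionDataset,
    weights: np.ndarray | None = None,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> np.ndarray:
    """Two-group t with an empirical-Bayes posterior residual variance.

    The per-feature residual variance s_g^2 is replaced by

        s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

    with hyperparameters (d0, s0^2) estimated across features by
    moment-matching the marginal distribution of log sample variances
    (pass them explicitly to override; d0 = 0 gives the ordinary t).
    Optional per-observation precision ``weights`` (M x N) give the
    voom-style weighted fit.
    """
    mask = data.group_mask
    y = data.values
    m, n = y.shape
    dg = n - 2
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must match the data matrix shape")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")

    means = np.empty_like(y)
    sw = np.zeros((m, 2))
    for g, gmask in enumerate((~mask, mask)):
        if gmask.sum() < 2:
            raise ValueError("each group needs at least 2 samples")
        wg = w[:, gmask]
        sw[:, g] = wg.sum(axis=1)
        mu = (wg * y[:, gmask]).sum(axis=1) / sw[:, g]
        means[:, gmask] = mu[:, None]
    rss = (w * (y - means) ** 2).sum(axis=1)
    s2 = rss / dg

    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_variance_prior(s2, dg)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    d0 = min(float(d0), 1e6)
    s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)

    diff = (w[:, mask] * y[:, mask]).sum(axis=1) / sw[:, 1] - (
        (w[:, ~mask] * y[:, ~mask]).sum(axis=1) / sw[:, 0]
    )
    se = np.sqrt(s2_post * (1.0 / sw[:, 0] + 1.0 / sw[:, 1]))
    out = np.zeros(m)
    ok = se > 0
    out[ok] = diff[ok] / se[ok]
    return out


# ---------------------------------------------------------------------------
# voom-style weighted moderated t


def log_cpm(counts: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with the standard half-count offset."""
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def voom_weights(counts: np.ndarray, group_mask: np.ndarray, frac: float = 0.5):
    """Mean-variance precision weights for log-cpm values.

    Fits a lowess smooth of the per-feature residual sqrt-SD against the
    average log2 count, then assigns each observation the weight
    (predicted sqrt-SD at its fitted log2 count)^-4.  Returns
    ``(logcpm, weights)``; weights are None when fewer than 50 features
    make the smooth unreliable.
    """
    m, _ = counts.shape
    lib = counts.sum(axis=0)
    lc = log_cpm(counts)
    if m < 50:
        warnings.warn(
            "fewer than 50 features: mean-variance trend unreliable, using unit weights",
            stacklevel=2,
        )
        return lc, None

    fitted = np.empty_like(lc)
    for gmask in (~group_mask, group_mask):
        fitted[:, gmask] = lc[:, gmask].mean(axis=1, keepdims=True)
    resid_sd = np.sqrt(((lc - fitted) ** 2).sum(axis=1) / (lc.shape[1] - 2))
    sqrt_sd = np.sqrt(resid_sd)

    # x-axis on the average log2-count scale, as for the fitted values below
    lib_offset = np.log2(np.exp(np.mean(np.log(lib + 1.0)))) - np.log2(1e6)
    x = lc.mean(axis=1) + lib_offset
    delta = 0.01 * (x.max() - x.min())
    smooth = lowess(sqrt_sd, x, frac=frac, it=3, delta=delta, return_sorted=True)
    sx, sy = smooth[:, 0], smooth[:, 1]

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, sx, sy)  # clamped at the trend's ends
    pred = np.maximum(pred, 1e-6)
    return lc, pred ** -4


def compute_voom_t(data: ExpressionDataset, lowess_frac: float = 0.5) -> np.ndarray:
    """Moderated t on log-cpm values with mean-variance precision weights."""
    counts = _require_counts(data, "voom_t")
    lc, w = voom_weights(counts, data.group_mask, frac=lowess_frac)
    logdata = ExpressionDataset(
        values=lc,
        feature_ids=data.feature_ids,
        sample_ids=data.sample_ids,
        labels=data.labels,
    )
    return compute_moderated_t(logdata, weights=w)


# ---------------------------------------------------------------------------
# NB Wald


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, scaled to geometric mean 1."""
    counts = np.asarray(counts, dtype=float)
    all_pos = np.all(counts > 0, axis=1)
    if not np.any(all_pos):
        warnings.warn(
            "no feature with all-positive counts; falling back to library-size factors",
            stacklevel=2,
        )
        lib = counts.sum(axis=0)
        factors = lib / np.exp(np.mean(np.log(lib)))
        return factors
    sub = counts[all_pos]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return factors / np.exp(np.mean(np.log(factors)))


def _nb_loglik(y, mu, alpha):
    """NB log-likelihood summed over samples, per feature (alpha per feature)."""
    mu = np.maximum(mu, 1e-10)
    if np.isscalar(alpha):
        alpha = np.full(y.shape[0], float(alpha))
    alpha = np.asarray(alpha)[:, None]
    small = alpha[:, 0] < 1e-8
    ll = np.empty(y.shape[0])
    if np.any(~small):
        a = alpha[~small]
        r = 1.0 / a
        yy, mm = y[~small], mu[~small]
        ll[~small] = (
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1)
            + r * np.log(r / (r + mm)) + yy * np.log(mm / (r + mm) + 1e-300)
        ).sum(axis=1)
    if np.any(small):
        yy, mm = y[small], mu[small]
        ll[small] = (yy * np.log(mm) - mm - gammaln(yy + 1)).sum(axis=1)
    return ll


def _fit_group_means(y, s, group_mask, alpha, n_iter: int = 15):
    """Per-feature, per-group MLE of eta in mu_ij = s_j exp(eta_g).

    Newton iterations on the NB score, vectorized across features.
    Returns (eta1, eta2, mu) and a boolean non-convergence flag.
    """
    m = y.shape[0]
    alpha = np.asarray(alpha)
    if alpha.ndim == 0:
        alpha = np.full(m, float(alpha))
    etas = np.empty((m, 2))
    mu = np.empty_like(y, dtype=float)
    bad = np.zeros(m, dtype=bool)
    for g, gmask in enumerate((~group_mask, group_mask)):
        yg = y[:, gmask]
        sg = s[gmask]
        tot = yg.sum(axis=1)
        eta = np.log((tot + 0.5) / sg.sum())  # half-count start, finite for all-zero
        a = alpha[:, None]
        for _ in range(n_iter):
            mug = sg[None, :] * np.exp(eta)[:, None]
            denom = 1.0 + a * mug
            score = ((yg - mug) / denom).sum(axis=1)
            info = (mug / denom).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            eta = eta + step
            eta = np.clip(eta, -50.0, 50.0)
        mug = sg[None, :] * np.exp(eta)[:, None]
        resid = np.abs(((yg - mug) / (1.0 + a * mug)).sum(axis=1))
        bad |= (resid > 1e-3 * (1.0 + tot)) & (tot > 0)
        etas[:, g] = eta
        mu[:, gmask] = mug
    return etas[:, 0], etas[:, 1], mu, bad


def estimate_dispersions(
    y: np.ndarray,
    s: np.ndarray,
    group_mask: np.ndarray,
    log_alpha_bounds: tuple[float, float] = (-16.0, 3.0),
    n_iter: int = 26,
) -> np.ndarray:
    """Per-feature NB dispersion MLE by golden-section search on log alpha.

    The group means are fit once at a method-of-moments dispersion and
    held fixed during the search (the standard fitted-mean profile); a
    dispersion at the lower bound is effectively Poisson.
    """
    lo = np.full(y.shape[0], log_alpha_bounds[0])
    hi = np.full(y.shape[0], log_alpha_bounds[1])
    gr = (np.sqrt(5.0) - 1.0) / 2.0

    # method-of-moments start on normalized counts
    yn = y / s[None, :]
    mom = (yn.var(axis=1, ddof=1) - yn.mean(axis=1)) / np.maximum(yn.mean(axis=1), 1e-8) ** 2
    alpha0 = np.clip(mom, 1e-6, np.exp(log_alpha_bounds[1]))
    _, _, mu, _ = _fit_group_means(y, s, group_mask, alpha0)

    def profile_ll(log_a):
        return _nb_loglik(y, mu, np.exp(log_a))

    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc = profile_ll(c)
    fd = profile_ll(d)
    for _ in range(n_iter):
        left = fc >= fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc = profile_ll(c)
        fd = profile_ll(d)
    return np.exp((lo + hi) / 2.0)


def shrink_dispersions(alpha_mle: np.ndarray, base_mean: np.ndarray, weight: float = 0.5):
    """Shrink log-dispersions toward an a + b / mean trend.

    The trend is a least-squares fit of the MLE dispersions on 1/mean;
    each feature's log-dispersion is then pulled toward the trend with
    the given fixed weight.
    """
    floor = 1e-8
    a = np.maximum(alpha_mle, floor)
    mu = np.maximum(base_mean, 1e-8)
    x = np.column_stack([np.ones_like(mu), 1.0 / mu])
    informative = alpha_mle > 1e-6  # ignore boundary (Poisson-like) fits
    if informative.sum() >= 3:
        coef, *_ = np.linalg.lstsq(x[informative], a[informative], rcond=None)
    else:
        coef = np.array([float(np.median(a)), 0.0])
    trend = np.maximum(x @ coef, floor)
    return np.exp(weight * np.log(a) + (1.0 - weight) * np.log(trend))


def compute_nb_wald(
    data: ExpressionDataset,
    factors: np.ndarray | None = None,
    dispersion: float | np.ndarray | None = None,
    shrink: bool = True,
) -> np.ndarray:
    """Wald statistic of the condition effect in an NB log-linear model.

    Fits, per feature, mu_ij = s_j exp(b0 + b1 x_j) with x the group-2
    indicator and s_j the size factors; the statistic is b1 / SE(b1)
    with the SE from the Fisher information.  Dispersions are estimated
    by per-feature maximum likelihood and shrunk toward an a + b/mean
    trend on the log scale (pass ``dispersion`` to fix them; 0 gives the
    Poisson Wald statistic).
    """
    y = _require_counts(data, "nb_wald")
    if factors is None:
        factors = size_factors(y)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be strictly positive")
    mask = data.group_mask

    nonzero = y.sum(axis=1) > 0
    out = np.zeros(data.n_features)
    if not np.any(nonzero):
        return out
    ysub = y[nonzero]

    if dispersion is None:
        alpha = estimate_dispersions(ysub, factors, mask)
        if shrink:
            base_mean = (ysub / factors[None, :]).mean(axis=1)
            alpha = shrink_dispersions(alpha, base_mean)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (data.n_features,))[
            nonzero
        ].copy()

    eta1, eta2, mu, bad = _fit_group_means(ysub, factors, mask, alpha)
    if np.any(bad):
        # Poisson fallback for non-convergent features
        warnings.warn(f"{int(bad.sum())} NB fit(s) fell back to Poisson", stacklevel=2)
        alpha = np.where(bad, 0.0, alpha)
        eta1, eta2, mu, _ = _fit_group_means(ysub, factors, mask, alpha)

    # observed information: -d2l/deta2 = sum mu (1 + alpha y) / (1 + alpha mu)^2
    a = np.asarray(alpha)[:, None]
    wobs = mu * (1.0 + a * ysub) / (1.0 + a * mu) ** 2
    w1 = wobs[:, ~mask].sum(axis=1)
    w2 = wobs[:, mask].sum(axis=1)
    se = np.sqrt(1.0 / np.maximum(w1, 1e-12) + 1.0 / np.maximum(w2, 1e-12))
    out[nonzero] = (eta2 - eta1) / se
    return out


# ---------------------------------------------------------------------------
# attribute-matrix assembly

SUPPORTED_ATTRIBUTES = {
    "sam_t": compute_sam_t,
    "sam_ranksum": compute_sam_ranksum,
    "moderated_t": compute_moderated_t,
    "voom_t": compute_voom_t,
    "nb_wald": compute_nb_wald,
}


def build_attribute_matrix(data: ExpressionDataset, spec) -> AttributeMatrix:
    """Compute the requested attribute columns in order.

    ``spec`` is a list whose entries are attribute names or
    ``(name, settings_dict)`` pairs; recognized names are the keys of
    ``SUPPORTED_ATTRIBUTES``.  The same spec re-run on permuted labels
    reproduces the identical pipeline (all data-dependent tuning, such
    as the SAM fudge factor or voom weights, is refit per run).
    """
    entries = []
    for item in spec:
        if isinstance(item, str):
            entries.append((item, {}))
        else:
            name, settings = item
            entries.append((name, dict(settings)))
    if not entries:
        raise ValueError("attribute spec must be non-empty")
    names = [name for name, _ in entries]
    for name in names:
        if name not in SUPPORTED_ATTRIBUTES:
            raise ValueError(
                f"unknown attribute {name!r}; supported: {sorted(SUPPORTED_ATTRIBUTES)}"
            )
    if len(set(names)) != len(names):
        warnings.warn("duplicate attribute names in spec; columns will repeat", stacklevel=2)

    cols = [SUPPORTED_ATTRIBUTES[name](data, **settings) for name, settings in entries]
    return AttributeMatrix(
        stats=np.column_stack(cols),
        attribute_names=names,
        feature_ids=list(data.feature_ids),
        settings={"spec": [(n, s) for n, s in entries]},
    )
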