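"""Inference on group differences in indirect effects and on simple indirect
effects: z and Wald tests, likelihood-ratio tests, percentile and
bias-corrected bootstrap confidence intervals, and Monte Carlo confidence
intervals for products of coefficients.

Method tags follow the field's naming: a trailing ``S``/``M`` marks the
single-group (interaction) versus multi-group parameterization, and
``ind``/``diff`` marks the estimand (simple indirect effect in one group
versus the between-group difference). E.g. ``WdiffS`` is the delta-method
Wald test of a3*b = 0 in the single-group model and ``PCdiffM`` the
percentile bootstrap interval for a_G1*b_G1 - a_G2*b_G2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GroupCoding, MediationDataset
from .errors import DataError, EstimationError
from .model import (
    MultiGroupFit,
    SingleGroupFit,
    asymptotic_cov_products,
    fit_multi_group,
    fit_single_group,
    simple_indirect_effects,
)

__all__ = [
    "TestResult",
    "IntervalEstimate",
    "DrawSet",
    "z_test_a3",
    "wald_product_test",
    "wald_diff_test",
    "lr_test",
    "bootstrap_draws",
    "bootstrap_draw_sets",
    "monte_carlo_draws",
    "percentile_ci",
    "bc_ci",
    "ci_excludes_zero",
]

DIFFERENCE = "difference"


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its reference distribution.

    ``df`` is None for the z test (standard normal reference, two-sided p);
    LR and Wald statistics are referred to the upper tail of chi-square(df).
    """

    method: str
    statistic: float
    df: int | None
    p_value: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class IntervalEstimate:
    """A method-tagged confidence interval for one estimand."""

    method: str
    target: str  # a group label, or "difference"
    lower: float
    upper: float
    level: float
    n_draws: int
    seed: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("interval endpoints out of order")

    @property
    def excludes_zero(self) -> bool:
        return ci_excludes_zero(self)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "target": self.target,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "flags": list(self.flags),
            "excludes_zero": self.excludes_zero,
        }


@dataclass
class DrawSet:
    """Replicate estimates of one estimand (bootstrap or Monte Carlo).

    ``values`` contains only finite replicates; non-finite ones are dropped
    after redraw attempts and counted in ``n_dropped``.
    """

    values: np.ndarray
    provenance: str  # "bootstrap" | "monte_carlo"
    point_estimate: float
    target: str
    approach: str  # "single" | "multi"
    n_requested: int
    n_dropped: int = 0
    seed: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Wald-family tests
# ---------------------------------------------------------------------------


def z_test_a3(fit: SingleGroupFit) -> TestResult:
    """z test of the X-by-group interaction path: z = a3 / se(a3)."""
    se = fit.se("a3")
    if se <= 0.0:
        raise EstimationError("se(a3) is zero; z test undefined")
    z = fit.a3 / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(method="za3S", statistic=float(z), df=None, p_value=float(p))


def wald_product_test(fit: SingleGroupFit) -> TestResult:
    """Delta-method Wald test of a3*b = 0 in the single-group model.

    avar(a3*b) = b^2 var(a3) + a3^2 var(b) + 2 a3 b cov(a3, b), with the
    covariance taken from the joint ML covariance (zero across equations).
    """
    cov = asymptotic_cov_products(fit)
    theta = fit.a3 * fit.b
    grad = np.array([fit.b, fit.a3])
    avar = float(grad @ cov.matrix @ grad)
    if avar <= 0.0:
        raise EstimationError("non-positive asymptotic variance of a3*b")
    W = theta * theta / avar
    return TestResult(
        method="WdiffS", statistic=float(W), df=1, p_value=float(stats.chi2.sf(W, 1))
    )


def wald_diff_test(fit: MultiGroupFit) -> TestResult:
    """Delta-method Wald test of a_G1*b_G1 = a_G2*b_G2 in the multi-group model."""
    if fit.constraints:
        raise EstimationError("wald_diff_test requires an unconstrained fit")
    l1, l2 = fit.order
    cov = asymptotic_cov_products(fit)
    theta = fit.a(l1) * fit.b(l1) - fit.a(l2) * fit.b(l2)
    grad = np.array([fit.b(l1), fit.a(l1), -fit.b(l2), -fit.a(l2)])
    avar = float(grad @ cov.matrix @ grad)
    if avar <= 0.0:
        raise EstimationError("non-positive asymptotic variance of the difference")
    W = theta * theta / avar
    return TestResult(
        method="WdiffM", statistic=float(W), df=1, p_value=float(stats.chi2.sf(W, 1))
    )


def lr_test(unconstrained: MultiGroupFit, constrained: MultiGroupFit) -> TestResult:
    """Likelihood-ratio test between nested multi-group fits.

    statistic = (-2logL of the constrained fit) - (-2logL of the unconstrained
    fit), referred to chi-square with df = difference in free parameters.
    Small negative values (within optimizer tolerance) are clamped to zero.
    """
    if unconstrained.data_fingerprint != constrained.data_fingerprint:
        raise DataError("LR test requires both fits on the same data")
    if not (constrained.constraints >= unconstrained.constraints):
        raise ValueError(
            "constrained fit must include every constraint of the unconstrained fit"
        )
    df = unconstrained.n_free_params - constrained.n_free_params
    stat = constrained.neg2loglik - unconstrained.neg2loglik
    if stat < 0.0:
        if stat < -1e-6 * (1.0 + abs(unconstrained.neg2loglik)):
            raise EstimationError(
                f"constrained fit has better likelihood by {-stat:.3g}; "
                "the constrained optimization did not converge"
            )
        stat = 0.0
    added = constrained.constraints - unconstrained.constraints
    if added == {"a_equal"}:
        tag = "LRaM"
    elif added == {"ab_product_equal"} or added == {"ab_product_equal", "b_equal"}:
        tag = "LRdiffM"
    else:
        tag = "LR"
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(method=tag, statistic=float(stat), df=df, p_value=p)


# ---------------------------------------------------------------------------
# bootstrap machinery (vectorized closed-form refits)
# ---------------------------------------------------------------------------

_MAX_REDRAW = 10
_SXX_TINY = 1e-12


def _slope(xs: np.ndarray, ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise LS slope of m on x (with intercept): S_xm / S_xx."""
    xb = xs.mean(axis=1)
    mb = ms.mean(axis=1)
    sxx = (xs * xs).mean(axis=1) - xb * xb
    sxm = (xs * ms).mean(axis=1) - xb * mb
    bad = sxx <= _SXX_TINY
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
    return a, bad | ~np.isfinite(a)


def _two_pred(ms, xs, ys) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise LS of y on (1, m, x): returns (b, c, bad)."""
    n = ms.shape[1]
    mb = ms.mean(axis=1)
    xb = xs.mean(axis=1)
    yb = ys.mean(axis=1)
    smm = (ms * ms).mean(axis=1) - mb * mb
    sxx = (xs * xs).mean(axis=1) - xb * xb
    smx = (ms * xs).mean(axis=1) - mb * xb
    smy = (ms * ys).mean(axis=1) - mb * yb
    sxy = (xs * ys).mean(axis=1) - xb * yb
    det = smm * sxx - smx * smx
    bad = det <= _SXX_TINY * np.maximum(smm * sxx, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (smy * sxx - sxy * smx) / det
        c = (sxy * smm - smy * smx) / det
    bad |= ~np.isfinite(b) | ~np.isfinite(c)
    return b, c, bad


def _group_boot_paths(rng, x, m, y, B):
    """Bootstrap (a*, b*) for one group under the multi-group model, with
    per-row redraws for degenerate resamples."""
    n = len(x)
    idx = rng.integers(0, n, size=(B, n))
    a, bad_a = _slope(x[idx], m[idx])
    b, _, bad_b = _two_pred(m[idx], x[idx], y[idx])
    bad = bad_a | bad_b
    rounds = 0
    while bad.any() and rounds < _MAX_REDRAW:
        k = int(bad.sum())
        idx2 = rng.integers(0, n, size=(k, n))
        a2, bad_a2 = _slope(x[idx2], m[idx2])
        b2, _, bad_b2 = _two_pred(m[idx2], x[idx2], y[idx2])
        a[bad] = a2
        b[bad] = b2
        nb = np.zeros_like(bad)
        nb[np.flatnonzero(bad)[bad_a2 | bad_b2]] = True
        bad = nb
        rounds += 1
    return a, b, bad


def _single_stratified_boot(rng, data, coding, B):
    """Bootstrap (a1*, a3*, b*) under the single-group model with resampling
    stratified by group (group sizes held fixed)."""
    xr, mr, yr = data.arrays(coding.reference)
    xf, mf, yf = data.arrays(coding.focal)
    sums = np.zeros((B, 9))  # Sy Sm Sx Smm Sxx Smx Smy Sxy N
    slopes = {}
    bads = {}
    idxs = {}
    for lab, (x, m, y) in (("ref", (xr, mr, yr)), ("foc", (xf, mf, yf))):
        n = len(x)
        idx = rng.integers(0, n, size=(B, n))
        idxs[lab] = (idx, x, m, y)
        s, bad = _slope(x[idx], m[idx])
        slopes[lab] = s
        bads[lab] = bad
    bad = bads["ref"] | bads["foc"]
    rounds = 0
    while bad.any() and rounds < _MAX_REDRAW:
        for lab in ("ref", "foc"):
            idx, x, m, y = idxs[lab]
            k = int(bad.sum())
            idx2 = rng.integers(0, len(x), size=(k, len(x)))
            idx[bad] = idx2
            s, b2 = _slope(x[idx], m[idx])
            slopes[lab] = s
            bads[lab] = b2
        bad = bads["ref"] | bads["foc"]
        rounds += 1
    # pooled Y-equation across both groups' resampled rows
    for lab in ("ref", "foc"):
        idx, x, m, y = idxs[lab]
        xs, ms, ys = x[idx], m[idx], y[idx]
        sums[:, 0] += ys.sum(axis=1)
        sums[:, 1] += ms.sum(axis=1)
        sums[:, 2] += xs.sum(axis=1)
        sums[:, 3] += (ms * ms).sum(axis=1)
        sums[:, 4] += (xs * xs).sum(axis=1)
        sums[:, 5] += (ms * xs).sum(axis=1)
        sums[:, 6] += (ms * ys).sum(axis=1)
        sums[:, 7] += (xs * ys).sum(axis=1)
        sums[:, 8] += idx.shape[1]
    N = sums[:, 8]
    yb, mb, xb = sums[:, 0] / N, sums[:, 1] / N, sums[:, 2] / N
    smm = sums[:, 3] / N - mb * mb
    sxx = sums[:, 4] / N - xb * xb
    smx = sums[:, 5] / N - mb * xb
    smy = sums[:, 6] / N - mb * yb
    sxy = sums[:, 7] / N - xb * yb
    det = smm * sxx - smx * smx
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (smy * sxx - sxy * smx) / det
    bad |= (det <= _SXX_TINY * np.maximum(smm * sxx, 1e-300)) | ~np.isfinite(b)
    a1 = slopes["ref"]
    a3 = slopes["foc"] - slopes["ref"]
    return a1, a3, b, bad


def _single_pooled_boot(rng, data, coding, B):
    """Bootstrap under the single-group model with pooled (unstratified)
    resampling: replicate group sizes vary; replicates missing a group or with
    a degenerate within-group design are redrawn."""
    x, m, y = data.x, data.m, data.y
    gfl = (data.group == coding.focal).astype(float)
    N = len(x)

    def compute(idx):
        xs, ms, ys, gs = x[idx], m[idx], y[idx], gfl[idx]
        out = {}
        bad = np.zeros(idx.shape[0], dtype=bool)
        for lab, w in (("ref", 1.0 - gs), ("foc", gs)):
            nw = w.sum(axis=1)
            bad |= nw < 2
            with np.errstate(divide="ignore", invalid="ignore"):
                xbar = (w * xs).sum(axis=1) / nw
                mbar = (w * ms).sum(axis=1) / nw
                sxx = (w * xs * xs).sum(axis=1) / nw - xbar * xbar
                sxm = (w * xs * ms).sum(axis=1) / nw - xbar * mbar
                s = sxm / sxx
            bad |= (sxx <= _SXX_TINY) | ~np.isfinite(s)
            out[lab] = s
        b, _, bad_y = _two_pred(ms, xs, ys)
        bad |= bad_y
        return out["ref"], out["foc"] - out["ref"], b, bad

    idx = rng.integers(0, N, size=(B, N))
    a1, a3, b, bad = compute(idx)
    rounds = 0
    while bad.any() and rounds < _MAX_REDRAW:
        idx[bad] = rng.integers(0, N, size=(int(bad.sum()), N))
        a1, a3, b, bad = compute(idx)
        rounds += 1
    return a1, a3, b, bad


def _finalize_draws(values, bad, B, provenance, pe, target, approach, seed_repr):
    flags = []
    values = values[~bad]
    n_dropped = int(bad.sum())
    if n_dropped > 0.10 * B:
        raise EstimationError(
            f"{n_dropped}/{B} bootstrap replicates had degenerate designs"
        )
    if n_dropped > 0.01 * B:
        flags.append("high_drop_rate")
        warnings.warn(
            f"{n_dropped}/{B} bootstrap replicates dropped after redraws",
            stacklevel=3,
        )
    return DrawSet(
        values=values,
        provenance=provenance,
        point_estimate=pe,
        target=target,
        approach=approach,
        n_requested=B,
        n_dropped=n_dropped,
        seed=seed_repr,
        flags=tuple(flags),
    )


def bootstrap_draw_sets(
    data: MediationDataset,
    targets: tuple[str, ...],
    approach: str = "multi",
    B: int = 1000,
    seed=None,
    resampling: str = "stratified",
    coding: GroupCoding | None = None,
    order: tuple[str, str] | None = None,
) -> dict[str, DrawSet]:
    """Bootstrap replicate estimates for several estimands sharing one set of
    resamples (the convention when percentile and bias-corrected intervals for
    several targets are reported together).

    Targets are group labels (simple indirect effects) and/or ``"difference"``.
    Resampling is stratified by group by default — group sizes are held fixed,
    matching the multi-group scheme; ``resampling="pooled"`` resamples rows
    from the pooled single-group data instead (single-group approach only).
    Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if approach not in ("single", "multi"):
        raise ValueError(f"unknown approach {approach!r}")
    if resampling not in ("stratified", "pooled"):
        raise ValueError(f"unknown resampling {resampling!r}")
    if approach == "multi" and resampling == "pooled":
        raise ValueError("multi-group bootstrap is always stratified")
    coding = coding or data.default_coding()
    order = order or data.labels
    for t in targets:
        if t != DIFFERENCE and t not in data.labels:
            raise DataError(f"unknown target {t!r}")
    rng = np.random.default_rng(seed)
    seed_repr = repr(seed)

    if approach == "single":
        fit = fit_single_group(data, coding)
        eff = simple_indirect_effects(fit)
        if resampling == "stratified":
            a1, a3, b, bad = _single_stratified_boot(rng, data, coding, B)
        else:
            a1, a3, b, bad = _single_pooled_boot(rng, data, coding, B)
        raw = {
            coding.reference: a1 * b,
            coding.focal: (a1 + a3) * b,
            DIFFERENCE: a3 * b,
        }
        return {
            t: _finalize_draws(
                raw[t], bad, B, "bootstrap",
                eff.by_group.get(t, eff.difference) if t != DIFFERENCE else eff.difference,
                t, "single", seed_repr,
            )
            for t in targets
        }

    # multi-group: resample only the groups the targets require
    fit = fit_multi_group(data, order=order)
    eff = simple_indirect_effects(fit)
    need = set()
    for t in targets:
        need.update(order if t == DIFFERENCE else (t,))
    paths = {}
    bad = np.zeros(B, dtype=bool)
    for lab in order:
        if lab in need:
            x, m, y = data.arrays(lab)
            a, b, bd = _group_boot_paths(rng, x, m, y, B)
            paths[lab] = a * b
            bad |= bd
    out = {}
    for t in targets:
        if t == DIFFERENCE:
            vals = paths[order[0]] - paths[order[1]]
            pe = eff.difference
        else:
            vals = paths[t]
            pe = eff.by_group[t]
        out[t] = _finalize_draws(vals, bad, B, "bootstrap", pe, t, "multi", seed_repr)
    return out


def bootstrap_draws(
    data: MediationDataset,
    target: str,
    approach: str = "multi",
    B: int = 1000,
    seed=None,
    resampling: str = "stratified",
    coding: GroupCoding | None = None,
    order: tuple[str, str] | None = None,
) -> DrawSet:
    """Bootstrap replicate estimates of one estimand (see
    :func:`bootstrap_draw_sets`)."""
    return bootstrap_draw_sets(
        data, (target,), approach=approach, B=B, seed=seed,
        resampling=resampling, coding=coding, order=order,
    )[target]


# ---------------------------------------------------------------------------
# Monte Carlo draws
# ---------------------------------------------------------------------------


def monte_carlo_draws(
    fit: MultiGroupFit, R: int = 1000, seed=None
) -> dict[str, DrawSet]:
    """Monte Carlo replicate estimates from the asymptotic normal of the paths.

    Draws (a_G1+, b_G1+, a_G2+, b_G2+) from the multivariate normal centered
    at the estimates with diagonal covariance diag(se_a1^2, se_b1^2, se_a2^2,
    se_b2^2): the within-group cov(a, b) is zero (the two coefficients come
    from separate equations) and the cross-group covariance is zero (the
    samples are independent). Returns draw sets for both simple indirect
    effects and their difference. Deterministic given ``seed``.
    """
    if fit.constraints:
        raise EstimationError("monte_carlo_draws requires an unconstrained fit")
    l1, l2 = fit.order
    point = np.array([fit.a(l1), fit.b(l1), fit.a(l2), fit.b(l2)])
    ses = np.array([fit.se_a(l1), fit.se_b(l1), fit.se_a(l2), fit.se_b(l2)])
    if not np.all(np.isfinite(ses)) or np.any(ses < 0.0):
        raise EstimationError(f"invalid standard errors {ses}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((R, 4))
    draws = point + z * ses
    ind1 = draws[:, 0] * draws[:, 1]
    ind2 = draws[:, 2] * draws[:, 3]
    eff = simple_indirect_effects(fit)
    seed_repr = repr(seed)

    def mk(vals, target, pe):
        return DrawSet(
            values=vals,
            provenance="monte_carlo",
            point_estimate=pe,
            target=target,
            approach="multi",
            n_requested=R,
            n_dropped=0,
            seed=seed_repr,
        )

    return {
        l1: mk(ind1, l1, eff.by_group[l1]),
        l2: mk(ind2, l2, eff.by_group[l2]),
        DIFFERENCE: mk(ind1 - ind2, DIFFERENCE, eff.difference),
    }


# ---------------------------------------------------------------------------
# interval construction
# ---------------------------------------------------------------------------


def _quantile_indices(B: int, p_lo: float, p_hi: float) -> tuple[int, int]:
    # symmetric order-statistic rule: floor((B+1)p) from below, ceil from above
    k_lo = min(max(int(math.floor((B + 1) * p_lo)), 1), B)
    k_hi = min(max(int(math.ceil((B + 1) * p_hi)), 1), B)
    return k_lo, k_hi


def _method_tag(draws: DrawSet, kind: str) -> str:
    if draws.provenance == "monte_carlo" and kind == "PC":
        kind = "MC"
    scope = "diff" if draws.target == DIFFERENCE else "ind"
    suffix = "S" if draws.approach == "single" else "M"
    return f"{kind}{scope}{suffix}"


def percentile_ci(draws: DrawSet, level: float = 0.95) -> IntervalEstimate:
    """Percentile interval: empirical alpha/2 and 1-alpha/2 quantiles of the
    replicate estimates, by the order-statistic rule at floor/ceil((B+1)p)."""
    B = draws.n_draws
    if B < 100:
        raise ValueError("need at least 100 draws")
    alpha = 1.0 - level
    k_lo, k_hi = _quantile_indices(B, alpha / 2.0, 1.0 - alpha / 2.0)
    s = np.sort(draws.values)
    return IntervalEstimate(
        method=_method_tag(draws, "PC"),
        target=draws.target,
        lower=float(s[k_lo - 1]),
        upper=float(s[k_hi - 1]),
        level=level,
        n_draws=B,
        seed=draws.seed,
    )


def bc_ci(draws: DrawSet, level: float = 0.95) -> IntervalEstimate:
    """Bias-corrected bootstrap interval.

    z0 = Phi^-1(proportion of replicates below the point estimate), with
    replicates exactly equal to the point estimate counting half; the
    percentile levels are shifted to Phi(2 z0 + z_{alpha/2}) and
    Phi(2 z0 + z_{1-alpha/2}) and read off with the same order-statistic
    rule as :func:`percentile_ci`. A proportion of 0 or 1 is clamped to
    1/(2B) (resp. 1 - 1/(2B)) and flagged.
    """
    B = draws.n_draws
    if B < 100:
        raise ValueError("need at least 100 draws")
    alpha = 1.0 - level
    pe = draws.point_estimate
    below = float(np.sum(draws.values < pe) + 0.5 * np.sum(draws.values == pe))
    prop = below / B
    flags = []
    if prop <= 0.0 or prop >= 1.0:
        prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
        flags.append("z0_clamped")
    z0 = stats.norm.ppf(prop)
    p_lo = float(stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2.0)))
    p_hi = float(stats.norm.cdf(2 * z0 + stats.norm.ppf(1.0 - alpha / 2.0)))
    k_lo, k_hi = _quantile_indices(B, p_lo, p_hi)
    s = np.sort(draws.values)
    return IntervalEstimate(
        method=_method_tag(draws, "BC"),
        target=draws.target,
        lower=float(s[k_lo - 1]),
        upper=float(s[k_hi - 1]),
        level=level,
        n_draws=B,
        seed=draws.seed,
        flags=tuple(flags),
    )


def ci_excludes_zero(interval: IntervalEstimate) -> bool:
    """True iff the closed interval does not contain zero (boundary covers)."""
    return interval.lower > 0.0 or interval.upper < 0.0
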