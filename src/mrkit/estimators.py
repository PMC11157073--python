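"""Causal-effect estimators for two-sample MR on summary statistics.

Five estimators operate on a harmonized instrument set of per-SNP exposure
effects gamma_j (se sigma_Xj) and outcome effects Gamma_j (se sigma_Yj):

* inverse-variance weighted (IVW): weighted regression of Gamma on gamma
  through the origin with weights 1/sigma_Yj^2 — the primary analysis;
* MR-Egger: the same regression with a free intercept; a nonzero intercept
  indicates directional pleiotropy and the slope is pleiotropy-adjusted;
* weighted median: the 50% weighted quantile of the per-SNP Wald ratios,
  consistent when up to half the weight lies on invalid instruments;
* simple and weighted mode: the argmax of a normal-kernel density over the
  Wald ratios, consistent when the largest group of instruments is valid.

The estimators are written in the scikit-learn idiom: construct with
hyper-parameters, call ``fit(X, y, x_se=..., y_se=...)`` where ``X`` holds
the SNP-exposure effects and ``y`` the SNP-outcome effects, then read the
fitted ``effect_``, ``se_``, ``pvalue_`` attributes (or ``estimate_`` for a
packaged :class:`~mrkit.datatypes.MREstimate`). ``fit_set`` accepts a
:class:`~mrkit.datatypes.HarmonizedInstrumentSet` directly. Module-level
functions (:func:`ivw`, :func:`egger`, ...) are thin wrappers.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import HarmonizedInstrumentSet, MREstimate
from .exceptions import ConfigurationError, InputError, InsufficientInstrumentsError

log = logging.getLogger("mrkit.estimators")

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _as_1d(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2 and a.shape[1] == 1:
        a = a[:, 0]
    if a.ndim != 1:
        raise InputError(f"{name} must be 1-d (or a single-column 2-d array)")
    return a


def _validate_inputs(X, y, x_se, y_se, min_n: int, method: str):
    g = _as_1d(X, "X")
    G = _as_1d(y, "y")
    if y_se is None:
        raise InputError(f"{method}: outcome standard errors (y_se) are required")
    sy = _as_1d(y_se, "y_se")
    sx = _as_1d(x_se, "x_se") if x_se is not None else np.zeros_like(g)
    n = g.size
    if not (G.size == sy.size == sx.size == n):
        raise InputError(f"{method}: input arrays have mismatched lengths")
    if np.any(sy <= 0) or (x_se is not None and np.any(sx <= 0)):
        raise InputError(f"{method}: standard errors must be > 0")
    if n < min_n:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {min_n} instruments, got {n}"
        )
    return g, G, sx, sy


def wald_ratio(gamma: float, sigma_x: float, Gamma: float, sigma_y: float) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order se sigma_Y/|gamma|."""
    if gamma == 0:
        raise InputError("Wald ratio undefined for gamma = 0")
    if sigma_y <= 0 or sigma_x <= 0:
        raise InputError("standard errors must be > 0")
    theta = Gamma / gamma
    se = sigma_y / abs(gamma)
    return MREstimate.build("wald_ratio", theta, se, n_snps=1)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Interpolated weighted quantile using cumulative-midpoint positions."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    mid = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, mid, v))


def _golden_section_max(fun, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Deterministic golden-section search for the maximum of fun on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol * max(1.0, abs(a) + abs(b)):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


class _BaseMREstimator(BaseEstimator):
    """Shared fit plumbing for the summary-data MR estimators."""

    method: str = ""
    min_instruments: int = 1

    def fit_set(self, hset: HarmonizedInstrumentSet):
        """Fit from a harmonized instrument set."""
        return self.fit(
            hset.beta_exposure,
            hset.beta_outcome,
            x_se=hset.se_exposure,
            y_se=hset.se_outcome,
        )

    def _package(self, *, pvalue=None, df=None, extra=None) -> None:
        self.pvalue_: float
        est = MREstimate.build(
            self.method,
            self.effect_,
            self.se_,
            self.n_snps_,
            pvalue=pvalue,
            df=df,
            extra=extra,
        )
        self.pvalue_ = est.pvalue
        self.ci_ = (est.ci_low, est.ci_high)
        self.estimate_ = est


class IVWEstimator(_BaseMREstimator):
    """Inverse-variance weighted estimator (the primary analysis).

    theta_hat = sum(w gamma Gamma) / sum(w gamma^2) with w = 1/sigma_Y^2,
    i.e. weighted least squares of Gamma on gamma through the origin. The
    fixed-effect se is (sum w gamma^2)^(-1/2); the default multiplicative
    random-effects model scales it by max(1, sqrt(Q/(J-1))) to absorb
    heterogeneity without changing the point estimate. A single instrument
    collapses exactly to the Wald ratio.

    Parameters
    ----------
    effects_model : {"multiplicative_random", "fixed"}
    """

    method = "ivw"
    min_instruments = 1

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def fit(self, X, y, x_se=None, y_se=None):
        if self.effects_model not in ("fixed", "multiplicative_random"):
            raise ConfigurationError(
                f"unknown effects_model {self.effects_model!r}"
            )
        g, G, sx, sy = _validate_inputs(X, y, x_se, y_se, self.min_instruments, self.method)
        J = g.size
        model = self.effects_model
        if J == 1:
            if model == "multiplicative_random":
                log.warning("IVW with one SNP: falling back to fixed effects")
                model = "fixed"
            if g[0] == 0:
                raise InputError("IVW undefined: single instrument with gamma = 0")
            # exact Wald-ratio collapse, bit-for-bit
            theta = G[0] / g[0]
            se = sy[0] / abs(g[0])
            q = 0.0
        else:
            w = 1.0 / sy**2
            denom = float(np.sum(w * g * g))
            if denom == 0:
                raise InputError("IVW undefined: all gamma are zero")
            theta = float(np.sum(w * g * G)) / denom
            se = denom**-0.5
            q = float(np.sum(w * (G - theta * g) ** 2))
            if model == "multiplicative_random":
                se *= max(1.0, math.sqrt(q / (J - 1)))
        self.effect_ = float(theta)
        self.se_ = float(se)
        self.q_ = q
        self.n_snps_ = J
        self._package(extra={"effects_model": model, "q": q})
        return self


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    Each SNP is first oriented so gamma_j >= 0 (joint sign flip of gamma and
    Gamma), which makes the intercept interpretable as the average directional
    pleiotropic effect. Weights are 1/sigma_Y^2; both coefficient variances
    are inflated multiplicatively by max(1, RSS_w/(J-2)) and p-values use a
    t distribution with J-2 degrees of freedom. Requires J >= 3.
    """

    method = "egger"
    min_instruments = 3

    def fit(self, X, y, x_se=None, y_se=None):
        g, G, sx, sy = _validate_inputs(X, y, x_se, y_se, self.min_instruments, self.method)
        J = g.size
        flip = np.where(g < 0, -1.0, 1.0)
        x = flip * g
        yy = flip * G
        w = 1.0 / sy**2
        sw = float(np.sum(w))
        swx = float(np.sum(w * x))
        swxx = float(np.sum(w * x * x))
        swy = float(np.sum(w * yy))
        swxy = float(np.sum(w * x * yy))
        xtwx = np.array([[sw, swx], [swx, swxx]])
        xtwy = np.array([swy, swxy])
        det = sw * swxx - swx * swx
        if det <= 0 or not np.isfinite(det):
            raise InputError("Egger regression is singular (no spread in gamma)")
        intercept, slope = np.linalg.solve(xtwx, xtwy)
        resid = yy - intercept - slope * x
        rss = float(np.sum(w * resid**2))
        df = J - 2
        phi = max(1.0, rss / df)
        cov = phi * np.linalg.inv(xtwx)
        se_int = math.sqrt(cov[0, 0])
        se_slope = math.sqrt(cov[1, 1])
        self.effect_ = float(slope)
        self.se_ = float(se_slope)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pvalue_ = float(2 * stats.t.sf(abs(intercept) / se_int, df))
        self.df_ = df
        self.n_snps_ = J
        self._package(
            df=df,
            extra={
                "intercept": self.intercept_,
                "intercept_se": self.intercept_se_,
                "intercept_pvalue": self.intercept_pvalue_,
                "residual_inflation": phi,
            },
        )
        return self


def _ratio_inputs(g, G, sy, method: str):
    if np.any(g == 0):
        raise InputError(f"{method}: per-SNP ratio undefined for gamma = 0")
    ratios = G / g
    ratio_se = sy / np.abs(g)
    return ratios, ratio_se


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted median of the per-SNP Wald ratios.

    Weights are proportional to the inverse-variance of each ratio
    (normalized to sum one); the estimate interpolates the ordered ratios at
    cumulative-midpoint position 0.5. The standard error comes from a
    parametric bootstrap that resamples gamma_j and Gamma_j from normals
    centered on the observed effects. Requires J >= 3 and an explicit seed
    for reproducibility.
    """

    method = "weighted_median"
    min_instruments = 3

    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, x_se=None, y_se=None):
        g, G, sx, sy = _validate_inputs(X, y, x_se, y_se, self.min_instruments, self.method)
        ratios, ratio_se = _ratio_inputs(g, G, sy, self.method)
        weights = 1.0 / ratio_se**2
        theta = _weighted_quantile(ratios, weights, 0.5)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            gb = g + sx * rng.standard_normal(g.size)
            Gb = G + sy * rng.standard_normal(g.size)
            ok = gb != 0
            rb = Gb[ok] / gb[ok]
            wb = (np.abs(gb[ok]) / sy[ok]) ** 2
            boots[b] = _weighted_quantile(rb, wb, 0.5)
        se = float(np.std(boots, ddof=1))
        self.effect_ = float(theta)
        self.se_ = se
        self.n_snps_ = g.size
        self._package(extra={"n_boot": self.n_boot, "seed": self.random_state})
        return self


class ModeEstimator(_BaseMREstimator):
    """Mode-based estimate: argmax of a kernel density over the Wald ratios.

    ``weighted=False`` gives the simple mode (uniform weights);
    ``weighted=True`` weights each ratio by its inverse variance. The normal
    kernel bandwidth is ``phi * 0.9 * s * J^(-1/5)`` with
    ``s = min(sd, mad/0.6745)`` the robust spread of the ratios. The density
    is evaluated on a fixed 512-point grid spanning the ratios +/- 3
    bandwidths and the winning cell is refined by golden-section search, so
    the argmax is deterministic. Bootstrap se as for the weighted median.
    """

    min_instruments = 3

    def __init__(
        self,
        weighted: bool = True,
        phi: float = 1.0,
        n_boot: int = 1000,
        random_state: int = 0,
    ):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self) -> str:  # type: ignore[override]
        return "weighted_mode" if self.weighted else "simple_mode"

    def _bandwidth(self, ratios: np.ndarray) -> float:
        J = ratios.size
        sd = float(np.std(ratios, ddof=1))
        mad = float(np.median(np.abs(ratios - np.median(ratios))))
        s = min(sd, mad / 0.6745)
        return self.phi * 0.9 * s * J ** (-1.0 / 5.0)

    def _mode(self, ratios: np.ndarray, weights: np.ndarray) -> float:
        h = self._bandwidth(ratios)
        if not np.isfinite(h) or h <= 0:
            # all ratios (essentially) identical: the mode is that point mass
            return float(np.median(ratios))
        w = weights / weights.sum()

        def density(x):
            z = (np.asarray(x)[..., None] - ratios[None, :]) / h
            return (w[None, :] * np.exp(-0.5 * z**2)).sum(axis=-1)

        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = density(grid)
        i = int(np.argmax(dens))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        return _golden_section_max(lambda x: float(density(np.array([x]))[0]), lo, hi)

    def fit(self, X, y, x_se=None, y_se=None):
        g, G, sx, sy = _validate_inputs(X, y, x_se, y_se, self.min_instruments, self.method)
        ratios, ratio_se = _ratio_inputs(g, G, sy, self.method)
        weights = (
            1.0 / ratio_se**2 if self.weighted else np.ones_like(ratios)
        )
        theta = self._mode(ratios, weights)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            gb = g + sx * rng.standard_normal(g.size)
            Gb = G + sy * rng.standard_normal(g.size)
            ok = gb != 0
            rb = Gb[ok] / gb[ok]
            wb = (np.abs(gb[ok]) / sy[ok]) ** 2 if self.weighted else np.ones(ok.sum())
            boots[b] = self._mode(rb, wb)
        se = float(np.std(boots, ddof=1))
        self.effect_ = float(theta)
        self.se_ = se
        self.n_snps_ = g.size
        self._package(
            extra={
                "phi": self.phi,
                "n_boot": self.n_boot,
                "seed": self.random_state,
                "weighted": self.weighted,
            }
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def ivw(hset: HarmonizedInstrumentSet, effects_model: str = "multiplicative_random") -> MREstimate:
    return IVWEstimator(effects_model=effects_model).fit_set(hset).estimate_


def egger(hset: HarmonizedInstrumentSet) -> MREstimate:
    return EggerRegression().fit_set(hset).estimate_


def weighted_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    return (
        WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit_set(hset).estimate_
    )


def mode_estimate(
    hset: HarmonizedInstrumentSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    return (
        ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot, random_state=seed)
        .fit_set(hset)
        .estimate_
    )


#: Fixed method order for run_all_methods.
METHOD_ORDER = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


def run_all_methods(
    hset: HarmonizedInstrumentSet,
    *,
    effects_model: str = "multiplicative_random",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[list[MREstimate], list[dict]]:
    """Run every estimator whose instrument minimum is met, in fixed order.

    Returns (estimates, skipped) where ``skipped`` holds one record per
    method that could not run (too few instruments), rather than raising.
    Bootstrap seeds for the median/mode estimators are derived from ``seed``
    by fixed stream indices, so results are reproducible per method.
    """
    ss = np.random.SeedSequence(seed)
    child = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
             zip(METHOD_ORDER, ss.spawn(len(METHOD_ORDER)))}
    factories = {
        "ivw": lambda: IVWEstimator(effects_model=effects_model),
        "egger": EggerRegression,
        "weighted_median": lambda: WeightedMedianEstimator(
            n_boot=n_boot, random_state=child["weighted_median"]
        ),
        "simple_mode": lambda: ModeEstimator(
            weighted=False, phi=phi, n_boot=n_boot, random_state=child["simple_mode"]
        ),
        "weighted_mode": lambda: ModeEstimator(
            weighted=True, phi=phi, n_boot=n_boot, random_state=child["weighted_mode"]
        ),
    }
    estimates: list[MREstimate] = []
    skipped: list[dict] = []
    for name in METHOD_ORDER:
        est = factories[name]()
        if hset.n_snps < est.min_instruments:
            skipped.append(
                {
                    "method": name,
                    "reason": f"needs >= {est.min_instruments} instruments, have {hset.n_snps}",
                }
            )
            continue
        estimates.append(est.fit_set(hset).estimate_)
    return estimates, skipped
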