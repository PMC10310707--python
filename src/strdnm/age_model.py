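"""Latent-phase Poisson model of parental age effects on mDNM counts.

Each trio t contributes y_P paternally phased, y_M maternally phased and
y_U unphased de novo events, with parental ages at conception A_P and A_M
and m_t markers available for detection.  The true paternal count y*_P is
latent — it lies between y_P and y_P + y_U — and the likelihood sums the
product of two Poisson masses over all allocations of the unphased events:

    L_t = sum_{y*_P = y_P}^{y_P + y_U} f(y_T - y*_P; mu_M,t) f(y*_P; mu_P,t)

with identity-link means mu_P,t = (alpha_P + beta_P A_P,t) e_t and
mu_M,t = (alpha_M + beta_M A_M,t) e_t, where the exposure e_t = m_t / Mbar
(Mbar the cohort mean of m_t) absorbs variable marker availability.  The
identity link makes beta the additive number of extra mutations per year
of parental age on the mean-availability scale; multiplying by
M_total / Mbar converts it to a genome-wide per-year effect.

The latent sum is unweighted (each allocation of unphased events counts
once); an optional binomially weighted variant is provided for comparison
via ``weighted=True`` but is not the default.

Significance of each age slope is assessed by a likelihood-ratio test
against the nested model with that slope fixed to zero (chi-square, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

TOTAL_MICROSATELLITES = 1_394_292

PARAM_NAMES = ("alpha_p", "beta_p", "alpha_m", "beta_m")
_MIN_MEAN = 1e-12


class InvalidMeanError(ValueError):
    """A parameter vector gives a non-positive Poisson mean for some trio."""


@dataclass
class _Prepared:
    """Flattened latent-sum arrays for fast repeated likelihood evaluation."""

    age_p: np.ndarray
    age_m: np.ndarray
    exposure: np.ndarray
    y_t: np.ndarray
    starts: np.ndarray        # segment starts into the flat arrays
    seg: np.ndarray           # trio index of each flat element
    k: np.ndarray             # candidate paternal count y*_P per element
    log_weight: np.ndarray    # 0, or log C(y_U, k - y_P) if weighted
    mbar: float
    n: int


def _prepare(data: pd.DataFrame, use_exposure: bool = True, weighted: bool = False) -> _Prepared:
    y_p = data["y_p"].to_numpy(dtype=int)
    y_m = data["y_m"].to_numpy(dtype=int)
    y_u = data["y_u"].to_numpy(dtype=int)
    if (y_p < 0).any() or (y_m < 0).any() or (y_u < 0).any():
        raise ValueError("counts must be non-negative")
    age_p = data["father_age"].to_numpy(dtype=float)
    age_m = data["mother_age"].to_numpy(dtype=float)
    if ((age_p <= 12) | (age_p >= 80) | (age_m <= 12) | (age_m >= 80)).any():
        raise ValueError("parental ages outside the plausible (12, 80) range")
    if use_exposure and "m_t" in data.columns:
        m_t = data["m_t"].to_numpy(dtype=float)
        mbar = float(m_t.mean())
        exposure = m_t / mbar
    else:
        mbar = float(data["m_t"].mean()) if "m_t" in data.columns else 1.0
        exposure = np.ones(len(y_p))
    y_t = y_p + y_m + y_u
    lengths = y_u + 1
    n = len(y_p)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    total = int(lengths.sum())
    seg = np.repeat(np.arange(n), lengths)
    k = np.arange(total) - starts[seg] + y_p[seg]
    if weighted:
        log_weight = (
            special.gammaln(y_u[seg] + 1)
            - special.gammaln(k - y_p[seg] + 1)
            - special.gammaln(y_u[seg] - (k - y_p[seg]) + 1)
        )
    else:
        log_weight = np.zeros(total)
    return _Prepared(age_p, age_m, exposure, y_t, starts, seg, k, log_weight, mbar, n)


def _means(params: np.ndarray, prep: _Prepared) -> tuple[np.ndarray, np.ndarray]:
    a_p, b_p, a_m, b_m = params
    mu_p = (a_p + b_p * prep.age_p) * prep.exposure
    mu_m = (a_m + b_m * prep.age_m) * prep.exposure
    return mu_p, mu_m


def _loglik_terms(params: np.ndarray, prep: _Prepared):
    mu_p, mu_m = _means(params, prep)
    if (mu_p <= _MIN_MEAN).any() or (mu_m <= _MIN_MEAN).any():
        return None
    mu_p_f = mu_p[prep.seg]
    mu_m_f = mu_m[prep.seg]
    k = prep.k
    j = prep.y_t[prep.seg] - k
    a = (
        k * np.log(mu_p_f)
        - mu_p_f
        - special.gammaln(k + 1)
        + j * np.log(mu_m_f)
        - mu_m_f
        - special.gammaln(j + 1)
        + prep.log_weight
    )
    m = np.maximum.reduceat(a, prep.starts)
    sums = np.add.reduceat(np.exp(a - m[prep.seg]), prep.starts)
    ll_t = m + np.log(sums)
    return ll_t, a, mu_p, mu_m, mu_p_f, mu_m_f


def loglik(params, data: pd.DataFrame | _Prepared, use_exposure: bool = True,
           weighted: bool = False) -> float:
    """Log-likelihood of the latent-phase model at ``params``.

    ``params`` is (alpha_P, beta_P, alpha_M, beta_M).  Raises
    :class:`InvalidMeanError` if any trio's mean is non-positive — a
    parameter-domain failure, distinct from numerical underflow (which the
    log-space accumulation avoids).
    """
    prep = data if isinstance(data, _Prepared) else _prepare(data, use_exposure, weighted)
    params = np.asarray(params, dtype=float)
    terms = _loglik_terms(params, prep)
    if terms is None:
        raise InvalidMeanError("non-positive Poisson mean for at least one trio")
    return float(terms[0].sum())


def _nll_and_grad(free: np.ndarray, prep: _Prepared, mask: np.ndarray,
                  fixed: np.ndarray) -> tuple[float, np.ndarray]:
    params = fixed.copy()
    params[mask] = free
    terms = _loglik_terms(params, prep)
    if terms is None:
        # smooth pushback toward the feasible region
        a_p, b_p, a_m, b_m = params
        viol_p = np.minimum(a_p + b_p * prep.age_p - 1e-6, 0.0)
        viol_m = np.minimum(a_m + b_m * prep.age_m - 1e-6, 0.0)
        pen = float((viol_p**2).sum() + (viol_m**2).sum())
        g = np.array(
            [
                2 * viol_p.sum(),
                2 * (viol_p * prep.age_p).sum(),
                2 * viol_m.sum(),
                2 * (viol_m * prep.age_m).sum(),
            ]
        )
        return 1e10 + pen, g[mask]
    ll_t, a, mu_p, mu_m, mu_p_f, mu_m_f = terms
    w = np.exp(a - ll_t[prep.seg])
    k = prep.k
    j = prep.y_t[prep.seg] - k
    gp_elem = w * (k / mu_p_f - 1.0)
    gm_elem = w * (j / mu_m_f - 1.0)
    gp = np.add.reduceat(gp_elem, prep.starts) * prep.exposure
    gm = np.add.reduceat(gm_elem, prep.starts) * prep.exposure
    grad = np.array(
        [gp.sum(), (gp * prep.age_p).sum(), gm.sum(), (gm * prep.age_m).sum()]
    )
    return -float(ll_t.sum()), -grad[mask]


def _starting_grid(prep: _Prepared) -> list[np.ndarray]:
    """Multi-start grid: intercepts at {0.5, 1, 2}x the (unphased-inflated)
    phased-count means, slopes at 0 and a crude per-parent regression slope."""
    # phased counts are the segment-start k values; unphased count from span
    y_p = prep.k[prep.starts]
    spans = np.diff(np.append(prep.starts, len(prep.k))) - 1  # = y_u
    y_m = prep.y_t - y_p - spans
    phased = y_p + y_m
    inflate = prep.y_t.sum() / max(phased.sum(), 1)
    m_p = max(float(y_p.mean()) * inflate, 0.1)
    m_m = max(float(y_m.mean()) * inflate, 0.1)
    sl_p = float(np.polyfit(prep.age_p, y_p * inflate / prep.exposure, 1)[0])
    sl_m = float(np.polyfit(prep.age_m, y_m * inflate / prep.exposure, 1)[0])
    starts = []
    for f in (0.5, 1.0, 2.0):
        for bp, bm in ((0.0, 0.0), (sl_p, sl_m)):
            a_p = f * m_p - bp * prep.age_p.mean()
            a_m = f * m_m - bm * prep.age_m.mean()
            starts.append(np.array([a_p, bp, a_m, bm]))
    return starts


def _numerical_hessian(params: np.ndarray, prep: _Prepared, mask: np.ndarray,
                       fixed: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the log-likelihood from the analytic gradient."""
    free = params[mask]
    p = free.size
    hess = np.zeros((p, p))
    for i in range(p):
        h = step * max(1.0, abs(free[i]))
        up, dn = free.copy(), free.copy()
        up[i] += h
        dn[i] -= h
        _, g_up = _nll_and_grad(up, prep, mask, fixed)
        _, g_dn = _nll_and_grad(dn, prep, mask, fixed)
        hess[i] = -(g_up - g_dn) / (2 * h)  # of +loglik
    return (hess + hess.T) / 2


@dataclass
class AgeModelFit:
    """Maximum-likelihood fit of the latent-phase age model."""

    params: dict[str, float]
    loglik: float
    cov: np.ndarray | None
    conf_int: dict[str, tuple[float, float]]
    mbar: float
    n_trios: int
    converged: bool
    boundary: bool
    free_names: tuple[str, ...] = PARAM_NAMES
    lrt: dict[str, dict] = field(default_factory=dict)

    @property
    def params_array(self) -> np.ndarray:
        return np.array([self.params[p] for p in PARAM_NAMES])


def _fit(prep: _Prepared, fix: dict[str, float] | None = None,
         extra_starts: list[np.ndarray] | None = None,
         starts_override: list[np.ndarray] | None = None,
         gtol: float = 1e-7) -> AgeModelFit:
    fix = fix or {}
    mask = np.array([name not in fix for name in PARAM_NAMES])
    fixed = np.array([fix.get(name, 0.0) for name in PARAM_NAMES])
    if starts_override is not None:
        starts = starts_override
    else:
        starts = _starting_grid(prep) + (extra_starts or [])
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _nll_and_grad,
            np.asarray(s0, dtype=float)[mask],
            args=(prep, mask, fixed),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    # Nelder-Mead polish of the best candidate guards against line-search
    # stalls near the positivity boundary.
    res2 = optimize.minimize(
        lambda x: _nll_and_grad(x, prep, mask, fixed)[0],
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
    )
    if res2.fun < best.fun:
        best = res2
    if best is None or best.fun >= 1e9:
        raise RuntimeError("age-model optimization failed from all starting points")
    params = fixed.copy()
    params[mask] = best.x
    ll = -best.fun
    mu_p, mu_m = _means(params, prep)
    boundary = bool(min(mu_p.min(), mu_m.min()) < 1e-4)
    hess = _numerical_hessian(params, prep, mask, fixed)
    cov = None
    ci: dict[str, tuple[float, float]] = {}
    try:
        cov_free = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov_free), 0, None))
        cov = cov_free
        z = stats.norm.ppf(0.975)
        for i, name in enumerate(np.array(PARAM_NAMES)[mask]):
            est = params[PARAM_NAMES.index(name)]
            ci[name] = (est - z * se[i], est + z * se[i])
    except np.linalg.LinAlgError:
        pass
    return AgeModelFit(
        params=dict(zip(PARAM_NAMES, params)),
        loglik=ll,
        cov=cov,
        conf_int=ci,
        mbar=prep.mbar,
        n_trios=prep.n,
        converged=bool(best.fun < 1e9),
        boundary=boundary,
        free_names=tuple(np.array(PARAM_NAMES)[mask]),
    )


def fit_age_model(
    data: pd.DataFrame,
    use_exposure: bool = True,
    weighted: bool = False,
    fix: dict[str, float] | None = None,
    with_lrt: bool = False,
) -> AgeModelFit:
    """Fit the latent-phase Poisson age model by maximum likelihood.

    ``data`` columns: y_p, y_m, y_u, father_age, mother_age and optionally
    m_t (marker availability).  Wald CIs come from the numerical Hessian.
    With ``with_lrt`` the likelihood-ratio tests for both slopes are
    attached to the returned fit.
    """
    ages_p = data["father_age"].nunique()
    ages_m = data["mother_age"].nunique()
    if ages_p < 2 or ages_m < 2:
        raise ValueError("need at least two distinct ages per parent for identifiability")
    prep = _prepare(data, use_exposure, weighted)
    fit = _fit(prep, fix=fix)
    if with_lrt:
        for parent in ("p", "m"):
            fit.lrt[f"beta_{parent}"] = _lrt(prep, fit, f"beta_{parent}")
    return fit


def _lrt(prep: _Prepared, full: AgeModelFit, which: str) -> dict:
    nested = _fit(prep, fix={which: 0.0})
    # the nested optimum (with slope 0) is a valid full-model start, which
    # guarantees ll_full >= ll_nested up to optimizer tolerance
    refit = _fit(prep, starts_override=[nested.params_array, full.params_array])
    ll_full = max(full.loglik, refit.loglik)
    stat = 2.0 * (ll_full - nested.loglik)
    if stat < -1e-6:
        raise RuntimeError(f"nested log-likelihood exceeds full ({stat}): optimization failure")
    stat = max(stat, 0.0)
    return {"stat": stat, "p_value": float(stats.chi2.sf(stat, df=1))}


def lrt_age_effect(data: pd.DataFrame, which_parent: str,
                   use_exposure: bool = True) -> tuple[float, float]:
    """Chi-square LRT (1 df) for the paternal ('p') or maternal ('m') slope."""
    if which_parent not in ("p", "m"):
        raise ValueError("which_parent must be 'p' or 'm'")
    prep = _prepare(data, use_exposure)
    full = _fit(prep)
    out = _lrt(prep, full, f"beta_{which_parent}")
    return out["stat"], out["p_value"]


def scale_to_genomewide(coefficient: float, mbar: float,
                        m_total: int = TOTAL_MICROSATELLITES) -> float:
    """Convert a per-mean-availability coefficient to a genome-wide one.

    The fitted intercepts/slopes act on counts detectable at the cohort's
    mean of Mbar available markers; multiplying by M_total / Mbar
    interpolates to the full microsatellite census.
    """
    if mbar <= 0:
        raise ValueError("mean availability must be positive")
    return coefficient * (m_total / mbar)


def predict_genomewide(
    fit: AgeModelFit | dict[str, float],
    father_age: float,
    mother_age: float,
    mbar: float | None = None,
    m_total: int = TOTAL_MICROSATELLITES,
) -> dict[str, float]:
    """Expected genome-wide mDNM count for an offspring of given parent ages.

    (I_F + beta_F X + I_M + beta_M Y) / (Mbar / M_total), with the
    coefficients on the per-Mbar-markers scale.
    """
    if isinstance(fit, AgeModelFit):
        params = fit.params
        mbar = fit.mbar if mbar is None else mbar
    else:
        params = fit
    if mbar is None or mbar <= 0:
        raise ValueError("mbar required")
    if not (12 < father_age < 80 and 12 < mother_age < 80):
        import warnings

        warnings.warn("ages outside the observed range: extrapolating")
    scale = m_total / mbar
    paternal = (params["alpha_p"] + params["beta_p"] * father_age) * scale
    maternal = (params["alpha_m"] + params["beta_m"] * mother_age) * scale
    return {"paternal": paternal, "maternal": maternal, "total": paternal + maternal}


class AgeEffectModel:
    """Thin fit-style wrapper around :func:`fit_age_model`.

    Parameters mirror the function; after :meth:`fit` the results are
    available as ``params_``, ``loglik_``, ``conf_int_``, ``lrt_`` and
    ``mbar_``, and :meth:`predict` returns genome-wide expectations.
    """

    def __init__(self, use_exposure: bool = True, weighted: bool = False,
                 m_total: int = TOTAL_MICROSATELLITES):
        self.use_exposure = use_exposure
        self.weighted = weighted
        self.m_total = m_total

    def fit(self, data: pd.DataFrame, with_lrt: bool = True) -> "AgeEffectModel":
        res = fit_age_model(
            data, use_exposure=self.use_exposure, weighted=self.weighted, with_lrt=with_lrt
        )
        self.result_ = res
        self.params_ = res.params
        self.loglik_ = res.loglik
        self.conf_int_ = res.conf_int
        self.lrt_ = res.lrt
        self.mbar_ = res.mbar
        return self

    def predict(self, father_age, mother_age) -> dict[str, float]:
        return predict_genomewide(self.result_, father_age, mother_age, m_total=self.m_total)

    def genomewide_slopes(self) -> dict[str, float]:
        return {
            "paternal": scale_to_genomewide(self.params_["beta_p"], self.mbar_, self.m_total),
            "maternal": scale_to_genomewide(self.params_["beta_m"], self.mbar_, self.m_total),
        }
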