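"""Recinormal latency-distribution model with an optional early-saccade unit.

Saccadic latencies are modelled through their reciprocal ("promptness",
Hz): a main decision unit with rate ~ N(mu, sigma^2) races an early unit
with rate ~ N(0, sigma_e^2), and the observed promptness is the faster
(larger) of the two rates, conditioned on being positive.  Parameters are
estimated by minimising the one-sample Kolmogorov-Smirnov statistic, and
reciprobit coordinates are provided for diagnostic plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri


@dataclass(frozen=True)
class LATERFit:
    """Result of a KS-minimisation fit of the promptness distribution.

    Attributes
    ----------
    mu, sigma : float
        Mean and SD of the main unit's rate distribution (Hz).
    sigma_e : float
        SD of the zero-mean early unit (Hz); 0 when the early unit is
        disabled.
    ks : float
        Minimised one-sample KS sup-distance, in [0, 1].
    n : int
        Sample size used for the fit.
    converged : bool
        False when the local refinement failed to improve on the grid
        minimum or terminated on a parameter bound.
    """

    mu: float
    sigma: float
    sigma_e: float
    ks: float
    n: int
    converged: bool


class FitError(ValueError):
    """Raised when a promptness sample cannot support a fit."""


def race_cdf(p, mu: float, sigma: float, sigma_e: float = 0.0):
    """CDF of the observed promptness at value(s) ``p`` (Hz).

    The unconditional race CDF is ``G(p) = Phi((p - mu)/sigma) *
    Phi(p/sigma_e)``; the returned value is renormalised to condition on a
    positive outcome, ``F(p) = (G(p) - G(0)) / (1 - G(0))`` for ``p > 0``.
    With ``sigma_e = 0`` the early factor is an indicator and F reduces to
    the zero-truncated Gaussian CDF of the main unit.

    Parameters
    ----------
    p : array_like
        Promptness values; entries ``<= 0`` evaluate to 0.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if sigma_e < 0:
        raise ValueError(f"sigma_e must be >= 0, got {sigma_e}")
    p = np.asarray(p, dtype=float)
    main = ndtr((p - mu) / sigma)
    if sigma_e > 0:
        g = main * ndtr(p / sigma_e)
        g0 = ndtr(-mu / sigma) * 0.5
    else:
        g = main
        g0 = ndtr(-mu / sigma)
    out = np.where(p > 0, (g - g0) / (1.0 - g0), 0.0)
    return np.clip(out, 0.0, 1.0)


def ks_statistic(sample, cdf) -> float:
    """Exact one-sample KS sup-distance between ``sample`` and ``cdf``.

    Evaluates ``max(|F(p_i) - i/n|, |F(p_i) - (i-1)/n|)`` over the sorted
    sample, which attains the supremum of the D-statistic.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("sample must contain at least one value")
    f = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(np.maximum(np.abs(f - i / n), np.abs(f - (i - 1) / n)).max())


_DEFAULT_BOUNDS = {"mu": (1e-3, 20.0), "sigma": (1e-3, 10.0), "sigma_e": (0.0, 20.0)}


def _ks_of(sample_sorted, n, theta, with_early):
    mu, sigma = theta[0], theta[1]
    se = theta[2] if with_early else 0.0
    if sigma <= 0 or se < 0:
        return 2.0
    f = race_cdf(sample_sorted, mu, sigma, se)
    i = np.arange(1, n + 1)
    return float(np.maximum(np.abs(f - i / n), np.abs(f - (i - 1) / n)).max())


def fit_later(sample, with_early: bool = False, bounds: dict | None = None,
              grid_density: int = 25) -> LATERFit:
    """Fit (mu, sigma[, sigma_e]) by minimising the one-sample KS statistic.

    A coarse grid search over ``bounds`` locates the basin; a Nelder-Mead
    refinement polishes the best grid point.  Deterministic given inputs —
    no random restarts.

    Parameters
    ----------
    sample : array_like
        Promptness values (Hz), all positive.
    with_early : bool
        Include the zero-mean early unit (three-parameter fit).
    bounds : dict, optional
        Per-parameter ``(lo, hi)`` overrides for "mu", "sigma", "sigma_e".
    grid_density : int
        Grid points per dimension for the coarse search.

    Raises
    ------
    FitError
        If the sample is too small (n < 10 two-parameter, n < 20
        three-parameter) or degenerate (zero variance).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    n_min = 20 if with_early else 10
    if n < n_min:
        raise FitError(f"need at least {n_min} values for this fit, got {n}")
    if np.ptp(x) == 0:
        raise FitError("degenerate sample: all values identical")
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    mus = np.linspace(*b["mu"], grid_density)
    sigmas = np.linspace(*b["sigma"], grid_density)
    best_ks, best = np.inf, None
    if with_early:
        sigma_es = np.linspace(*b["sigma_e"], grid_density)
        for mu in mus:
            for sg in sigmas:
                for se in sigma_es:
                    ks = _ks_of(x, n, (mu, sg, se), True)
                    if ks < best_ks:
                        best_ks, best = ks, (mu, sg, se)
    else:
        for mu in mus:
            for sg in sigmas:
                ks = _ks_of(x, n, (mu, sg), False)
                if ks < best_ks:
                    best_ks, best = ks, (mu, sg)

    res = minimize(lambda t: _ks_of(x, n, t, with_early), np.asarray(best),
                   method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-4, "maxiter": 2000})
    theta = res.x if res.fun <= best_ks else np.asarray(best)
    ks = min(float(res.fun), best_ks)

    mu, sigma = float(theta[0]), float(theta[1])
    sigma_e = float(theta[2]) if with_early else 0.0
    on_bound = (
        not (b["mu"][0] < mu < b["mu"][1])
        or not (b["sigma"][0] < sigma < b["sigma"][1])
        or (with_early and sigma_e >= b["sigma_e"][1])
    )
    converged = (res.fun <= best_ks + 1e-12) and not on_bound
    return LATERFit(mu=mu, sigma=sigma, sigma_e=max(sigma_e, 0.0), ks=ks,
                    n=n, converged=bool(converged))


def reciprobit_coords(sample):
    """Reciprobit coordinates of a promptness sample.

    Returns an ``(n, 2)`` array of ``(x, y)`` points sorted by latency,
    where ``x = -1/latency`` in s^-1 (i.e. minus the promptness in Hz) and
    ``y`` is the probit of the empirical cumulative probability
    ``(i - 0.5)/n``.  A pure recinormal sample plots as a straight line.
    """
    p = np.asarray(sample, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 values for reciprobit coordinates")
    # sort by latency = 1/p ascending <=> promptness descending
    p_sorted = np.sort(p)[::-1]
    n = p.size
    x = -p_sorted  # -1/latency with latency in seconds
    y = ndtri((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([x, y])


def express_window_mass(mu: float, sigma: float, sigma_e: float,
                        window_ms=(80.0, 120.0), valid_ms=(80.0, 1000.0)) -> float:
    """Model probability of a latency in ``window_ms`` among valid latencies.

    Latency bounds map to promptness bounds via p = 1000/SRT; the mass in
    the express window is reported relative to the mass of the valid SRT
    window, matching the denominator used by trial classification.
    """
    lo, hi = 1000.0 / window_ms[1], 1000.0 / window_ms[0]
    vlo, vhi = 1000.0 / valid_ms[1], 1000.0 / valid_ms[0]
    num = race_cdf(hi, mu, sigma, sigma_e) - race_cdf(lo, mu, sigma, sigma_e)
    den = race_cdf(vhi, mu, sigma, sigma_e) - race_cdf(vlo, mu, sigma, sigma_e)
    return float(num / den) if den > 0 else float("nan")
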