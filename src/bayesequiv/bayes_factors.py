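"""Interval Bayes factors for the two-sample t-test.

Given the pooled t-statistic, its degrees of freedom nu and the effective
sample size n_delta = n1*n2/(n1+n2), the marginal likelihood of the data
under a prior pi(delta) is, up to a common factor,

    m(pi) = integral T_nu(t | sqrt(n_delta) * delta) pi(delta) d(delta),

where T_nu(t | a) is the noncentral-t density with noncentrality a.  Four
tests are built from such marginals:

* ``jzs_bf01``   -- point null delta = 0 vs a Cauchy alternative; BF01 is
  the central-t density at t divided by m(pi).
* ``oh_bf01``    -- overlapping hypotheses: null C(0, r0) vs alternative
  C(0, r1); by transitivity BF01 = m(C(0, r0)) / m(C(0, r1)).
* ``noh_bf01``   -- non-overlapping interval hypotheses: the prior is split
  at an equivalence region (l, u); BF01 is the ratio of the two marginals
  under the prior truncated to the region and to its complement.
* ``hybrid_bf01`` -- a mixture null that places probability pi0 on the
  exact point delta = 0 and 1 - pi0 on the interval null of the NOH model.

All marginals are computed by adaptive quadrature split at the likelihood
peak delta_hat = t / sqrt(n_delta), the prior location, zero, and the
region boundaries; the reported ``numerical_error`` propagates the
quadrature error bounds through the ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, stats

from ._nct import nct_pdf
from .core import EquivalenceRegion
from .errors import DegenerateRegionError, InvalidDataError, NumericalError, ScaleMismatchError
from .priors import CauchyPrior

__all__ = [
    "BFModelSpec",
    "BFResult",
    "MarginalResult",
    "marginal_t_density",
    "jzs_bf01",
    "oh_bf01",
    "noh_bf01",
    "hybrid_bf01",
]

# Quadrature tolerances.  The integrand can be sharply peaked far from 0
# for large n, hence the explicit splitting below.
_EPSABS = 1e-10
_EPSREL = 1e-8

# Smallest admissible prior mass on either side of an interval split.
_MIN_SIDE_MASS = 1e-12

# Floor for marginals that underflow to zero (decisions still work; the
# log Bayes factor saturates instead of becoming -inf/inf).
_TINY = 1e-300


@dataclass(frozen=True)
class BFModelSpec:
    """Which interval-Bayes-factor model, with which prior and region."""

    model: str  # "jzs" | "oh" | "noh" | "hybrid"
    prior: CauchyPrior
    null_scale_ratio: float | None = None  # oh only: r0 / r1
    region: EquivalenceRegion | None = None  # noh / hybrid
    point_null_weight: float | None = None  # hybrid only: pi0

    def __post_init__(self):
        if self.model not in ("jzs", "oh", "noh", "hybrid"):
            raise InvalidDataError(f"unknown model {self.model!r}")
        if self.model == "oh" and not (self.null_scale_ratio and self.null_scale_ratio > 0):
            raise InvalidDataError("oh model requires a positive null_scale_ratio")
        if self.model in ("noh", "hybrid") and self.region is None:
            raise InvalidDataError(f"{self.model} model requires an equivalence region")
        if self.model == "hybrid":
            w = self.point_null_weight
            if w is None or not 0 <= w <= 1:
                raise InvalidDataError("hybrid model requires point_null_weight in [0, 1]")


@dataclass(frozen=True)
class BFResult:
    """A Bayes factor BF01 with its log and a quadrature error estimate."""

    bf01: float
    log_bf01: float
    model: BFModelSpec
    numerical_error: float


class MarginalResult(NamedTuple):
    value: float
    error: float


def _piecewise_quad(f, a: float, b: float, interior_points) -> tuple[float, float]:
    """Integrate f over [a, b] splitting at the given interior points.

    Convergence is judged from the summed error estimate below, so the
    per-panel quadrature warnings are silenced.
    """
    pts = sorted(p for p in set(interior_points) if a < p < b and np.isfinite(p))
    edges = [a, *pts, b]
    total = 0.0
    err = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for lo, hi in zip(edges[:-1], edges[1:]):
            v, e = integrate.quad(f, lo, hi, epsabs=_EPSABS, epsrel=_EPSREL)
            total += v
            err += e
    if err > 50 * max(_EPSABS, abs(total) * _EPSREL) and err > 1e-6 * abs(total):
        raise NumericalError(
            f"quadrature did not converge (error estimate {err:.3e} for value {total:.3e})",
            achieved_error=err,
        )
    return total, err


def marginal_t_density(
    t: float,
    df: float,
    effective_n: float,
    prior: CauchyPrior,
    support: tuple[float, float] | None = None,
) -> MarginalResult:
    """Marginal density of t under the (optionally truncated) prior.

    ``support=None`` integrates over the whole real line.  When a finite or
    half-infinite interval (l, u) is given, the prior is renormalized to
    that interval, i.e. the result is
    ``integral_l^u T_nu(t | sqrt(n_delta) d) pi(d) dd / Pr_pi(l < d < u)``.
    """
    sn = math.sqrt(effective_n)

    def f(d):
        return nct_pdf(t, df, sn * d) * prior.pdf(d)

    if support is None:
        a, b, mass = -np.inf, np.inf, 1.0
    else:
        a, b = support
        if not a < b:
            raise InvalidDataError(f"empty support ({a}, {b})")
        lo = a if np.isfinite(a) else -np.inf
        hi = b if np.isfinite(b) else np.inf
        mass = prior.interval_mass(lo, hi)
        if mass < _MIN_SIDE_MASS:
            raise DegenerateRegionError(
                f"prior mass {mass:.3e} on support ({a}, {b}) is too small"
            )
        a, b = lo, hi
    val, err = _piecewise_quad(f, a, b, _breakpoints(t, df, sn, prior))
    return MarginalResult(value=val / mass, error=err / mass)


def _breakpoints(t: float, df: float, sn: float, prior: CauchyPrior):
    """Split points covering the likelihood peak and the prior body.

    Both factors of the integrand can be narrow spikes (large n, or a
    nearly-degenerate prior scale), so quadrature panels are anchored at
    each peak and a few widths around it.
    """
    d_hat = t / sn
    lik_sd = math.sqrt(1 + t * t / (2 * df)) / sn
    return (d_hat, d_hat - 5 * lik_sd, d_hat + 5 * lik_sd,
            prior.location, prior.location - 5 * prior.scale,
            prior.location + 5 * prior.scale, 0.0)


def _result(model: BFModelSpec, num: float, den: float, rel_err: float) -> BFResult:
    log_bf = math.log(max(num, _TINY)) - math.log(max(den, _TINY))
    bf = math.exp(log_bf)
    return BFResult(bf01=bf, log_bf01=log_bf, model=model,
                    numerical_error=abs(bf) * rel_err)


def jzs_bf01(t: float, df: float, effective_n: float,
             prior: CauchyPrior | None = None) -> BFResult:
    """Bayes factor for the point null delta = 0 vs a Cauchy alternative.

    With a zero-location prior this is the default (JZS) Bayesian t-test;
    nonzero locations give the informed nil-hypothesis variant.
    """
    prior = prior if prior is not None else CauchyPrior()
    m1 = marginal_t_density(t, df, effective_n, prior)
    num = stats.t.pdf(t, df)
    spec = BFModelSpec(model="jzs", prior=prior)
    rel = m1.error / max(m1.value, _TINY)
    return _result(spec, num, m1.value, rel)


def oh_bf01(t: float, df: float, effective_n: float,
            r1: float = 1.0, r0: float | None = None) -> BFResult:
    """Overlapping-hypotheses Bayes factor: null C(0, r0) vs alt C(0, r1).

    Obtained by transitivity from two point-null Bayes factors,
    BF01_OH = BF01(r1) / BF01(r0) = m(C(0, r0)) / m(C(0, r1)).
    The default r0 is r1/10, which places the null prior tightly around 0.
    """
    if r0 is None:
        r0 = r1 / 10
    if not (r0 > 0 and r1 > 0):
        raise InvalidDataError("prior scales must be > 0")
    b1 = jzs_bf01(t, df, effective_n, CauchyPrior(0.0, r1))
    b0 = jzs_bf01(t, df, effective_n, CauchyPrior(0.0, r0))
    spec = BFModelSpec(model="oh", prior=CauchyPrior(0.0, r1), null_scale_ratio=r0 / r1)
    rel = (b1.numerical_error / max(b1.bf01, _TINY)
           + b0.numerical_error / max(b0.bf01, _TINY))
    return _result(spec, b1.bf01, b0.bf01, rel)


def _split_marginals(t, df, effective_n, prior, region):
    """Truncated-prior marginals inside and outside the region."""
    if region.scale != "standardized_effect":
        raise ScaleMismatchError("interval Bayes factors need a region on the delta scale")
    l, u = region.lower, region.upper
    mass_in = prior.interval_mass(l, u)
    mass_out = 1.0 - mass_in
    if mass_in < _MIN_SIDE_MASS or mass_out < _MIN_SIDE_MASS:
        raise DegenerateRegionError(
            f"prior mass inside ({mass_in:.3e}) or outside ({mass_out:.3e}) "
            f"the region is too small"
        )
    sn = math.sqrt(effective_n)

    def f(d):
        return nct_pdf(t, df, sn * d) * prior.pdf(d)

    pts = _breakpoints(t, df, sn, prior)
    v_in, e_in = _piecewise_quad(f, l, u, pts)
    v_lo, e_lo = _piecewise_quad(f, -np.inf, l, pts)
    v_hi, e_hi = _piecewise_quad(f, u, np.inf, pts)
    m0 = v_in / mass_in
    m1 = (v_lo + v_hi) / mass_out
    e0 = e_in / mass_in
    e1 = (e_lo + e_hi) / mass_out
    return m0, e0, m1, e1


def noh_bf01(t: float, df: float, effective_n: float, prior: CauchyPrior,
             region: EquivalenceRegion, nu0: int = 1) -> BFResult:
    """Non-overlapping interval Bayes factor.

    The null hypothesis is delta in (l, u) and the alternative is its
    complement, both under the same t_nu0 effect-size prior renormalized
    to their side of the split.  This equals the informed interval Bayes
    factor obtained by extending the point-null marginal-likelihood
    identity to interval hypotheses.  Only nu0 = 1 (Cauchy) is supported.
    """
    if nu0 != 1:
        raise NotImplementedError("only nu0 = 1 (Cauchy effect-size prior) is implemented")
    m0, e0, m1, e1 = _split_marginals(t, df, effective_n, prior, region)
    spec = BFModelSpec(model="noh", prior=prior, region=region)
    rel = e0 / max(m0, _TINY) + e1 / max(m1, _TINY)
    return _result(spec, m0, m1, rel)


def hybrid_bf01(t: float, df: float, effective_n: float, prior: CauchyPrior,
                region: EquivalenceRegion, pi0: float) -> BFResult:
    """Mixture null: point mass pi0 at delta = 0 plus the interval null.

    BF01 = [pi0 * T_nu(t) + (1 - pi0) * m0] / m1 with m0, m1 the truncated
    marginals of the non-overlapping model.  pi0 = 0 recovers the NOH
    Bayes factor; pi0 = 1 puts the whole null on the exact point.
    """
    if not 0 <= pi0 <= 1:
        raise InvalidDataError("pi0 must lie in [0, 1]")
    m0, e0, m1, e1 = _split_marginals(t, df, effective_n, prior, region)
    num = pi0 * stats.t.pdf(t, df) + (1 - pi0) * m0
    spec = BFModelSpec(model="hybrid", prior=prior, region=region, point_null_weight=pi0)
    rel = (1 - pi0) * e0 / max(num, _TINY) + e1 / max(m1, _TINY)
    return _result(spec, num, m1, rel)
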