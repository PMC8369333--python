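"""Effect-size priors.

The package places a Cauchy prior C(location, scale) on the standardized
effect size delta.  This covers the standard default Bayesian t-test
(Jeffreys-Zellner-Siow: a zero-centred Cauchy on delta together with the
1/sigma^2 reference prior on the variance) as well as informed variants
with a shifted location.  The t_nu0 prior of the non-overlapping interval
model is supported for nu0 = 1, where it coincides with the Cauchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InvalidDataError

__all__ = ["CauchyPrior", "DEFAULT_SCALES"]

#: The three conventional Cauchy widths: medium, wide, ultrawide.
DEFAULT_SCALES = (1 / math.sqrt(2), 1.0, math.sqrt(2))


@dataclass(frozen=True)
class CauchyPrior:
    """Cauchy prior on the standardized effect size."""

    location: float = 0.0
    scale: float = 1 / math.sqrt(2)

    def __post_init__(self):
        if not self.scale > 0:
            raise InvalidDataError("prior scale must be > 0")

    def pdf(self, x):
        # inline density: called inside tight quadrature loops
        s = self.scale
        d = x - self.location
        return s / (math.pi * (s * s + d * d))

    def logpdf(self, x):
        return stats.cauchy.logpdf(x, loc=self.location, scale=self.scale)

    def cdf(self, x):
        return stats.cauchy.cdf(x, loc=self.location, scale=self.scale)

    def ppf(self, q):
        return stats.cauchy.ppf(q, loc=self.location, scale=self.scale)

    def interval_mass(self, lower: float, upper: float) -> float:
        """Prior probability of the interval [lower, upper]."""
        return float(self.cdf(upper) - self.cdf(lower))

    @classmethod
    def from_t_nu(cls, nu0: int, scale: float = 1.0, location: float = 0.0) -> "CauchyPrior":
        """The t_nu0-distribution prior, available for nu0 = 1 (Cauchy)."""
        if nu0 != 1:
            raise NotImplementedError(
                "only nu0 = 1 (the Cauchy prior) is implemented; general t_nu0 "
                "priors are not supported"
            )
        return cls(location=location, scale=scale)
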