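"""Named simulation study conditions.

These fix the four benchmark scenarios used by the package's reproduction
studies: n = 10,000 samples and p = 88 features throughout, four risk base
variables with effects beta_1 = -1.5 and +1.5 for the rest, and a 16.2%
marginal prevalence for dichotomous traits.

* Dichotomous scenarios use the block covariance (20 min/mean/max triplets
  at within-group correlation 0.5, background 0.1, 20 dichotomized
  singletons); a drawn triplet contributes all three sub-features to the
  risk set.
* The linear quantitative scenario draws its four risk features as
  mutually uncorrelated singletons (no correlated blocks, zero background
  correlation), so the population R-squared has the closed form
  beta'beta / (beta'beta + 1) = 9/10.
* The quadratic quantitative scenario keeps the block covariance and group
  expansion and applies f(x) = x^2 inside the outcome model.
"""

from __future__ import annotations

from knockoffml.sim_data import (
    CovarianceSpec,
    SimulationScenario,
    default_covariance,
)

__all__ = [
    "linear_dichotomous",
    "quadratic_dichotomous",
    "linear_quantitative",
    "quadratic_quantitative",
]


def linear_dichotomous(n: int = 10_000) -> SimulationScenario:
    return SimulationScenario(trait="dichotomous", link="linear", n=n)


def quadratic_dichotomous(n: int = 10_000) -> SimulationScenario:
    return SimulationScenario(trait="dichotomous", link="quadratic", n=n)


def _uncorrelated_cov() -> CovarianceSpec:
    # 68 independent continuous singletons + 20 dichotomized columns
    return CovarianceSpec(
        p=88,
        groups=(),
        within_group_rho=0.5,
        background_rho=0.0,
        binary_columns=frozenset(range(68, 88)),
    )


def linear_quantitative(n: int = 10_000) -> SimulationScenario:
    return SimulationScenario(
        trait="quantitative", link="linear", n=n, cov=_uncorrelated_cov()
    )


def quadratic_quantitative(n: int = 10_000) -> SimulationScenario:
    return SimulationScenario(
        trait="quantitative", link="quadratic", n=n, cov=default_covariance()
    )
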