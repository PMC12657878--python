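"""Synthetic EHR-style feature matrices and outcomes.

The generator emulates a tabular ICU cohort: multivariate Gaussian features
with a block-correlation structure (triplets of sub-features such as the
min/mean/max of one vital sign are strongly correlated; everything else is
weakly correlated), a subset of columns dichotomized into 0/1 dummies, and a
binary or quantitative outcome driven by a handful of "risk" base variables
through a linear, quadratic, or exponential link. Defaults follow the study
conditions used throughout this package: n = 10,000 samples, p = 88 features
(20 correlated triplets + 28 singletons, 20 of them binary), four risk
groups, effects -1.5/+1.5, and a 16.2% marginal event rate for binary traits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import FeatureMatrix, spawn_rngs

__all__ = [
    "CovarianceSpec",
    "SimulationScenario",
    "SimulatedDataset",
    "default_covariance",
    "build_covariance",
    "draw_design",
    "choose_risk_features",
    "simulate_outcome",
    "simulate_dataset",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "write_dataset",
    "read_dataset",
]

LINKS = {
    "linear": lambda x: x,
    "quadratic": lambda x: x**2,
    "exponential": np.exp,
}


@dataclass(frozen=True)
class CovarianceSpec:
    """Block covariance: within-group correlation for sub-feature groups,
    a weak background correlation elsewhere, unit variances."""

    p: int
    groups: tuple[tuple[int, ...], ...] = ()
    within_group_rho: float = 0.5
    background_rho: float = 0.1
    binary_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        seen: set[int] = set()
        for g in self.groups:
            idx = set(g)
            if not idx <= set(range(self.p)):
                raise ValueError("group index out of range")
            if idx & seen:
                raise ValueError("groups must be pairwise disjoint")
            seen |= idx
        if not set(self.binary_columns) <= set(range(self.p)):
            raise ValueError("binary column index out of range")

    def group_sets(self) -> list[set[int]]:
        return [set(g) for g in self.groups]

    def base_variables(self) -> list[tuple[int, ...]]:
        """Base variables: each group is one variable; ungrouped columns are
        singleton variables."""
        grouped = {i for g in self.groups for i in g}
        out = [tuple(sorted(g)) for g in self.groups]
        out += [(i,) for i in range(self.p) if i not in grouped]
        return sorted(out)


def default_covariance(
    n_triplet_groups: int = 20,
    n_singletons: int = 28,
    n_binary: int = 20,
    within_group_rho: float = 0.5,
    background_rho: float = 0.1,
) -> CovarianceSpec:
    """The default 88-feature block structure: 20 min/mean/max triplets
    followed by 28 singleton columns, the last ``n_binary`` of which are
    dichotomized into dummies."""
    p = 3 * n_triplet_groups + n_singletons
    if n_binary > n_singletons:
        raise ValueError("binary columns must be singletons")
    groups = tuple(
        tuple(range(3 * g, 3 * g + 3)) for g in range(n_triplet_groups)
    )
    binary = frozenset(range(p - n_binary, p))
    return CovarianceSpec(
        p=p,
        groups=groups,
        within_group_rho=within_group_rho,
        background_rho=background_rho,
        binary_columns=binary,
    )


def build_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Assemble the p x p correlation matrix and verify it is positive
    definite (Cholesky)."""
    sigma = np.full((spec.p, spec.p), spec.background_rho, dtype=float)
    for g in spec.groups:
        idx = np.array(g)
        sigma[np.ix_(idx, idx)] = spec.within_group_rho
    np.fill_diagonal(sigma, 1.0)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            "covariance is not positive definite for within_group_rho="
            f"{spec.within_group_rho}, background_rho={spec.background_rho}"
        ) from None
    return sigma


@dataclass(frozen=True)
class SimulationScenario:
    trait: str = "dichotomous"  # "dichotomous" | "quantitative"
    link: str = "linear"  # "linear" | "quadratic" | "exponential"
    n: int = 10_000
    cov: CovarianceSpec = field(default_factory=default_covariance)
    n_risk_groups: int = 4
    beta_first: float = -1.5
    beta_rest: float = 1.5
    baseline_rate: float = 0.162
    noise_sd: float = 1.0
    seed: int = 0
    risk_from_binary: bool = False
    calibration: str = "marginal"  # "marginal" | "intercept"
    calibration_n: int = 1_000_000

    def __post_init__(self) -> None:
        if self.trait not in ("dichotomous", "quantitative"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulatedDataset:
    X: FeatureMatrix
    y: np.ndarray
    risk_set: tuple[int, ...]
    scenario: SimulationScenario | None = None

    @property
    def risk_columns(self) -> list[str]:
        cols = self.X.columns
        return [cols[j] for j in self.risk_set]


def _column_names(spec: CovarianceSpec) -> list[str]:
    names = [""] * spec.p
    stats = ("min", "mean", "max")
    for g, group in enumerate(spec.groups):
        for s, j in enumerate(sorted(group)):
            suffix = stats[s] if len(group) == 3 else str(s + 1)
            names[j] = f"var{g + 1:02d}_{suffix}"
    k = 0
    for j in range(spec.p):
        if not names[j]:
            k += 1
            prefix = "flag" if j in spec.binary_columns else "single"
            names[j] = f"{prefix}{k:02d}"
    return names


def draw_design(
    spec: CovarianceSpec, n: int, rng: np.random.Generator
) -> FeatureMatrix:
    """Draw an n x p multivariate Gaussian design (mean 0, covariance from
    ``spec``) and dichotomize the binary columns: non-negative -> 1,
    negative -> 0."""
    sigma = build_covariance(spec)
    chol = np.linalg.cholesky(sigma)
    Z = rng.standard_normal((n, spec.p))
    X = Z @ chol.T
    binary = sorted(spec.binary_columns)
    if binary:
        X[:, binary] = (X[:, binary] >= 0).astype(float)
    names = _column_names(spec)
    groups = {
        names[min(g)].rsplit("_", 1)[0]: tuple(names[j] for j in sorted(g))
        for g in spec.groups
    }
    return FeatureMatrix(
        frame=pd.DataFrame(X, columns=names),
        binary=frozenset(names[j] for j in binary),
        groups=groups,
    )


def choose_risk_features(
    spec: CovarianceSpec,
    n_risk_groups: int,
    rng: np.random.Generator,
    include_binary: bool = False,
) -> tuple[int, ...]:
    """Pick ``n_risk_groups`` base variables uniformly without replacement;
    a drawn group contributes all of its sub-features to the risk set."""
    variables = spec.base_variables()
    if not include_binary:
        variables = [
            v for v in variables if not set(v) & set(spec.binary_columns)
        ]
    if n_risk_groups > len(variables):
        raise ValueError(
            f"n_risk_groups={n_risk_groups} exceeds the "
            f"{len(variables)} selectable base variables"
        )
    chosen = rng.choice(len(variables), size=n_risk_groups, replace=False)
    risk: list[int] = []
    for i in chosen:
        risk.extend(variables[i])
    return tuple(sorted(risk))


def _risk_betas(n_risk: int, beta_first: float, beta_rest: float) -> np.ndarray:
    beta = np.full(n_risk, beta_rest, dtype=float)
    if n_risk:
        beta[0] = beta_first
    return beta


def _calibrate_intercept(
    scenario: SimulationScenario,
    risk_set: tuple[int, ...],
    rng: np.random.Generator,
) -> float:
    """beta_0 such that the marginal event rate equals ``baseline_rate``,
    found by Brent root-finding on a large Monte-Carlo draw of the risk
    features from their joint Gaussian marginal."""
    if scenario.calibration == "intercept":
        rate = scenario.baseline_rate
        return float(np.log(rate / (1 - rate)))
    sigma = build_covariance(scenario.cov)
    idx = np.array(risk_set)
    sub = sigma[np.ix_(idx, idx)]
    chol = np.linalg.cholesky(sub)
    S = rng.standard_normal((scenario.calibration_n, len(idx))) @ chol.T
    beta = _risk_betas(len(idx), scenario.beta_first, scenario.beta_rest)
    lp = LINKS[scenario.link](S) @ beta
    target = scenario.baseline_rate

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp))) - target

    return float(brentq(gap, -60.0, 60.0, xtol=1e-10))


def simulate_outcome(
    X: FeatureMatrix,
    risk_set: tuple[int, ...],
    scenario: SimulationScenario,
    rng: np.random.Generator,
    calibration_rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate the outcome from the risk columns of ``X``.

    Dichotomous traits: logit(E[Y]) = beta_0 + sum_j beta_j f(S_j), with
    beta_0 calibrated so the marginal prevalence matches ``baseline_rate``.
    Quantitative traits: Y = sum_j beta_j f(S_j) + eps, eps ~ N(0, noise_sd^2).
    """
    if not risk_set:
        raise ValueError("risk_set must be non-empty")
    link = LINKS[scenario.link]
    S = X.values[:, np.array(risk_set)]
    beta = _risk_betas(len(risk_set), scenario.beta_first, scenario.beta_rest)
    signal = link(S) @ beta
    if scenario.trait == "dichotomous":
        cal_rng = calibration_rng if calibration_rng is not None else rng
        b0 = _calibrate_intercept(scenario, risk_set, cal_rng)
        y = (rng.random(X.n) < expit(b0 + signal)).astype(float)
    else:
        y = signal + scenario.noise_sd * rng.standard_normal(X.n)
    return SimulatedDataset(X=X, y=y, risk_set=tuple(risk_set), scenario=scenario)


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """One replicate: design draw, risk-variable draw, and outcome, with
    deterministic sub-streams derived from ``scenario.seed``."""
    design_rng, risk_rng, noise_rng, cal_rng = spawn_rngs(scenario.seed, 4)
    X = draw_design(scenario.cov, scenario.n, design_rng)
    risk = choose_risk_features(
        scenario.cov,
        scenario.n_risk_groups,
        risk_rng,
        include_binary=scenario.risk_from_binary,
    )
    return simulate_outcome(X, risk, scenario, noise_rng, calibration_rng=cal_rng)


# ---------------------------------------------------------------------------
# serialization


def _scenario_dict(s: SimulationScenario) -> dict:
    return {
        "trait": s.trait,
        "link": s.link,
        "n": s.n,
        "cov": {
            "p": s.cov.p,
            "groups": [list(g) for g in s.cov.groups],
            "within_group_rho": s.cov.within_group_rho,
            "background_rho": s.cov.background_rho,
            "binary_columns": sorted(s.cov.binary_columns),
        },
        "n_risk_groups": s.n_risk_groups,
        "beta_first": s.beta_first,
        "beta_rest": s.beta_rest,
        "baseline_rate": s.baseline_rate,
        "noise_sd": s.noise_sd,
        "seed": s.seed,
        "risk_from_binary": s.risk_from_binary,
        "calibration": s.calibration,
        "calibration_n": s.calibration_n,
    }


def scenario_to_yaml(scenario: SimulationScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_scenario_dict(scenario)))


def scenario_from_yaml(path: str | Path) -> SimulationScenario:
    raw = yaml.safe_load(Path(path).read_text())
    cov_raw = raw.pop("cov")
    cov = CovarianceSpec(
        p=cov_raw["p"],
        groups=tuple(tuple(g) for g in cov_raw.get("groups", [])),
        within_group_rho=cov_raw.get("within_group_rho", 0.5),
        background_rho=cov_raw.get("background_rho", 0.1),
        binary_columns=frozenset(cov_raw.get("binary_columns", [])),
    )
    return SimulationScenario(cov=cov, **raw)


def write_dataset(dataset: SimulatedDataset, path: str | Path) -> None:
    """CSV with the outcome in column 'y' plus a sidecar JSON risk set."""
    path = Path(path)
    table = dataset.X.frame.copy()
    table["y"] = dataset.y
    table.to_csv(path, index=False)
    meta = {
        "risk_set": list(dataset.risk_set),
        "risk_columns": dataset.risk_columns,
        "binary": sorted(dataset.X.binary),
        "groups": {k: list(v) for k, v in dataset.X.groups.items()},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path) -> SimulatedDataset:
    path = Path(path)
    table = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    y = table.pop("y").to_numpy(dtype=float)
    X = FeatureMatrix(
        frame=table,
        binary=frozenset(meta.get("binary", [])),
        groups={k: tuple(v) for k, v in meta.get("groups", {}).items()},
    )
    return SimulatedDataset(X=X, y=y, risk_set=tuple(meta["risk_set"]))


def with_seed(scenario: SimulationScenario, seed: int) -> SimulationScenario:
    return replace(scenario, seed=int(seed))
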