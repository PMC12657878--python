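"""Conventional feature-selection comparators.

Stepwise AIC search over generalized linear models (forward from the
intercept, backward from the full model, or bidirectional from the full
model) and the lasso with a cross-validated penalty, reporting both the
CV-error minimizer lambda_min and the one-standard-error choice lambda_1se.
The baselines always model a linear index — even when the truth is quadratic
or exponential — which is exactly the misspecification the benchmarks probe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.model_selection import KFold

from ._utils import as_frame, child_seed

__all__ = [
    "BaselineFit",
    "stepwise_select",
    "lasso_select",
    "top_k_by_coefficient",
]


@dataclass
class BaselineFit:
    method: str
    selected: list[str]
    coefficients: pd.Series
    trace: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "selected": self.selected,
                    "coefficients": {
                        k: float(v) for k, v in self.coefficients.items()
                    },
                    "trace": self.trace,
                },
                indent=1,
                default=float,
            )
        )


def _fit_glm(y: np.ndarray, X: pd.DataFrame, trait: str):
    design = sm.add_constant(X, has_constant="add")
    if trait == "dichotomous":
        model = sm.GLM(y, design, family=sm.families.Binomial())
    else:
        model = sm.OLS(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def _aic(result) -> float:
    return float(result.aic)


def stepwise_select(X, y, direction: str = "both", trait: str = "dichotomous") -> BaselineFit:
    """Greedy AIC search. Forward starts from the intercept-only model;
    backward and bidirectional start from the full model. Stops when no
    single add/drop lowers the AIC."""
    if direction not in ("both", "backward", "forward"):
        raise ValueError("direction must be 'both', 'backward' or 'forward'")
    frame = as_frame(X)
    y = np.asarray(y, dtype=float)
    columns = list(frame.columns)
    current = [] if direction == "forward" else list(columns)
    best = _fit_glm(y, frame[current], trait)
    best_aic = _aic(best)
    path = [{"step": 0, "aic": best_aic, "size": len(current)}]
    allow_add = direction in ("forward", "both")
    allow_drop = direction in ("backward", "both")
    step = 0
    while True:
        moves: list[tuple[float, str, str]] = []
        if allow_add:
            for c in columns:
                if c in current:
                    continue
                try:
                    moves.append(
                        (_aic(_fit_glm(y, frame[current + [c]], trait)), "add", c)
                    )
                except Exception:  # separation / non-convergence: skip move
                    continue
        if allow_drop:
            for c in current:
                trial = [k for k in current if k != c]
                try:
                    moves.append((_aic(_fit_glm(y, frame[trial], trait)), "drop", c))
                except Exception:
                    continue
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))
        aic, kind, col = moves[0]
        if aic >= best_aic - 1e-10:
            break
        if kind == "add":
            current = current + [col]
        else:
            current = [k for k in current if k != col]
        best_aic = aic
        step += 1
        path.append({"step": step, "aic": best_aic, "size": len(current)})
    final = _fit_glm(y, frame[current], trait)
    coefs = pd.Series(
        {c: float(final.params[c]) for c in current}, dtype=float
    )
    method = {"both": "stepwise", "backward": "backward", "forward": "forward"}[
        direction
    ]
    return BaselineFit(
        method=method,
        selected=[c for c in columns if c in current],
        coefficients=coefs,
        trace={"aic_path": path, "final_aic": best_aic},
    )


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100) -> np.ndarray:
    """Log-spaced path from lambda_max (all-zero solution) down by 1e-4."""
    n = X.shape[0]
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / n
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)


def lasso_select(
    X,
    y,
    which: str = "min",
    trait: str = "quantitative",
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
) -> BaselineFit:
    """L1 selection at lambda_min or lambda_1se from ``folds``-fold CV over a
    fixed 100-point penalty path; the selection is the support of the
    refitted coefficients at the chosen penalty."""
    if which not in ("min", "1se"):
        raise ValueError("which must be 'min' or '1se'")
    frame = as_frame(X)
    values = frame.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        raise ValueError("constant outcome")
    lambdas = _lambda_grid(values, y, n_lambdas)
    kf = KFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, 0))
    errors = np.empty((folds, len(lambdas)))
    for f, (tr, va) in enumerate(kf.split(values)):
        errors[f] = _cv_errors(values[tr], y[tr], values[va], y[va], lambdas, trait)
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_err))
    cutoff = mean_err[i_min] + se_err[i_min]
    # largest penalty (smallest index; lambdas descend) within one SE
    i_1se = int(np.where(mean_err <= cutoff)[0][0])
    idx = i_min if which == "min" else i_1se
    coef = _lasso_coefs(values, y, lambdas[idx], trait)
    coefs = pd.Series(coef, index=frame.columns)
    selected = [c for c in frame.columns if coefs[c] != 0]
    return BaselineFit(
        method=f"lasso_{which}",
        selected=selected,
        coefficients=coefs[coefs != 0],
        trace={
            "lambda_min": float(lambdas[i_min]),
            "lambda_1se": float(lambdas[i_1se]),
            "lambda_used": float(lambdas[idx]),
            "cv_error": mean_err.tolist(),
            "cv_se": se_err.tolist(),
            "lambdas": lambdas.tolist(),
        },
    )


def _cv_errors(Xtr, ytr, Xva, yva, lambdas, trait) -> np.ndarray:
    if trait == "quantitative":
        _, coefs, _ = lasso_path(Xtr, ytr, alphas=lambdas)
        intercept = ytr.mean() - Xtr.mean(axis=0) @ coefs
        pred = Xva @ coefs + intercept
        return np.mean((yva[:, None] - pred) ** 2, axis=0)
    errs = np.empty(len(lambdas))
    n = Xtr.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", warm_start=True, max_iter=500
    )
    for i, lam in enumerate(lambdas):
        clf.C = 1.0 / (n * lam)
        clf.fit(Xtr, ytr)
        p = np.clip(clf.predict_proba(Xva)[:, 1], 1e-12, 1 - 1e-12)
        errs[i] = -np.mean(yva * np.log(p) + (1 - yva) * np.log(1 - p))
    return errs


def _lasso_coefs(X, y, lam, trait) -> np.ndarray:
    if trait == "quantitative":
        _, coefs, _ = lasso_path(X, y, alphas=[lam])
        return coefs[:, 0]
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=1.0 / (X.shape[0] * lam), max_iter=500
    )
    clf.fit(X, y)
    return clf.coef_[0]


def top_k_by_coefficient(fit: BaselineFit, k: int) -> list[str]:
    """The k features with the largest |beta-hat|, index tie-break."""
    coefs = fit.coefficients
    if k > len(coefs):
        raise ValueError(f"k={k} exceeds the {len(coefs)} estimated features")
    order = sorted(
        range(len(coefs)), key=lambda i: (-abs(coefs.iloc[i]), i)
    )
    return [coefs.index[i] for i in order[:k]]
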