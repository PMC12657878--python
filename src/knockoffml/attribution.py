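"""Per-feature importance from additive attributions.

A fitted tree-ensemble model is explained row by row with SHAP-style additive
attributions (native prediction contributions for lightgbm/xgboost boosters,
the package's own tree-path algorithm for sklearn ensembles). The importance
of feature j is the mean absolute attribution over the explained rows.

For large cohorts the rows to explain are chosen by shrinkage leveraging
(SLEV): a 50/50 mixture of normalized statistical leverage scores — squared
row norms of the top r = ceil(sqrt(p log p)) left singular vectors of the
intercept-augmented design — and the uniform distribution, with subsample
size k = floor(10 n^(1/3) log n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_frame
from .knockoffs import KnockoffSet
from .treeshap import exhaustive_shap_values, tree_shap_values, trees_from_sklearn

__all__ = [
    "AttributionMatrix",
    "LeverageSampling",
    "ImportanceVector",
    "leverage_scores",
    "slev_subsample_size",
    "slev_subsample",
    "attribute",
    "exhaustive_attribute",
    "feature_importance",
    "importance_for_knockoff_analysis",
]


@dataclass
class AttributionMatrix:
    """Additive attributions: for every explained row,
    base_value + sum_j values[i, j] equals the model's raw output."""

    values: pd.DataFrame  # rows x features
    base_value: float
    model_id: str
    output_space: str  # "margin" | "probability" | "response"

    def predictions(self) -> np.ndarray:
        return self.base_value + self.values.to_numpy().sum(axis=1)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)


@dataclass
class LeverageSampling:
    leverages: np.ndarray  # h_ii
    probabilities: np.ndarray  # pi_i
    rank: int
    subsample_size: int

    def __post_init__(self) -> None:
        if not math.isclose(float(self.probabilities.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("sampling probabilities must sum to 1")


@dataclass
class ImportanceVector:
    """T^0 (originals) alongside T^1..T^M (one row per knockoff copy)."""

    original: pd.Series
    knockoffs: pd.DataFrame  # M rows x p columns

    @property
    def M(self) -> int:
        return self.knockoffs.shape[0]

    @property
    def features(self) -> list[str]:
        return list(self.original.index)

    def to_tsv(self, path) -> None:
        rows = [
            {"feature": f, "copy": 0, "FI": v} for f, v in self.original.items()
        ]
        for m in range(self.M):
            for f in self.features:
                rows.append(
                    {"feature": f, "copy": m + 1, "FI": self.knockoffs.iloc[m][f]}
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def slev_subsample_size(n: int, scale: float = 10.0, log_base: float = math.e) -> int:
    """k = floor(scale * n^(1/3) * log n), capped at n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    k = math.floor(scale * n ** (1 / 3) * math.log(n, log_base))
    return min(max(k, 1), n)


def leverage_scores(X, rank: int | None = None, log_base: float = math.e) -> LeverageSampling:
    """Leverage-based sampling distribution for the rows of X.

    A column of ones is appended, the top r left singular vectors are taken
    (r = ceil(sqrt(p log p)) by default, p the original feature count), and
    h_ii is the squared norm of row i in that basis. The sampling law is
    pi = 0.5 * h/sum(h) + 0.5 * uniform.
    """
    frame = as_frame(X)
    values = frame.to_numpy(dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least two rows")
    if rank is None:
        rank = math.ceil(math.sqrt(p * math.log(max(p, 2), log_base)))
    rank = min(rank, n, p + 1)
    design = np.concatenate([np.ones((n, 1)), values], axis=1)
    U, s, _ = np.linalg.svd(design, full_matrices=False)
    effective = int(np.sum(s > s[0] * max(n, p + 1) * np.finfo(float).eps))
    if rank > effective:
        warnings.warn(
            f"requested rank {rank} exceeds the effective rank {effective}; reduced"
        )
        rank = effective
    h = np.sum(U[:, :rank] ** 2, axis=1)
    pi = 0.5 * h / h.sum() + 0.5 / n
    pi = pi / pi.sum()
    return LeverageSampling(
        leverages=h,
        probabilities=pi,
        rank=rank,
        subsample_size=slev_subsample_size(n, log_base=log_base),
    )


def slev_subsample(
    sampling: LeverageSampling, seed: int, k: int | None = None
) -> np.ndarray:
    """Draw k distinct row indices without replacement with probabilities
    proportional to pi (sequential weighted draw); sorted for stable
    downstream slicing."""
    n = sampling.probabilities.shape[0]
    k = sampling.subsample_size if k is None else int(k)
    if k > n:
        raise ValueError("subsample size exceeds the number of rows")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False, p=sampling.probabilities)
    return np.sort(idx)


def _is_lightgbm(model) -> bool:
    mod = type(model).__module__
    return mod.startswith("lightgbm")


def _is_xgboost(model) -> bool:
    return type(model).__module__.startswith("xgboost")


def attribute(model, rows) -> AttributionMatrix:
    """Additive attributions of ``model`` on ``rows``.

    lightgbm and xgboost models use their native tree-path prediction
    contributions; sklearn tree ensembles use this package's implementation.
    Boosted classifiers are explained on the margin (log-odds) scale, random
    forests on the probability scale.
    """
    frame = as_frame(rows)
    model, columns = _unwrap(model)
    if columns is not None:
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"rows are missing model columns: {missing[:5]}")
        frame = frame[columns]
    values = frame.to_numpy(dtype=float)

    if _is_lightgbm(model):
        booster = model.booster_ if hasattr(model, "booster_") else model
        contrib = np.asarray(booster.predict(values, pred_contrib=True))
        phi, base = contrib[:, :-1], float(contrib[0, -1])
        space = "margin" if hasattr(model, "predict_proba") else "response"
    elif _is_xgboost(model):
        import xgboost as xgb

        booster = model.get_booster() if hasattr(model, "get_booster") else model
        dm = xgb.DMatrix(values, feature_names=list(frame.columns))
        contrib = booster.predict(dm, pred_contribs=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
        space = "margin" if hasattr(model, "predict_proba") else "response"
    else:
        trees, scales, offset = trees_from_sklearn(model)
        phi, base = tree_shap_values(trees, scales, offset, values)
        from sklearn.ensemble import (
            GradientBoostingClassifier,
        )

        if isinstance(model, GradientBoostingClassifier):
            space = "margin"
        elif hasattr(model, "predict_proba"):
            space = "probability"
        else:
            space = "response"
    return AttributionMatrix(
        values=pd.DataFrame(phi, columns=frame.columns),
        base_value=base,
        model_id=type(model).__name__,
        output_space=space,
    )


def exhaustive_attribute(model, rows) -> AttributionMatrix:
    """Attributions by direct coalition enumeration (testing oracle; sklearn
    models with at most ~12 features)."""
    frame = as_frame(rows)
    model, columns = _unwrap(model)
    if columns is not None:
        frame = frame[columns]
    trees, scales, offset = trees_from_sklearn(model)
    phi, base = exhaustive_shap_values(
        trees, scales, offset, frame.to_numpy(dtype=float)
    )
    return AttributionMatrix(
        values=pd.DataFrame(phi, columns=frame.columns),
        base_value=base,
        model_id=type(model).__name__,
        output_space="oracle",
    )


def _unwrap(model):
    """Accept either a raw estimator or a learners.FittedModel."""
    from .learners import FittedModel

    if isinstance(model, FittedModel):
        return model.estimator, list(model.columns)
    return model, None


def feature_importance(att: AttributionMatrix) -> pd.Series:
    """FI_j = mean |phi_ij| over the attributed rows."""
    if att.values.empty:
        raise ValueError("empty attribution matrix")
    return att.values.abs().mean(axis=0).rename("FI")


def importance_for_knockoff_analysis(
    model,
    ks: KnockoffSet,
    sampling: LeverageSampling | None = None,
    seed: int = 0,
    subsample: bool = True,
) -> ImportanceVector:
    """Importances for the augmented fit, split back into originals and the
    M knockoff copies.

    The model must have been trained on ``ks.augmented()``. Leverage scores
    are computed on the original feature matrix; attributions are evaluated
    on the SLEV-selected rows only.
    """
    augmented = ks.augmented()
    if subsample and augmented.shape[0] > 2:
        if sampling is None:
            sampling = leverage_scores(ks.original)
        idx = slev_subsample(sampling, seed=seed)
        rows = augmented.iloc[idx]
    else:
        rows = augmented
    att = attribute(model, rows)
    fi = feature_importance(att)
    cmap = ks.column_map()
    original = pd.Series(
        {c: fi[c] for c in ks.original.columns}, name="T0"
    )
    knock = pd.DataFrame(
        [
            {c: fi[cmap[c][m]] for c in ks.original.columns}
            for m in range(1, ks.M + 1)
        ],
        index=[f"T{m}" for m in range(1, ks.M + 1)],
    )
    return ImportanceVector(original=original, knockoffs=knock[ks.original.columns])
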