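"""Multiple knockoff generation by sequential conditional sampling.

Each feature column X_j is visited in order. A least-squares fit of X_j on
all other original columns and every previously generated knockoff column
gives fitted values H_j and residuals e_j; the m-th knockoff of X_j is
H_j + a fresh uniform-random permutation of e_j. Because the permuted
residual has the same empirical distribution as e_j and is decoupled from
the rows, each knockoff preserves the (second-order) joint structure of the
original column while carrying no information about any outcome — the
outcome is never an input to this module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._utils import FeatureMatrix, as_frame

__all__ = [
    "ConditionalFit",
    "KnockoffSet",
    "fit_conditional",
    "generate_knockoffs",
    "exchangeability_diagnostics",
]


@dataclass
class ConditionalFit:
    """OLS fit of one column on the remaining originals plus the knockoffs
    generated so far, with the residual permutations used for its knockoffs."""

    target_index: int
    coefficients: np.ndarray  # intercept first, then X_{-j}, then prior knockoffs
    fitted_values: np.ndarray
    residuals: np.ndarray
    permuted_residuals: np.ndarray  # shape (n, M)

    def knockoff_columns(self) -> np.ndarray:
        return self.fitted_values[:, None] + self.permuted_residuals


@dataclass
class KnockoffSet:
    original: FeatureMatrix
    copies: list[pd.DataFrame]
    M: int
    seed: int

    def __post_init__(self) -> None:
        for c in self.copies:
            if list(c.columns) != self.original.columns:
                raise ValueError("knockoff copies must share the original columns")
            if c.shape != self.original.frame.shape:
                raise ValueError("knockoff copies must share the original shape")

    @property
    def p(self) -> int:
        return self.original.p

    def augmented(self) -> pd.DataFrame:
        """[X | X~^1 | ... | X~^M] with knockoff columns named
        ``<feature>__ko<m>``."""
        parts = [self.original.frame]
        for m, copy in enumerate(self.copies, start=1):
            parts.append(copy.add_suffix(f"__ko{m}"))
        return pd.concat(parts, axis=1)

    def column_map(self) -> dict[str, list[str]]:
        """Original column name -> augmented column names [orig, ko1..koM]."""
        return {
            c: [c] + [f"{c}__ko{m}" for m in range(1, self.M + 1)]
            for c in self.original.columns
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.original.frame.to_csv(directory / "original.csv", index=False)
        for m, copy in enumerate(self.copies, start=1):
            copy.to_csv(directory / f"knockoff_{m}.csv", index=False)
        meta = {"M": self.M, "seed": self.seed, "columns": self.original.columns}
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1))


def _solve_normal_equations(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve of G beta = b with a minimum-norm fallback when the
    design is rank deficient."""
    try:
        return cho_solve(cho_factor(G, lower=True, check_finite=False), b)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient conditional design; using a minimum-norm fit")
        return np.linalg.lstsq(G, b, rcond=None)[0]


def fit_conditional(
    X,
    prior_knockoffs: np.ndarray | None,
    j: int,
    M: int = 5,
    rng: np.random.Generator | None = None,
) -> ConditionalFit:
    """Fit column ``j`` of ``X`` on the other columns plus ``prior_knockoffs``
    (an n x K block of already-generated knockoff columns), and draw the M
    residual permutations."""
    frame = as_frame(X)
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("X contains non-finite entries")
    n, p = values.shape
    rng = rng if rng is not None else np.random.default_rng(0)
    target = values[:, j]
    blocks = [np.ones((n, 1)), np.delete(values, j, axis=1)]
    if prior_knockoffs is not None and prior_knockoffs.size:
        blocks.append(np.asarray(prior_knockoffs, dtype=float))
    A = np.concatenate(blocks, axis=1)
    if n <= A.shape[1]:
        warnings.warn(
            f"n={n} does not exceed the {A.shape[1]} predictors for column {j}"
        )
    beta = _solve_normal_equations(A.T @ A, A.T @ target)
    fitted = A @ beta
    residuals = target - fitted
    permuted = np.column_stack([rng.permutation(residuals) for _ in range(M)])
    return ConditionalFit(
        target_index=j,
        coefficients=beta,
        fitted_values=fitted,
        residuals=residuals,
        permuted_residuals=permuted,
    )


def generate_knockoffs(
    X, M: int = 5, seed: int = 0, conditioning: str = "per_copy"
) -> KnockoffSet:
    """Generate M knockoff copies of ``X``.

    Columns are visited in input order. With ``conditioning="per_copy"``
    (the default) each copy m forms its own sequential chain: the fit for
    column j of copy m conditions on X_{-j} plus the previously generated
    columns of copy m only, so the M copies are conditionally independent
    chains. ``conditioning="joint"`` instead pools the histories of all M
    copies into one shared fit whose residual is permuted M times. The
    pooled variant degenerates for M > 1: the M copies per step share one
    fitted vector, so an unregularized least-squares fit can average their
    permutation noise away and progressively reconstruct each X_j exactly,
    collapsing the residuals — it is provided for comparison only.

    Each chain shares an incrementally updated Gram matrix, so a sweep
    costs O(M(n p^2 + p^4)). Deterministic given ``seed``; the outcome is
    never an input.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if conditioning not in ("per_copy", "joint"):
        raise ValueError("conditioning must be 'per_copy' or 'joint'")
    if isinstance(X, FeatureMatrix):
        fm = X
    else:
        frame = as_frame(X)
        fm = FeatureMatrix(frame=frame)
    values = fm.values
    if not np.all(np.isfinite(values)):
        raise ValueError("X contains non-finite entries")
    n, p = values.shape
    rng = np.random.default_rng(seed)
    ko = np.empty((n, p, M))

    if conditioning == "joint":
        _generate_joint(values, M, rng, ko)
    else:
        # per-chain state: A_m = [1 | X | chain-m knockoffs], G_m = A_m'A_m
        base = np.concatenate([np.ones((n, 1)), values], axis=1)
        G0 = base.T @ base
        A = [base] * M
        G = [G0] * M
        for j in range(p):
            for m in range(M):
                keep = np.arange(A[m].shape[1]) != (1 + j)
                beta = _solve_normal_equations(
                    G[m][np.ix_(keep, keep)], G[m][keep, 1 + j]
                )
                # avoid materializing A[:, keep]: insert a zero at the
                # excluded column and use the full matrix
                beta_full = np.insert(beta, 1 + j, 0.0)
                fitted = A[m] @ beta_full
                residuals = values[:, j] - fitted
                new = fitted + rng.permutation(residuals)
                ko[:, j, m] = new
                cross = A[m].T @ new
                k = G[m].shape[0]
                Gm = np.empty((k + 1, k + 1))
                Gm[:k, :k] = G[m]
                Gm[:k, k] = cross
                Gm[k, :k] = cross
                Gm[k, k] = new @ new
                G[m] = Gm
                A[m] = np.concatenate([A[m], new[:, None]], axis=1)

    copies = [
        pd.DataFrame(ko[:, :, m], columns=fm.columns) for m in range(M)
    ]
    return KnockoffSet(original=fm, copies=copies, M=M, seed=seed)


def _generate_joint(
    values: np.ndarray, M: int, rng: np.random.Generator, ko: np.ndarray
) -> None:
    """Pooled conditioning: one fit per column on X_{-j} plus the prior
    knockoffs of every copy, residual permuted M times."""
    n, p = values.shape
    A = np.concatenate([np.ones((n, 1)), values], axis=1)
    G = A.T @ A
    for j in range(p):
        keep = np.arange(A.shape[1]) != (1 + j)
        beta = _solve_normal_equations(G[np.ix_(keep, keep)], G[keep, 1 + j])
        fitted = A[:, keep] @ beta
        residuals = values[:, j] - fitted
        new = np.empty((n, M))
        for m in range(M):
            new[:, m] = fitted + rng.permutation(residuals)
        ko[:, j, :] = new
        cross = A.T @ new
        G = np.block([[G, cross], [cross.T, new.T @ new]])
        A = np.concatenate([A, new], axis=1)


def exchangeability_diagnostics(ks: KnockoffSet) -> pd.DataFrame:
    """Per feature and copy: mean difference, variance ratio, and the largest
    absolute discrepancy between corr(X~_j, X_k) and corr(X_j, X_k) over the
    other original columns k."""
    X = ks.original.values
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    corr_orig = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    rows = []
    for m, copy in enumerate(ks.copies, start=1):
        K = copy.to_numpy(dtype=float)
        mean_diff = K.mean(axis=0) - X.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_ratio = K.var(axis=0, ddof=1) / X.var(axis=0, ddof=1)
        for j in range(p):
            if p > 1 and sd[j] > 0:
                others = np.arange(p) != j
                kj = K[:, j]
                if kj.std(ddof=1) > 0:
                    cross = [
                        np.corrcoef(kj, X[:, k])[0, 1] for k in np.where(others)[0]
                    ]
                    disc = float(np.max(np.abs(np.array(cross) - corr_orig[j, others])))
                else:
                    disc = float(np.max(np.abs(corr_orig[j, others])))
            else:
                disc = 0.0
            rows.append(
                {
                    "feature": ks.original.columns[j],
                    "copy": m,
                    "mean_diff": float(mean_diff[j]),
                    "var_ratio": float(var_ratio[j]) if sd[j] > 0 else 1.0,
                    "max_corr_discrepancy": disc,
                }
            )
    return pd.DataFrame(rows)
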