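"""The multiple-knockoff filter: statistics, adaptive threshold, q-values.

For feature j with original importance T0_j and knockoff importances
T1_j..TM_j:

* W_j = (T0_j - median_m Tm_j) * 1[T0_j >= max_m Tm_j]
* kappa_j indexes the largest of {T0_j, T1_j..TM_j} (0 = original; ties go
  to the original, then the smallest copy index)
* tau_j = largest importance minus the median of the remaining M values

The FDR-adaptive threshold at target q is the smallest positive candidate t
(a positive tau_j value) with
(1/M + (1/M) #{kappa_j>=1, tau_j>=t}) / #{kappa_j=0, tau_j>=t} <= q, and the
knockoff q-value of feature j is the minimum of that ratio over candidates
t <= tau_j (features whose maximum is a knockoff get q_j = 1 and can never
be selected). Selecting {W_j >= tau} equals selecting {q_j <= q}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import ImportanceVector

__all__ = [
    "KnockoffStats",
    "SelectionResult",
    "knockoff_statistic",
    "kappa_tau",
    "q_values",
    "adaptive_threshold",
    "compute_stats",
    "select",
    "consensus",
    "rank_features",
]


@dataclass
class KnockoffStats:
    features: list[str]
    W: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray
    q: np.ndarray
    M: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "W": self.W,
                "kappa": self.kappa,
                "tau": self.tau,
                "q": self.q,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SelectionResult:
    target_fdr: float
    threshold: float  # +inf when nothing is selectable
    selected: list[str]
    stats: KnockoffStats

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "target_fdr": self.target_fdr,
                    "threshold": None if np.isinf(self.threshold) else self.threshold,
                    "selected": self.selected,
                },
                indent=1,
            )
        )


def _stack(iv: ImportanceVector) -> tuple[np.ndarray, np.ndarray]:
    t0 = iv.original.to_numpy(dtype=float)
    tm = iv.knockoffs.to_numpy(dtype=float)  # M x p
    if tm.shape[1] != t0.shape[0]:
        raise ValueError("original and knockoff importance lengths differ")
    return t0, tm


def knockoff_statistic(iv: ImportanceVector) -> np.ndarray:
    """W_j as defined above; the >= indicator lets exact ties with the
    knockoff maximum count as an original win."""
    t0, tm = _stack(iv)
    med = np.median(tm, axis=0)
    win = t0 >= tm.max(axis=0)
    return np.where(win, t0 - med, 0.0)


def kappa_tau(iv: ImportanceVector) -> tuple[np.ndarray, np.ndarray]:
    """kappa_j (argmax over {original, copies}, ties toward the original)
    and tau_j (max minus median of the remaining M values)."""
    t0, tm = _stack(iv)
    stacked = np.vstack([t0, tm])  # (M+1) x p
    # argmax of the boolean mask returns the smallest index achieving the max
    kappa = np.argmax(stacked >= stacked.max(axis=0), axis=0)
    p = stacked.shape[1]
    tau = np.empty(p)
    for j in range(p):
        col = stacked[:, j]
        k = kappa[j]
        rest = np.delete(col, k)
        tau[j] = col[k] - np.median(rest)
    return kappa, tau


def _ratio(kappa: np.ndarray, tau: np.ndarray, t: float, M: int) -> float:
    numer = 1.0 / M + (1.0 / M) * np.sum((kappa >= 1) & (tau >= t))
    denom = np.sum((kappa == 0) & (tau >= t))
    return numer / denom if denom > 0 else np.inf


def adaptive_threshold(
    kappa: np.ndarray, tau: np.ndarray, q: float, M: int
) -> float:
    """Smallest positive candidate threshold meeting the target-FDR bound;
    +inf when none qualifies. Candidates are the positive tau_j values (the
    ratio is a step function of t, so these attain the minimum)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    candidates = np.unique(tau[tau > 0])
    ok = [t for t in candidates if _ratio(kappa, tau, t, M) <= q]
    return float(min(ok)) if ok else np.inf


def q_values(kappa: np.ndarray, tau: np.ndarray, M: int) -> np.ndarray:
    """q_j = min over candidate t <= tau_j of the threshold ratio; features
    with kappa_j >= 1 (a knockoff wins) get q_j = 1."""
    candidates = np.unique(tau[tau > 0])
    ratios = np.array([_ratio(kappa, tau, t, M) for t in candidates])
    # prefix minima over descending t: min ratio across candidates <= tau_j
    order = np.argsort(candidates)
    qj = np.ones_like(tau, dtype=float)
    for j in range(tau.shape[0]):
        if kappa[j] != 0 or tau[j] <= 0:
            continue
        usable = ratios[order][candidates[order] <= tau[j]]
        if usable.size:
            qj[j] = min(1.0, float(usable.min()))
    return qj


def compute_stats(iv: ImportanceVector) -> KnockoffStats:
    W = knockoff_statistic(iv)
    kappa, tau = kappa_tau(iv)
    q = q_values(kappa, tau, iv.M)
    return KnockoffStats(
        features=iv.features, W=W, kappa=kappa, tau=tau, q=q, M=iv.M
    )


def select(stats: KnockoffStats, q: float) -> SelectionResult:
    """Features with W_j >= tau; asserts agreement with the q-value route
    (a mismatch means the two formulas have drifted apart)."""
    tau = adaptive_threshold(stats.kappa, stats.tau, q, stats.M)
    if np.isinf(tau):
        by_threshold: set[int] = set()
    else:
        by_threshold = set(np.where(stats.W >= tau)[0])
    by_q = set(np.where(stats.q <= q)[0])
    if by_threshold != by_q:
        raise AssertionError(
            "threshold and q-value selections disagree: "
            f"{sorted(by_threshold)} vs {sorted(by_q)}"
        )
    selected = [stats.features[j] for j in sorted(by_threshold)]
    return SelectionResult(
        target_fdr=q, threshold=tau, selected=selected, stats=stats
    )


def consensus(results: list[SelectionResult], min_votes: int = 3) -> list[str]:
    """Features selected by at least ``min_votes`` of the per-model results,
    in first-seen order."""
    if not results:
        raise ValueError("need at least one selection result")
    order: list[str] = []
    votes: dict[str, int] = {}
    for r in results:
        for f in r.selected:
            if f not in votes:
                votes[f] = 0
                order.append(f)
            votes[f] += 1
    return [f for f in order if votes[f] >= min_votes]


def rank_features(
    scores: pd.Series | np.ndarray,
    direction: str = "descending",
    names: list[str] | None = None,
) -> list[str]:
    """Stable ordering of features by score; ties break by column index."""
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    if isinstance(scores, pd.Series):
        names = list(scores.index)
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if names is None:
            names = [str(i) for i in range(values.shape[0])]
    key = values if direction == "ascending" else -values
    order = np.argsort(key, kind="stable")
    return [names[i] for i in order]
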