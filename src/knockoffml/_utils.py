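"""Shared small helpers: RNG stream management and table typing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one integer seed."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def child_seed(seed: int, index: int) -> int:
    """A deterministic 31-bit child seed (e.g. for library random_state args)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class FeatureMatrix:
    """A named numeric samples-by-features table.

    ``binary`` lists the 0/1 dummy-coded columns; everything else is treated as
    continuous. ``groups`` maps a base-variable name to the tuple of column
    names that are its sub-features (e.g. min/mean/max of one vital sign);
    columns not covered by any group are singletons.
    """

    frame: pd.DataFrame
    binary: frozenset[str] = frozenset()
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = set(self.frame.columns)
        unknown = set(self.binary) - cols
        if unknown:
            raise ValueError(f"binary columns not in table: {sorted(unknown)}")
        seen: set[str] = set()
        for name, members in self.groups.items():
            m = set(members)
            if not m <= cols:
                raise ValueError(f"group {name!r} references unknown columns")
            if m & seen:
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= m

    @property
    def n(self) -> int:
        return self.frame.shape[0]

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def kinds(self) -> pd.Series:
        return pd.Series(
            ["binary" if c in self.binary else "continuous" for c in self.frame.columns],
            index=self.frame.columns,
            name="kind",
        )

    def group_of(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {c: None for c in self.frame.columns}
        for name, members in self.groups.items():
            for c in members:
                out[c] = name
        return out


def as_frame(X, columns: Iterable[str] | None = None) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if columns is None:
        columns = [f"x{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(columns))
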