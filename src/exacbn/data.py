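"""Integer-coded discrete data with fast contingency-table queries.

Structure learning spends essentially all of its time counting cells of
marginal contingency tables.  :class:`DiscreteData` radix-encodes every row
into one integer once; when the full joint table is small enough it is
materialised with a single ``bincount`` and every marginal table is then a
axis-sum over that array, independent of the number of rows.  Bootstrap
resamples reuse the encoded vector, so a replicate costs one ``bincount``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DiscreteData", "ContinuousDataError"]

_JOINT_LIMIT = 1 << 21  # materialise the joint table up to ~2M cells


class ContinuousDataError(TypeError):
    """Raised when continuous columns reach a discrete-only routine."""


class DiscreteData:
    """Columns of categorical codes plus cached contingency tables."""

    def __init__(self, codes: np.ndarray, levels: list[np.ndarray],
                 columns: list[str]):
        self.codes = np.asarray(codes)
        self.levels = levels
        self.columns = list(columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        self.card = np.array([len(l) for l in levels], dtype=np.int64)
        self.n = self.codes.shape[0]
        self._memo: dict[tuple[int, ...], np.ndarray] = {}
        self._joint: np.ndarray | None = None
        self._encoded: np.ndarray | None = None
        if int(np.prod(self.card, dtype=np.float64)) <= _JOINT_LIMIT:
            self._encode_joint()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       columns: list[str] | None = None) -> "DiscreteData":
        cols = list(columns) if columns is not None else list(df.columns)
        codes = np.empty((len(df), len(cols)), dtype=np.int32)
        levels = []
        for j, c in enumerate(cols):
            s = df[c]
            if pd.api.types.is_float_dtype(s) and not _is_integral(s):
                raise ContinuousDataError(
                    f"column {c!r} is continuous; discretize it first "
                    "(fixed_clinical_cuts or discretize_hartemink)")
            if s.isna().any():
                raise ValueError(f"column {c!r} contains missing values")
            cat = pd.Categorical(s)
            codes[:, j] = cat.codes
            levels.append(np.asarray(cat.categories))
        return cls(codes, levels, cols)

    def _encode_joint(self) -> None:
        strides = np.ones(len(self.card), dtype=np.int64)
        for j in range(len(self.card) - 2, -1, -1):
            strides[j] = strides[j + 1] * self.card[j + 1]
        self._strides = strides
        enc = self.codes @ strides  # row -> cell id
        self._encoded = enc
        size = int(strides[0] * self.card[0])
        self._joint = np.bincount(enc, minlength=size).reshape(tuple(self.card))

    def bootstrap(self, rng: np.random.Generator,
                  m: int | None = None) -> "DiscreteData":
        """Resample rows with replacement (sharing level metadata)."""
        m = self.n if m is None else int(m)
        idx = rng.integers(0, self.n, size=m)
        out = object.__new__(DiscreteData)
        out.codes = self.codes[idx]
        out.levels = self.levels
        out.columns = self.columns
        out.index = self.index
        out.card = self.card
        out.n = m
        out._memo = {}
        out._joint = None
        out._encoded = None
        if self._encoded is not None:
            out._strides = self._strides
            enc = self._encoded[idx]
            out._encoded = enc
            size = int(self._strides[0] * self.card[0])
            out._joint = np.bincount(enc, minlength=size).reshape(tuple(self.card))
        return out

    def subset_columns(self, cols: list[str]) -> "DiscreteData":
        j = [self.index[c] for c in cols]
        return DiscreteData(self.codes[:, j], [self.levels[i] for i in j], cols)

    # -- counting ----------------------------------------------------------
    def counts(self, cols: tuple[str, ...] | list[str]) -> np.ndarray:
        """Contingency table over ``cols`` in the given axis order."""
        j = tuple(self.index[c] for c in cols)
        key = tuple(sorted(j))
        tab = self._memo.get(key)
        if tab is None:
            if self._joint is not None:
                axes = tuple(a for a in range(len(self.card)) if a not in key)
                tab = self._joint.sum(axis=axes, dtype=np.int64)
            else:
                tab = self._count_direct(key)
            self._memo[key] = tab
        # reorder axes from sorted order to requested order
        order = [sorted(j).index(a) for a in j]
        return np.transpose(tab, order) if order != list(range(len(j))) else tab

    def _count_direct(self, key: tuple[int, ...]) -> np.ndarray:
        card = self.card[list(key)]
        enc = np.zeros(self.n, dtype=np.int64)
        for a in key:
            enc = enc * self.card[a] + self.codes[:, a]
        size = int(np.prod(card))
        return np.bincount(enc, minlength=size).reshape(tuple(card))

    def n_levels(self, col: str) -> int:
        return int(self.card[self.index[col]])


def _is_integral(s: pd.Series) -> bool:
    vals = s.dropna().to_numpy()
    return bool(np.all(vals == np.round(vals)))
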