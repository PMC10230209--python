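"""Primary/duplicate case labeling under a chosen key.

For each key value the first (or, configurably, last) record holding it
is the *primary* case; every other holder is a *duplicate*. The count
of primaries equals the count of distinct key values regardless of
convention, so all downstream cross-tab counts are convention-invariant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["flag_primaries", "group_counts", "PrimaryFlagger"]


def flag_primaries(keys: Sequence, convention: str = "first") -> np.ndarray:
    """Boolean mask: True where the record is the primary holder of its key.

    Records are scanned in sequence order (the roster's record order);
    under ``first`` the earliest holder of each key value is primary,
    under ``last`` the latest.
    """
    if convention not in ("first", "last"):
        raise ValueError(f"convention must be 'first' or 'last', got {convention!r}")
    s = pd.Series(keys)
    return (~s.duplicated(keep=convention)).to_numpy()


def group_counts(keys: Sequence) -> tuple[int, int]:
    """(number of records, number of distinct key values)."""
    s = pd.Series(keys)
    return len(s), int(s.nunique(dropna=False))


class PrimaryFlagger(TransformerMixin, BaseEstimator):
    """Transformer adding a boolean primary-case column for ``key_col``.

    The output column is named ``<key_col>_primary``. Stateless; kept
    as an estimator so deduplication composes in a Pipeline after the
    hash encoder.
    """

    def __init__(self, key_col: str = "uid", convention: str = "first"):
        self.key_col = key_col
        self.convention = convention

    def fit(self, X: pd.DataFrame, y=None):
        if self.convention not in ("first", "last"):
            raise ValueError(
                f"convention must be 'first' or 'last', got {self.convention!r}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.key_col not in X.columns:
            raise KeyError(f"key column {self.key_col!r} not in input")
        out = X.copy()
        out[f"{self.key_col}_primary"] = flag_primaries(
            X[self.key_col].to_numpy(), self.convention
        )
        return out
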