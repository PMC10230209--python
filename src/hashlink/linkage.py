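"""One-to-one dataset linkage on the anonymous identifier.

Each roster is first reduced to one record per identifier (its primary
cases); the linkage count is then the size of the identifier-set
intersection. Matching is exact equality on the uid — no fuzzy
fallback. A strict mode refuses duplicate keys instead of collapsing
them, mimicking a hard one-to-one merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = ["LinkageReport", "link_one_to_one"]


@dataclass
class LinkageReport:
    """Counts from a one-to-one identifier match of two rosters."""

    matched: int
    left_only: int
    right_only: int
    left_duplicates_collapsed: int
    right_duplicates_collapsed: int
    matched_uids: list[str] | None = None

    @property
    def n_left_primaries(self) -> int:
        return self.matched + self.left_only

    @property
    def n_right_primaries(self) -> int:
        return self.matched + self.right_only

    def to_dict(self) -> dict:
        d = {
            "matched": self.matched,
            "left_only": self.left_only,
            "right_only": self.right_only,
            "n_left_primaries": self.n_left_primaries,
            "n_right_primaries": self.n_right_primaries,
            "left_duplicates_collapsed": self.left_duplicates_collapsed,
            "right_duplicates_collapsed": self.right_duplicates_collapsed,
        }
        if self.matched_uids is not None:
            d["matched_uids"] = self.matched_uids
        return d


def link_one_to_one(
    left: pd.DataFrame | Sequence[str],
    right: pd.DataFrame | Sequence[str],
    uid_col: str = "uid",
    strict: bool = False,
    keep_matched_uids: bool = False,
) -> LinkageReport:
    """Match two hashed rosters one-to-one on their identifiers.

    Parameters
    ----------
    left, right : DataFrame with a ``uid_col`` column, or a plain
        sequence of identifier strings.
    strict : bool
        Error on duplicate identifiers within a side instead of
        collapsing them to their primary record.
    keep_matched_uids : bool
        Include the sorted list of shared identifiers in the report.
    """
    def uids(x, side):
        s = pd.Series(x[uid_col] if isinstance(x, pd.DataFrame) else list(x), dtype="string")
        n_dup = int(s.duplicated().sum())
        if strict and n_dup:
            raise ValueError(
                f"{side} dataset has {n_dup} duplicate identifiers; "
                "deduplicate first or disable strict mode"
            )
        return set(s.dropna()), n_dup

    left_set, left_dup = uids(left, "left")
    right_set, right_dup = uids(right, "right")
    shared = left_set & right_set
    return LinkageReport(
        matched=len(shared),
        left_only=len(left_set) - len(shared),
        right_only=len(right_set) - len(shared),
        left_duplicates_collapsed=left_dup,
        right_duplicates_collapsed=right_dup,
        matched_uids=sorted(shared) if keep_matched_uids else None,
    )
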