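"""Roster data preparation: gender and service-number normalization.

Service rosters arrive as free-text CSV exports. Before an anonymous
identifier can be derived, the two key fields must be brought to a
canonical form: gender coded as ``M``/``F`` and the service number
uppercased, stripped of whitespace and checked against an expected
format. Records missing either key field are deleted (listwise), and
every exclusion is logged with a single reason so the record count is
fully auditable: ``|clean| + |excluded| = |raw|``.
"""

from __future__ import annotations

import re
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MISSING_GENDER",
    "MISSING_SERVICE_NUMBER",
    "INVALID_GENDER",
    "INVALID_SERVICE_NUMBER_FORMAT",
    "DEFAULT_SERVICE_PATTERN",
    "SERVICE_PATTERN_PRESETS",
    "normalize_gender",
    "normalize_service_number",
    "clean_roster",
    "RosterCleaner",
]

# Exclusion reason codes, in rule order (first failing rule wins).
MISSING_GENDER = "missing_gender"
INVALID_GENDER = "invalid_gender"
MISSING_SERVICE_NUMBER = "missing_service_number"
INVALID_SERVICE_NUMBER_FORMAT = "invalid_service_number_format"

#: Permissive default: any non-empty run of letters/digits after
#: canonicalization. Real deployments should pick a service-specific
#: preset or supply their own anchored pattern.
DEFAULT_SERVICE_PATTERN = r"^[A-Z0-9]+$"

#: Named presets for common service-number shapes.
SERVICE_PATTERN_PRESETS = {
    "any": DEFAULT_SERVICE_PATTERN,
    "two-letters-six-digits": r"^[A-Z]{2}[0-9]{6}$",
    "eight-digits": r"^[0-9]{8}$",
}

_GENDER_MAP = {"M": "M", "MALE": "M", "F": "F", "FEMALE": "F"}

_WS = re.compile(r"\s+")


def _is_absent(raw) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and np.isnan(raw):
        return True
    return isinstance(raw, str) and raw.strip() == ""


def normalize_gender(raw) -> tuple[str | None, str | None]:
    """Map free-text gender to the ``M``/``F`` coding.

    Trims surrounding whitespace and case-folds, then maps
    ``{m, male} -> M`` and ``{f, female} -> F``.

    Returns
    -------
    (code, reason)
        ``(code, None)`` on success; ``(None, reason)`` where reason is
        ``missing_gender`` for absent/blank input or ``invalid_gender``
        for anything outside the mapping. Never raises.
    """
    if _is_absent(raw):
        return None, MISSING_GENDER
    code = _GENDER_MAP.get(str(raw).strip().upper())
    if code is None:
        return None, INVALID_GENDER
    return code, None


def normalize_service_number(
    raw, pattern: str | re.Pattern = DEFAULT_SERVICE_PATTERN
) -> tuple[str | None, str | None]:
    """Canonicalize a service number and validate its format.

    Trims, uppercases and removes internal whitespace, then matches the
    result against ``pattern`` (an anchored regular expression, or one
    of the :data:`SERVICE_PATTERN_PRESETS` names).

    Returns
    -------
    (canonical, reason)
        ``(canonical, None)`` on success. Absent/blank input yields
        ``missing_service_number``; a pattern mismatch yields
        ``invalid_service_number_format`` with the canonicalized value
        still returned first for the audit trail caller to discard.
    """
    pat = _compile_pattern(pattern)
    if _is_absent(raw):
        return None, MISSING_SERVICE_NUMBER
    canonical = _WS.sub("", str(raw).strip().upper())
    if canonical == "":
        return None, MISSING_SERVICE_NUMBER
    if not pat.fullmatch(canonical):
        return canonical, INVALID_SERVICE_NUMBER_FORMAT
    return canonical, None


def _compile_pattern(pattern: str | re.Pattern) -> re.Pattern:
    if isinstance(pattern, re.Pattern):
        return pattern
    pattern = SERVICE_PATTERN_PRESETS.get(pattern, pattern)
    try:
        return re.compile(pattern)
    except re.error as exc:  # config error, surface at startup
        raise ValueError(f"malformed service-number pattern {pattern!r}: {exc}") from exc


def clean_roster(
    roster: pd.DataFrame,
    gender_col: str = "gender",
    service_col: str = "service_number",
    pattern: str | re.Pattern = DEFAULT_SERVICE_PATTERN,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply both normalizers to every record and delete failures.

    Records with a missing key field are always excluded; records whose
    service number fails the format check are excluded only when
    ``strict`` is set (otherwise the canonicalized value is kept and
    counted as a warning). Each excluded record carries exactly one
    reason: gender is checked before the service number.

    Parameters
    ----------
    roster : DataFrame
        One row per service contact. Row order is meaningful (it
        defines the ``record_index`` used for primary-case labeling).
    gender_col, service_col : str
        Names of the two key columns.
    pattern : str or compiled pattern
        Anchored service-number format, or a preset name.
    strict : bool
        Exclude (rather than keep) format-inconsistent service numbers.

    Returns
    -------
    clean : DataFrame
        Surviving records in input order, with a ``record_index``
        column (0-based position in the input), canonical ``gender``
        and ``service_number`` columns, and all auxiliary columns
        passed through untouched.
    exclusions : DataFrame
        Columns ``record_index`` and ``reason``.
    """
    pat = _compile_pattern(pattern)
    if gender_col not in roster.columns:
        raise KeyError(f"gender column {gender_col!r} not in roster")
    if service_col not in roster.columns:
        raise KeyError(f"service-number column {service_col!r} not in roster")

    genders: list[str | None] = []
    services: list[str | None] = []
    excl_idx: list[int] = []
    excl_reason: list[str] = []
    keep = np.ones(len(roster), dtype=bool)

    for i, (g_raw, s_raw) in enumerate(
        zip(roster[gender_col].to_numpy(), roster[service_col].to_numpy())
    ):
        g, g_flag = normalize_gender(g_raw)
        s, s_flag = normalize_service_number(s_raw, pat)
        reason = None
        if g_flag is not None:
            reason = g_flag
        elif s_flag == MISSING_SERVICE_NUMBER:
            reason = s_flag
        elif s_flag == INVALID_SERVICE_NUMBER_FORMAT and strict:
            reason = s_flag
        if reason is not None:
            keep[i] = False
            excl_idx.append(i)
            excl_reason.append(reason)
        else:
            genders.append(g)
            services.append(s)

    aux_cols = [c for c in roster.columns if c not in (gender_col, service_col)]
    clean = pd.DataFrame(
        {
            "record_index": np.nonzero(keep)[0],
            "gender": pd.array(genders, dtype="string"),
            "service_number": pd.array(services, dtype="string"),
        }
    )
    for c in aux_cols:
        clean[c] = roster[c].to_numpy()[keep]
    exclusions = pd.DataFrame(
        {"record_index": pd.array(excl_idx, dtype="int64"),
         "reason": pd.array(excl_reason, dtype="string")}
    )
    return clean, exclusions


class RosterCleaner(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`clean_roster`.

    Stateless by design — ``fit`` only validates the configured
    pattern — so the cleaner can sit at the head of a sklearn
    :class:`~sklearn.pipeline.Pipeline` feeding the hash encoder.

    Attributes
    ----------
    pattern_ : re.Pattern
        Compiled service-number pattern (set by ``fit``).
    exclusion_log_ : DataFrame
        Exclusion audit trail from the most recent ``transform``
        (columns ``record_index``, ``reason``).
    n_excluded_ : dict
        Exclusion counts per reason from the most recent ``transform``.
    """

    def __init__(
        self,
        gender_col: str = "gender",
        service_col: str = "service_number",
        pattern: str = DEFAULT_SERVICE_PATTERN,
        strict: bool = False,
    ):
        self.gender_col = gender_col
        self.service_col = service_col
        self.pattern = pattern
        self.strict = strict

    def fit(self, X: pd.DataFrame, y=None):
        self.pattern_ = _compile_pattern(self.pattern)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pattern_"):
            self.fit(X)
        clean, exclusions = clean_roster(
            X,
            gender_col=self.gender_col,
            service_col=self.service_col,
            pattern=self.pattern_,
            strict=self.strict,
        )
        self.exclusion_log_ = exclusions
        self.n_excluded_ = exclusions["reason"].value_counts().to_dict()
        return clean
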