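"""Diagnostic-accuracy validation of the hash identifier.

The hash identifier is validated against the current gold standard
(the service number alone) by cross-tabulating primary/duplicate status
under the two keys:

====================  ===============  ================
                      gold primary     gold duplicate
====================  ===============  ================
hash primary          a                b
hash duplicate        c                d
====================  ===============  ================

Sensitivity = a/(a+c) is the proportion of gold-standard unique records
the hash also calls unique; specificity = d/(b+d) the proportion of
gold-standard duplicates the hash also rejects. Because the hash input
contains the gold key, the hash partition refines the gold partition:
cell c is structurally zero and sensitivity is structurally 100%.
Cell b counts records where distinct individuals share a service number
but differ in gender — exactly the collisions the two-field hash
resolves.

Confidence intervals are Clopper–Pearson exact by default (Wilson score
available), the chi-square is the uncorrected Pearson statistic on the
2x2 table, and the ROC of a single-threshold binary classifier gives
AUC = (sensitivity + specificity)/2.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CrossTab2x2",
    "AccuracyReport",
    "cross_tabulate",
    "sensitivity_specificity",
    "exact_binomial_ci",
    "pearson_chi2",
    "binary_roc_auc",
    "build_report",
    "format_percent",
]


@dataclass(frozen=True)
class CrossTab2x2:
    """Agreement counts between gold-standard and hash primary status.

    a: gold-primary and hash-primary; b: gold-duplicate, hash-primary;
    c: gold-primary, hash-duplicate; d: gold-duplicate, hash-duplicate.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cross-tab counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def cross_tabulate(
    gold_primary: Sequence[bool], hash_primary: Sequence[bool]
) -> CrossTab2x2:
    """Count every record into one cell of the 2x2 table.

    The two label sequences must cover the same records in the same
    order; a length mismatch is a hard error.
    """
    g = np.asarray(gold_primary, dtype=bool)
    h = np.asarray(hash_primary, dtype=bool)
    if g.shape != h.shape:
        raise ValueError(
            f"label sequences cover different record sets: {g.shape} vs {h.shape}"
        )
    return CrossTab2x2(
        a=int(np.sum(g & h)),
        b=int(np.sum(~g & h)),
        c=int(np.sum(g & ~h)),
        d=int(np.sum(~g & ~h)),
    )


def sensitivity_specificity(t: CrossTab2x2) -> tuple[float | None, float | None]:
    """(a/(a+c), d/(b+d)); an empty margin yields None, never a silent 0."""
    sens = t.a / (t.a + t.c) if (t.a + t.c) > 0 else None
    spec = t.d / (t.b + t.d) if (t.b + t.d) > 0 else None
    return sens, spec


def exact_binomial_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float] | None:
    """Binomial confidence interval for a proportion.

    Clopper–Pearson exact by default: endpoints are beta-distribution
    quantiles inverting the binomial tails, with the closed-form
    boundaries (alpha/2)**(1/n) at successes == trials and
    1 - (alpha/2)**(1/n) at successes == 0. ``method='wilson'`` gives
    the Wilson score interval instead. ``trials == 0`` is undefined and
    returns None.
    """
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    if trials == 0:
        return None
    alpha = 1.0 - level
    if method == "wilson":
        return tuple(proportion_confint(successes, trials, alpha=alpha, method="wilson"))
    if method != "clopper-pearson":
        raise ValueError(f"unknown CI method {method!r}")
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


def pearson_chi2(t: CrossTab2x2) -> tuple[float, float] | None:
    """Uncorrected Pearson chi-square on the 2x2 table, with its p-value.

    statistic = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]; p from the
    chi-square distribution with 1 degree of freedom. No continuity
    correction. A zero margin leaves the statistic undefined (None).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = (a + b, c + d, a + c, b + d)
    if t.n == 0 or any(m == 0 for m in margins):
        return None
    # int arithmetic keeps the numerator exact for large counts
    stat = t.n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def binary_roc_auc(sensitivity: float, specificity: float) -> float:
    """AUC of the single-threshold binary classifier.

    Trapezoidal area over (0,0), (1-specificity, sensitivity), (1,1),
    which reduces algebraically to (sensitivity + specificity)/2.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def format_percent(p: float | None, decimals: int = 1) -> str:
    """Render a proportion as a percentage, round-half-up.

    One decimal place by default, with a trailing ``.0`` dropped so
    exact proportions print as e.g. ``100%``.
    """
    if p is None:
        return "undefined"
    q = (decimal.Decimal(str(p)) * 100).quantize(
        decimal.Decimal("1." + "0" * decimals), rounding=decimal.ROUND_HALF_UP
    )
    text = str(q)
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text + "%"


def _fmt3(x: float) -> str:
    return str(
        decimal.Decimal(str(x)).quantize(
            decimal.Decimal("1.000"), rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass
class AccuracyReport:
    """Validation statistics for one roster, with print formatting.

    Proportions are stored exact; rounding (percentages to one decimal
    place, chi-square to three, round-half-up) happens only in
    ``summary``/``to_dict``. ``p_value`` below 0.001 renders as
    ``p < 0.001``.
    """

    crosstab: CrossTab2x2
    sensitivity: float | None
    specificity: float | None
    sens_ci: tuple[float, float] | None
    spec_ci: tuple[float, float] | None
    chi2: float | None
    p_value: float | None
    auc: float | None
    ci_level: float = 0.95
    ci_method: str = "clopper-pearson"
    algorithm: str = "sha256"

    @property
    def undefined(self) -> list[str]:
        out = []
        if self.sensitivity is None:
            out.append("sensitivity")
        if self.specificity is None:
            out.append("specificity")
        if self.chi2 is None:
            out.append("chi2")
        return out

    def to_dict(self) -> dict:
        t = self.crosstab
        ci = lambda pair: None if pair is None else [pair[0], pair[1]]
        return {
            "crosstab": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n},
            "n_gold_primaries": t.a + t.c,
            "n_hash_primaries": t.a + t.b,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sens_ci": ci(self.sens_ci),
            "spec_ci": ci(self.spec_ci),
            "chi2": None if self.chi2 is None else round(self.chi2, 3),
            "p_value": self.p_value,
            "auc": self.auc,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "hash_algorithm": self.algorithm,
            "undefined": self.undefined,
            "formatted": self.summary(),
        }

    def summary(self) -> str:
        t = self.crosstab
        lines = [
            f"records: {t.n}",
            f"primary cases (gold standard): {t.a + t.c} "
            f"({format_percent(None if t.n == 0 else (t.a + t.c) / t.n)})",
            f"primary cases (hash identifier): {t.a + t.b} "
            f"({format_percent(None if t.n == 0 else (t.a + t.b) / t.n)})",
            f"cross-tab [a b; c d]: [{t.a} {t.b}; {t.c} {t.d}]",
        ]
        if self.sensitivity is not None and self.sens_ci is not None:
            lines.append(
                f"sensitivity: {format_percent(self.sensitivity)} "
                f"(95%CI {format_percent(self.sens_ci[0])}-{format_percent(self.sens_ci[1])})"
            )
        if self.specificity is not None and self.spec_ci is not None:
            lines.append(
                f"specificity: {format_percent(self.specificity)} "
                f"(95%CI {format_percent(self.spec_ci[0])}-{format_percent(self.spec_ci[1])})"
            )
        if self.chi2 is not None:
            p = "p < 0.001" if self.p_value < 0.001 else f"p = {_fmt3(self.p_value)}"
            lines.append(f"chi-square: {_fmt3(self.chi2)}, {p}")
        if self.auc is not None:
            lines.append(
                f"AUC [(sens+spec)/2]: {format_percent(self.auc, decimals=2)}"
            )
        if self.undefined:
            lines.append("undefined statistics: " + ", ".join(self.undefined))
        return "\n".join(lines)


def build_report(
    t: CrossTab2x2,
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
    algorithm: str = "sha256",
) -> AccuracyReport:
    """Compute every validation statistic for one cross-tabulation."""
    sens, spec = sensitivity_specificity(t)
    sens_ci = exact_binomial_ci(t.a, t.a + t.c, level, ci_method) if sens is not None else None
    spec_ci = exact_binomial_ci(t.d, t.b + t.d, level, ci_method) if spec is not None else None
    chi = pearson_chi2(t)
    auc = binary_roc_auc(sens, spec) if sens is not None and spec is not None else None
    return AccuracyReport(
        crosstab=t,
        sensitivity=sens,
        specificity=spec,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        chi2=None if chi is None else chi[0],
        p_value=None if chi is None else chi[1],
        auc=auc,
        ci_level=level,
        ci_method=ci_method,
        algorithm=algorithm,
    )
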