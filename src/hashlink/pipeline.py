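"""End-to-end orchestration: clean -> hash -> dedup -> validate / link.

`RunConfig` gathers every knob of the pipeline and is recorded verbatim
into each report for provenance. `build_pipeline` exposes the three
processing stages as a sklearn Pipeline; `run_validation` and
`run_linkage` execute the two analysis steps and optionally write
machine-readable outputs (JSON reports, CSV exclusion logs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from sklearn.pipeline import Pipeline

from .dedup import PrimaryFlagger, flag_primaries
from .hashing import HashIdentifier, HashSpec, assign_identifiers
from .linkage import LinkageReport, link_one_to_one
from .preprocess import DEFAULT_SERVICE_PATTERN, RosterCleaner, clean_roster
from .validate import AccuracyReport, build_report, cross_tabulate

__all__ = ["RunConfig", "build_pipeline", "run_validation", "run_linkage", "load_roster"]

log = logging.getLogger("hashlink")


class EmptyRosterError(RuntimeError):
    """No records survived cleaning; every statistic is undefined."""


@dataclass
class RunConfig:
    """All pipeline settings, validated up front.

    Defaults reproduce the reference analysis: hash input is
    (gender, service number), "|" delimiter, no salt, first-occurrence
    primary convention, Clopper–Pearson 95% intervals.
    """

    gender_col: str = "gender"
    service_col: str = "service_number"
    pattern: str = DEFAULT_SERVICE_PATTERN
    strict: bool = False
    delimiter: str = "|"
    salt: str = ""
    drop_identifiers: bool = False
    convention: str = "first"
    ci_level: float = 0.95
    ci_method: str = "clopper-pearson"

    def __post_init__(self):
        if self.convention not in ("first", "last"):
            raise ValueError(f"convention must be 'first' or 'last', got {self.convention!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.ci_method not in ("clopper-pearson", "wilson"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash_spec(self) -> HashSpec:
        return HashSpec(
            field_order=("gender", "service_number"),
            delimiter=self.delimiter,
            salt=self.salt,
        )


def build_pipeline(config: RunConfig | None = None) -> Pipeline:
    """sklearn Pipeline: RosterCleaner -> HashIdentifier -> PrimaryFlagger.

    The flagger labels the hash key; the gold-standard labels are added
    by `run_validation`, which needs the service-number column before
    any identifier dropping.
    """
    config = config or RunConfig()
    return Pipeline(
        [
            (
                "clean",
                RosterCleaner(
                    gender_col=config.gender_col,
                    service_col=config.service_col,
                    pattern=config.pattern,
                    strict=config.strict,
                ),
            ),
            (
                "hash",
                HashIdentifier(delimiter=config.delimiter, salt=config.salt),
            ),
            ("flag", PrimaryFlagger(key_col="uid", convention=config.convention)),
        ]
    )


def load_roster(path: str | Path) -> pd.DataFrame:
    """Read a roster CSV (UTF-8, header row required), all columns as text."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if df.columns.size == 0:
        raise ValueError(f"{path}: no header row")
    return df


def _prepare(roster: pd.DataFrame, config: RunConfig):
    """clean + hash + both dedup labelings; shared by the two steps."""
    clean, exclusions = clean_roster(
        roster,
        gender_col=config.gender_col,
        service_col=config.service_col,
        pattern=config.pattern,
        strict=config.strict,
    )
    log.info(
        "cleaned roster: %d raw, %d clean, %d excluded (%s)",
        len(roster),
        len(clean),
        len(exclusions),
        dict(exclusions["reason"].value_counts()) if len(exclusions) else {},
    )
    hashed = assign_identifiers(clean, config.hash_spec())
    return hashed, exclusions


def run_validation(
    roster: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[AccuracyReport, pd.DataFrame]:
    """Step 1: validate the hash identifier against the gold standard.

    Returns the accuracy report and the exclusion log; with ``outdir``
    also writes ``report.json``, ``exclusions.csv`` and the hashed
    roster (identifier columns dropped when the config says so).

    Raises :class:`EmptyRosterError` when no records survive cleaning.
    """
    config = config or RunConfig()
    if not isinstance(roster, pd.DataFrame):
        roster = load_roster(roster)
    hashed, exclusions = _prepare(roster, config)
    if len(hashed) == 0:
        raise EmptyRosterError(
            f"no records survived cleaning ({len(exclusions)} excluded); "
            "validation statistics undefined"
        )
    gold = flag_primaries(hashed["service_number"].to_numpy(), config.convention)
    hash_ = flag_primaries(hashed["uid"].to_numpy(), config.convention)
    tab = cross_tabulate(gold, hash_)
    report = build_report(tab, level=config.ci_level, ci_method=config.ci_method)
    log.info(
        "validation: n=%d gold-primaries=%d hash-primaries=%d",
        tab.n, tab.a + tab.c, tab.a + tab.b,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.to_dict()
        payload["config"] = asdict(config)
        (outdir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
        exclusions.to_csv(outdir / "exclusions.csv", index=False)
        out_roster = hashed.drop(columns=["gender", "service_number"]) if config.drop_identifiers else hashed
        out_roster.to_csv(outdir / "hashed_roster.csv", index=False)
    return report, exclusions


def run_linkage(
    left: pd.DataFrame | str | Path,
    right: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    keep_matched_uids: bool = False,
) -> LinkageReport:
    """Step 2: one-to-one linkage of two rosters on the hash identifier."""
    config = config or RunConfig()
    sides = []
    for r in (left, right):
        if not isinstance(r, pd.DataFrame):
            r = load_roster(r)
        hashed, _ = _prepare(r, config)
        sides.append(hashed)
    report = link_one_to_one(sides[0], sides[1], keep_matched_uids=keep_matched_uids)
    log.info(
        "linkage: matched=%d left_only=%d right_only=%d",
        report.matched, report.left_only, report.right_only,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.to_dict()
        payload["config"] = asdict(config)
        (outdir / "linkage.json").write_text(json.dumps(payload, indent=2) + "\n")
    return report
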