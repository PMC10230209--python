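"""Synthetic service rosters with known ground truth.

Real charity rosters are confidential, so validation is exercised on
generated ones that reproduce the structure the analysis assumes:

* a latent population of persons, most of them male, each holding a
  service number;
* repeated contacts — one roster row per contact, with a
  geometric-tailed number of contacts per person (a few heavy users);
* *collisions*: a small number of person pairs who share one service
  number but differ in gender — the data-quality phenomenon the
  two-field hash identifier resolves and the gold standard cannot;
* missing values in either key field (deleted downstream);
* formatting noise (case, whitespace) that normalization reverses.

Every generated roster carries a :class:`SyntheticTruth` giving the
latent person behind each record, so the expected value of every
downstream statistic can be recomputed by brute force, independently of
the pipeline's own code paths (:func:`oracle_statistics`).

All randomness flows from one seeded ``numpy.random.Generator``; a
fixed seed gives byte-identical output.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .validate import CrossTab2x2

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_population",
    "generate_roster",
    "oracle_statistics",
    "roster_from_crosstab",
]

_LETTERS = np.array(list(string.ascii_uppercase))
_DIGITS = np.array(list(string.digits))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the roster generator.

    n_persons : latent population size.
    n_records : total roster rows (>= n_persons; every person appears
        at least once, extras follow a geometric-tailed allocation).
    collision_pairs : person pairs planted to share one service number
        with discordant gender.
    same_gender_collision_pairs : pairs sharing a number with the SAME
        gender — undetectable by the two-field hash; off by default,
        provided to demonstrate that blind spot.
    missing_rate : per key field, probability a record's value is blank.
    noise_rate : probability a record's fields get reversible
        case/whitespace mangling.
    male_rate : P(male) for non-collision persons; service populations
        are heavily male, default 0.9.
    contact_geom_p : success parameter of the geometric weights that
        spread the extra contacts over persons (smaller = heavier tail).
    seed : generator seed.
    """

    n_persons: int = 1000
    n_records: int = 2500
    collision_pairs: int = 10
    same_gender_collision_pairs: int = 0
    missing_rate: float = 0.01
    noise_rate: float = 0.1
    male_rate: float = 0.9
    contact_geom_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.n_records < self.n_persons:
            raise ValueError("n_records must be >= n_persons")
        for name in ("missing_rate", "noise_rate", "male_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.contact_geom_p <= 1.0:
            raise ValueError("contact_geom_p must lie in (0, 1]")
        planted = 2 * (self.collision_pairs + self.same_gender_collision_pairs)
        if planted > self.n_persons:
            raise ValueError(
                f"{self.collision_pairs}+{self.same_gender_collision_pairs} collision "
                f"pairs need {planted} persons, only {self.n_persons} available"
            )


@dataclass
class SyntheticTruth:
    """Latent truth behind a generated roster.

    ``records`` is row-aligned with the emitted roster and carries the
    latent person_id, the canonical field values, and the planted
    missing/noise flags. The scalar counts summarize the population.
    """

    records: pd.DataFrame
    n_persons: int
    n_distinct_service_numbers: int
    n_distinct_pairs: int
    collision_pairs: int
    same_gender_collision_pairs: int
    n_missing_gender: int
    n_missing_service: int
    n_noised: int


def _random_service_numbers(n: int, rng: np.random.Generator) -> list[str]:
    """n distinct service numbers, two letters + six digits."""
    out: set[str] = set()
    while len(out) < n:
        k = n - len(out)
        letters = rng.choice(_LETTERS, size=(k, 2))
        digits = rng.choice(_DIGITS, size=(k, 6))
        for row_l, row_d in zip(letters, digits):
            out.add("".join(row_l) + "".join(row_d))
    return sorted(out)


def generate_population(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Latent persons: person_id, gender, service_number.

    Exactly ``collision_pairs`` service numbers are shared by two
    persons of different gender (and ``same_gender_collision_pairs`` by
    two persons of equal gender); all other numbers are unique.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_persons
    k_cross = config.collision_pairs
    k_same = config.same_gender_collision_pairs
    n_numbers = n - k_cross - k_same
    numbers = _random_service_numbers(n_numbers, rng)
    rng.shuffle(numbers)

    genders = np.where(rng.random(n) < config.male_rate, "M", "F").astype(object)
    service = [""] * n
    # persons 0..2k-1 hold the planted collisions; ids are shuffled into
    # roster order later so position carries no signal
    pos = 0
    for j in range(k_cross):
        service[pos] = numbers[j]
        service[pos + 1] = numbers[j]
        genders[pos], genders[pos + 1] = "M", "F"
        pos += 2
    for j in range(k_cross, k_cross + k_same):
        service[pos] = numbers[j]
        service[pos + 1] = numbers[j]
        g = "M" if rng.random() < config.male_rate else "F"
        genders[pos] = genders[pos + 1] = g
        pos += 2
    for j, i in enumerate(range(pos, n)):
        service[i] = numbers[k_cross + k_same + j]

    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "gender": genders.astype(str),
            "service_number": service,
        }
    )


def _mangle(value: str, rng: np.random.Generator) -> str:
    """Reversible formatting noise: case flips and stray whitespace."""
    chars = [c.lower() if rng.random() < 0.5 else c for c in value]
    s = "".join(chars)
    if rng.random() < 0.5 and len(s) > 1:  # internal space
        cut = int(rng.integers(1, len(s)))
        s = s[:cut] + " " + s[cut:]
    if rng.random() < 0.5:
        s = " " + s
    if rng.random() < 0.5:
        s = s + " "
    return s


_GENDER_NOISE = {"M": ["m", " M", "male", "Male", "MALE", "m "], "F": ["f", " F", "female", "Female", "FEMALE", "f "]}


def generate_roster(
    population: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a raw roster (one row per contact) plus its latent truth.

    Every person contributes at least one record; the
    ``n_records - n_persons`` extra contacts are spread with
    geometric-tailed weights. Noise applies only reversible formatting
    changes; missingness is applied after noise.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_persons = len(population)
    extras = config.n_records - n_persons
    weights = rng.geometric(config.contact_geom_p, size=n_persons).astype(float)
    extra_counts = rng.multinomial(extras, weights / weights.sum())
    counts = 1 + extra_counts

    person_rows = np.repeat(np.arange(n_persons), counts)
    rng.shuffle(person_rows)

    true_gender = population["gender"].to_numpy()[person_rows]
    true_service = np.asarray(population["service_number"], dtype=object)[person_rows]
    person_ids = population["person_id"].to_numpy()[person_rows]

    n_rec = config.n_records
    noised = rng.random(n_rec) < config.noise_rate
    miss_g = rng.random(n_rec) < config.missing_rate
    miss_s = rng.random(n_rec) < config.missing_rate

    out_gender: list[str | None] = []
    out_service: list[str | None] = []
    for i in range(n_rec):
        g, s = true_gender[i], true_service[i]
        if noised[i]:
            g = _GENDER_NOISE[g][int(rng.integers(len(_GENDER_NOISE[g])))]
            s = _mangle(s, rng)
        out_gender.append(None if miss_g[i] else g)
        out_service.append(None if miss_s[i] else s)

    roster = pd.DataFrame(
        {
            "gender": out_gender,
            "service_number": out_service,
            "contact_id": [f"C{i:07d}" for i in range(n_rec)],
        }
    )
    truth_records = pd.DataFrame(
        {
            "person_id": person_ids,
            "true_gender": true_gender,
            "true_service_number": true_service,
            "missing_gender": miss_g,
            "missing_service_number": miss_s,
            "noised": noised,
        }
    )
    pairs = set(zip(population["gender"], population["service_number"]))
    truth = SyntheticTruth(
        records=truth_records,
        n_persons=n_persons,
        n_distinct_service_numbers=int(population["service_number"].nunique()),
        n_distinct_pairs=len(pairs),
        collision_pairs=config.collision_pairs,
        same_gender_collision_pairs=config.same_gender_collision_pairs,
        n_missing_gender=int(miss_g.sum()),
        n_missing_service=int(miss_s.sum()),
        n_noised=int(noised.sum()),
    )
    return roster, truth


def oracle_statistics(truth: SyntheticTruth) -> dict:
    """Expected validation statistics, by brute force from the truth.

    Replays the cleaning and both dedup passes directly on the latent
    canonical fields with a plain first-occurrence scan — no shared
    code with the pipeline — and counts the four cross-tab cells one
    record at a time.
    """
    rec = truth.records
    survives = ~(rec["missing_gender"] | rec["missing_service_number"])
    seen_gold: set = set()
    seen_hash: set = set()
    a = b = c = d = 0
    for g, s, ok in zip(
        rec["true_gender"], rec["true_service_number"], survives
    ):
        if not ok:
            continue
        gold_primary = s not in seen_gold
        hash_primary = (g, s) not in seen_hash
        seen_gold.add(s)
        seen_hash.add((g, s))
        if gold_primary and hash_primary:
            a += 1
        elif not gold_primary and hash_primary:
            b += 1
        elif gold_primary and not hash_primary:
            c += 1
        else:
            d += 1
    n = a + b + c + d
    sens = a / (a + c) if a + c else None
    spec = d / (b + d) if b + d else None
    return {
        "crosstab": CrossTab2x2(a, b, c, d),
        "n_clean": n,
        "n_gold_primaries": a + c,
        "n_hash_primaries": a + b,
        "sensitivity": sens,
        "specificity": spec,
    }


def roster_from_crosstab(
    n_records: int,
    n_gold_primaries: int,
    n_hash_primaries: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct a clean roster realizing a given cross-tabulation.

    Builds ``n_gold_primaries`` service numbers, of which
    ``n_hash_primaries - n_gold_primaries`` are each held by an M/F
    person pair (the planted collisions), and pads with repeat contacts
    up to ``n_records``. The resulting roster's gold/hash cross-tab is
    exactly ``(a, b, c, d) = (n_gold, n_hash - n_gold, 0,
    n_records - n_hash)`` — useful for reconstructing any published
    validation table from its four cells.
    """
    if not n_gold_primaries <= n_hash_primaries <= n_records:
        raise ValueError("need n_gold_primaries <= n_hash_primaries <= n_records")
    if n_hash_primaries - n_gold_primaries > n_gold_primaries:
        raise ValueError("more collision pairs than service numbers")
    rng = np.random.default_rng(seed)
    numbers = _random_service_numbers(n_gold_primaries, rng)
    rng.shuffle(numbers)
    n_coll = n_hash_primaries - n_gold_primaries
    persons: list[tuple[str, str]] = []
    for j, sn in enumerate(numbers):
        if j < n_coll:
            persons.append(("M", sn))
            persons.append(("F", sn))
        else:
            persons.append(("M" if rng.random() < 0.9 else "F", sn))
    rows = list(persons)
    extra_of = rng.integers(0, len(persons), size=n_records - len(persons))
    rows.extend(persons[i] for i in extra_of)
    order = rng.permutation(len(rows))
    return pd.DataFrame(
        [rows[i] for i in order], columns=["gender", "service_number"]
    )
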