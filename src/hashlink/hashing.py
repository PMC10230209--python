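"""Anonymous unique identifiers from SHA-256 digests of key fields.

The identifier is the SHA-256 digest of a delimiter-joined canonical
string built from the configured fields (by default gender and service
number, optionally preceded by a secret salt). Equal field values give
equal identifiers, so repeated contacts by the same person collapse to
one key, while any differing field — in particular a differing gender
on a shared service number — yields a different identifier.

Delimiter joining (rather than bare concatenation) keeps the encoding
injective: ``("M", "1A")`` and ``("M1", "A")`` hash differently. An
unsalted digest of a small identifier space can be reversed by
enumeration, so real deployments must set a secret salt; the default is
empty only so that worked examples are reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["HashSpec", "make_hash_input", "digest", "assign_identifiers", "HashIdentifier"]

ALGORITHM = "sha256"


@dataclass(frozen=True)
class HashSpec:
    """Configuration of the identifier derivation.

    field_order : ordered, duplicate-free field names taken from the
        clean record; delimiter : separator that must not occur inside
        any field value; salt : optional secret prefix (empty = none).
    """

    field_order: tuple[str, ...] = ("gender", "service_number")
    delimiter: str = "|"
    salt: str = ""
    algorithm: str = ALGORITHM

    def __post_init__(self):
        if not self.field_order:
            raise ValueError("field_order must be non-empty")
        if len(set(self.field_order)) != len(self.field_order):
            raise ValueError("field_order must be duplicate-free")
        if self.algorithm != ALGORITHM:
            raise ValueError(f"unsupported hash algorithm {self.algorithm!r}")


def make_hash_input(values: dict, spec: HashSpec = HashSpec(), record_index=None) -> str:
    """Join salt and field values into the canonical pre-image string.

    Raises ``ValueError`` naming the offending record if the delimiter
    occurs inside any field value (which would make the concatenation
    ambiguous).
    """
    parts = [] if spec.salt == "" else [spec.salt]
    for name in spec.field_order:
        value = str(values[name])
        if spec.delimiter in value:
            where = "" if record_index is None else f" (record_index={record_index})"
            raise ValueError(
                f"delimiter {spec.delimiter!r} occurs inside field {name}={value!r}{where}"
            )
        parts.append(value)
    return spec.delimiter.join(parts)


def digest(canonical: str) -> str:
    """SHA-256 of the UTF-8 encoding, as 64 lowercase hex characters."""
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def assign_identifiers(
    records: pd.DataFrame, spec: HashSpec = HashSpec(), drop_identifiers: bool = False
) -> pd.DataFrame:
    """Add a ``uid`` column to a cleaned roster.

    Order-preserving and deterministic: running twice, on any platform,
    yields byte-identical identifiers. With ``drop_identifiers`` the
    personal fields used as hash input are removed from the output, so
    downstream stages see only the anonymous key.
    """
    missing = [f for f in spec.field_order if f not in records.columns]
    if missing:
        raise KeyError(f"hash input fields absent from roster: {missing}")
    out = records.copy()
    idx = records["record_index"] if "record_index" in records.columns else records.index
    uids = [
        digest(make_hash_input(dict(zip(spec.field_order, row)), spec, record_index=ri))
        for ri, *row in zip(idx, *(records[f] for f in spec.field_order))
    ]
    out["uid"] = pd.array(uids, dtype="string")
    if drop_identifiers:
        out = out.drop(columns=list(spec.field_order))
    return out


class HashIdentifier(TransformerMixin, BaseEstimator):
    """Transformer that derives the anonymous ``uid`` column.

    Parameters mirror :class:`HashSpec`; ``drop_identifiers`` enforces
    the anonymity contract by removing the hash-input fields from every
    output after the identifier is derived.
    """

    def __init__(
        self,
        fields: tuple[str, ...] = ("gender", "service_number"),
        delimiter: str = "|",
        salt: str = "",
        drop_identifiers: bool = False,
    ):
        self.fields = fields
        self.delimiter = delimiter
        self.salt = salt
        self.drop_identifiers = drop_identifiers

    def fit(self, X: pd.DataFrame, y=None):
        self.spec_ = HashSpec(
            field_order=tuple(self.fields), delimiter=self.delimiter, salt=self.salt
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "spec_"):
            self.fit(X)
        return assign_identifiers(X, self.spec_, drop_identifiers=self.drop_identifiers)
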