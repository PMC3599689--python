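"""Predicate-driven filtering and splitting of record containers.

A :class:`FilterSpec` is a small closed vocabulary of atomic clauses over
one molecule record — atom/bond count ranges, element presence/absence,
molecule-name regex, bond-type presence, and a clean-consistency check —
combined with ``all`` or ``any`` and optionally negated.
:func:`filter_collection` applies a spec in one streaming pass, routing
every entry to exactly one of the accept/reject outputs with order
preserved, so a spec and its negation always partition a collection.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field

from .container import ContainerWriter, KIND_MOLENTRY, read_records
from .errors import FilterSpecError, MolstreamError
from .model import MolEntry, check_entry

__all__ = [
    "Clause",
    "FilterSpec",
    "atom_count_in",
    "bond_count_in",
    "contains_element",
    "lacks_element",
    "name_matches",
    "has_bond_type",
    "passes_check",
    "parse_clause",
    "filter_collection",
]

_CLAUSE_KINDS = {
    "atom_count_in", "bond_count_in", "contains_element", "lacks_element",
    "name_matches", "has_bond_type", "passes_check",
}


@dataclass(frozen=True)
class Clause:
    """One atomic predicate; ``kind`` selects the test, ``params`` its
    arguments (validated eagerly, before any I/O)."""

    kind: str
    params: tuple = ()

    def __post_init__(self):
        if self.kind not in _CLAUSE_KINDS:
            raise FilterSpecError(f"unknown clause kind {self.kind!r}")
        if self.kind in ("atom_count_in", "bond_count_in"):
            lo, hi = self.params
            if lo > hi:
                raise FilterSpecError(
                    f"{self.kind}: lower bound {lo} exceeds upper bound {hi}")
        if self.kind == "name_matches":
            try:
                re.compile(self.params[0])
            except re.error as exc:
                raise FilterSpecError(
                    f"invalid regular expression "
                    f"{self.params[0]!r}: {exc}") from None

    def evaluate(self, entry: MolEntry) -> bool:
        k = self.kind
        if k == "atom_count_in":
            lo, hi = self.params
            return lo <= len(entry.atoms) <= hi
        if k == "bond_count_in":
            lo, hi = self.params
            return lo <= len(entry.bonds) <= hi
        if k == "contains_element":
            return any(a.symbol == self.params[0] for a in entry.atoms)
        if k == "lacks_element":
            return all(a.symbol != self.params[0] for a in entry.atoms)
        if k == "name_matches":
            return re.search(self.params[0],
                             entry.header.molecule_name) is not None
        if k == "has_bond_type":
            return any(b.bond_type == self.params[0] for b in entry.bonds)
        if k == "passes_check":
            return not check_entry(entry)
        raise AssertionError(k)


def atom_count_in(lo: int, hi: float = math.inf) -> Clause:
    return Clause("atom_count_in", (lo, hi))


def bond_count_in(lo: int, hi: float = math.inf) -> Clause:
    return Clause("bond_count_in", (lo, hi))


def contains_element(symbol: str) -> Clause:
    return Clause("contains_element", (symbol,))


def lacks_element(symbol: str) -> Clause:
    return Clause("lacks_element", (symbol,))


def name_matches(pattern: str) -> Clause:
    return Clause("name_matches", (pattern,))


def has_bond_type(code: int) -> Clause:
    return Clause("has_bond_type", (code,))


def passes_check() -> Clause:
    return Clause("passes_check")


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction/disjunction of clauses, optionally negated."""

    clauses: tuple[Clause, ...]
    combinator: str = "all"  # "all" | "any"
    negate: bool = False

    def __post_init__(self):
        if not self.clauses:
            raise FilterSpecError("a filter spec needs at least one clause")
        if self.combinator not in ("all", "any"):
            raise FilterSpecError(
                f"combinator must be 'all' or 'any', got {self.combinator!r}")

    def evaluate(self, entry: MolEntry) -> bool:
        combine = all if self.combinator == "all" else any
        result = combine(c.evaluate(entry) for c in self.clauses)
        return (not result) if self.negate else result

    def negated(self) -> "FilterSpec":
        return FilterSpec(self.clauses, self.combinator, not self.negate)


def _parse_range(text: str) -> tuple[int, float]:
    lo_s, _, hi_s = text.partition(":")
    try:
        lo = int(lo_s) if lo_s.strip() else 0
        hi = math.inf if hi_s.strip() in ("", "*") else int(hi_s)
    except ValueError:
        raise FilterSpecError(f"bad count range {text!r}; expected "
                              f"LO:HI (HI may be '*')") from None
    return lo, hi


def parse_clause(text: str) -> Clause:
    """Parse one CLI/config clause like ``contains-element=N`` or
    ``atom-count=2:9``.  Recognized keys: atom-count, bond-count,
    contains-element, lacks-element, name-matches, has-bond-type,
    passes-check (valueless)."""
    key, sep, value = text.partition("=")
    key = key.strip()
    if key == "atom-count":
        return atom_count_in(*_parse_range(value))
    if key == "bond-count":
        return bond_count_in(*_parse_range(value))
    if key == "contains-element":
        return contains_element(value.strip())
    if key == "lacks-element":
        return lacks_element(value.strip())
    if key == "name-matches":
        return name_matches(value)
    if key == "has-bond-type":
        try:
            return has_bond_type(int(value))
        except ValueError:
            raise FilterSpecError(
                f"has-bond-type needs an integer code, got {value!r}"
            ) from None
    if key == "passes-check" and not sep:
        return passes_check()
    raise FilterSpecError(f"unrecognized filter clause {text!r}")


def filter_collection(container_path: str | os.PathLike,
                      spec: FilterSpec,
                      accept_path: str | os.PathLike,
                      reject_path: str | os.PathLike | None = None
                      ) -> tuple[int, int, int]:
    """Split a container by *spec* in one streaming pass.

    Every entry goes to exactly one side; order is preserved within each
    output.  Returns ``(n_in, n_accepted, n_rejected)``.  When
    *reject_path* is omitted, rejected entries are counted but dropped.
    """
    if not isinstance(spec, FilterSpec):
        raise FilterSpecError("spec must be a FilterSpec")
    n_in = n_acc = n_rej = 0
    accept_w = ContainerWriter(accept_path)
    reject_w = ContainerWriter(reject_path) if reject_path else None
    try:
        for rec in read_records(container_path):
            if rec.content_kind != KIND_MOLENTRY:
                raise MolstreamError(
                    f"cannot filter record {rec.object_name!r} of kind "
                    f"{rec.content_kind!r}; expected molecule records")
            n_in += 1
            if spec.evaluate(rec.object_content):
                n_acc += 1
                accept_w.append(rec)
            else:
                n_rej += 1
                if reject_w is not None:
                    reject_w.append(rec)
    except BaseException:
        accept_w.abort()
        if reject_w is not None:
            reject_w.abort()
        raise
    accept_w.close()
    if reject_w is not None:
        reject_w.close()
    return n_in, n_acc, n_rej
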