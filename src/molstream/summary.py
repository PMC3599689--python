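"""Collection-level statistics and plain-text reports.

:func:`summarize_collection` makes a single streaming pass over a
container of molecule records and accumulates entry counts, atom/bond
count distributions, element and bond-type frequencies and a consistency
tally.  :func:`merge_summaries` combines summaries of disjoint
collections, so summarizing a concatenation equals merging the parts.
:func:`summary_report` renders a summary as a deterministic text report
(identical summaries give byte-identical reports).

Quartiles use linear interpolation between order statistics (the numpy
default), so reported distributions are reproducible across
implementations that document the same convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .container import KIND_MOLENTRY, read_records
from .errors import MolstreamError
from .model import MolEntry, check_entry

__all__ = [
    "CountStats",
    "CollectionSummary",
    "summarize_collection",
    "merge_summaries",
    "summary_report",
    "format_summary_report",
]


@dataclass(frozen=True)
class CountStats:
    """min / max / mean / quartiles of a per-entry count."""

    min: float
    max: float
    mean: float
    q1: float
    median: float
    q3: float

    @classmethod
    def from_values(cls, values: list[int]) -> "CountStats | None":
        if not values:
            return None
        arr = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
        return cls(min=float(arr.min()), max=float(arr.max()),
                   mean=float(arr.mean()), q1=float(q1), median=float(med),
                   q3=float(q3))


@dataclass
class CollectionSummary:
    """Per-collection statistics of a container of molecule records.

    ``element_frequency`` counts atoms per element symbol across the whole
    collection (case-sensitive, exactly as in the atom block), so its
    values sum to the collection's total atom count; likewise
    ``bond_type_frequency`` over bond-type codes.  ``per_entry_index``
    keeps (object_name, n_atoms, n_bonds) in container order.
    """

    n_entries: int = 0
    element_frequency: dict[str, int] = field(default_factory=dict)
    bond_type_frequency: dict[int, int] = field(default_factory=dict)
    n_entries_with_violations: int = 0
    per_entry_index: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def atom_count_stats(self) -> CountStats | None:
        return CountStats.from_values([a for _, a, _ in self.per_entry_index])

    @property
    def bond_count_stats(self) -> CountStats | None:
        return CountStats.from_values([b for _, _, b in self.per_entry_index])

    @property
    def total_atoms(self) -> int:
        return sum(self.element_frequency.values())

    @property
    def total_bonds(self) -> int:
        return sum(self.bond_type_frequency.values())

    def add_entry(self, name: str, entry: MolEntry) -> None:
        self.n_entries += 1
        self.per_entry_index.append((name, len(entry.atoms),
                                     len(entry.bonds)))
        for atom in entry.atoms:
            self.element_frequency[atom.symbol] = \
                self.element_frequency.get(atom.symbol, 0) + 1
        for bond in entry.bonds:
            self.bond_type_frequency[bond.bond_type] = \
                self.bond_type_frequency.get(bond.bond_type, 0) + 1
        if check_entry(entry):
            self.n_entries_with_violations += 1

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "element_frequency": dict(self.element_frequency),
            "bond_type_frequency": {str(k): v for k, v
                                    in self.bond_type_frequency.items()},
            "n_entries_with_violations": self.n_entries_with_violations,
            "per_entry_index": [list(t) for t in self.per_entry_index],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CollectionSummary":
        return cls(
            n_entries=d["n_entries"],
            element_frequency=dict(d["element_frequency"]),
            bond_type_frequency={int(k): v for k, v
                                 in d["bond_type_frequency"].items()},
            n_entries_with_violations=d["n_entries_with_violations"],
            per_entry_index=[(n, a, b) for n, a, b in d["per_entry_index"]],
        )


def summarize_collection(container_path: str | os.PathLike
                         ) -> CollectionSummary:
    """Summarize a container of molecule records in one streaming pass."""
    summary = CollectionSummary()
    for rec in read_records(container_path):
        if rec.content_kind != KIND_MOLENTRY:
            raise MolstreamError(
                f"cannot summarize record {rec.object_name!r} of kind "
                f"{rec.content_kind!r}; expected molecule records")
        summary.add_entry(rec.object_name, rec.object_content)
    return summary


def merge_summaries(a: CollectionSummary,
                    b: CollectionSummary) -> CollectionSummary:
    """Summary of the concatenation A ++ B from the two part summaries."""
    elem = dict(a.element_frequency)
    for k, v in b.element_frequency.items():
        elem[k] = elem.get(k, 0) + v
    btf = dict(a.bond_type_frequency)
    for k, v in b.bond_type_frequency.items():
        btf[k] = btf.get(k, 0) + v
    return CollectionSummary(
        n_entries=a.n_entries + b.n_entries,
        element_frequency=elem,
        bond_type_frequency=btf,
        n_entries_with_violations=(a.n_entries_with_violations
                                   + b.n_entries_with_violations),
        per_entry_index=list(a.per_entry_index) + list(b.per_entry_index),
    )


def _stats_lines(label: str, stats: CountStats | None) -> list[str]:
    if stats is None:
        return [f"{label}: (no entries)"]
    return [
        f"{label}: min {stats.min:g}  q1 {stats.q1:g}  median "
        f"{stats.median:g}  q3 {stats.q3:g}  max {stats.max:g}  "
        f"mean {stats.mean:.4f}"
    ]


def format_summary_report(summary: CollectionSummary) -> str:
    """Render the deterministic plain-text report.

    Frequency tables are sorted by descending count, ties broken
    lexicographically (elements) or by ascending code (bond types), so two
    equal summaries always render to identical bytes.
    """
    lines: list[str] = []
    lines.append("molstream collection summary")
    lines.append("============================")
    lines.append("")
    lines.append("Collection totals")
    lines.append("-----------------")
    lines.append(f"entries:                 {summary.n_entries}")
    lines.append(f"total atoms:             {summary.total_atoms}")
    lines.append(f"total bonds:             {summary.total_bonds}")
    lines.append(f"entries with violations: "
                 f"{summary.n_entries_with_violations}")
    lines.append("")
    lines.append("Atom/bond count distributions")
    lines.append("-----------------------------")
    lines.extend(_stats_lines("atoms per entry", summary.atom_count_stats))
    lines.extend(_stats_lines("bonds per entry", summary.bond_count_stats))
    lines.append("")
    lines.append("Element frequencies")
    lines.append("-------------------")
    for sym, count in sorted(summary.element_frequency.items(),
                             key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"{sym:<3} {count}")
    lines.append("")
    lines.append("Bond-type frequencies")
    lines.append("---------------------")
    for code, count in sorted(summary.bond_type_frequency.items(),
                              key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"type {code}: {count}")
    lines.append("")
    return "\n".join(lines)


def summary_report(summary: CollectionSummary,
                   out_path: str | os.PathLike) -> None:
    """Write the plain-text report for *summary* to *out_path*."""
    text = format_summary_report(summary)
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write(text)
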