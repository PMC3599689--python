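"""Deterministic synthesis of V2000 SD-file text: canned reference
molecules and a seeded generator of valid (and deliberately corrupted)
entries.

Every other module is testable against this one with no external data.
Generated molecules are random connected trees over a weighted element
alphabet, optionally with extra edges to create rings; coordinates are
all 0.0000 — these are molecular *graphs*, not geometries, and no
consumer should read 3D information out of them.  The random source is
Python's :class:`random.Random` (Mersenne Twister) with integer seeding:
one spec, one seed, one byte-identical SD-file and manifest.

The manifest returned by :func:`generate_sdf` records per entry the name,
atom/bond counts, element composition and whether (and how) the entry was
corrupted; it is the ground truth that parser, summary and filter tests
compare against.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from .errors import FixtureSpecError
from .model import (Atom, Bond, CountsLine, EntryHeader, MolEntry,
                    entry_to_molfile_text)

__all__ = [
    "GenSpec",
    "ManifestRow",
    "generate_sdf",
    "write_manifest_tsv",
    "canned_fixture",
    "CANNED_FIXTURE_NAMES",
]

CORRUPTION_KINDS = ("truncated-block", "bad-counts", "out-of-range-bond",
                    "garbled-field")


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one synthetic SD-file.

    ``element_alphabet`` is a tuple of (symbol, weight) pairs sampled per
    atom.  ``topology`` is ``"tree"`` (connected random tree, so
    n_bonds = n_atoms - 1) or ``"tree-plus-cycles"`` (tree plus each
    non-tree pair added independently with probability ``p_extra_edge``).
    ``corruption_kind`` of ``"mixed"`` draws uniformly among the four
    corruption kinds for each corrupted entry.
    """

    n_molecules: int
    atom_count_range: tuple[int, int] = (2, 9)
    element_alphabet: tuple[tuple[str, float], ...] = (
        ("C", 12.0), ("N", 2.0), ("O", 2.0), ("S", 1.0))
    topology: str = "tree"
    p_extra_edge: float = 0.0
    seed: int = 0
    corruption_kind: str | None = None
    corruption_rate: float = 0.0

    def __post_init__(self):
        lo, hi = self.atom_count_range
        if lo < 1 or lo > hi:
            raise FixtureSpecError(
                f"atom_count_range must satisfy 1 <= lo <= hi, got "
                f"{self.atom_count_range}")
        if self.n_molecules < 0:
            raise FixtureSpecError("n_molecules must be non-negative")
        if not self.element_alphabet or any(w <= 0 for _, w
                                            in self.element_alphabet):
            raise FixtureSpecError("element_alphabet needs positive weights")
        if self.topology not in ("tree", "tree-plus-cycles"):
            raise FixtureSpecError(f"unknown topology {self.topology!r}")
        if not 0.0 <= self.p_extra_edge <= 1.0:
            raise FixtureSpecError("p_extra_edge must be in [0, 1]")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise FixtureSpecError("corruption rate must be in [0, 1]")
        if self.corruption_rate > 0 and self.corruption_kind not in (
                CORRUPTION_KINDS + ("mixed",)):
            raise FixtureSpecError(
                f"corruption_kind must be one of {CORRUPTION_KINDS} or "
                f"'mixed' when corruption_rate > 0, got "
                f"{self.corruption_kind!r}")


@dataclass
class ManifestRow:
    """Ground truth for one generated entry (pre-corruption values)."""

    name: str
    n_atoms: int
    n_bonds: int
    element_counts: dict[str, int] = field(default_factory=dict)
    corrupted: bool = False
    corruption_kind: str = ""


def _standard_tail() -> tuple[str, ...]:
    return ("  0",) * 6


def _make_atom(symbol: str) -> Atom:
    return Atom(x=0.0, y=0.0, z=0.0, symbol=symbol,
                remaining_fields=_standard_tail())


def _random_molecule(rng: random.Random, spec: GenSpec, name: str,
                     min_atoms: int = 1) -> MolEntry:
    lo, hi = spec.atom_count_range
    lo = max(lo, min_atoms)
    hi = max(hi, lo)
    k = rng.randint(lo, hi)
    symbols = rng.choices([s for s, _ in spec.element_alphabet],
                          weights=[w for _, w in spec.element_alphabet], k=k)
    edges: list[tuple[int, int]] = []
    for i in range(2, k + 1):
        edges.append((rng.randint(1, i - 1), i))
    if spec.topology == "tree-plus-cycles" and spec.p_extra_edge > 0:
        present = {(min(u, v), max(u, v)) for u, v in edges}
        for u in range(1, k + 1):
            for v in range(u + 1, k + 1):
                if (u, v) not in present and rng.random() < spec.p_extra_edge:
                    edges.append((u, v))
    atoms = [_make_atom(s) for s in symbols]
    bonds = [Bond(first_atom=u, second_atom=v, bond_type=1)
             for u, v in edges]
    return MolEntry(
        header=EntryHeader(molecule_name=name,
                           program_line="  molstream synthetic",
                           comment=""),
        counts=CountsLine(n_atoms=k, n_bonds=len(bonds)),
        atoms=atoms, bonds=bonds)


def _corrupt_text(text: str, kind: str, entry: MolEntry,
                  rng: random.Random) -> str:
    """Damage one rendered Molfile so the pipeline must reject it."""
    lines = text.split("\n")
    n_atoms, n_bonds = len(entry.atoms), len(entry.bonds)
    if kind == "truncated-block":
        # drop the last atom line; counts then over-declare the block
        del lines[4 + n_atoms - 1]
    elif kind == "bad-counts":
        lines[3] = " x " + lines[3][3:]
    elif kind == "out-of-range-bond":
        row = 4 + n_atoms  # first bond line
        bad = n_atoms + 1 + rng.randint(1, 9)
        b = entry.bonds[0]
        lines[row] = (f"{b.first_atom:3d}{bad:3d}{b.bond_type:3d}"
                      f"  0  0  0  0")
    elif kind == "garbled-field":
        if n_bonds:
            row = 4 + n_atoms
            lines[row] = lines[row][:6] + " X " + lines[row][9:]
        else:
            row = 4
            lines[row] = lines[row][:36] + " X " + lines[row][39:]
    else:  # pragma: no cover
        raise FixtureSpecError(f"unknown corruption kind {kind!r}")
    return "\n".join(lines)


def generate_sdf(spec: GenSpec, out_path: str | os.PathLike,
                 manifest_path: str | os.PathLike | None = None
                 ) -> list[ManifestRow]:
    """Write a synthetic SD-file and return its ground-truth manifest.

    An entry is corrupted with probability ``corruption_rate``; the
    corruption kinds map to the pipeline's failure stages: truncated
    atom block and garbled fixed-width fields fail at parse, a bad counts
    line fails at the counts stage, and an out-of-range bond index parses
    cleanly but fails the consistency check.  Corruptions needing at
    least one bond force a minimum of two atoms.
    """
    rng = random.Random(spec.seed)
    manifest: list[ManifestRow] = []
    with open(out_path, "w", encoding="utf-8", newline="") as fh:
        for i in range(1, spec.n_molecules + 1):
            name = f"gen_{i:06d}"
            corrupt = (spec.corruption_rate > 0
                       and rng.random() < spec.corruption_rate)
            kind = ""
            if corrupt:
                kind = (rng.choice(CORRUPTION_KINDS)
                        if spec.corruption_kind == "mixed"
                        else spec.corruption_kind)  # type: ignore[assignment]
            needs_bond = kind in ("out-of-range-bond",)
            entry = _random_molecule(rng, spec, name,
                                     min_atoms=2 if needs_bond else 1)
            text = entry_to_molfile_text(entry)
            if corrupt:
                text = _corrupt_text(text, kind, entry, rng)
            fh.write(text)
            fh.write("$$$$\n")
            counts: dict[str, int] = {}
            for a in entry.atoms:
                counts[a.symbol] = counts.get(a.symbol, 0) + 1
            manifest.append(ManifestRow(
                name=name, n_atoms=len(entry.atoms),
                n_bonds=len(entry.bonds), element_counts=counts,
                corrupted=corrupt, corruption_kind=kind))
    if manifest_path is not None:
        write_manifest_tsv(manifest, manifest_path)
    return manifest


def write_manifest_tsv(manifest: list[ManifestRow],
                       path: str | os.PathLike) -> None:
    """Manifest as TSV: name, n_atoms, n_bonds, element_counts
    (``SYM:COUNT`` pairs joined by ``;``), corrupted (0/1),
    corruption_kind."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("name\tn_atoms\tn_bonds\telement_counts\tcorrupted\t"
                 "corruption_kind\n")
        for row in manifest:
            comp = ";".join(f"{s}:{c}" for s, c
                            in sorted(row.element_counts.items()))
            fh.write(f"{row.name}\t{row.n_atoms}\t{row.n_bonds}\t{comp}\t"
                     f"{int(row.corrupted)}\t{row.corruption_kind}\n")


# ---------------------------------------------------------------------------
# Canned reference molecules.  The text blocks are authored by hand against
# the CT-file column layout (fixed widths throughout) and the expected
# records are constructed independently; tests assert both directions.

def _atom_line(symbol: str, x: float = 0.0, y: float = 0.0,
               z: float = 0.0) -> str:
    return f"{x:10.4f}{y:10.4f}{z:10.4f} {symbol:<3}" + " 0" + "  0" * 11


def _bond_line(u: int, v: int, t: int) -> str:
    return f"{u:3d}{v:3d}{t:3d}  0  0  0  0"


_COUNTS = "{:3d}{:3d}  0  0  0  0  0  0  0  0999 V2000"


def _mol_text(name: str, atoms: list[str], bonds: list[str],
              props: list[str] | None = None) -> str:
    lines = [name, "  molstream canned", "",
             _COUNTS.format(len(atoms), len(bonds))]
    lines += atoms + bonds + (props or []) + ["M  END"]
    return "\n".join(lines) + "\n"


def _expected(name: str, symbols: list[str],
              bonds: list[tuple[int, int, int]],
              props: list[str] | None = None) -> MolEntry:
    return MolEntry(
        header=EntryHeader(molecule_name=name,
                           program_line="  molstream canned", comment=""),
        counts=CountsLine(n_atoms=len(symbols), n_bonds=len(bonds)),
        atoms=[_make_atom(s) for s in symbols],
        bonds=[Bond(u, v, t) for u, v, t in bonds],
        properties_raw=list(props or []))


def _ring_bonds(n: int, types: list[int]) -> list[tuple[int, int, int]]:
    return [(i, i % n + 1, types[i - 1]) for i in range(1, n + 1)]


_CANNED: dict[str, tuple[list[str], list[tuple[int, int, int]],
                         list[str]]] = {
    # symbols, bonds, property lines
    "methane_full_H": (["C", "H", "H", "H", "H"],
                       [(1, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1)], []),
    "ethanol_heavy": (["C", "C", "O"], [(1, 2, 1), (2, 3, 1)], []),
    "benzene_kekulized": (["C"] * 6, _ring_bonds(6, [1, 2, 1, 2, 1, 2]), []),
    "pyridine": (["N", "C", "C", "C", "C", "C"],
                 _ring_bonds(6, [1, 2, 1, 2, 1, 2]), []),
    "cyclohexane": (["C"] * 6, _ring_bonds(6, [1] * 6), []),
    "disconnected_pair": (["C", "C", "O"], [(1, 2, 1)], []),
    "charged_isotope": (["N", "H", "H", "H", "H"],
                        [(1, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1)],
                        ["M  CHG  1   1   1", "M  ISO  1   1  15"]),
}

CANNED_FIXTURE_NAMES = tuple(sorted(_CANNED))


def canned_fixture(name: str) -> tuple[str, MolEntry]:
    """Return (Molfile text, expected parsed record) for a reference
    molecule.  Raises :class:`KeyError` for unknown names."""
    if name not in _CANNED:
        raise KeyError(f"unknown canned fixture {name!r}; available: "
                       f"{', '.join(CANNED_FIXTURE_NAMES)}")
    symbols, bonds, props = _CANNED[name]
    text = _mol_text(name, [_atom_line(s) for s in symbols],
                     [_bond_line(u, v, t) for u, v, t in bonds], props)
    return text, _expected(name, symbols, bonds, props)


def canned_sdf(names: list[str] | None = None) -> str:
    """Concatenate canned fixtures into SD-file text with delimiters."""
    out = []
    for name in (names if names is not None else CANNED_FIXTURE_NAMES):
        text, _ = canned_fixture(name)
        out.append(text)
        out.append("$$$$\n")
    return "".join(out)
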