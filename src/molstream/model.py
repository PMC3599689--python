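"""In-memory molecule records mirroring the four structural blocks of an
MDL Molfile (V2000): entry header, counts line, atom block, bond block.

The record is deliberately dumb: every connection-table column is kept,
either as a typed field named after the CT-file specification field code,
or — for the rarely used tail columns — as raw fixed-width strings.  Nothing
is chemically interpreted; the legacy charge code, for instance, stays a
code (see :mod:`molstream.elements` for the decoding table).  This is what
makes the mapping lossless: ``entry_to_molfile_text`` can reproduce a
canonical Molfile whose re-parse equals the original record field for
field.

Validation is split in two:

* parsing (:mod:`molstream.parser`) fails only on *structural* problems —
  a counts line that cannot be read, truncated blocks, non-numeric fields;
* :func:`check_entry` reports *consistency and plausibility* violations
  (count mismatches, out-of-range bond indices, self-loops, duplicate
  bonds, unknown element symbols) as data, never as exceptions, so a
  conversion pipeline can log and reject without dying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elements import is_known_symbol
from .errors import StructuralIntegrityError

__all__ = [
    "EntryHeader",
    "CountsLine",
    "Atom",
    "Bond",
    "MolEntry",
    "Violation",
    "entry_to_molfile_text",
    "check_entry",
]


def _coord_text(value: float) -> str:
    """Fixed-point 10.4 rendering used both for writing and for equality."""
    return f"{value:10.4f}"


@dataclass
class EntryHeader:
    """The three free-text header lines of a Molfile entry."""

    molecule_name: str = ""
    program_line: str = ""
    comment: str = ""

    def lines(self) -> list[str]:
        return [self.molecule_name, self.program_line, self.comment]


#: Default raw content for the five obsolete 3-char counts-line columns
#: (fff, xxx, rrr, ppp, iii in CT-spec order).
_OBSOLETE_DEFAULT = ("  0", "  0", "  0", "  0", "  0")


@dataclass
class CountsLine:
    """The counts line: block sizes, flags and the version tag.

    Field names follow the CT specification codes: ``aaa`` atom count,
    ``bbb`` bond count, ``lll`` atom lists, ``ccc`` chiral flag, ``sss``
    stext count, ``mmm`` number of property lines (conventionally 999).
    The five obsolete columns are preserved verbatim in
    ``obsolete_fields``.
    """

    n_atoms: int
    n_bonds: int
    n_atom_lists: int = 0
    chiral_flag: int = 0
    n_stext: int = 0
    n_properties: int = 999
    version: str = "V2000"
    obsolete_fields: tuple[str, ...] = _OBSOLETE_DEFAULT

    def text(self) -> str:
        ob = [f"{s:>3.3s}" if s else "  0" for s in self.obsolete_fields]
        while len(ob) < 5:
            ob.append("  0")
        tail = f"{self.version:>6}" if self.version else ""
        return (
            f"{self.n_atoms:3d}{self.n_bonds:3d}{self.n_atom_lists:3d}{ob[0]}"
            f"{self.chiral_flag:3d}{self.n_stext:3d}{ob[1]}{ob[2]}{ob[3]}{ob[4]}"
            f"{self.n_properties:3d}{tail}"
        )


@dataclass(eq=False)
class Atom:
    """One atom-block row.

    ``x, y, z`` are the printed fixed-point coordinates; two atoms compare
    equal when their 10.4 fixed-point renderings match, so round-trips
    through text are exact.  Typed integer fields carry the CT codes
    ``dd`` (mass difference), ``ccc`` (legacy charge code 0-7), ``sss``
    (stereo parity), ``hhh`` (hydrogen-count code), ``bbb`` (stereo care),
    ``vvv`` (valence code) and ``mmm`` (atom-atom mapping).  The raw tail
    columns after ``vvv`` (HHH rrr iii mmm nnn eee) are preserved verbatim
    in ``remaining_fields``; when present, ``remaining_fields[3]`` is the
    source of the typed ``atom_map``.
    """

    x: float
    y: float
    z: float
    symbol: str
    mass_diff: int = 0
    charge_code: int = 0
    stereo_parity: int = 0
    h_count_code: int = 0
    stereo_care: int = 0
    valence_code: int = 0
    atom_map: int = 0
    remaining_fields: tuple[str, ...] = ()

    def coord_texts(self) -> tuple[str, str, str]:
        return (_coord_text(self.x), _coord_text(self.y), _coord_text(self.z))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (
            self.coord_texts() == other.coord_texts()
            and self.symbol == other.symbol
            and self.mass_diff == other.mass_diff
            and self.charge_code == other.charge_code
            and self.stereo_parity == other.stereo_parity
            and self.h_count_code == other.h_count_code
            and self.stereo_care == other.stereo_care
            and self.valence_code == other.valence_code
            and self.atom_map == other.atom_map
            and tuple(self.remaining_fields) == tuple(other.remaining_fields)
        )

    def text(self) -> str:
        xs, ys, zs = self.coord_texts()
        head = (
            f"{xs}{ys}{zs} {self.symbol:<3}{self.mass_diff:2d}"
            f"{self.charge_code:3d}{self.stereo_parity:3d}{self.h_count_code:3d}"
            f"{self.stereo_care:3d}{self.valence_code:3d}"
        )
        return head + "".join(self.remaining_fields)


@dataclass
class Bond:
    """One bond-block row: 1-based atom indices, bond-type code (1 single,
    2 double, 3 triple, 4 aromatic, 5-8 query), stereo, topology and
    reacting-center columns."""

    first_atom: int
    second_atom: int
    bond_type: int
    stereo: int = 0
    topology: int = 0
    reacting_center: int = 0

    def text(self) -> str:
        return (
            f"{self.first_atom:3d}{self.second_atom:3d}{self.bond_type:3d}"
            f"{self.stereo:3d}  0{self.topology:3d}{self.reacting_center:3d}"
        )


@dataclass
class MolEntry:
    """One molecule: header + counts + atom block + bond block + the raw
    property lines (everything between the bond block and ``M  END``,
    preserved verbatim).

    ``provenance`` records where the entry came from (source name and
    1-based entry index) and is excluded from equality so that a re-parse
    of written text compares equal to the original record.
    """

    header: EntryHeader
    counts: CountsLine
    atoms: list[Atom]
    bonds: list[Bond]
    properties_raw: list[str] = field(default_factory=list)
    provenance: tuple[str, int] = field(default=("", 0), compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    # -- JSON mapping (the container payload schema) --------------------

    def to_dict(self) -> dict:
        return {
            "header": [self.header.molecule_name, self.header.program_line,
                       self.header.comment],
            "counts": {
                "n_atoms": self.counts.n_atoms,
                "n_bonds": self.counts.n_bonds,
                "n_atom_lists": self.counts.n_atom_lists,
                "chiral_flag": self.counts.chiral_flag,
                "n_stext": self.counts.n_stext,
                "n_properties": self.counts.n_properties,
                "version": self.counts.version,
                "obsolete_fields": list(self.counts.obsolete_fields),
            },
            "atoms": [
                [a.coord_texts()[0].strip(), a.coord_texts()[1].strip(),
                 a.coord_texts()[2].strip(), a.symbol, a.mass_diff,
                 a.charge_code, a.stereo_parity, a.h_count_code,
                 a.stereo_care, a.valence_code, a.atom_map,
                 list(a.remaining_fields)]
                for a in self.atoms
            ],
            "bonds": [
                [b.first_atom, b.second_atom, b.bond_type, b.stereo,
                 b.topology, b.reacting_center]
                for b in self.bonds
            ],
            "properties_raw": list(self.properties_raw),
            "provenance": [self.provenance[0], self.provenance[1]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MolEntry":
        c = d["counts"]
        return cls(
            header=EntryHeader(*d["header"]),
            counts=CountsLine(
                n_atoms=c["n_atoms"], n_bonds=c["n_bonds"],
                n_atom_lists=c["n_atom_lists"], chiral_flag=c["chiral_flag"],
                n_stext=c["n_stext"], n_properties=c["n_properties"],
                version=c["version"],
                obsolete_fields=tuple(c["obsolete_fields"]),
            ),
            atoms=[
                Atom(x=float(a[0]), y=float(a[1]), z=float(a[2]), symbol=a[3],
                     mass_diff=a[4], charge_code=a[5], stereo_parity=a[6],
                     h_count_code=a[7], stereo_care=a[8], valence_code=a[9],
                     atom_map=a[10], remaining_fields=tuple(a[11]))
                for a in d["atoms"]
            ],
            bonds=[Bond(*b) for b in d["bonds"]],
            properties_raw=list(d["properties_raw"]),
            provenance=(d["provenance"][0], d["provenance"][1]),
        )


@dataclass(frozen=True)
class Violation:
    """One consistency/plausibility finding from :func:`check_entry`.

    ``severity`` is ``"error"`` for consistency violations and
    ``"warning"`` for plausibility findings (unknown atom symbols).
    ``row`` is the 1-based row within the offending block, when applicable.
    """

    check: str
    message: str
    row: int | None = None
    severity: str = "error"


def check_entry(entry: MolEntry) -> list[Violation]:
    """Run all consistency and plausibility checks on *entry*.

    Returns an empty list iff the entry is internally consistent.  Checks:
    counts-vs-block-length agreement, bond atom indices in range, no
    self-loop bonds, no duplicate undirected bond pairs, and (as a
    plausibility warning only) atom symbols drawn from the periodic table
    or the documented pseudo-atom set.
    """
    out: list[Violation] = []
    if entry.counts.n_atoms != len(entry.atoms):
        out.append(Violation(
            "counts_atom_mismatch",
            f"counts line declares {entry.counts.n_atoms} atoms but atom "
            f"block has {len(entry.atoms)} rows"))
    if entry.counts.n_bonds != len(entry.bonds):
        out.append(Violation(
            "counts_bond_mismatch",
            f"counts line declares {entry.counts.n_bonds} bonds but bond "
            f"block has {len(entry.bonds)} rows"))

    n = len(entry.atoms)
    seen_pairs: dict[tuple[int, int], int] = {}
    for i, b in enumerate(entry.bonds, start=1):
        for idx in (b.first_atom, b.second_atom):
            if not 1 <= idx <= n:
                out.append(Violation(
                    "bond_index_range",
                    f"bond row {i} references atom {idx} of {n}", row=i))
        if b.first_atom == b.second_atom:
            out.append(Violation(
                "self_loop", f"bond row {i} is a self-loop on atom "
                f"{b.first_atom}", row=i))
        key = (min(b.first_atom, b.second_atom),
               max(b.first_atom, b.second_atom))
        if key in seen_pairs:
            out.append(Violation(
                "duplicate_bond",
                f"bond row {i} duplicates atom pair {key} first seen at "
                f"row {seen_pairs[key]}", row=i))
        else:
            seen_pairs[key] = i
        if not 1 <= b.bond_type <= 8:
            out.append(Violation(
                "bond_type_range",
                f"bond row {i} has bond type {b.bond_type} outside 1..8",
                row=i))

    for i, a in enumerate(entry.atoms, start=1):
        if not a.symbol:
            out.append(Violation(
                "empty_symbol", f"atom row {i} has an empty symbol", row=i))
        elif not is_known_symbol(a.symbol):
            out.append(Violation(
                "unknown_symbol",
                f"atom row {i} symbol {a.symbol!r} is not a periodic-table "
                f"element or known pseudo-atom", row=i, severity="warning"))
    return out


def entry_to_molfile_text(entry: MolEntry) -> str:
    """Render *entry* as a canonical V2000 Molfile text block.

    The output has fixed-width columns per the CT specification: three
    header lines, the counts line, one line per atom and bond, the raw
    property lines, then ``M  END``.  Raises
    :class:`StructuralIntegrityError` if the block lengths disagree with
    the counts line or a bond index is out of range (a record like that
    cannot be expressed as a self-consistent Molfile).
    """
    structural = {"counts_atom_mismatch", "counts_bond_mismatch",
                  "bond_index_range"}
    hard = [v for v in check_entry(entry) if v.check in structural]
    if hard:
        raise StructuralIntegrityError(
            "entry violates structural invariants: "
            + "; ".join(v.message for v in hard))
    lines = entry.header.lines()
    lines.append(entry.counts.text())
    lines.extend(a.text() for a in entry.atoms)
    lines.extend(b.text() for b in entry.bonds)
    lines.extend(entry.properties_raw)
    lines.append("M  END")
    return "\n".join(lines) + "\n"
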