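"""Streaming SD-file reader and Molfile (V2000) parser.

An SD-file is a concatenation of Molfile entries separated by ``$$$$``
delimiter lines, each entry optionally followed by tagged data items.
:func:`pick_sdf_entries` splits the stream lazily — memory use is bounded
by the largest single entry — and :func:`parse_sdf_entry` turns the Molfile
portion of one entry into a :class:`~molstream.model.MolEntry`.
:func:`convert_sdf` chains picking, parsing, consistency checking and
container writing into one logged pipeline.

Parsing is fixed-width-first: fields are sliced at the CT-specification
columns; when a line is too short for slicing, the parser falls back to
whitespace tokenisation and records a dialect warning.  Input bytes are
decoded as Latin-1 so decoding can never fail; gzip- and bzip2-compressed
inputs are detected by magic bytes.
"""

from __future__ import annotations

import bz2
import datetime as _dt
import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, TextIO

from .errors import MolstreamError, ParseError
from .model import Atom, Bond, CountsLine, EntryHeader, MolEntry, check_entry

__all__ = [
    "RawEntry",
    "ParseReport",
    "pick_sdf_entries",
    "parse_sdf_entry",
    "convert_sdf",
    "open_sdf_text",
]

#: Event callback signature: (level, entry_index, stage, message).
EventHook = Callable[[str, int, str, str], None]


@dataclass
class RawEntry:
    """One un-parsed SD-file entry.

    ``lines`` holds the Molfile portion (through ``M  END`` when present);
    ``data_items_raw`` holds everything between ``M  END`` and the
    ``$$$$`` delimiter verbatim (the tagged data-item section), opaque.
    """

    lines: list[str]
    source_name: str
    entry_index: int
    data_items_raw: str = ""


@dataclass
class ParseReport:
    """Bookkeeping of one conversion run: every raw entry read is either
    accepted or rejected, so ``n_read == n_accepted + n_rejected``."""

    n_read: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str, str]] = field(default_factory=list)


def open_sdf_text(path: str | os.PathLike) -> TextIO:
    """Open an SD-file for reading, sniffing gzip/bzip2 by magic bytes.

    Text is decoded as Latin-1 (a byte-transparent superset: decoding
    never fails and round-trips every byte).
    """
    raw = open(path, "rb")
    magic = raw.read(3)
    raw.seek(0)
    if magic[:2] == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="latin-1")
    if magic == b"BZh":
        return io.TextIOWrapper(bz2.BZ2File(raw), encoding="latin-1")
    return io.TextIOWrapper(raw, encoding="latin-1")


def _is_delimiter(line: str) -> bool:
    return line.rstrip("\r\n\t ") == "$$$$"


def pick_sdf_entries(stream: Iterable[str], source_name: str = "",
                     on_event: EventHook | None = None) -> Iterator[RawEntry]:
    """Lazily split an SD-file line stream into raw entries.

    Splits on lines whose content, after stripping trailing whitespace,
    is exactly ``$$$$``; entries are yielded in file order with 1-based
    ``entry_index``.  The Molfile portion ends at the first ``M  END``
    line; anything after it (the data-item section) is kept opaque in
    ``data_items_raw``.  A final entry with no trailing ``$$$$`` is still
    yielded, with a warning through *on_event*; trailing blank lines alone
    do not make an entry.
    """
    buf: list[str] = []
    index = 0

    def make(entry_lines: list[str]) -> RawEntry:
        mol: list[str] = []
        data: list[str] = []
        in_data = False
        for ln in entry_lines:
            if in_data:
                data.append(ln)
            else:
                mol.append(ln)
                if ln.rstrip() == "M  END":
                    in_data = True
        return RawEntry(lines=mol, source_name=source_name,
                        entry_index=index,
                        data_items_raw="".join(s + "\n" for s in data))

    for raw_line in stream:
        line = raw_line.rstrip("\r\n")
        if _is_delimiter(raw_line):
            index += 1
            yield make(buf)
            buf = []
        else:
            buf.append(line)
    if any(s.strip() for s in buf):
        index += 1
        if on_event is not None:
            on_event("WARNING", index, "pick",
                     "final entry has no trailing $$$$ delimiter")
        yield make(buf)


def _int_field(text: str, default: int = 0) -> int:
    s = text.strip()
    return int(s) if s else default


def _parse_counts(line: str, entry_index: int | None) -> CountsLine:
    try:
        n_atoms = _int_field(line[0:3])
        n_bonds = _int_field(line[3:6])
        n_atom_lists = _int_field(line[6:9])
        chiral = _int_field(line[12:15])
        n_stext = _int_field(line[15:18])
        n_props = _int_field(line[30:33], default=999)
    except ValueError as exc:
        raise ParseError(f"unparseable counts line: {line!r} ({exc})",
                         stage="counts", entry_index=entry_index) from None
    version = line[33:39].strip()
    if version and version != "V2000":
        raise ParseError(f"unsupported Molfile version tag {version!r}",
                         stage="version", entry_index=entry_index)
    obsolete = tuple(line[a:b] if line[a:b].strip() else "  0"
                     for a, b in ((9, 12), (18, 21), (21, 24),
                                  (24, 27), (27, 30)))
    return CountsLine(n_atoms=n_atoms, n_bonds=n_bonds,
                      n_atom_lists=n_atom_lists, chiral_flag=chiral,
                      n_stext=n_stext, n_properties=n_props,
                      version=version, obsolete_fields=obsolete)


# atom-line tail columns after vvv, in CT order: HHH rrr iii mmm nnn eee
_ATOM_TAIL_START = 51
_ATOM_MAP_TAIL_POS = 3


def _parse_atom(line: str, row: int, entry_index: int | None,
                warn: Callable[[str], None]) -> Atom:
    def err(col: str, detail: str) -> ParseError:
        return ParseError(
            f"atom block row {row}, field {col}: {detail} in line {line!r}",
            stage="atom", entry_index=entry_index, row=row)

    if len(line) >= 34 and line[30:31] == " ":
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
        except ValueError:
            raise err("xyz", "non-numeric coordinate") from None
        symbol = line[31:34].strip()
        ints = []
        for col, (a, b) in (("dd", (34, 36)), ("ccc", (36, 39)),
                            ("sss", (39, 42)), ("hhh", (42, 45)),
                            ("bbb", (45, 48)), ("vvv", (48, 51))):
            try:
                ints.append(_int_field(line[a:b]))
            except ValueError:
                raise err(col, "non-numeric field") from None
        tail = line[_ATOM_TAIL_START:]
        remaining = tuple(tail[i:i + 3] for i in range(0, len(tail), 3))
    else:
        # ragged line: whitespace fallback
        toks = line.split()
        if len(toks) < 4:
            raise err("xyz/symbol", "too few whitespace-separated tokens")
        try:
            x, y, z = (float(t) for t in toks[:3])
        except ValueError:
            raise err("xyz", "non-numeric coordinate") from None
        symbol = toks[3]
        try:
            extra = [int(t) for t in toks[4:10]]
        except ValueError:
            raise err("tail", "non-numeric field") from None
        ints = (extra + [0] * 6)[:6]
        remaining = ()
        warn(f"atom block row {row}: short line parsed by whitespace "
             f"fallback")
    atom_map = 0
    if len(remaining) > _ATOM_MAP_TAIL_POS:
        try:
            atom_map = _int_field(remaining[_ATOM_MAP_TAIL_POS])
        except ValueError:
            raise err("mmm", "non-numeric atom-map field") from None
    if not symbol:
        raise err("aaa", "empty atom symbol")
    return Atom(x=x, y=y, z=z, symbol=symbol,
                mass_diff=ints[0], charge_code=ints[1], stereo_parity=ints[2],
                h_count_code=ints[3], stereo_care=ints[4],
                valence_code=ints[5], atom_map=atom_map,
                remaining_fields=remaining)


def _parse_bond(line: str, row: int, entry_index: int | None,
                warn: Callable[[str], None]) -> Bond:
    def err(col: str, detail: str) -> ParseError:
        return ParseError(
            f"bond block row {row}, field {col}: {detail} in line {line!r}",
            stage="bond", entry_index=entry_index, row=row)

    if len(line) >= 9:
        vals = []
        for col, (a, b) in (("111", (0, 3)), ("222", (3, 6)), ("ttt", (6, 9)),
                            ("sss", (9, 12)), ("rrr", (15, 18)),
                            ("ccc", (18, 21))):
            try:
                vals.append(_int_field(line[a:b]))
            except ValueError:
                raise err(col, "non-numeric field") from None
    else:
        toks = line.split()
        if len(toks) < 3:
            raise err("111/222/ttt", "too few tokens")
        try:
            nums = [int(t) for t in toks[:6]]
        except ValueError:
            raise err("bond", "non-numeric field") from None
        vals = (nums + [0] * 6)[:6]
        warn(f"bond block row {row}: short line parsed by whitespace "
             f"fallback")
    return Bond(first_atom=vals[0], second_atom=vals[1], bond_type=vals[2],
                stereo=vals[3], topology=vals[4], reacting_center=vals[5])


def parse_sdf_entry(raw: RawEntry,
                    on_warning: Callable[[str], None] | None = None
                    ) -> MolEntry:
    """Parse the Molfile portion of *raw* into a :class:`MolEntry`.

    Raises :class:`ParseError` with a stage tag on structural failure:
    ``"counts"`` (missing/garbled counts line), ``"version"`` (tag other
    than V2000), ``"truncated block"`` (fewer atom/bond lines than the
    counts declare), ``"atom"``/``"bond"`` (non-numeric fixed-width field,
    naming block, row and column).  Dialect oddities that can be tolerated
    (short lines, missing ``M  END``) go through *on_warning* instead.
    """
    warn = on_warning if on_warning is not None else (lambda msg: None)
    idx = raw.entry_index
    lines = raw.lines
    if len(lines) < 4:
        raise ParseError(
            f"entry has only {len(lines)} lines; need 3 header lines plus "
            f"a counts line", stage="counts", entry_index=idx)
    header = EntryHeader(molecule_name=lines[0], program_line=lines[1],
                         comment=lines[2])
    counts = _parse_counts(lines[3], idx)

    pos = 4
    atoms: list[Atom] = []
    for row in range(1, counts.n_atoms + 1):
        if pos >= len(lines) or lines[pos].rstrip() == "M  END":
            raise ParseError(
                f"atom block truncated: counts declare {counts.n_atoms} "
                f"atoms but block ends at row {row}",
                stage="truncated block", entry_index=idx, row=row)
        atoms.append(_parse_atom(lines[pos], row, idx, warn))
        pos += 1
    bonds: list[Bond] = []
    for row in range(1, counts.n_bonds + 1):
        if pos >= len(lines) or lines[pos].rstrip() == "M  END":
            raise ParseError(
                f"bond block truncated: counts declare {counts.n_bonds} "
                f"bonds but block ends at row {row}",
                stage="truncated block", entry_index=idx, row=row)
        bonds.append(_parse_bond(lines[pos], row, idx, warn))
        pos += 1

    properties: list[str] = []
    saw_end = False
    for ln in lines[pos:]:
        if ln.rstrip() == "M  END":
            saw_end = True
            break
        properties.append(ln)
    if not saw_end:
        warn("no M  END terminator found; properties block taken to the "
             "end of the entry")
    return MolEntry(header=header, counts=counts, atoms=atoms, bonds=bonds,
                    properties_raw=properties,
                    provenance=(raw.source_name, idx))


def _timestamp() -> str:
    return _dt.datetime.now().isoformat(timespec="seconds")


class _Logger:
    """One-line-per-event plain-text log: ISO timestamp, level, source,
    entry index, stage, message, tab-separated."""

    def __init__(self, fh: TextIO | None, source: str):
        self.fh = fh
        self.source = source

    def __call__(self, level: str, entry_index: int, stage: str,
                 message: str) -> None:
        if self.fh is not None:
            self.fh.write(f"{_timestamp()}\t{level}\t{self.source}\t"
                          f"{entry_index}\t{stage}\t{message}\n")


def convert_sdf(sdf_path: str | os.PathLike,
                out_container: str | os.PathLike,
                log_path: str | os.PathLike | None = None,
                strict: bool = True,
                keep_data_items: bool = False) -> ParseReport:
    """Convert an SD-file into a record container, entry by entry.

    The pipeline is pick → parse → check → append, one entry resident at
    a time.  In strict mode (the default) an entry with *any*
    consistency/plausibility violation is rejected and logged; in lenient
    mode plausibility warnings are logged but the entry is kept (hard
    consistency violations still reject).  Every rejection is logged with
    entry index, stage and message, and counted in the returned
    :class:`ParseReport`.  The output container is written atomically: on
    failure no partial file is left behind; an input whose every entry is
    rejected still yields a valid, empty container.
    """
    from .container import container_open

    report = ParseReport()
    log_fh = open(log_path, "w", encoding="utf-8") if log_path else None
    try:
        log = _Logger(log_fh, str(sdf_path))
        stream = open_sdf_text(sdf_path)
        try:
            writer = container_open(out_container, "write")
        except BaseException:
            stream.close()
            raise
        try:
            for raw in pick_sdf_entries(stream, source_name=str(sdf_path),
                                        on_event=log):
                report.n_read += 1
                warnings: list[str] = []
                try:
                    entry = parse_sdf_entry(raw, on_warning=warnings.append)
                except ParseError as exc:
                    report.n_rejected += 1
                    report.errors.append((raw.entry_index, "parse", str(exc)))
                    log("ERROR", raw.entry_index, exc.stage, str(exc))
                    continue
                for msg in warnings:
                    log("WARNING", raw.entry_index, "parse", msg)
                violations = check_entry(entry)
                hard = [v for v in violations if v.severity == "error"]
                soft = [v for v in violations if v.severity == "warning"]
                reject = bool(hard) or (strict and bool(soft))
                for v in soft:
                    if not strict:
                        log("WARNING", raw.entry_index, "check", v.message)
                if reject:
                    report.n_rejected += 1
                    first = (hard or soft)[0]
                    report.errors.append(
                        (raw.entry_index, "check", first.message))
                    for v in hard + (soft if strict else []):
                        log("ERROR", raw.entry_index, "check", v.message)
                    continue
                report.n_accepted += 1
                name = entry.header.molecule_name.strip() or "mol"
                writer.append_entry(
                    f"{name}_{raw.entry_index:06d}", entry,
                    data_items_raw=(raw.data_items_raw
                                    if keep_data_items else None))
        except BaseException:
            writer.abort()
            raise
        finally:
            stream.close()
        writer.close()
    except OSError as exc:
        raise MolstreamError(f"I/O error during conversion: {exc}") from exc
    finally:
        if log_fh is not None:
            log_fh.close()
    return report
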