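"""Serial record container: a bzip2-compressed stream of named,
serialized objects, read and written one record at a time.

Large compound libraries do not fit comfortably in memory; the container
stores each molecule (or any JSON-serializable object) as an independent
record so that both writing and reading are single-pass with one record
resident.  The on-disk layout (documented bit-exactly in
``docs/container-format.md``) is a sequence of concatenated bzip2 streams:
the first stream holds a one-line text header (magic + format version),
each following stream holds exactly one record as a one-line JSON document
``{"name": ..., "kind": ..., "payload": ...}``.  Standard bzip2 readers
decompress concatenated streams transparently, so the decompressed content
is plain header + JSON-lines; per-record streams additionally make a
truncated file fail cleanly at the first unreadable record while earlier
records stay readable.

Compression level is fixed (bzip2 level 9) so identical inputs produce
byte-identical containers.  There is no index and no random access: the
design is serial, append-only, stream-read.
"""

from __future__ import annotations

import bz2
import json
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Sequence

from .errors import (ContainerCorruptionError, ContainerFormatError,
                     ContainerStateError, MolstreamError)
from .model import MolEntry

__all__ = [
    "MAGIC_LINE",
    "ContainerRecord",
    "ContainerReader",
    "ContainerWriter",
    "container_open",
    "read_records",
    "collection_to_container",
    "container_to_collection",
    "count_records",
]

MAGIC_LINE = "#molstream-container 1"
DEFAULT_COMPRESSLEVEL = 9

KIND_MOLENTRY = "molentry"
KIND_SUMMARY = "summary"
KIND_OTHER = "other"


@dataclass
class ContainerRecord:
    """One named serialized object.

    ``object_name`` is a label, not a key: duplicates are permitted.
    ``content_kind`` tags the payload schema: ``"molentry"`` (a
    :class:`MolEntry`), ``"summary"`` (a collection summary dict), or
    ``"other"`` (any JSON value).  ``data_items_raw`` optionally carries
    the SD-file data-item text belonging to a molecule record.
    """

    object_name: str
    object_content: Any
    content_kind: str = KIND_OTHER
    data_items_raw: str | None = None

    def to_json_obj(self) -> dict:
        if isinstance(self.object_content, MolEntry):
            payload: Any = self.object_content.to_dict()
            kind = KIND_MOLENTRY
        else:
            payload = self.object_content
            kind = self.content_kind
        obj = {"name": self.object_name, "kind": kind, "payload": payload}
        if self.data_items_raw is not None:
            obj["data_items_raw"] = self.data_items_raw
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ContainerRecord":
        kind = obj.get("kind", KIND_OTHER)
        payload = obj.get("payload")
        if kind == KIND_MOLENTRY:
            payload = MolEntry.from_dict(payload)
        return cls(object_name=obj["name"], object_content=payload,
                   content_kind=kind,
                   data_items_raw=obj.get("data_items_raw"))


def _compress_line(text: str, level: int) -> bytes:
    return bz2.compress((text + "\n").encode("utf-8"), level)


class ContainerWriter:
    """Write handle: append records one at a time, then close.

    Output is written to a temporary sibling file and moved into place on
    :meth:`close`, so a failed conversion never leaves a partial container
    behind (:meth:`abort` discards the temporary file).
    """

    def __init__(self, path: str | os.PathLike,
                 compresslevel: int = DEFAULT_COMPRESSLEVEL):
        self.path = os.fspath(path)
        self.compresslevel = compresslevel
        self._tmp = self.path + ".part"
        self._fh = open(self._tmp, "wb")
        self._fh.write(_compress_line(MAGIC_LINE, compresslevel))
        self._closed = False
        self.n_written = 0

    def append(self, record: ContainerRecord) -> None:
        """Append one record.  Empty names and unserializable payloads are
        rejected before anything is written."""
        if self._closed:
            raise ContainerStateError("append on closed container handle")
        if not record.object_name:
            raise MolstreamError("record object_name must be non-empty")
        try:
            line = json.dumps(record.to_json_obj(), ensure_ascii=False,
                              separators=(",", ":"))
        except (TypeError, ValueError) as exc:
            raise MolstreamError(
                f"payload of record {record.object_name!r} is not "
                f"serializable: {exc}") from exc
        self._fh.write(_compress_line(line, self.compresslevel))
        self.n_written += 1

    def append_entry(self, name: str, entry: MolEntry,
                     data_items_raw: str | None = None) -> None:
        self.append(ContainerRecord(object_name=name, object_content=entry,
                                    content_kind=KIND_MOLENTRY,
                                    data_items_raw=data_items_raw))

    def close(self) -> None:
        """Flush and atomically move the container into place (idempotent)."""
        if self._closed:
            return
        self._closed = True
        self._fh.close()
        os.replace(self._tmp, self.path)

    def abort(self) -> None:
        """Discard the partially written container (idempotent)."""
        if self._closed:
            return
        self._closed = True
        self._fh.close()
        if os.path.exists(self._tmp):
            os.remove(self._tmp)

    def __enter__(self) -> "ContainerWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()
        else:
            self.abort()


class ContainerReader:
    """Read handle: yields records in write order, exactly once each,
    with memory proportional to one record."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        try:
            self._fh = bz2.open(self.path, "rt", encoding="utf-8")
        except OSError:
            raise
        try:
            first = self._fh.readline()
        except (OSError, EOFError, ValueError) as exc:
            self._fh.close()
            raise ContainerFormatError(
                f"{self.path}: not a bzip2 stream ({exc})") from None
        if first.rstrip("\n") != MAGIC_LINE:
            self._fh.close()
            raise ContainerFormatError(
                f"{self.path}: bad magic line {first.rstrip()!r}; expected "
                f"{MAGIC_LINE!r}")
        self._closed = False
        self.position = 0  # records already returned

    def next_record(self) -> ContainerRecord | None:
        """Return the next record, or None at end of container."""
        if self._closed:
            raise ContainerStateError("next_record on closed handle")
        ordinal = self.position + 1
        try:
            line = self._fh.readline()
        except (EOFError, OSError, ValueError) as exc:
            raise ContainerCorruptionError(
                f"{self.path}: record {ordinal} is truncated or corrupt "
                f"({exc})", ordinal=ordinal) from None
        if line == "":
            return None
        try:
            obj = json.loads(line)
            record = ContainerRecord.from_json_obj(obj)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise ContainerCorruptionError(
                f"{self.path}: record {ordinal} is undecodable ({exc})",
                ordinal=ordinal) from None
        self.position = ordinal
        return record

    def __iter__(self) -> Iterator[ContainerRecord]:
        while True:
            rec = self.next_record()
            if rec is None:
                return
            yield rec

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        self._fh.close()

    def __enter__(self) -> "ContainerReader":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        self.close()


def container_open(path: str | os.PathLike, mode: str
                   ) -> ContainerReader | ContainerWriter:
    """Open a container for ``"read"`` or ``"write"``.

    Read mode requires an existing file with a valid magic header; write
    mode creates or truncates.
    """
    if mode == "read":
        return ContainerReader(path)
    if mode == "write":
        return ContainerWriter(path)
    raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")


def read_records(path: str | os.PathLike) -> Iterator[ContainerRecord]:
    """Iterate all records of a container, one resident at a time."""
    with ContainerReader(path) as reader:
        yield from reader


def count_records(path: str | os.PathLike) -> int:
    n = 0
    for _ in read_records(path):
        n += 1
    return n


def collection_to_container(entries: Iterable[tuple[str, Any]],
                            path: str | os.PathLike) -> int:
    """Write an in-memory sequence of (name, object) pairs as a container.

    Returns the number of records written.  The inverse,
    :func:`container_to_collection`, reads everything back into memory and
    is therefore unsuitable for huge collections — the streaming handles
    exist precisely to avoid that.
    """
    with ContainerWriter(path) as writer:
        for name, obj in entries:
            kind = KIND_MOLENTRY if isinstance(obj, MolEntry) else KIND_OTHER
            writer.append(ContainerRecord(object_name=name,
                                          object_content=obj,
                                          content_kind=kind))
        n = writer.n_written
    return n


def container_to_collection(path: str | os.PathLike
                            ) -> list[tuple[str, Any]]:
    """Read a whole container into memory as (name, object) pairs,
    preserving order and duplicate names."""
    return [(rec.object_name, rec.object_content)
            for rec in read_records(path)]
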