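# The molstream container format (`.rbz.jsonl.bz2`)

A molstream container is a serial, append-only store of named serialized
objects, designed so that both writing and reading proceed one record at
a time with bounded memory, and so that identical inputs always produce
byte-identical files.

## Physical layout

The file is a sequence of **concatenated bzip2 streams**, each produced
at compression level 9:

| stream  | decompressed content                                  |
|---------|-------------------------------------------------------|
| 1       | the header line `#molstream-container 1` + `\n`       |
| 2..N+1  | one record each: a single JSON document + `\n`        |

Standard bzip2 readers (the `bzip2` tool, Python's `bz2`, R's
`bzfile`, ...) decompress concatenated streams transparently, so
`bunzip2 < file` yields plain text: the header line followed by one JSON
document per line (JSON-lines).

One stream per record has two consequences:

* **appending** a record is writing one more complete bzip2 stream at the
  end of the file — no rewriting;
* **truncation is recoverable**: a file cut off mid-record still yields
  every earlier record, and the reader raises a corruption error carrying
  the 1-based ordinal of the first unreadable record.

The fixed compression level makes the writer deterministic: converting
the same input bytes twice gives byte-identical containers.

## Record schema

Each record line is a JSON object:

```json
{"name": "<object name>", "kind": "<content kind>", "payload": ...}
```

* `name` — non-empty label. Labels are **not** keys: duplicates are
  allowed and preserved in order.
* `kind` — `"molentry"`, `"summary"`, or `"other"`.
* `payload` — for `"other"`, any JSON value; for `"molentry"`, the
  molecule-record schema below.
* `data_items_raw` *(optional)* — the verbatim SD-file data-item text
  belonging to a molecule record, present only when conversion was asked
  to keep it.

## Molecule payload (`kind = "molentry"`)

```json
{
  "header": ["<name line>", "<program line>", "<comment line>"],
  "counts": {"n_atoms": 3, "n_bonds": 2, "n_atom_lists": 0,
             "chiral_flag": 0, "n_stext": 0, "n_properties": 999,
             "version": "V2000",
             "obsolete_fields": ["  0", "  0", "  0", "  0", "  0"]},
  "atoms": [["0.0000", "0.0000", "0.0000", "C",
             0, 0, 0, 0, 0, 0, 0, ["  0", "  0", "  0", "  0", "  0", "  0"]],
            ...],
  "bonds": [[1, 2, 1, 0, 0, 0], ...],
  "properties_raw": ["M  CHG  1   1   1"],
  "provenance": ["<source file>", 1]
}
```

Atom rows are `[x, y, z, symbol, mass_diff, charge_code, stereo_parity,
h_count_code, stereo_care, valence_code, atom_map, remaining_fields]`
with coordinates as their fixed-point 10.4 text (so round-trips are
exact) and `remaining_fields` the raw 3-character tail columns of the
atom line. Bond rows are `[first_atom, second_atom, bond_type, stereo,
topology, reacting_center]` with 1-based atom indices.

## Non-features (by design)

No random access or index, no in-place deletion, no concurrent writers,
no encryption. The serialization is JSON, not any language's native
object serializer, so any environment with bzip2 + JSON can read a
container.
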