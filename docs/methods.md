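# Methods

## The molecule record and what "lossless" means here

An MDL Molfile (V2000 dialect) encodes one molecule as four structural
blocks: a three-line entry header, a counts line, a fixed-width atom
block and a fixed-width bond block, followed by a properties block that
ends with `M  END`. molstream maps these onto a `MolEntry` record whose
fields are named after the CT-file specification codes (`aaa` atom
count, `ccc` charge code, `ttt` bond type, ...). Every column is kept:
the commonly used columns as typed fields, the rarely used tail columns
of the atom line and the obsolete counts-line columns as raw 3-character
strings. Nothing is chemically interpreted — the legacy charge code
stays a code (a documented table maps 0-7 to charges, with `M  CHG`
property lines taking precedence for interpretation-level consumers),
no aromaticity perception, no valence model, no implicit hydrogens.

Losslessness is a testable contract, not a slogan: rendering a record
back to Molfile text and re-parsing it reproduces every typed field and
every raw tail exactly. Coordinates compare as their fixed-point 10.4
renderings rather than as floats, so text round-trips are exact by
construction. The writer emits one canonical layout (full-width columns,
`  0` for absent optional fields, the bond line's obsolete `xxx` column
always `  0`); a ragged input therefore normalizes to canonical form on
the first round trip and is byte-stable from then on. The hand-written
reference fixtures are authored in canonical form and round-trip
byte-for-byte. The SD-file data-item section (`>  <tag>` blocks) is not
part of the molecule record — it can be carried through conversion as
opaque text on request, but the structural mapping concerns the Molfile
portion only.

## Parsing policy

Entries are picked by splitting on lines that equal `$$$$` after
stripping trailing whitespace (CR/LF and LF both accepted); a final
entry without the delimiter is still yielded, with a logged warning.
Parsing is fixed-width-first: fields are sliced at the CT-spec columns;
only when a line is too short for slicing does the parser fall back to
whitespace tokenization, recording a dialect warning. Input bytes are
decoded as Latin-1, which never fails and round-trips every byte;
gzip/bzip2-compressed inputs are sniffed by magic bytes.

Failures are split into two classes with different machinery:

* **Parse errors** (exceptions): unreadable counts line, version tag
  other than `V2000`, truncated atom/bond block, non-numeric fixed-width
  field. The entry cannot be represented and is rejected at the parse
  stage.
* **Check violations** (data): counts disagreeing with block lengths,
  bond indices out of range, self-loops, duplicate undirected bond
  pairs — plus, as a *plausibility warning* rather than an error, atom
  symbols outside the periodic table and the documented pseudo-atom set
  (`* A Q L LP R R# D T X`). `check_entry` returns these as a list so a
  batch pipeline can log and count instead of dying.

Strict mode (default) rejects an entry with any violation, warnings
included; lenient mode keeps entries whose only findings are
plausibility warnings. Either way the bookkeeping identity
`n_read = n_accepted + n_rejected` holds and every rejection is logged
with entry index, stage and message.

## The record container

Collections are stored as bzip2-compressed streams of named JSON
records, read and written strictly one record at a time so that memory
is bounded by the largest single record, never the collection
(see `container-format.md` for the bit-exact layout). Each record is its
own complete bzip2 stream; concatenated streams are transparent to
standard bzip2 readers, appending never rewrites, and a truncated file
fails at the exact ordinal of the first unreadable record while earlier
records stay readable. Level-9 compression is fixed so identical inputs
yield identical bytes. `collection_to_container` /
`container_to_collection` cover the in-memory ↔ serial conversion for
small collections; they are documented as unsuitable for huge files,
which is what the streaming handles are for.

## Summaries and filters

`summarize_collection` accumulates, in one pass: entry count, per-entry
atom/bond counts (min/max/mean/quartiles, quartiles by linear
interpolation between order statistics — the numpy default — so reports
are reproducible), element and bond-type frequencies (symbols
case-sensitive exactly as in the atom block), and a violation tally.
Summaries merge additively: the summary of a concatenation equals the
merge of the part summaries, which is also how the per-part/whole
consistency is tested. The report renderer is deterministic; frequency
tables sort by descending count with lexicographic (elements) or
ascending-code (bond types) tie-breaks.

The filter vocabulary is a small closed set of per-molecule predicates —
atom/bond count ranges, element presence/absence, name regex, bond-type
presence, clean-consistency — combined with all/any and negation.
Invalid specs (bad regex, empty clause list, inverted range) fail before
any I/O. A spec and its negation always partition a container into two
order-preserving subsequences; this partition law is asserted over the
whole vocabulary.

## Graph export

Three views of the same molecular graph are kept mutually consistent by
construction and by test: the symmetric adjacency matrix (binary, or
weighted by bond order with aromatic code 4 → 1.5), the normalized
connection table (ascending indices within a row, bond-block row
order), and an undirected networkx graph with `symbol`, `charge_code`,
`mass_diff` vertex attributes and a `bond_type` edge attribute — the
labeled-graph object topological-descriptor packages consume.
Computing descriptors themselves is out of scope; the export is the
interface.

Design choices where the design was open:

* **Hydrogen policy** defaults to `keep` (the atom block is converted
  as-is); `suppress` removes explicit H atoms and incident bonds,
  reindexes contiguously and reports the old→new index map, because
  H-suppressed graphs are the conventional substrate of topological
  indices. Suppression is oracle-checked against deleting H vertices
  from the kept graph.
* **Query bond types 5-8** have no defined bond order: weighted mode
  rejects them with a clear error; binary mode records the connection
  with weight 1.
* **Duplicate bonds** between one atom pair (possible only via lenient
  parsing) are an export error, never a silent merge.

## The synthetic-data generator

The generator emulates the *structural* shape of small-molecule
SD-files: connected random trees on 2-9 heavy atoms (uniform), grown by
attaching each new atom to a uniformly chosen earlier atom, optionally
densified into rings by adding each non-tree pair with a small
probability; element symbols drawn from a weighted alphabet dominated by
carbon (C:N:O:S = 12:2:2:1, a caricature of organic libraries); all
bonds single; all coordinates 0.0000 — these are graphs, not geometries,
and no consumer should read 3D information out of them. It does not
emulate chemically sensible valences, stereochemistry, charges,
aromatic perception or realistic coordinate data, so passing tests
demonstrate correctness of parsing, storage, bookkeeping and graph
topology — not chemical validity handling on real-world libraries.

Deliberate corruption exercises each failure stage: dropped atom lines
(truncated block), non-numeric counts, garbled fixed-width fields (parse
errors), and out-of-range bond indices (a consistency-check rejection).
The generator's manifest — per entry: name, atom/bond counts, element
composition, corruption flag — is the ground truth that conversion
reports and summaries are compared against. Randomness comes from
Python's Mersenne Twister (`random.Random`) with integer seeds: one
spec, one seed, one byte-identical SD-file and manifest within this
implementation (cross-language ports can share manifests but not
necessarily bytes).

## Problem sizes and numerical choices

Round-trip properties run over all seven canned fixtures plus 500
generated molecules; bookkeeping over 300 molecules at corruption rates
0/0.1/0.3; graph consistency over 200; the streaming check converts and
summarizes a 10^4-molecule file through the per-record iterator alone.
These sizes make every property run in seconds while still exercising
the streaming paths well past the single-entry regime. There is no
floating-point fitting anywhere; the only numeric conventions are the
fixed-point 10.4 coordinate rendering and the linear-interpolation
quartiles, both stated above.

## Known limitations

V3000 Molfiles, reaction files (RXN/RDF), and recovery of entries with
unparseable counts lines are out of scope. The container does not read
the R-native serialized format of the original toolset; the documented
JSON-in-bzip2 layout is a deliberate portable substitution. Filtering
offers no substructure/SMARTS matching and no physicochemical
properties. The CLI is intentionally serial — one record in flight —
matching the serialized-pipeline design; there are no parallel workers.
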