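# molstream

Streaming toolset for SD/Molfile (MDL V2000) chemical-structure data:
a lossless parser from Molfile text into four-block molecule records,
a bzip2-compressed record container for large collections, collection
statistics and predicate filters, and export of molecules as adjacency
matrices, connection tables and attribute-labeled graphs for network
analysis.

## Who it is for

Cheminformatics and bioinformatics workflows that treat molecules as
*graphs*: screening-library curation, batch conversion of SD-files into
analysis-ready form, and feeding topological-descriptor or
network-measure packages. An SD-file is a concatenation of Molfile
entries separated by `$$$$`; each Molfile carries an entry header (EH),
a counts line (CL), an atom block (AB) and a bond block (BB) in fixed
CT-specification columns. molstream maps these four blocks onto a
`MolEntry` record *losslessly* — every column kept, nothing chemically
reinterpreted — so the record can stand in for the file, and converts
records into the containers and graph objects downstream analysis needs.

The core contracts, all enforced by tests:

* **Losslessness** — `parse(write(E)) == E` field-for-field for every
  record, and byte-for-byte for canonical text.
* **Bookkeeping** — conversion accounts for every entry:
  `n_read = n_accepted + n_rejected`, each rejection logged with entry
  index, stage and message.
* **Streaming** — files, containers, summaries and filters are
  processed one record at a time; memory is bounded by the largest
  entry, never the collection.
* **Consistency triangle** — adjacency matrix, connection table and
  labeled graph of a molecule always describe the same edge set; binary
  adjacency row sums equal graph degrees.

## Worked example

```python
from molstream import (canned_fixture, adjacency_matrix, to_labeled_graph,
                       entry_to_molfile_text)

text, _ = canned_fixture("benzene_kekulized")

from molstream import parse_sdf_entry
from molstream.parser import RawEntry
benzene = parse_sdf_entry(RawEntry(lines=text.splitlines(),
                                   source_name="demo", entry_index=1))

am = adjacency_matrix(benzene)           # binary 6x6
print(am.values.sum(axis=1))             # -> [2. 2. 2. 2. 2. 2.]
g = to_labeled_graph(benzene)
print(g.number_of_nodes(), g.number_of_edges())   # -> 6 6
print(entry_to_molfile_text(benzene) == text)     # -> True
```

Every benzene vertex has degree 2 — the molecule is a six-cycle — and
the record renders back to the exact bytes it was parsed from.

Batch use from the shell (`molstream` console script):

```sh
molstream gen library.sdf --n 1000 --seed 42 --manifest manifest.tsv
molstream convert library.sdf library.rbz.jsonl.bz2 --log convert.log
# -> 1000 read, 1000 accepted, 0 rejected
molstream summarize library.rbz.jsonl.bz2
molstream filter library.rbz.jsonl.bz2 --where contains-element=N \
    --accept nitrogen.rbz.jsonl.bz2
molstream export-graph library.rbz.jsonl.bz2 --entry 1 \
    --format graphml --out mol1.graphml
```

The `examples/` directory holds one short narrative script per
capability (parsing/round trip, convert + summarize, filtering, graph
export); each prints the numbers it computes and what they mean.

## Documentation

* `docs/methods.md` — the record model, parsing policy, check
  semantics, generator design and numerical conventions.
* `docs/container-format.md` — the container file format, bit-exactly.

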