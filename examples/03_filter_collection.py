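"""Split a collection with predicate filters.

Builds a small container of reference molecules and extracts the
nitrogen-containing ones; the accepted and rejected outputs always
partition the input.
"""

import tempfile
from pathlib import Path

from molstream import (FilterSpec, canned_sdf, contains_element,
                       container_to_collection, convert_sdf,
                       filter_collection)

tmp = Path(tempfile.mkdtemp())
sdf = tmp / "five.sdf"
sdf.write_text(canned_sdf(["ethanol_heavy", "benzene_kekulized", "pyridine",
                           "methane_full_H", "cyclohexane"]),
               encoding="utf-8")
cont = tmp / "five.rbz.jsonl.bz2"
convert_sdf(sdf, cont)

spec = FilterSpec((contains_element("N"),))
n_in, n_acc, n_rej = filter_collection(cont, spec,
                                       accept_path=tmp / "nitrogen.rbz",
                                       reject_path=tmp / "rest.rbz")
print(f"{n_in} molecules in, {n_acc} contain nitrogen, {n_rej} do not")
for name, entry in container_to_collection(tmp / "nitrogen.rbz"):
    print(f"accepted: {name}  "
          f"({sum(a.symbol == 'N' for a in entry.atoms)} N atom)")
# Only pyridine carries a nitrogen, so exactly one record is accepted.
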