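"""Batch-convert an SD-file into a compressed record container, then
summarize it in one streaming pass.

A synthetic 1000-molecule library is generated (seeded, so reproducible),
converted with strict consistency checking, and summarized; the printed
element frequencies sum to the collection's total atom count.
"""

import tempfile
from pathlib import Path

from molstream import (GenSpec, convert_sdf, format_summary_report,
                       generate_sdf, summarize_collection)

tmp = Path(tempfile.mkdtemp())
sdf = tmp / "library.sdf"
container = tmp / "library.rbz.jsonl.bz2"

manifest = generate_sdf(GenSpec(n_molecules=1000, seed=42), sdf)
report = convert_sdf(sdf, container, log_path=tmp / "convert.log")
print(f"conversion: {report.n_read} read, {report.n_accepted} accepted, "
      f"{report.n_rejected} rejected")

summary = summarize_collection(container)
print(format_summary_report(summary))
print(f"manifest atom total: {sum(r.n_atoms for r in manifest)} "
      f"(must equal the summary's total atoms)")
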