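#!/usr/bin/env python
"""Apply the copy filter and genomic fold-change selection to the simulated
study and score recovery of the planted B-linked genes.  A contig is a
candidate when every 1B individual shows gFC >= log2(1.5) (three-replicate
design); the [0.5, 4]-copy filter removes repetitive and low-copy contigs
first.
"""

import json
from pathlib import Path

from bseeker import candidate_selection as sel
from bseeker.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    result = run_pipeline(seed=0)
    out = ROOT / "results" / "gfc_candidates.tsv"
    out.parent.mkdir(exist_ok=True)
    sel.gfc_table(result.gfc_records).to_csv(out, sep="\t", index=False,
                                             float_format="%.4f")
    s = result.manifest.summary
    print(f"{s['n_contigs']} contigs; {s['n_pass_copy_filter']} pass the "
          f"[0.5, 4]-copy filter; {s['n_candidates']} selected as B-linked candidates")
    print("recovery vs planted truth:",
          json.dumps(result.recovery["candidates"], sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
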