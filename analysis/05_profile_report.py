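"""Render the per-condition reference-profile figure (the 'red dots' view).

One panel per growth condition: the Z-score of every reference subunit in
each replicate, with the per-sample median of the reference set overlaid in
red.  The plotted numbers are also written as TSV next to the figure.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from coabund import (
    build_consensus_profile,
    compute_zscores,
    read_abundance_table,
    read_design,
    read_reference_ids,
    render_profile_report,
)

DATASET = ROOT / "scratch" / "dataset"


def main():
    if not (DATASET / "abundance.tsv").exists():
        sys.exit("run 01_simulate_dataset.py first")
    design = read_design(DATASET / "design.tsv")
    matrix = read_abundance_table(DATASET / "abundance.tsv", design)
    refs = read_reference_ids(DATASET / "reference_ids.txt", matrix)
    z = compute_zscores(matrix)
    cons = build_consensus_profile(z, refs)
    out = ROOT / "scratch" / "run" / "profile_report.png"
    out.parent.mkdir(parents=True, exist_ok=True)
    render_profile_report(z, cons, design, out)
    lo, hi = cons.values.min(), cons.values.max()
    print(
        f"figure written to {out.relative_to(ROOT)} "
        f"(+ .data.tsv); consensus Z-scores span [{lo:.2f}, {hi:.2f}] "
        f"across {len(design.conditions)} conditions"
    )


if __name__ == "__main__":
    main()
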