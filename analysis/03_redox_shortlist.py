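"""Shortlist redox-plausible candidates and score recovery against the truth.

Reads the ranked table and redox calls from 02_rank_candidates.py, reports
the redox shortlist (the analogue of a curated candidate table), and — since
the dataset is synthetic — scores how well the selection recovered the
planted partners.  Writes results/redox_shortlist.tsv and
results/recovery_metrics.json.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from coabund import evaluate_recovery
from coabund.matching import DistanceTable, SelectionResult, PartnerCompletion
from coabund.simulate import SyntheticTruth

RUN = ROOT / "scratch" / "run"
DATASET = ROOT / "scratch" / "dataset"


def main():
    if not (RUN / "ranked.tsv").exists():
        sys.exit("run 02_rank_candidates.py first")
    ranked = pd.read_csv(RUN / "ranked.tsv", sep="\t")
    sel_spec = json.loads((RUN / "selection.json").read_text())
    selection = SelectionResult(
        threshold=sel_spec["threshold"],
        mode=sel_spec["mode"],
        selected_ids=tuple(sel_spec["selected_ids"]),
        reference_passing=tuple(sel_spec["reference_passing"]),
        partner_completed=tuple(
            PartnerCompletion(c["partner_id"], c["trigger_id"], c["distance"])
            for c in sel_spec["partner_completed"]
        ),
    )
    table = DistanceTable(
        frame=ranked.rename(columns={"distance_full": "d"})
        .assign(distance=lambda f: f["d"])[["protein_id", "distance", "rank", "is_reference"]]
    )
    truth_frame = pd.read_csv(DATASET / "truth.tsv", sep="\t")
    truth = SyntheticTruth(frame=truth_frame, latent=None)

    shortlist = ranked[ranked["redox"] & (ranked["selected"] | ranked["partner_completed"])]
    shortlist.to_csv(ROOT / "results" / "redox_shortlist.tsv", sep="\t", index=False)

    metrics = evaluate_recovery(selection, table, truth)
    (ROOT / "results" / "recovery_metrics.json").write_text(
        json.dumps(asdict(metrics), indent=2) + "\n"
    )
    n_true = shortlist["protein_id"].isin(set(truth.partner_ids)).sum()
    print(
        f"redox shortlist: {len(shortlist)} proteins ({n_true} planted partners); "
        f"selection recall {metrics.recall:.2f}, precision {metrics.precision:.3f}, "
        f"background FPR {metrics.fpr_background:.3f}, "
        f"median partner rank {metrics.median_partner_rank:.0f}"
    )


if __name__ == "__main__":
    main()
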