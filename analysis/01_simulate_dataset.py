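"""Generate the synthetic study dataset the downstream analyses run on.

Emulates a 6-condition x 3-replicate label-free proteomics experiment: 10
reference subunits tightly coupled to a latent complex activity, 5 planted
partner proteins, 2000 uncorrelated background proteins.  The full dataset
(abundance matrix, design, reference IDs, annotations, sequences, truth) is
written under scratch/dataset/ in the exact formats the pipeline reads; a
small summary goes to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from coabund import SimulationConfig
from coabund.simulate import write_dataset

SEED = 1


def main():
    config = SimulationConfig(seed=SEED)
    out = ROOT / "scratch" / "dataset"
    paths = write_dataset(config, out)
    summary = {
        "seed": SEED,
        "n_proteins": config.n_proteins,
        "n_samples": config.n_samples,
        "conditions": config.n_conditions,
        "replicates": config.n_replicates,
        "files": {k: str(p.relative_to(ROOT)) for k, p in paths.items()},
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "dataset_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"wrote {config.n_proteins} proteins x {config.n_samples} samples "
        f"(seed {SEED}) to {out.relative_to(ROOT)}"
    )


if __name__ == "__main__":
    main()
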