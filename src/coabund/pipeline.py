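"""End-to-end pipeline orchestration and the per-condition profile report."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from coabund import io, matching, redox

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file.

    Paths are resolved relative to the config file's directory when loaded
    with :meth:`from_yaml`.
    """

    abundance: Path
    design: Path
    reference: Path
    output_dir: Path
    annotations: Optional[Path] = None
    sequences: Optional[Path] = None
    partner_map: tuple[tuple[str, str], ...] = ()
    transform: str = "none"
    min_present_fraction: float = 0.5
    sd_convention: str = "sample"
    threshold_mode: str = "auto"
    threshold_value: Optional[float] = None
    include_reference: bool = False
    decimal: Optional[str] = None
    redox_rules: Optional[redox.RedoxRuleSet] = None
    make_report: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        path = Path(path)
        spec = yaml.safe_load(path.read_text()) or {}
        spec.update({k: v for k, v in overrides.items() if v is not None})
        base = path.parent

        def p(key):
            return (base / spec[key]).resolve() if key in spec and spec[key] else None

        rules = None
        if "redox_rules" in spec and spec["redox_rules"]:
            rules = redox.RedoxRuleSet.from_dict(spec["redox_rules"])
        return cls(
            abundance=p("abundance"),
            design=p("design"),
            reference=p("reference"),
            output_dir=(base / spec.get("output_dir", "results")).resolve(),
            annotations=p("annotations"),
            sequences=p("sequences"),
            partner_map=tuple(tuple(pair) for pair in spec.get("partner_map", ())),
            transform=spec.get("transform", "none"),
            min_present_fraction=float(spec.get("min_present_fraction", 0.5)),
            sd_convention=spec.get("sd_convention", "sample"),
            threshold_mode=spec.get("threshold_mode", "auto"),
            threshold_value=spec.get("threshold_value"),
            include_reference=bool(spec.get("include_reference", False)),
            decimal=spec.get("decimal"),
            redox_rules=rules,
            make_report=bool(spec.get("make_report", False)),
        )


def run_pipeline(config: RunConfig):
    """Execute read -> Z-score -> consensus -> rank -> select -> complete -> redox.

    Writes ranked.tsv, selection.json, redox_calls.tsv and run_log.json into
    ``config.output_dir`` and returns the final :class:`SelectionResult`.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = io.read_design(config.design)
    matrix = io.read_abundance_table(config.abundance, design, decimal=config.decimal)
    reference_ids = io.read_reference_ids(config.reference, matrix)
    annotations = io.read_annotations(config.annotations) if config.annotations else None
    sequences = io.read_sequences(config.sequences) if config.sequences else None

    z = matching.compute_zscores(
        matrix,
        transform=config.transform,
        min_present_fraction=config.min_present_fraction,
        sd_convention=config.sd_convention,
    )
    consensus = matching.build_consensus_profile(z, reference_ids)
    table = matching.rank_by_distance(z, consensus, reference_ids)
    threshold = matching.select_threshold(
        table, reference_ids, mode=config.threshold_mode, fixed_value=config.threshold_value
    )
    selection = matching.select_candidates(
        table, threshold, mode=config.threshold_mode,
        include_reference=config.include_reference,
    )
    selection = matching.complete_partners(selection, table, config.partner_map)

    calls = []
    if annotations is not None:
        screen_ids = list(selection.selected_ids) + [
            c.partner_id for c in selection.partner_completed
        ]
        calls = redox.classify_redox(
            screen_ids, annotations, sequences=sequences,
            rules=config.redox_rules or redox.RedoxRuleSet(),
        )
        pd.DataFrame(
            [
                {
                    "protein_id": c.protein_id,
                    "is_redox": c.is_redox,
                    "evidence": ";".join(c.evidence),
                }
                for c in calls
            ]
        ).to_csv(out / "redox_calls.tsv", sep="\t", index=False)

    io.write_ranked_table(
        table, out / "ranked.tsv", annotations=annotations,
        selection=selection, redox_calls=calls,
    )
    selection.to_json(out / "selection.json")

    log = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_proteins": int(len(matrix.protein_ids)),
        "n_samples": int(matrix.n_samples),
        "n_reference": len(reference_ids),
        "n_excluded": len(table.excluded),
        "transform": config.transform,
        "sd_convention": config.sd_convention,
        "min_present_fraction": config.min_present_fraction,
        "threshold_mode": config.threshold_mode,
        "threshold": selection.threshold,
        "n_selected": len(selection.selected_ids),
        "n_partner_completed": len(selection.partner_completed),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    logger.info(
        "selected %d candidates at threshold %.4f (%s mode)",
        len(selection.selected_ids), selection.threshold, selection.mode,
    )

    if config.make_report:
        render_profile_report(z, consensus, design, out / "profile_report.png")
    return selection


def render_profile_report(
    z: matching.ZScoreMatrix,
    consensus: matching.ConsensusProfile,
    design: io.SampleDesign,
    out: str | Path,
) -> None:
    """Per-condition panels of reference-subunit Z-scores with the median marked.

    One panel per condition; each reference subunit contributes one point per
    replicate, and the consensus (per-sample median) is overlaid as red dots.
    The plotted numbers are also written next to the figure as
    ``<out>.data.tsv`` so the report is testable without parsing the image.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    ref_ids = [r for r in consensus.reference_ids if r in set(z.protein_ids)]
    conditions = design.conditions

    rows = []
    for pid in ref_ids:
        for sid in z.sample_ids:
            rows.append({"series": pid, "sample_id": sid, "z": float(z.z.loc[pid, sid])})
    for sid in z.sample_ids:
        rows.append(
            {"series": "consensus", "sample_id": sid, "z": float(consensus.values[sid])}
        )
    pd.DataFrame(rows).to_csv(out.with_suffix(out.suffix + ".data.tsv"), sep="\t", index=False)

    ncol = min(3, len(conditions))
    nrow = int(np.ceil(len(conditions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for k, cond in enumerate(conditions):
        ax = axes[k // ncol][k % ncol]
        samples = design.samples_for(cond)
        xs = np.arange(len(samples))
        for pid in ref_ids:
            ax.plot(xs, z.z.loc[pid, samples], "o-", color="grey", alpha=0.5, markersize=3)
        ax.plot(
            xs, [consensus.values[s] for s in samples], "o", color="red",
            markersize=6, zorder=3, label="median",
        )
        ax.set_title(cond)
        ax.set_xticks(xs)
        ax.set_xticklabels([f"r{i + 1}" for i in xs])
        ax.set_ylabel("Z-score")
    for k in range(len(conditions), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
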