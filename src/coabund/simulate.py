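"""Synthetic multi-condition proteomics data with planted co-abundance partners.

The generator emulates the statistical structure the guilt-by-association
analysis assumes: a latent per-condition activity of the protein complex, a
block of reference subunits tightly coupled to it, a handful of planted
partner proteins coupled slightly less tightly, and a large uncorrelated
background.  On the log2 scale the abundance of protein ``p`` in sample
``(condition k, replicate r)`` is

    b_p + s_p * (rho_p * a_k + sqrt(1 - rho_p^2) * u_{p,k}) + eps_{p,k,r}

with ``a_k ~ N(0,1)`` the shared latent condition activity, ``u_{p,k} ~
N(0,1)`` a protein-specific condition effect (shared by replicates),
``eps ~ N(0, sigma_rep^2)`` replicate noise, ``b_p`` a per-protein baseline
and ``s_p`` a positive signal loading.  Emitted abundances are ``2**log2``,
hence strictly positive and on a linear scale, like processed label-free
quantification output.

The generator also plants recognisable annotations (redox keywords on the
partners) and sequences (a 4Fe-4S cysteine motif in the partners) so the
downstream annotation filter is exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from coabund.io import (
    AbundanceMatrix,
    AnnotationTable,
    SampleDesign,
    ValidationError,
    write_abundance_table,
    write_design,
)

#: growth-condition labels used when the design has exactly six conditions
#: (electron donor / electron acceptor pairs typical of organohalide respirers)
SIX_CONDITION_LABELS = ("Py-only", "Py/Fu", "La/Fu", "La/ClOHPA", "H2/Fu", "H2/ClOHPA")

_PARTNER_DESCRIPTIONS = (
    "Pyruvate flavodoxin/ferredoxin oxidoreductase",
    "[4Fe-4S] ferredoxin iron-sulfur binding domain protein",
    "FeFe-hydrogenase",
    "Rubrerythrin",
    "Carbon monoxide dehydrogenase, catalytic subunit",
)
_BACKGROUND_DESCRIPTIONS = (
    "hypothetical protein",
    "ribosomal protein",
    "ABC transporter permease",
    "elongation factor Tu",
    "cell division protein FtsZ",
    "chaperonin GroEL",
    "DNA polymerase III subunit",
    "phosphate transport system protein",
)
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: inserted into partner sequences; matches the 4Fe-4S CxxCxxCxxxC spacing
_FES_MOTIF = "CIACGACEPECP"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults mirror a 6-condition x 3-replicate study."""

    n_conditions: int = 6
    n_replicates: int = 3
    n_reference: int = 10
    n_partners: int = 5
    n_background: int = 2000
    rho_reference: float = 0.95
    rho_partner: float = 0.9
    sigma_rep: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    loading_mean: float = 1.0
    loading_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_conditions", "n_replicates", "n_reference"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("n_partners", "n_background"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("rho_reference", "rho_partner"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.sigma_rep < 0:
            raise ValidationError("sigma_rep must be non-negative")
        if self.baseline_sd < 0 or self.loading_sd < 0:
            raise ValidationError("standard deviations must be non-negative")

    @property
    def n_proteins(self) -> int:
        return self.n_reference + self.n_partners + self.n_background

    @property
    def n_samples(self) -> int:
        return self.n_conditions * self.n_replicates


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset: labels, couplings, latent activity."""

    frame: pd.DataFrame  # columns: protein_id, label, rho, loading
    latent: np.ndarray  # realised a_k, one per condition

    def ids_with_label(self, label: str) -> list[str]:
        return list(self.frame.loc[self.frame["label"] == label, "protein_id"])

    @property
    def reference_ids(self) -> list[str]:
        return self.ids_with_label("reference")

    @property
    def partner_ids(self) -> list[str]:
        return self.ids_with_label("partner")

    @property
    def background_ids(self) -> list[str]:
        return self.ids_with_label("background")


def _protein_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    def tag(prefix: str, count: int, width: int) -> list[str]:
        return [f"{prefix}{i + 1:0{width}d}" for i in range(count)]

    ids = (
        tag("NUO", config.n_reference, 2)
        + tag("PTN", config.n_partners, 2)
        + tag("BKG", config.n_background, 4)
    )
    labels = (
        ["reference"] * config.n_reference
        + ["partner"] * config.n_partners
        + ["background"] * config.n_background
    )
    return ids, labels


def _make_design(config: SimulationConfig) -> SampleDesign:
    if config.n_conditions == 6:
        conditions = list(SIX_CONDITION_LABELS)
    else:
        conditions = [f"C{k + 1}" for k in range(config.n_conditions)]
    rows = [
        {"sample_id": f"{cond}_r{r + 1}", "condition": cond, "replicate": r + 1}
        for cond in conditions
        for r in range(config.n_replicates)
    ]
    return SampleDesign(pd.DataFrame(rows))


def _make_annotations(ids: list[str], labels: list[str]) -> AnnotationTable:
    rows = []
    subunit_letters = "ABCDHIJKLMN"  # the 11 subunits of the short complex I form
    ref_i = part_i = bg_i = 0
    for pid, label in zip(ids, labels):
        if label == "reference":
            letter = subunit_letters[ref_i % len(subunit_letters)]
            desc = f"NADH-quinone oxidoreductase subunit Nuo{letter}"
            ref_i += 1
        elif label == "partner":
            desc = _PARTNER_DESCRIPTIONS[part_i % len(_PARTNER_DESCRIPTIONS)]
            part_i += 1
        else:
            desc = _BACKGROUND_DESCRIPTIONS[bg_i % len(_BACKGROUND_DESCRIPTIONS)]
            bg_i += 1
        rows.append({"protein_id": pid, "description": desc})
    return AnnotationTable(pd.DataFrame(rows))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, SampleDesign, SyntheticTruth, AnnotationTable]:
    """Draw one fully seeded synthetic dataset.

    The RNG stream is consumed in a fixed order — baselines, loadings,
    latents, condition effects, replicate noise — so a (config, seed) pair
    always yields the identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n, n_cond, n_rep = config.n_proteins, config.n_conditions, config.n_replicates
    ids, labels = _protein_ids(config)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n)
    loadings = rng.normal(config.loading_mean, config.loading_sd, n)
    while (loadings <= 0).any():  # truncate loadings to positive by redraw
        bad = loadings <= 0
        loadings[bad] = rng.normal(config.loading_mean, config.loading_sd, int(bad.sum()))
    latent = rng.normal(0.0, 1.0, n_cond)
    effects = rng.normal(0.0, 1.0, (n, n_cond))
    noise = rng.normal(0.0, config.sigma_rep, (n, n_cond * n_rep))

    rho = np.empty(n)
    rho[: config.n_reference] = config.rho_reference
    rho[config.n_reference : config.n_reference + config.n_partners] = config.rho_partner
    rho[config.n_reference + config.n_partners :] = 0.0

    signal = rho[:, None] * latent[None, :] + np.sqrt(1.0 - rho[:, None] ** 2) * effects
    log2_abundance = (
        baselines[:, None]
        + loadings[:, None] * np.repeat(signal, n_rep, axis=1)
        + noise
    )
    design = _make_design(config)
    values = pd.DataFrame(
        np.exp2(log2_abundance), index=pd.Index(ids, name="protein_id"),
        columns=design.sample_ids,
    )
    matrix = AbundanceMatrix(values=values, design=design)
    truth = SyntheticTruth(
        frame=pd.DataFrame(
            {"protein_id": ids, "label": labels, "rho": rho, "loading": loadings}
        ),
        latent=latent,
    )
    return matrix, design, truth, _make_annotations(ids, labels)


def simulate_sequences(
    truth: SyntheticTruth, seed: int, length: int = 80
) -> dict[str, str]:
    """Random protein sequences; planted partners carry a 4Fe-4S-style motif."""
    rng = np.random.default_rng([seed, 1])
    seqs: dict[str, str] = {}
    partner_ids = set(truth.partner_ids)
    for pid in truth.frame["protein_id"]:
        residues = rng.choice(_AMINO_ACIDS, size=length)
        seq = "".join(residues)
        if pid in partner_ids:
            mid = length // 2
            seq = seq[:mid] + _FES_MOTIF + seq[mid + len(_FES_MOTIF):]
        seqs[pid] = "M" + seq[1:]
    return seqs


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the full dataset in the formats the pipeline reads.

    Emits abundance.tsv, design.tsv, reference_ids.txt, annotations.tsv,
    sequences.fasta (synthetic) and truth.tsv; returns the paths.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, design, truth, annotations = simulate_dataset(config)
    paths = {
        "abundance": out / "abundance.tsv",
        "design": out / "design.tsv",
        "reference": out / "reference_ids.txt",
        "annotations": out / "annotations.tsv",
        "sequences": out / "sequences.fasta",
        "truth": out / "truth.tsv",
    }
    write_abundance_table(matrix, paths["abundance"])
    write_design(design, paths["design"])
    paths["reference"].write_text("".join(f"{pid}\n" for pid in truth.reference_ids))
    annotations.frame.to_csv(paths["annotations"], sep="\t", index=False)
    seqs = simulate_sequences(truth, config.seed)
    records = [
        SeqRecord(Seq(seq), id=pid, description="synthetic") for pid, seq in seqs.items()
    ]
    SeqIO.write(records, str(paths["sequences"]), "fasta")
    truth.frame.to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well a selection recovered the planted partners."""

    recall: float
    precision: float
    fpr_background: float
    median_partner_rank: float
    n_selected: int


def evaluate_recovery(selection, table, truth: SyntheticTruth) -> RecoveryMetrics:
    """Score a selection against the ground truth of the simulated dataset.

    Recall and the background false-positive rate are per-class proportions;
    the partner rank is computed among non-reference proteins only (the
    reference set defines the consensus and is not a discovery).  An empty
    selection has precision 1 by convention — it contains no false positives.
    """
    truth_ids = set(truth.frame["protein_id"])
    table_ids = set(table.frame["protein_id"])
    if not table_ids <= truth_ids:
        stray = sorted(table_ids - truth_ids)[0]
        raise ValidationError(f"distance table contains unknown protein {stray!r}")

    partners = set(truth.partner_ids)
    background = set(truth.background_ids)
    selected = set(selection.selected_ids)

    recall = len(selected & partners) / len(partners) if partners else 1.0
    precision = len(selected & partners) / len(selected) if selected else 1.0
    fpr = len(selected & background) / len(background) if background else 0.0

    non_ref = table.frame[~table.frame["is_reference"]].reset_index(drop=True)
    partner_pos = non_ref.index[non_ref["protein_id"].isin(partners)] + 1
    median_rank = float(np.median(partner_pos)) if len(partner_pos) else float("nan")
    return RecoveryMetrics(
        recall=recall,
        precision=precision,
        fpr_background=fpr,
        median_partner_rank=median_rank,
        n_selected=len(selected),
    )
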