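"""Core co-abundance statistics: Z-scores, consensus profile, distance ranking.

The guilt-by-association procedure: each protein's abundance profile across
all samples is standardised to Z-scores, ``z = (x - mu) / sigma``, with ``mu``
and ``sigma`` computed per protein over its non-missing samples.  A consensus
profile is the per-sample median of the Z-scores of a reference subunit set
(the detected subunits of the complex of interest).  Every protein is then
ranked by the Euclidean distance of its Z-profile to the consensus, and
candidates are the proteins below a threshold derived from the dispersion of
the reference set itself (the distance of its most divergent member).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from coabund.io import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

Transform = Literal["none", "log2", "log10"]
SdConvention = Literal["sample", "population"]
ThresholdMode = Literal["auto", "fixed"]

#: reason codes for rows dropped during standardisation / ranking
REASON_ZERO_VARIANCE = "zero-variance"
REASON_EXCESS_MISSING = "excess-missing"
REASON_MISSING_PROFILE = "missing-profile"


@dataclass(frozen=True)
class ZScoreMatrix:
    """Row-standardised profiles plus the rows that had to be dropped.

    Every retained row has mean 0 and standard deviation 1 (to the chosen
    convention) over its non-missing samples.  ``excluded`` maps a dropped
    protein ID to its reason code.
    """

    z: pd.DataFrame
    excluded: dict[str, str]
    transform: Transform = "none"
    sd_convention: SdConvention = "sample"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-sample median of the reference subunits' Z-scores."""

    values: pd.Series  # indexed by sample_id
    reference_ids: tuple[str, ...]


@dataclass(frozen=True)
class DistanceTable:
    """Per-protein Euclidean distance to the consensus, ranked ascending.

    Ties are broken by protein ID so ranks are deterministic across runs.
    ``excluded`` carries proteins dropped for an incomplete Z-profile.
    """

    frame: pd.DataFrame  # columns: protein_id, distance, rank, is_reference
    excluded: dict[str, str] = field(default_factory=dict)

    def distance_of(self, protein_id: str) -> float:
        sub = self.frame.loc[self.frame["protein_id"] == protein_id, "distance"]
        if sub.empty:
            raise KeyError(protein_id)
        return float(sub.iloc[0])

    def __contains__(self, protein_id: str) -> bool:
        return (self.frame["protein_id"] == protein_id).any()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PartnerCompletion:
    """A protein pulled into the shortlist because its functional partner passed."""

    partner_id: str
    trigger_id: str
    distance: float


@dataclass(frozen=True)
class SelectionResult:
    """Candidate selection at a threshold, with provenance.

    ``selected_ids`` excludes the reference subunits unless the selection was
    run with ``include_reference``; the subunits passing the threshold are
    reported separately in ``reference_passing``.  ``partner_completed`` holds
    curated partners appended after selection; it never overlaps
    ``selected_ids``.
    """

    threshold: float
    mode: ThresholdMode
    selected_ids: tuple[str, ...]
    reference_passing: tuple[str, ...] = ()
    partner_completed: tuple[PartnerCompletion, ...] = ()
    include_reference: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "mode": self.mode,
            "include_reference": self.include_reference,
            "selected_ids": list(self.selected_ids),
            "reference_passing": list(self.reference_passing),
            "partner_completed": [
                {"partner_id": c.partner_id, "trigger_id": c.trigger_id, "distance": c.distance}
                for c in self.partner_completed
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def compute_zscores(
    matrix: AbundanceMatrix,
    transform: Transform = "none",
    min_present_fraction: float = 0.5,
    sd_convention: SdConvention = "sample",
) -> ZScoreMatrix:
    """Standardise every protein's profile to Z-scores.

    Parameters
    ----------
    matrix:
        Validated abundance matrix (columns already in design order).
    transform:
        Optional monotone transform applied before standardisation.  Under a
        log transform non-positive abundances become missing, since their log
        is undefined.
    min_present_fraction:
        Rows with a smaller fraction of non-missing samples are excluded with
        reason ``excess-missing``.
    sd_convention:
        ``"sample"`` uses the n-1 denominator (the default of common
        statistical environments); ``"population"`` uses n.

    Rows with zero variance are excluded with reason ``zero-variance`` —
    their Z-score is undefined.
    """
    if matrix.n_samples < 2:
        raise ValidationError("Z-scores need at least 2 samples")
    if not (0.0 < min_present_fraction <= 1.0):
        raise ValidationError("min_present_fraction must be in (0, 1]")
    vals = matrix.values.astype(float)
    if transform in ("log2", "log10"):
        nonpos = (vals <= 0).sum().sum()
        if nonpos:
            logger.warning(
                "%d non-positive abundances set to missing under %s transform",
                int(nonpos), transform,
            )
        vals = vals.where(vals > 0)
        vals = np.log2(vals) if transform == "log2" else np.log10(vals)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")

    excluded: dict[str, str] = {}
    present = vals.notna().mean(axis=1)
    for pid in vals.index[present < min_present_fraction]:
        excluded[pid] = REASON_EXCESS_MISSING
    kept = vals.loc[~vals.index.isin(excluded)]

    ddof = 1 if sd_convention == "sample" else 0
    mu = kept.mean(axis=1, skipna=True)
    sigma = kept.std(axis=1, ddof=ddof, skipna=True)
    degenerate = ~np.isfinite(sigma) | (sigma == 0)
    for pid in kept.index[degenerate]:
        excluded[pid] = REASON_ZERO_VARIANCE
    kept = kept.loc[~degenerate]
    z = kept.sub(mu.loc[kept.index], axis=0).div(sigma.loc[kept.index], axis=0)
    if z.empty:
        raise ValidationError("all rows excluded during standardisation")
    return ZScoreMatrix(z=z, excluded=excluded, transform=transform, sd_convention=sd_convention)


def build_consensus_profile(z: ZScoreMatrix, reference_ids: Sequence[str]) -> ConsensusProfile:
    """Per-sample median over the reference subunit rows.

    A reference subunit excluded during standardisation is a hard error: the
    consensus is defined over the full detected reference set.  Even-count
    medians use the midpoint of the two central values.
    """
    if not reference_ids:
        raise ValidationError("reference set is empty")
    dropped = [r for r in reference_ids if r in z.excluded]
    if dropped:
        raise ValidationError(
            f"reference subunit {dropped[0]!r} was excluded during standardisation "
            f"({z.excluded[dropped[0]]})"
        )
    absent = [r for r in reference_ids if r not in set(z.protein_ids)]
    if absent:
        raise ValidationError(f"reference subunit {absent[0]!r} not in the Z-score matrix")
    ref_rows = z.z.loc[list(reference_ids)]
    values = ref_rows.median(axis=0)
    return ConsensusProfile(values=values, reference_ids=tuple(reference_ids))


def euclidean_distance(y: Sequence[float], x: Sequence[float]) -> float:
    """sqrt of the summed squared per-coordinate differences between profiles."""
    ya = np.asarray(y, dtype=float)
    xa = np.asarray(x, dtype=float)
    if ya.shape != xa.shape:
        raise ValidationError(f"length mismatch: {ya.shape} vs {xa.shape}")
    if np.isnan(ya).any() or np.isnan(xa).any():
        raise ValidationError("profiles with missing values cannot be compared")
    return float(np.sqrt(np.sum((xa - ya) ** 2)))


def rank_by_distance(
    z: ZScoreMatrix,
    consensus: ConsensusProfile,
    reference_ids: Sequence[str],
) -> DistanceTable:
    """Rank every retained protein by distance to the consensus profile.

    Proteins with a missing Z-score at any sample are excluded with reason
    ``missing-profile`` — a distance over fewer coordinates would not be
    comparable.  Reference subunits are kept in the table and flagged.
    """
    zv = z.z
    complete = zv.notna().all(axis=1)
    excluded = dict(z.excluded)
    for pid in zv.index[~complete]:
        excluded[pid] = REASON_MISSING_PROFILE
    zc = zv.loc[complete]
    cons = consensus.values.reindex(zc.columns).to_numpy(dtype=float)
    d = np.sqrt(((zc.to_numpy(dtype=float) - cons) ** 2).sum(axis=1))
    frame = pd.DataFrame(
        {
            "protein_id": zc.index,
            "distance": d,
            "is_reference": zc.index.isin(set(reference_ids)),
        }
    )
    frame = frame.sort_values(["distance", "protein_id"], kind="mergesort").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame = frame[["protein_id", "distance", "rank", "is_reference"]]
    return DistanceTable(frame=frame, excluded=excluded)


def select_threshold(
    table: DistanceTable,
    reference_ids: Sequence[str],
    mode: ThresholdMode = "auto",
    fixed_value: Optional[float] = None,
) -> float:
    """Distance threshold for candidate selection.

    ``auto`` returns the distance of the most divergent reference subunit, so
    selection with ``<=`` always admits the full reference set.  ``fixed``
    passes ``fixed_value`` through; selection then uses a strict ``<``
    ("distance smaller than" the stated cut-off).
    """
    if mode == "fixed":
        if fixed_value is None:
            raise ValidationError("fixed threshold mode requires a value")
        return float(fixed_value)
    if mode != "auto":
        raise ValidationError(f"unknown threshold mode {mode!r}")
    ref = table.frame[table.frame["protein_id"].isin(set(reference_ids))]
    if ref.empty:
        raise ValidationError("no reference subunit present in the distance table")
    return float(ref["distance"].max())


def select_candidates(
    table: DistanceTable,
    threshold: float,
    mode: ThresholdMode = "auto",
    include_reference: bool = False,
) -> SelectionResult:
    """Select candidates below the threshold, in ascending-distance order."""
    frame = table.frame
    passing = frame["distance"] <= threshold if mode == "auto" else frame["distance"] < threshold
    hits = frame[passing]
    ref_passing = tuple(hits.loc[hits["is_reference"], "protein_id"])
    if not include_reference:
        hits = hits[~hits["is_reference"]]
    return SelectionResult(
        threshold=float(threshold),
        mode=mode,
        selected_ids=tuple(hits["protein_id"]),
        reference_passing=ref_passing,
        include_reference=include_reference,
    )


def complete_partners(
    selection: SelectionResult,
    table: DistanceTable,
    partner_map: Sequence[tuple[str, str]],
) -> SelectionResult:
    """Append curated functional partners of selected proteins.

    ``partner_map`` encodes manual curation as (trigger, partner) pairs: when
    the trigger made the selection but its known operonic/functional partner
    did not, the partner is appended to ``partner_completed`` with its
    distance — it does not join ``selected_ids``.  A partner absent from the
    distance table is skipped with a warning.
    """
    selected = set(selection.selected_ids)
    already = {c.partner_id for c in selection.partner_completed}
    completions = list(selection.partner_completed)
    for trigger, partner in partner_map:
        if trigger not in selected:
            continue
        if partner in selected or partner in already:
            continue
        if partner not in table:
            logger.warning("partner %r not in distance table; pair (%s, %s) skipped",
                           partner, trigger, partner)
            continue
        completions.append(
            PartnerCompletion(partner_id=partner, trigger_id=trigger,
                              distance=table.distance_of(partner))
        )
        already.add(partner)
    return replace(selection, partner_completed=tuple(completions))
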