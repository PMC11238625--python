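"""Reading, validation and writing of the pipeline's tabular inputs and outputs.

Formats are deliberately plain: abundance matrices and annotation tables are
TSV/CSV, the sample design is a three-column TSV (sample, condition,
replicate), reference IDs are one per line, sequences are FASTA.  European
decimal commas (``1,20``) are auto-detected because processed proteomics
tables exported from spreadsheets frequently use them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A"}
_COMMA_NUMBER = re.compile(r"^-?\d+,\d+$")
_PLAIN_NUMBER = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")


class ValidationError(ValueError):
    """Raised when an input file violates the pipeline's contracts."""


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of sample IDs to (condition, replicate).

    Invariants: sample IDs unique, (condition, replicate) pairs unique, at
    least two samples.
    """

    frame: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(
                f"sample design needs columns {sorted(required)}, got {list(self.frame.columns)}"
            )
        if len(self.frame) < 2:
            raise ValidationError("sample design must contain at least 2 samples")
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate sample_id in design: {dup.iloc[0]!r}")
        pairs = self.frame[["condition", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            bad = pairs[pairs.duplicated()].iloc[0]
            raise ValidationError(f"duplicate (condition, replicate) pair in design: {bad}")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sub = self.frame[self.frame["condition"] == condition]
        return list(sub["sample_id"])


@dataclass(frozen=True)
class AbundanceMatrix:
    """Proteins x samples relative abundances, tied to a :class:`SampleDesign`.

    ``values`` is indexed by protein ID with columns in design order; entries
    are non-negative floats, NaN for missing.
    """

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            bad = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein ID: {bad!r}")
        if self.values.columns.duplicated().any():
            bad = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {bad!r}")
        design_ids = self.design.sample_ids
        extra = [s for s in self.values.columns if s not in set(design_ids)]
        if extra:
            raise ValidationError(f"sample {extra[0]!r} not present in the design")
        missing = [s for s in design_ids if s not in set(self.values.columns)]
        if missing:
            raise ValidationError(f"design sample {missing[0]!r} absent from the matrix")
        if list(self.values.columns) != design_ids:
            # reorder silently to design order; frozen dataclass workaround
            object.__setattr__(self, "values", self.values[design_ids])
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("abundance values must be finite or missing")
        with np.errstate(invalid="ignore"):
            if (arr < 0).any():
                raise ValidationError("negative abundance value encountered")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnnotationTable:
    """Protein ID -> free-text description (+ optional FASTA record reference)."""

    frame: pd.DataFrame  # columns: protein_id, description[, sequence_ref]

    def __post_init__(self) -> None:
        if "protein_id" not in self.frame.columns or "description" not in self.frame.columns:
            raise ValidationError("annotation table needs columns protein_id, description")
        dup = self.frame["protein_id"][self.frame["protein_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate protein ID in annotations: {dup.iloc[0]!r}")

    def description(self, protein_id: str) -> str:
        sub = self.frame.loc[self.frame["protein_id"] == protein_id, "description"]
        if sub.empty:
            raise KeyError(protein_id)
        val = sub.iloc[0]
        return "" if pd.isna(val) else str(val)

    def __contains__(self, protein_id: str) -> bool:
        return (self.frame["protein_id"] == protein_id).any()


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _detect_decimal(raw: pd.DataFrame) -> str:
    """Return ',' when a column is numeric only under the decimal-comma dialect."""
    for col in raw.columns:
        cells = [c.strip() for c in raw[col].astype(str)]
        cells = [c for c in cells if c not in _MISSING_TOKENS]
        if not cells:
            continue
        has_comma = any(_COMMA_NUMBER.match(c) for c in cells)
        all_comma_numeric = all(
            _COMMA_NUMBER.match(c) or re.match(r"^-?\d+$", c) for c in cells
        )
        if has_comma and all_comma_numeric:
            return ","
    return "."


def _to_float(raw: pd.DataFrame, decimal: str, what: str) -> pd.DataFrame:
    def convert(cell: str) -> float:
        cell = cell.strip()
        if cell in _MISSING_TOKENS:
            return np.nan
        if decimal == ",":
            cell = cell.replace(",", ".")
        if not _PLAIN_NUMBER.match(cell):
            raise ValidationError(f"non-numeric {what} value: {cell!r}")
        return float(cell)

    return raw.map(convert)


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV with columns sample, condition, replicate."""
    frame = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    rename = {"sample": "sample_id"}
    frame = frame.rename(columns=rename)
    frame["replicate"] = frame["replicate"].astype(int)
    return SampleDesign(frame[["sample_id", "condition", "replicate"]])


def read_abundance_table(
    path: str | Path,
    design: SampleDesign,
    decimal: Optional[str] = None,
) -> AbundanceMatrix:
    """Read a proteins x samples abundance table and validate it against the design.

    The first column holds protein IDs, the header holds sample IDs.  When
    ``decimal`` is None the decimal-comma dialect is auto-detected (a column
    whose cells all match ``^\\d+,\\d+$`` or plain integers).  Columns are
    returned in design order regardless of file order.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=_sniff_sep(path), dtype=str, index_col=0, keep_default_na=False
    )
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    if raw.index.duplicated().any():
        bad = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate protein ID: {bad!r}")
    if decimal is None:
        decimal = _detect_decimal(raw)
    values = _to_float(raw, decimal, "abundance")
    matrix = AbundanceMatrix(values=values, design=design)
    logger.info(
        "read abundance table %s: %d proteins x %d samples (decimal %r)",
        path.name, values.shape[0], values.shape[1], decimal,
    )
    return matrix


def read_reference_ids(path: str | Path, matrix: AbundanceMatrix) -> list[str]:
    """Read reference subunit IDs (one per line), de-duplicated preserving order.

    Every ID must be present in the matrix: the reference set is by definition
    the *detected* subunits, so an absent ID is a hard error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    ids = list(dict.fromkeys(ids))
    if not ids:
        raise ValidationError(f"reference ID file {path} is empty")
    known = set(matrix.protein_ids)
    absent = [i for i in ids if i not in known]
    if absent:
        raise ValidationError(
            f"reference ID {absent[0]!r} not detected in the abundance matrix"
        )
    logger.info("read %d reference IDs from %s", len(ids), path)
    return ids


def read_annotations(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    frame = frame.rename(columns={"id": "protein_id", "accession": "protein_id"})
    return AnnotationTable(frame)


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA as a dict of record ID -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ranked_table(
    table,
    path: str | Path,
    annotations: Optional[AnnotationTable] = None,
    selection=None,
    redox_calls: Optional[Iterable] = None,
) -> None:
    """Write the ranked distance table as TSV.

    Columns: protein_id, description, distance (2 decimals, the conventional
    reporting precision), distance_full (full float precision), rank,
    is_reference, selected, partner_completed, redox.
    """
    frame = table.frame.copy()
    if annotations is not None:
        desc = annotations.frame.set_index("protein_id")["description"]
        frame["description"] = frame["protein_id"].map(desc).fillna("")
    else:
        frame["description"] = ""
    selected = set(selection.selected_ids) if selection is not None else set()
    completed = (
        {c.partner_id for c in selection.partner_completed} if selection is not None else set()
    )
    redox = {c.protein_id for c in redox_calls if c.is_redox} if redox_calls else set()
    frame["distance_full"] = frame["distance"]
    frame["distance"] = frame["distance_full"].map(lambda d: f"{d:.2f}")
    frame["selected"] = frame["protein_id"].isin(selected)
    frame["partner_completed"] = frame["protein_id"].isin(completed)
    frame["redox"] = frame["protein_id"].isin(redox)
    cols = [
        "protein_id", "description", "distance", "distance_full",
        "rank", "is_reference", "selected", "partner_completed", "redox",
    ]
    frame[cols].to_csv(path, sep="\t", index=False)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV layout :func:`read_abundance_table` reads."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.rename(columns={"sample_id": "sample"}).to_csv(path, sep="\t", index=False)
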