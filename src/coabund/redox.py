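"""Local redox-plausibility screen for candidate partners.

The shortlist of co-abundance candidates is screened for proteins that could
carry electrons: iron-sulfur carriers (ferredoxins, rubredoxins), hydrogenases,
oxidoreductases and dehydrogenases.  The screen is a deterministic rule set —
case-insensitive description keywords plus optional sequence-motif regular
expressions (a 4Fe-4S ferredoxin-type cysteine spacing and a paired-CxxC
rubredoxin-like pattern).  It approximates what a curator would do with
homology and domain search services; it is not a reimplementation of them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from coabund.io import AnnotationTable, ValidationError

logger = logging.getLogger(__name__)

#: description keywords for common redox-active protein families
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "ferredoxin",
    "rubredoxin",
    "rubrerythrin",
    "hydrogenase",
    "oxidoreductase",
    "dehydrogenase",
)

#: sequence motifs: 4Fe-4S ferredoxin-type CxxCxxCxxxC and a rubredoxin-like
#: pair of CxxC knuckles separated by a spacer
DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("4Fe-4S_ferredoxin", r"C..C..C...C"),
    ("rubredoxin_CxxC_pair", r"C..C.{10,40}C..C"),
)


@dataclass(frozen=True)
class RedoxRuleSet:
    """Keyword and motif rules; a protein is called redox when any rule fires."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    motifs: tuple[tuple[str, str], ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if not self.keywords and not self.motifs:
            raise ValidationError("rule set must contain at least one rule")
        for name, pattern in self.motifs:
            try:
                re.compile(pattern)
            except re.error as exc:
                raise ValidationError(f"motif {name!r} does not compile: {exc}") from exc

    @classmethod
    def from_dict(cls, spec: Mapping) -> "RedoxRuleSet":
        keywords = tuple(spec.get("keywords", ()))
        motifs = tuple((m["name"], m["pattern"]) for m in spec.get("motifs", ()))
        return cls(keywords=keywords, motifs=motifs)


@dataclass(frozen=True)
class RedoxCall:
    """Classification of one protein; ``evidence`` lists the rules that fired."""

    protein_id: str
    is_redox: bool
    evidence: tuple[str, ...]


def classify_redox(
    ids: Sequence[str],
    annotations: AnnotationTable,
    sequences: Optional[Mapping[str, str]] = None,
    rules: Optional[RedoxRuleSet] = None,
) -> list[RedoxCall]:
    """Classify each protein as plausibly redox-active or not.

    Keyword rules match case-insensitively against the annotation description;
    motif rules are applied only where a sequence is available (a configured
    motif rule with no sequence for an ID degrades to keywords-only with a
    warning).  Evidence is reported in rule order, keywords before motifs.
    """
    rules = rules or RedoxRuleSet()
    sequences = sequences or {}
    calls: list[RedoxCall] = []
    for pid in ids:
        if pid not in annotations:
            raise ValidationError(f"no annotation for protein {pid!r}")
        desc = annotations.description(pid).lower()
        evidence = [kw for kw in rules.keywords if kw.lower() in desc]
        seq = sequences.get(pid)
        if rules.motifs:
            if seq is None:
                if sequences:
                    logger.warning(
                        "no sequence for %s; motif rules skipped for this protein", pid
                    )
            else:
                evidence.extend(
                    name for name, pattern in rules.motifs if re.search(pattern, seq)
                )
        calls.append(RedoxCall(protein_id=pid, is_redox=bool(evidence), evidence=tuple(evidence)))
    return calls


def filter_candidates_redox(selection, calls: Sequence[RedoxCall]) -> list[str]:
    """Keep, in selection order, the candidates called redox-active.

    Partner-completed proteins follow the threshold-selected ones; the calls
    must cover both groups.
    """
    wanted = list(selection.selected_ids) + [c.partner_id for c in selection.partner_completed]
    by_id = {c.protein_id: c for c in calls}
    missing = [pid for pid in wanted if pid not in by_id]
    if missing:
        raise ValidationError(f"no redox call for selected protein {missing[0]!r}")
    return [pid for pid in wanted if by_id[pid].is_redox]
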