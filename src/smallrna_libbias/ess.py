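"""End-secondary-structure (ESS) classification.

A read "contains ESS" at an end when its predicted structure leaves a base
within the terminal window base-paired: the terminus is then part of an
intramolecular stem ("double-stranded"), which is hypothesized to block
direct adapter ligation during library construction. Hybridization-based
preps (SOLiD adapter mix, stem-loop RT primers) can melt such stems before
ligation, so ESS-bearing reads survive there but are depleted by direct
single-stranded ligation (Illumina V1).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from smallrna_libbias.folding import FoldResult


class ESSCategory(str, enum.Enum):
    ESS5_ONLY = "ess5_only"
    ESS3_ONLY = "ess3_only"
    BOTH = "both"
    NON_ESS = "non_ess"


@dataclass(frozen=True)
class ESSCall:
    """Per-read end-pairing classification."""

    read_id: str
    has_5prime_ess: bool
    has_3prime_ess: bool

    @property
    def category(self) -> ESSCategory:
        if self.has_5prime_ess and self.has_3prime_ess:
            return ESSCategory.BOTH
        if self.has_5prime_ess:
            return ESSCategory.ESS5_ONLY
        if self.has_3prime_ess:
            return ESSCategory.ESS3_ONLY
        return ESSCategory.NON_ESS


@dataclass(frozen=True)
class ESSSummary:
    """Per-library fractions of the four ESS categories."""

    library_id: str
    n_reads: int
    fractions: Mapping[ESSCategory, float]


def classify_ess(fold: FoldResult, end_window: int = 2, read_id: str = "") -> ESSCall:
    """Classify a folded read's end secondary structure.

    An end has ESS when any position within ``end_window`` of that terminus
    is base-paired in the predicted structure. The default window of 2 nt
    targets the ligatable terminal nucleotides; it is a declared convention,
    exposed because the biological definition gives no numeric window.
    """
    length = len(fold.sequence)
    if end_window < 1 or end_window > length // 2:
        raise ValueError(
            f"end_window must be in [1, {length // 2}] for a {length}-nt read"
        )
    paired = {i for pair in fold.pairs for i in pair}
    has5 = any(i < end_window for i in paired)
    has3 = any(i >= length - end_window for i in paired)
    return ESSCall(read_id=read_id, has_5prime_ess=has5, has_3prime_ess=has3)


def classify_structure(structure: str, end_window: int = 2, read_id: str = "") -> ESSCall:
    """Classify directly from a dot-bracket string (pure function of it)."""
    length = len(structure)
    if end_window < 1 or end_window > length // 2:
        raise ValueError(
            f"end_window must be in [1, {length // 2}] for a {length}-nt structure"
        )
    paired = [i for i, ch in enumerate(structure) if ch in "()"]
    has5 = any(i < end_window for i in paired)
    has3 = any(i >= length - end_window for i in paired)
    return ESSCall(read_id=read_id, has_5prime_ess=has5, has_3prime_ess=has3)


def ess_summary(calls: Sequence[ESSCall], library_id: str) -> ESSSummary:
    """Category fractions over a library's calls; fractions sum to 1."""
    if not calls:
        raise ValueError("cannot summarize an empty list of ESS calls")
    counts = Counter(call.category for call in calls)
    n = len(calls)
    fractions = {cat: counts.get(cat, 0) / n for cat in ESSCategory}
    return ESSSummary(library_id=library_id, n_reads=n, fractions=fractions)
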