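"""Read annotation against a mature small-RNA reference set.

Each read is assigned to its best-matching reference by an explicit ungapped
matcher that tolerates end-trimming (3'-truncation is a hallmark of some
protocols), a short unaligned 3' tail (non-templated additions), and a small
number of substitutions. Gapped alignment is unnecessary at miRNA scale and
would make tie-breaking harder to specify exactly.

Best match minimizes (mismatches, trimmed+added nucleotides) lexicographically;
remaining ties resolve by category priority miRNA > rRNA > mRNA > repeat >
other, then lexicographic ref_id, so annotation is a total, order-independent
function of the read and the reference set.
"""

from __future__ import annotations

import enum
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from smallrna_libbias.io_formats import ReferenceRecord, RefClass, SmallRNARead


class Category(str, enum.Enum):
    """Annotation category of a read (the library-quality breakdown)."""

    MIRNA = "miRNA"
    RRNA = "rRNA"
    MRNA = "mRNA"
    REPEAT = "repeat"
    NO_MATCH = "no_match"


_CLASS_TO_CATEGORY = {
    RefClass.MIRNA: Category.MIRNA,
    RefClass.RRNA: Category.RRNA,
    RefClass.MRNA: Category.MRNA,
    RefClass.REPEAT: Category.REPEAT,
    RefClass.OTHER: Category.NO_MATCH,
}

#: tie-break priority: smaller is better; miRNA assignment is primary
_CATEGORY_PRIORITY = {
    RefClass.MIRNA: 0,
    RefClass.RRNA: 1,
    RefClass.MRNA: 2,
    RefClass.REPEAT: 3,
    RefClass.OTHER: 4,
}


@dataclass(frozen=True)
class AnnotationResult:
    read_id: str
    library_id: str
    matched_ref: str | None
    category: Category
    offset5: int = 0
    offset3: int = 0
    n_mismatch: int = 0
    n_added3: int = 0

    def __post_init__(self) -> None:
        if (self.matched_ref is None) != (self.category == Category.NO_MATCH):
            raise ValueError("matched_ref is None exactly when category is no_match")


def strip_species_prefix(name: str) -> str:
    """Optional helper: "oar-miR-1" -> "miR-1". Family keys normally come
    from the reference table, not from parsing names."""
    return re.sub(r"^[a-z]{3,4}-", "", name)


def _align_read(
    read_seq: str,
    ref_seq: str,
    max_mismatch: int,
    max_trim: int,
    max_add3: int,
) -> tuple[int, int, int, int, int] | None:
    """Best ungapped placement of read within ref.

    Returns (n_mismatch, total_edit, offset5, offset3, n_added3) or None.
    The read's 5' start may sit ``offset5`` nt into the reference (5'-trimmed
    reference), its aligned 3' end ``offset3`` nt before the reference end,
    and up to ``max_add3`` read 3' nucleotides may hang unaligned past the
    reference (non-templated tail).
    """
    L, R = len(read_seq), len(ref_seq)
    best: tuple[int, int, int, int, int] | None = None
    for a3 in range(0, max_add3 + 1):
        aligned_len = L - a3
        if aligned_len <= 0:
            break
        for t5 in range(0, max_trim + 1):
            t3 = R - t5 - aligned_len
            if t3 < 0 or t3 > max_trim:
                continue
            mism = sum(
                1
                for x, y in zip(read_seq[:aligned_len], ref_seq[t5 : t5 + aligned_len])
                if x != y
            )
            if mism > max_mismatch:
                continue
            cand = (mism, t5 + t3 + a3, t5, t3, a3)
            if best is None or cand[:2] < best[:2]:
                best = cand
    return best


def annotate_read(
    read: SmallRNARead,
    refs: Sequence[ReferenceRecord],
    max_mismatch: int = 2,
    max_trim: int = 3,
    max_add3: int = 3,
    _cache: dict | None = None,
) -> AnnotationResult:
    """Assign a read to its best-matching reference record.

    Default tolerances (2 mismatches, 3 nt trimming per end, 3 nt unaligned
    3' tail) accept the 3'-truncations and non-templated additions that
    protocol bias introduces while keeping distinct miRNA families separable.
    ``_cache`` (keyed by read sequence) lets callers amortize annotation over
    libraries full of duplicate sequences.
    """
    if not refs:
        raise ValueError("reference list is empty")
    if min(max_mismatch, max_trim, max_add3) < 0:
        raise ValueError("tolerances must be >= 0")

    if _cache is not None and read.sequence in _cache:
        ref, aln = _cache[read.sequence]
        return _result(read, ref, aln)

    best_key: tuple | None = None
    best_ref: ReferenceRecord | None = None
    best_aln: tuple[int, int, int, int, int] | None = None
    for ref in refs:
        aln = _align_read(read.sequence, ref.sequence, max_mismatch, max_trim, max_add3)
        if aln is None:
            continue
        key = (aln[0], aln[1], _CATEGORY_PRIORITY[ref.ref_class], ref.ref_id)
        if best_key is None or key < best_key:
            best_key, best_ref, best_aln = key, ref, aln

    if _cache is not None:
        _cache[read.sequence] = (best_ref, best_aln)
    return _result(read, best_ref, best_aln)


def _result(
    read: SmallRNARead,
    ref: ReferenceRecord | None,
    aln: tuple[int, int, int, int, int] | None,
) -> AnnotationResult:
    if ref is None or aln is None:
        return AnnotationResult(
            read_id=read.read_id,
            library_id=read.library_id,
            matched_ref=None,
            category=Category.NO_MATCH,
        )
    mism, _, t5, t3, a3 = aln
    return AnnotationResult(
        read_id=read.read_id,
        library_id=read.library_id,
        matched_ref=ref.ref_id,
        category=_CLASS_TO_CATEGORY[ref.ref_class],
        offset5=t5,
        offset3=t3,
        n_mismatch=mism,
        n_added3=a3,
    )


def annotate_reads(
    reads: Sequence[SmallRNARead],
    refs: Sequence[ReferenceRecord],
    max_mismatch: int = 2,
    max_trim: int = 3,
    max_add3: int = 3,
) -> list[AnnotationResult]:
    """Annotate a read list with a shared per-sequence cache."""
    cache: dict = {}
    return [
        annotate_read(r, refs, max_mismatch, max_trim, max_add3, _cache=cache)
        for r in reads
    ]


def category_fractions(annos: Sequence[AnnotationResult]) -> dict[Category, float]:
    """Fraction of reads per annotation category; fractions sum to 1."""
    if not annos:
        raise ValueError("cannot compute category fractions of an empty annotation list")
    counts = Counter(a.category for a in annos)
    n = len(annos)
    return {cat: counts[cat] / n for cat in Category if counts[cat]}


@dataclass
class FamilyCountsTable:
    """Family x library matrix of miRNA read counts."""

    families: list[str]
    libraries: list[str]
    counts: np.ndarray  # shape (len(families), len(libraries)), int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.families), len(self.libraries)):
            raise ValueError("counts shape does not match families x libraries")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.families, columns=self.libraries)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyCountsTable":
        return cls(
            families=[str(f) for f in df.index],
            libraries=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=int),
        )

    def column(self, library_id: str) -> np.ndarray:
        if library_id not in self.libraries:
            raise KeyError(f"unknown library {library_id!r}")
        return self.counts[:, self.libraries.index(library_id)]

    def get(self, family: str, library_id: str) -> int:
        if family not in self.families:
            raise KeyError(f"unknown family {family!r}")
        return int(self.counts[self.families.index(family), self.libraries.index(library_id)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyCountsTable):
            return NotImplemented
        return (
            self.families == other.families
            and self.libraries == other.libraries
            and np.array_equal(self.counts, other.counts)
        )


def build_family_counts(
    annos: Sequence[AnnotationResult],
    refs: Sequence[ReferenceRecord],
    libraries: Sequence[str],
) -> FamilyCountsTable:
    """Tally miRNA-category reads per family per library.

    Families with zero counts across all libraries are excluded; families
    are ordered by total count (descending), then name, matching how
    abundance tables are usually presented.
    """
    ref_family = {r.ref_id: r.family for r in refs}
    tallies: dict[str, Counter] = defaultdict(Counter)
    for a in annos:
        if a.category != Category.MIRNA:
            continue
        if a.library_id not in libraries:
            raise ValueError(f"annotation references unknown library {a.library_id!r}")
        family = ref_family.get(a.matched_ref)
        if family is None:
            raise ValueError(f"matched_ref {a.matched_ref!r} missing from reference set")
        tallies[family][a.library_id] += 1
    families = sorted(
        tallies, key=lambda f: (-sum(tallies[f].values()), f)
    )
    counts = np.array(
        [[tallies[f].get(lib, 0) for lib in libraries] for f in families], dtype=int
    ).reshape(len(families), len(libraries))
    return FamilyCountsTable(families=families, libraries=list(libraries), counts=counts)
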