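"""Relative abundance, cross-platform correlation, and fold-difference statistics.

Sequencing abundance is the frequency of a family's read count among all
miRNA-annotated reads of a library. qRT-PCR abundance uses the 2^-ddCT
method against a reference miRNA (miR-16 by default). Between-sample fold
differences are log2 ratios of relative read frequencies (sequencing) or
-ddCT (qRT-PCR); the sign convention puts the first sample's excess positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from smallrna_libbias.annotation import FamilyCountsTable
from smallrna_libbias.io_formats import CTTable


@dataclass(frozen=True)
class RelativeAbundance:
    """Per-family fraction of miRNA-annotated reads in one library."""

    library_id: str
    fractions: Mapping[str, float]
    n_total: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance fractions sum to {total}, not 1")


@dataclass(frozen=True)
class QPCRQuant:
    """Relative quantification of one miRNA in one sample.

    ``delta_ct`` is mean CT(miRNA) - mean CT(reference) within the sample;
    ``relative_abundance`` is 2^(-delta_ct), exactly 1 for the reference.
    """

    sample_id: str
    mirna: str
    delta_ct: float
    relative_abundance: float


class UndetectableFoldDifference(ValueError):
    """A zero read count with pseudocount 0 makes the log ratio undefined."""


def relative_abundance(counts: FamilyCountsTable, library_id: str) -> RelativeAbundance:
    """Family read-count frequencies for one library."""
    col = counts.column(library_id)
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"library {library_id!r} has zero miRNA reads")
    return RelativeAbundance(
        library_id=library_id,
        fractions={f: int(c) / total for f, c in zip(counts.families, col)},
        n_total=total,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(
    tables: Mapping[str, Mapping[str, float]],
    families: Sequence[str],
    log_transform: bool = False,
    log_pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-family abundances across methods.

    ``tables`` maps a method/protocol label to its family -> abundance
    mapping; every listed family must be present in every method. By default
    correlations use untransformed abundances; ``log_transform`` applies
    log10(x + pseudocount) first for sensitivity analysis.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 methods to correlate")
    vectors: dict[str, np.ndarray] = {}
    for method, abund in tables.items():
        missing = [f for f in families if f not in abund]
        if missing:
            raise ValueError(f"method {method!r} missing families: {missing}")
        v = np.array([abund[f] for f in families], dtype=float)
        if log_transform:
            v = np.log10(v + log_pseudocount)
        vectors[method] = v
    methods = list(tables)
    mat = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            r = pearson(vectors[a], vectors[b])
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat


def families_in_all(
    counts: FamilyCountsTable, libraries: Sequence[str]
) -> list[str]:
    """Families observed (count > 0) in every one of the given libraries.

    This is the convention for restricting cross-protocol correlations to
    families detectable in all shallow cloning libraries.
    """
    keep = []
    for f in counts.families:
        row = counts.counts[counts.families.index(f)]
        idx = [counts.libraries.index(l) for l in libraries]
        if all(row[i] > 0 for i in idx):
            keep.append(f)
    return keep


def qpcr_quantify(
    ct: CTTable, reference_mirna: str = "miR-16"
) -> dict[str, dict[str, QPCRQuant]]:
    """2^-ddCT relative quantification, per sample.

    Replicate CTs are combined by arithmetic mean before differencing;
    delta CT is taken against the reference miRNA within each sample, so the
    reference's relative abundance is exactly 1.
    """
    ct.require_reference(reference_mirna)
    mean_ct = (
        ct.data.groupby(["sample_id", "mirna"])["ct"].mean().unstack("mirna")
    )
    out: dict[str, dict[str, QPCRQuant]] = {}
    for sample in mean_ct.index:
        ref_ct = mean_ct.loc[sample, reference_mirna]
        quants: dict[str, QPCRQuant] = {}
        for mirna in mean_ct.columns:
            value = mean_ct.loc[sample, mirna]
            if pd.isna(value):
                continue
            delta = float(value - ref_ct)
            quants[mirna] = QPCRQuant(
                sample_id=sample,
                mirna=mirna,
                delta_ct=delta,
                relative_abundance=2.0 ** (-delta),
            )
        out[sample] = quants
    return out


def _delta_ct(ct: CTTable, mirna: str, reference: str) -> float:
    for name in (mirna, reference):
        if name not in set(ct.data["mirna"]):
            raise ValueError(f"miRNA {name!r} missing from CT table")
    mean = ct.data.groupby("mirna")["ct"].mean()
    return float(mean[mirna] - mean[reference])


def fold_difference_qpcr(
    ct_a: CTTable, ct_b: CTTable, mirna: str, reference: str = "miR-16"
) -> float:
    """log2 fold difference of ``mirna`` between two samples by qRT-PCR.

    ddCT = delta_ct(sample A) - delta_ct(sample B); the log2 fold is -ddCT,
    so a positive value means the miRNA is more abundant in sample A.
    """
    ddct = _delta_ct(ct_a, mirna, reference) - _delta_ct(ct_b, mirna, reference)
    return -ddct


def fold_difference_seq(
    counts: FamilyCountsTable,
    lib_a: str,
    lib_b: str,
    family: str,
    pseudocount: float = 0.5,
) -> float:
    """log2 ratio of a family's relative read frequency between two libraries.

    With ``pseudocount`` 0 this is exactly log2((c_a/N_a)/(c_b/N_b)); a zero
    count then raises :class:`UndetectableFoldDifference`, mirroring how
    shallow libraries can fail to detect a miRNA at all. The default
    pseudocount 0.5 is added to every family count, with the library totals
    adjusted by 0.5 per family, keeping frequencies normalized.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c_a, c_b = counts.get(family, lib_a), counts.get(family, lib_b)
    n_a, n_b = int(counts.column(lib_a).sum()), int(counts.column(lib_b).sum())
    n_fam = len(counts.families)
    if pseudocount == 0 and (c_a == 0 or c_b == 0):
        raise UndetectableFoldDifference(
            f"family {family!r} has zero reads in "
            f"{lib_a if c_a == 0 else lib_b!r}; not detectable at this depth"
        )
    freq_a = (c_a + pseudocount) / (n_a + pseudocount * n_fam)
    freq_b = (c_b + pseudocount) / (n_b + pseudocount * n_fam)
    return math.log2(freq_a / freq_b)
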