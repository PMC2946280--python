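"""Length-distribution and positional sequence-variation statistics.

Length spread distinguishes protocols: direct-ligation preps enrich tightly
around the 22-nt mature length, while hybridization-based adapter ligation
admits a wider spread. Positional variation is summarized as a position
frequency matrix with information content in bits, after right-padding
variable 3' ends with N (5' ends left-aligned) — N marks a vacancy created
by alignment, not an observed base, so it is excluded from the entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from smallrna_libbias.io_formats import SmallRNARead

SYMBOLS = ("A", "C", "G", "U", "N")


@dataclass(frozen=True)
class LengthDistribution:
    """Read-length histogram normalized to fractions."""

    fractions: Mapping[int, float]
    n_reads: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length fractions sum to {total}, not 1")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position symbol counts and information content (bits).

    ``counts`` has one row per position and one column per symbol A,C,G,U,N;
    ``information`` holds 2 - H(p) bits per position, with H the Shannon
    entropy of the A,C,G,U frequencies after excluding N.
    """

    length: int
    counts: np.ndarray  # (length, 5) ints
    information: np.ndarray  # (length,) floats

    def __post_init__(self) -> None:
        if self.counts.shape != (self.length, len(SYMBOLS)):
            raise ValueError("counts must be (length, 5)")
        if (self.information < -1e-12).any() or (self.information > 2 + 1e-12).any():
            raise ValueError("information content must lie in [0, 2] bits")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(SYMBOLS))
        df.index.name = "position"
        df["IC"] = self.information
        return df


def length_distribution(reads: Sequence[SmallRNARead]) -> LengthDistribution:
    """Fraction of reads at each observed length."""
    if not reads:
        raise ValueError("cannot compute a length distribution of zero reads")
    lengths = np.array([len(r.sequence) for r in reads])
    values, counts = np.unique(lengths, return_counts=True)
    n = len(reads)
    return LengthDistribution(
        fractions={int(v): int(c) / n for v, c in zip(values, counts)}, n_reads=n
    )


def excess_kurtosis(dist: LengthDistribution) -> float:
    """Fisher excess kurtosis of the length variable under the distribution.

    Computed from the weighted population moments (m4/m2^2 - 3), not a
    read-level sample estimator, so the result is a deterministic function
    of the fractions. Flatter, more dispersed distributions give lower
    values; a Gaussian gives 0.
    """
    lengths = np.array(sorted(dist.fractions), dtype=float)
    weights = np.array([dist.fractions[int(l)] for l in lengths])
    mean = float(np.sum(weights * lengths))
    m2 = float(np.sum(weights * (lengths - mean) ** 2))
    if m2 == 0:
        raise ValueError("degenerate distribution: zero length variance")
    m4 = float(np.sum(weights * (lengths - mean) ** 4))
    return m4 / m2**2 - 3.0


def pad_3prime(sequences: Sequence[str], target_len: int) -> list[str]:
    """Right-pad sequences with N to ``target_len`` (5' ends left-aligned)."""
    out = []
    for seq in sequences:
        if len(seq) > target_len:
            raise ValueError(
                f"sequence of length {len(seq)} exceeds target length {target_len}"
            )
        out.append(seq + "N" * (target_len - len(seq)))
    return out


def position_matrix(
    sequences: Sequence[str], small_sample_correction: bool = False
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix with per-position information content.

    All sequences must already share one length (use :func:`pad_3prime`).
    IC(position) = 2 - H(p) bits over the A,C,G,U frequencies with N treated
    as missing data; an all-N position has IC 0 by convention. With
    ``small_sample_correction`` the e(n) = 3/(2 ln2 n) correction used by
    sequence-logo tools is subtracted (floored at 0).
    """
    if not sequences:
        raise ValueError("no sequences given")
    length = len(sequences[0])
    ragged = {len(s) for s in sequences}
    if ragged != {length}:
        raise ValueError(
            f"sequences have lengths {sorted(ragged)}; pad to a common length first"
        )
    sym_index = {s: k for k, s in enumerate(SYMBOLS)}
    counts = np.zeros((length, len(SYMBOLS)), dtype=int)
    for seq in sequences:
        for pos, ch in enumerate(seq):
            try:
                counts[pos, sym_index[ch]] += 1
            except KeyError:
                raise ValueError(f"invalid symbol {ch!r} at position {pos}") from None

    information = np.zeros(length)
    for pos in range(length):
        base_counts = counts[pos, :4].astype(float)
        n_obs = base_counts.sum()
        if n_obs == 0:
            continue  # all-N position: IC 0 by convention
        p = base_counts / n_obs
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        ic = 2.0 - entropy
        if small_sample_correction:
            ic -= 3.0 / (2.0 * np.log(2) * n_obs)
        information[pos] = max(ic, 0.0)
    return PositionFrequencyMatrix(length=length, counts=counts, information=information)
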