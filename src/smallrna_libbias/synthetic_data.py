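"""Protocol-biased small-RNA library simulator.

Generates reference sets and read libraries with the statistical structure
each library-construction protocol imprints on real data: insert-length
jitter around the mature length, 3'-end truncation, 5'-end substitution,
non-templated 3' additions, contamination by non-miRNA RNA, and — the
mechanism of interest — adapter-ligation success that depends on whether the
read's predicted structure leaves a terminal nucleotide base-paired (ESS).

The ESS-dependent acceptance step reuses the pipeline's own folding and
classification modules. That circularity is intentional and confined to the
simulator: it guarantees the simulator's notion of "3'-ESS read" is exactly
the one the analysis measures, so programmed ligation biases are recoverable.
Tests of the ESS rule itself always use hand-constructed sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from smallrna_libbias.ess import ESSCategory, classify_ess
from smallrna_libbias.folding import DEFAULT_PARAMS, FoldParams, fold_cached
from smallrna_libbias.io_formats import (
    Protocol,
    RefClass,
    ReferenceRecord,
    SmallRNARead,
    write_fasta,
)

BASES = ("A", "C", "G", "U")

#: attempts allowed per accepted read before the rejection sampler gives up
MAX_REJECTION_ATTEMPTS = 10**6


@dataclass(frozen=True)
class ProtocolBiasModel:
    """Bias parameters of one library-construction protocol.

    ``trunc3_probs`` gives the probability of losing 0-3 nt from the 3' end;
    ``ligation_success`` maps each ESS category to the probability that a
    molecule of that category acquires both adapters (rejected molecules are
    redrawn, mirroring sequencing to a target depth regardless of ligation
    efficiency). ``length_sd`` (nt) jitters the final insert length.
    """

    protocol: Protocol
    length_sd: float
    trunc3_probs: Mapping[int, float]
    var5_prob: float
    ligation_success: Mapping[ESSCategory, float]
    nta_prob: float
    depth: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        total = sum(self.trunc3_probs.get(d, 0.0) for d in range(4))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trunc3_probs must sum to 1 (got {total})")
        for name, p in [("var5_prob", self.var5_prob), ("nta_prob", self.nta_prob)]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for cat in ESSCategory:
            p = self.ligation_success.get(cat)
            if p is None or not 0 <= p <= 1:
                raise ValueError(f"ligation_success[{cat.value}] must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.value,
            "length_sd": self.length_sd,
            "trunc3_probs": {str(k): v for k, v in self.trunc3_probs.items()},
            "var5_prob": self.var5_prob,
            "ligation_success": {c.value: self.ligation_success[c] for c in ESSCategory},
            "nta_prob": self.nta_prob,
            "depth": self.depth,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolBiasModel":
        return cls(
            protocol=Protocol(d["protocol"]),
            length_sd=float(d["length_sd"]),
            trunc3_probs={int(k): float(v) for k, v in d["trunc3_probs"].items()},
            var5_prob=float(d["var5_prob"]),
            ligation_success={
                ESSCategory(k): float(v) for k, v in d["ligation_success"].items()
            },
            nta_prob=float(d["nta_prob"]),
            depth=int(d["depth"]),
            seed=int(d["seed"]),
        )


NEUTRAL_LIGATION: Mapping[ESSCategory, float] = {c: 1.0 for c in ESSCategory}
NO_TRUNCATION: Mapping[int, float] = {0: 1.0, 1: 0.0, 2: 0.0, 3: 0.0}


def neutral_model(protocol: Protocol, depth: int, seed: int = 0) -> ProtocolBiasModel:
    """A bias-free model: exact mature sequences, every molecule ligates."""
    return ProtocolBiasModel(
        protocol=protocol,
        length_sd=0.0,
        trunc3_probs=NO_TRUNCATION,
        var5_prob=0.0,
        ligation_success=NEUTRAL_LIGATION,
        nta_prob=0.0,
        depth=depth,
        seed=seed,
    )


@dataclass(frozen=True)
class AbundanceProfile:
    """True relative abundances of miRNA families plus contamination.

    ``families`` sums to 1 over the miRNA portion; the miRNA portion itself
    is 1 minus the contamination fractions (rRNA, mRNA, unmappable).
    """

    families: Mapping[str, float]
    contamination: Mapping[str, float] = field(
        default_factory=lambda: {"rRNA": 0.0, "mRNA": 0.0, "unmappable": 0.0}
    )

    def __post_init__(self) -> None:
        total = sum(self.families.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family abundances must sum to 1 (got {total})")
        for key, p in self.contamination.items():
            if key not in ("rRNA", "mRNA", "unmappable"):
                raise ValueError(f"unknown contamination key {key!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"contamination[{key}] must be in [0, 1]")
        if self.mirna_fraction < 0:
            raise ValueError("contamination fractions exceed 1")

    @property
    def mirna_fraction(self) -> float:
        return 1.0 - sum(self.contamination.values())


def zipf_profile(
    families: Sequence[str],
    exponent: float = 1.0,
    contamination: Mapping[str, float] | None = None,
) -> AbundanceProfile:
    """Rank-ordered power-law abundances: realistic few-dominant-families shape."""
    weights = np.array([1.0 / (i + 1) ** exponent for i in range(len(families))])
    weights /= weights.sum()
    return AbundanceProfile(
        families=dict(zip(families, weights)),
        contamination=dict(contamination or {"rRNA": 0.0, "mRNA": 0.0, "unmappable": 0.0}),
    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def make_reference_set(
    n_mirna: int,
    n_rrna: int = 0,
    n_mrna: int = 0,
    length_range: tuple[int, int] = (20, 24),
    seed: int = 0,
    min_distance: int = 5,
    max_retries: int = 200,
) -> list[ReferenceRecord]:
    """Generate an unambiguous synthetic reference set.

    Sequences are i.i.d. uniform over A,C,G,U; any two references of equal
    length are at Hamming distance >= ``min_distance`` (colliding draws are
    regenerated, with a bounded retry budget), so every simulated read has a
    unique best annotation.
    """
    lo, hi = length_range
    if not (15 <= lo <= hi <= 30):
        raise ValueError("miRNA length range must satisfy 15 <= lo <= hi <= 30")
    if min(n_mirna, n_rrna, n_mrna) < 0:
        raise ValueError("reference counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    sequences: list[str] = []

    def draw(length: int) -> str:
        for _ in range(max_retries):
            seq = _random_sequence(rng, length)
            if all(
                len(other) != len(seq) or _hamming(seq, other) >= min_distance
                for other in sequences
            ):
                return seq
        raise RuntimeError(
            f"could not place a length-{length} sequence at Hamming distance "
            f">= {min_distance} after {max_retries} retries; too many references "
            f"for this length range"
        )

    specs = (
        [(RefClass.MIRNA, "miR", i) for i in range(1, n_mirna + 1)]
        + [(RefClass.RRNA, "rRNA", i) for i in range(1, n_rrna + 1)]
        + [(RefClass.MRNA, "mRNA", i) for i in range(1, n_mrna + 1)]
    )
    for ref_class, stem, i in specs:
        length = int(rng.integers(lo, hi + 1))
        seq = draw(length)
        sequences.append(seq)
        family = f"{stem}-{i}"
        records.append(
            ReferenceRecord(
                ref_id=f"syn-{family}", family=family, ref_class=ref_class, sequence=seq
            )
        )
    return records


def _mutate_read(
    seq: str,
    model: ProtocolBiasModel,
    rng: np.random.Generator,
    trunc_cum: np.ndarray,
    min_len: int = 15,
    max_len: int = 35,
) -> str:
    """Apply 3'-truncation, 5'-substitution, non-templated addition, and jitter.

    ``trunc_cum`` is the cumulative distribution over truncation depths 0-3,
    precomputed once per library (inverse-CDF draws keep the per-read cost low).
    """
    d = int(np.searchsorted(trunc_cum, rng.random(), side="right"))
    if d and len(seq) - d >= min_len:
        seq = seq[:-d]
    if model.var5_prob and rng.random() < model.var5_prob:
        alternatives = [b for b in BASES if b != seq[0]]
        seq = alternatives[int(rng.integers(3))] + seq[1:]
    if model.nta_prob and rng.random() < model.nta_prob:
        seq = seq + BASES[int(rng.integers(4))]
    if model.length_sd > 0:
        delta = int(round(rng.normal(0.0, model.length_sd)))
        delta = max(min_len - len(seq), min(delta, max_len - len(seq)))
        if delta < 0:
            seq = seq[:delta]
        elif delta > 0:
            seq = seq + _random_sequence(rng, delta)
    return seq


def simulate_library(
    refs: Sequence[ReferenceRecord],
    profile: AbundanceProfile,
    model: ProtocolBiasModel,
    library_id: str | None = None,
    fold_params: FoldParams = DEFAULT_PARAMS,
    end_window: int = 2,
) -> list[SmallRNARead]:
    """Draw exactly ``model.depth`` accepted reads from a biased protocol.

    Each read: (1) a source molecule is drawn from the abundance profile
    (miRNA family or contaminant); (2) protocol mutations are applied;
    (3) the candidate is folded and its ESS category decides acceptance via
    ``ligation_success``; rejected candidates are redrawn, so the requested
    depth is exact. Deterministic given ``model.seed``.
    """
    if all(p == 0 for p in model.ligation_success.values()):
        raise ValueError("no read can ligate: all ligation probabilities are 0")
    by_family: dict[str, list[ReferenceRecord]] = {}
    for r in refs:
        if r.ref_class == RefClass.MIRNA:
            by_family.setdefault(r.family, []).append(r)
    missing = [f for f in profile.families if f not in by_family]
    if missing:
        raise ValueError(f"profile families absent from reference set: {missing}")
    rrna_refs = [r for r in refs if r.ref_class == RefClass.RRNA]
    mrna_refs = [r for r in refs if r.ref_class == RefClass.MRNA]
    for key, pool in (("rRNA", rrna_refs), ("mRNA", mrna_refs)):
        if profile.contamination.get(key, 0) > 0 and not pool:
            raise ValueError(f"{key} contamination requested but no {key} references")

    rng = np.random.default_rng(model.seed)
    # unmappable contaminants are drawn from a finite per-library pool:
    # degradation products do recur, and a bounded pool keeps folding cheap
    unmappable_pool: list[str] = []
    if profile.contamination.get("unmappable", 0) > 0:
        pool_size = min(2000, model.depth)
        unmappable_pool = [
            _random_sequence(rng, int(rng.integers(18, 27))) for _ in range(pool_size)
        ]
    family_names = list(profile.families)
    source_labels = family_names + ["__rRNA", "__mRNA", "__unmappable"]
    mirna_frac = profile.mirna_fraction
    source_probs = np.array(
        [profile.families[f] * mirna_frac for f in family_names]
        + [
            profile.contamination.get("rRNA", 0.0),
            profile.contamination.get("mRNA", 0.0),
            profile.contamination.get("unmappable", 0.0),
        ]
    )
    source_probs /= source_probs.sum()
    source_cum = np.cumsum(source_probs)
    trunc_cum = np.cumsum([model.trunc3_probs.get(d, 0.0) for d in range(4)])
    neutral_ligation = all(p == 1 for p in model.ligation_success.values())
    library_id = library_id or f"{model.protocol.value}_lib"

    reads: list[SmallRNARead] = []
    while len(reads) < model.depth:
        for _ in range(MAX_REJECTION_ATTEMPTS):
            label = source_labels[
                int(np.searchsorted(source_cum, rng.random(), side="right"))
            ]
            if label == "__unmappable":
                seq = unmappable_pool[int(rng.integers(len(unmappable_pool)))]
            elif label == "__rRNA":
                seq = rrna_refs[int(rng.integers(len(rrna_refs)))].sequence
            elif label == "__mRNA":
                seq = mrna_refs[int(rng.integers(len(mrna_refs)))].sequence
            else:
                pool = by_family[label]
                seq = pool[int(rng.integers(len(pool)))].sequence
            seq = _mutate_read(seq, model, rng, trunc_cum)
            if neutral_ligation:
                break
            call = classify_ess(fold_cached(seq, fold_params), end_window=end_window)
            if rng.random() < model.ligation_success[call.category]:
                break
        else:
            raise RuntimeError(
                f"rejection sampler exhausted {MAX_REJECTION_ATTEMPTS} attempts; "
                "ligation probabilities are too small"
            )
        flags = () if 15 <= len(seq) <= 35 else ("length_out_of_range",)
        reads.append(
            SmallRNARead(
                read_id=f"{library_id}_r{len(reads) + 1}",
                sequence=seq,
                library_id=library_id,
                protocol=model.protocol,
                flags=flags,
            )
        )
    return reads


def save_library(
    reads: Sequence[SmallRNARead], model: ProtocolBiasModel, fasta_path: str | Path
) -> None:
    """Write a simulated library as FASTA plus a JSON sidecar of its model."""
    fasta_path = Path(fasta_path)
    write_fasta(reads, fasta_path)
    sidecar = fasta_path.with_suffix(fasta_path.suffix + ".model.json")
    sidecar.write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def default_models(depth_cloning: int = 220, depth_sbs: int = 50_000, seed: int = 0) -> dict[Protocol, ProtocolBiasModel]:
    """Bias models encoding each protocol's reported signature.

    Orderings built in: length spread SOLiD > V1.5 > V1 (hybridization-based
    N6 adapter ligation admits a wider insert range); 3'-ESS ligation success
    SOLiD > V1.5 > V1, with V1 a hard zero (direct single-stranded T4 RNA
    ligase ligation fails on a base-paired 3' terminus, while V1.5's
    truncated Rnl2 tolerates it and SOLiD's pre-hybridization melts it);
    heavy 2-nt 3' truncation and 5' variation only in SOLiD. Cloning depth
    defaults to ~220 reads (Sanger-validation scale) and SBS depth to 50,000.
    """
    return {
        Protocol.SOLID_CLONING: ProtocolBiasModel(
            protocol=Protocol.SOLID_CLONING,
            length_sd=1.5,
            trunc3_probs={0: 0.25, 1: 0.10, 2: 0.60, 3: 0.05},
            var5_prob=0.08,
            ligation_success={
                ESSCategory.NON_ESS: 1.0,
                ESSCategory.ESS5_ONLY: 0.90,
                ESSCategory.ESS3_ONLY: 0.90,
                ESSCategory.BOTH: 0.85,
            },
            nta_prob=0.05,
            depth=depth_cloning,
            seed=seed,
        ),
        Protocol.ILLUMINA_V1_CLONING: ProtocolBiasModel(
            protocol=Protocol.ILLUMINA_V1_CLONING,
            length_sd=0.4,
            trunc3_probs={0: 0.90, 1: 0.08, 2: 0.02, 3: 0.0},
            var5_prob=0.005,
            ligation_success={
                ESSCategory.NON_ESS: 1.0,
                ESSCategory.ESS5_ONLY: 0.05,
                ESSCategory.ESS3_ONLY: 0.0,
                ESSCategory.BOTH: 0.0,
            },
            nta_prob=0.02,
            depth=depth_cloning,
            seed=seed,
        ),
        Protocol.ILLUMINA_V15_CLONING: ProtocolBiasModel(
            protocol=Protocol.ILLUMINA_V15_CLONING,
            length_sd=0.7,
            trunc3_probs={0: 0.75, 1: 0.15, 2: 0.08, 3: 0.02},
            var5_prob=0.005,
            ligation_success={
                ESSCategory.NON_ESS: 1.0,
                ESSCategory.ESS5_ONLY: 0.05,
                ESSCategory.ESS3_ONLY: 0.35,
                ESSCategory.BOTH: 0.05,
            },
            nta_prob=0.05,
            depth=depth_cloning,
            seed=seed,
        ),
        Protocol.ILLUMINA_GA: ProtocolBiasModel(
            protocol=Protocol.ILLUMINA_GA,
            length_sd=0.4,
            trunc3_probs={0: 0.90, 1: 0.08, 2: 0.02, 3: 0.0},
            var5_prob=0.005,
            ligation_success={
                ESSCategory.NON_ESS: 1.0,
                ESSCategory.ESS5_ONLY: 0.02,
                ESSCategory.ESS3_ONLY: 0.15,
                ESSCategory.BOTH: 0.02,
            },
            nta_prob=0.02,
            depth=depth_sbs,
            seed=seed,
        ),
    }
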