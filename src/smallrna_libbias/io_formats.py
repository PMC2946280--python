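"""External representations: FASTA read sets, reference/counts/CT tables, dot-bracket files.

The internal canonical alphabet is RNA (``U``); DNA input (``T``) is accepted
and normalized on read, because cloning data arrive as DNA sequence while
structure prediction operates on RNA.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")

#: Insert-length window of a typical small-RNA prep; reads outside are
#: flagged (never dropped) so the full length spread remains analyzable.
MIN_READ_LEN = 15
MAX_READ_LEN = 35


class Protocol(str, enum.Enum):
    """Library-construction protocol that produced a read."""

    SOLID_CLONING = "solid_cloning"
    ILLUMINA_V1_CLONING = "illumina_v1_cloning"
    ILLUMINA_V15_CLONING = "illumina_v15_cloning"
    ILLUMINA_GA = "illumina_ga"


class RefClass(str, enum.Enum):
    """Class of a reference sequence a read can map to."""

    MIRNA = "miRNA"
    RRNA = "rRNA"
    MRNA = "mRNA"
    REPEAT = "repeat"
    OTHER = "other"


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SmallRNARead:
    """One sequenced or cloned small-RNA read.

    ``flags`` records quality annotations such as ``length_out_of_range``;
    no read is ever silently discarded on input.
    """

    read_id: str
    sequence: str
    library_id: str
    protocol: Protocol
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)} "
                f"(alphabet is A,C,G,U,N; T is normalized on input)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceRecord:
    """A mature reference sequence with its class and family key."""

    ref_id: str
    family: str
    ref_class: RefClass
    sequence: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"reference {self.ref_id!r}: empty family")
        bad = set(self.sequence) - frozenset("ACGU")
        if bad:
            raise ValueError(
                f"reference {self.ref_id!r}: invalid characters {sorted(bad)}"
            )
        if len(self.sequence) < 15:
            raise ValueError(
                f"reference {self.ref_id!r}: sequence shorter than 15 nt"
            )


@dataclass
class CTTable:
    """qRT-PCR cycle-threshold measurements, long format.

    One row per (sample, miRNA, replicate); CT in PCR cycles, in (0, 45].
    """

    data: pd.DataFrame

    COLUMNS = ("sample_id", "mirna", "ct", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"CT table missing columns: {sorted(missing)}")
        cts = self.data["ct"].astype(float)
        if ((cts <= 0) | (cts > 45)).any():
            bad = self.data.loc[(cts <= 0) | (cts > 45), "mirna"].tolist()
            raise ValueError(f"CT values outside (0, 45] for: {bad}")
        if (self.data["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be >= 1")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.data["mirna"].unique())

    def require_reference(self, reference_mirna: str) -> None:
        """Check the normalizer miRNA is measured in every sample."""
        for sample in self.samples:
            sub = self.data[self.data["sample_id"] == sample]
            if reference_mirna not in set(sub["mirna"]):
                raise ValueError(
                    f"reference miRNA {reference_mirna!r} missing from sample {sample!r}"
                )


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def _length_flags(seq: str) -> tuple[str, ...]:
    if not (MIN_READ_LEN <= len(seq) <= MAX_READ_LEN):
        return ("length_out_of_range",)
    return ()


def read_fasta(path: str | Path, protocol: Protocol, library_id: str) -> list[SmallRNARead]:
    """Read a small-RNA FASTA file into :class:`SmallRNARead` records.

    T is normalized to U; record order is preserved. Reads outside the
    15-35 nt window are flagged ``length_out_of_range``, not dropped.
    Malformed input raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    protocol = Protocol(protocol)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(lines, 1) if ln.strip()), None
    )
    if first_content is None:
        logger.warning("FASTA file %s is empty; returning no reads", path)
        return []
    if not first_content[1].lstrip().startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_content[0]}: expected FASTA header starting with '>'"
        )
    reads: list[SmallRNARead] = []
    for n, record in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        seq = normalize_rna(str(record.seq))
        bad = set(seq) - RNA_ALPHABET
        if bad:
            # locate the first offending line for the error message
            for i, ln in enumerate(lines, 1):
                if not ln.startswith(">") and set(normalize_rna(ln.strip())) & bad:
                    raise FastaParseError(
                        f"{path}: line {i}: invalid sequence characters {sorted(bad)}"
                    )
            raise FastaParseError(
                f"{path}: record {n} ({record.id}): invalid characters {sorted(bad)}"
            )
        if not record.id:
            raise FastaParseError(f"{path}: record {n}: empty FASTA header")
        reads.append(
            SmallRNARead(
                read_id=record.id,
                sequence=seq,
                library_id=library_id,
                protocol=protocol,
                flags=_length_flags(seq),
            )
        )
    n_flagged = sum(1 for r in reads if r.flags)
    if n_flagged:
        logger.info(
            "%s: %d/%d reads outside %d-%d nt flagged length_out_of_range",
            path, n_flagged, len(reads), MIN_READ_LEN, MAX_READ_LEN,
        )
    return reads


def write_fasta(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    """Write reads as FASTA (RNA alphabet)."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_table(path: str | Path) -> list[ReferenceRecord]:
    """Read a TSV of reference sequences (columns ref_id, family, ref_class, sequence).

    Stands in for a mature-miRNA database download; the class column also
    admits rRNA/mRNA/repeat contaminant references.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ref_id", "family", "ref_class", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reference table missing columns {sorted(missing)}")
    dupes = df["ref_id"][df["ref_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate ref_ids: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        try:
            ref_class = RefClass(row.ref_class)
        except ValueError:
            raise ValueError(
                f"{path}: unknown class {row.ref_class!r} for {row.ref_id!r} "
                f"(expected one of {[c.value for c in RefClass]})"
            ) from None
        records.append(
            ReferenceRecord(
                ref_id=row.ref_id,
                family=row.family,
                ref_class=ref_class,
                sequence=normalize_rna(row.sequence),
            )
        )
    return records


def write_reference_table(refs: Sequence[ReferenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "ref_id": [r.ref_id for r in refs],
            "family": [r.family for r in refs],
            "ref_class": [r.ref_class.value for r in refs],
            "sequence": [r.sequence for r in refs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_counts_table(counts: "FamilyCountsTable", path: str | Path) -> None:
    """Serialize a family x library counts matrix as TSV (integer counts).

    Relative frequencies are always derived downstream, never stored.
    """
    df = counts.to_frame()
    df.to_csv(path, sep="\t", index=True, index_label="family")


def read_counts_table(path: str | Path) -> "FamilyCountsTable":
    """Read a family x library counts TSV; inverse of :func:`write_counts_table`."""
    from smallrna_libbias.annotation import FamilyCountsTable

    df = pd.read_csv(path, sep="\t", index_col="family")
    df.index = df.index.astype(str)
    return FamilyCountsTable.from_frame(df.astype(int))


def read_ct_table(path: str | Path) -> CTTable:
    """Read a long-format qRT-PCR CT TSV (sample_id, mirna, ct, replicate)."""
    df = pd.read_csv(path, sep="\t")
    df["ct"] = df["ct"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return CTTable(df)


def write_ct_table(table: CTTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_dotbracket(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write dot-bracket records as repeated ``>id / sequence / structure`` triplets."""
    with open(path, "w") as fh:
        for rec_id, seq, structure in records:
            fh.write(f">{rec_id}\n{seq}\n{structure}\n")


def read_dotbracket(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a dot-bracket file written by :func:`write_dotbracket`."""
    out: list[tuple[str, str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3 != 0:
        raise ValueError(f"{path}: expected id/sequence/structure triplets")
    for i in range(0, len(lines), 3):
        header, seq, structure = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {header!r}")
        if len(seq) != len(structure):
            raise ValueError(
                f"{path}: sequence/structure length mismatch for {header[1:]!r}"
            )
        out.append((header[1:], seq, structure))
    return out
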