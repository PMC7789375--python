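"""Reading, writing and normalisation of the formats pcirc touches.

Sequences are held as plain uppercase strings over the alphabet {A,C,G,T,N}:
RNA ``U`` is mapped to ``T`` and every other IUPAC ambiguity code to ``N``.
Junction coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "JunctionSpec",
    "FastaFormatError",
    "normalize_seq",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "load_genome",
    "read_junction_table",
    "write_junction_table",
    "write_feature_table",
    "read_feature_table",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_LABELS = {"positive", "negative"}


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


@dataclass
class SequenceRecord:
    """A candidate transcript: id, normalised sequence and optional class label."""

    id: str
    seq: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class JunctionSpec:
    """Genomic coordinates of the two splice sites of a candidate.

    ``site5``/``site3`` are the transcript's 5' and 3' splice sites as 0-based
    genomic positions.  For lncRNA-like negatives, which have no back-splice,
    the transcript's genomic start and end stand in as the two sites.
    """

    seq_id: str
    chrom: str
    site5: int
    site3: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.site5 < 0 or self.site3 < 0:
            raise ValueError(
                f"splice sites must be non-negative, got ({self.site5}, {self.site3})"
            )


def normalize_seq(seq: str) -> str:
    """Uppercase, U->T, and anything outside {A,C,G,T} -> N.  Idempotent."""
    s = seq.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _split_label(header_id: str) -> tuple[str, Optional[str]]:
    # lenient "id|label" convention: only strip a trailing field that is a label
    if "|" in header_id:
        stem, _, last = header_id.rpartition("|")
        if last.lower() in _LABELS:
            return stem, last.lower()
    return header_id, None


def read_fasta(path, label: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    A per-record label may come from an ``>id|positive`` header suffix; the
    ``label`` argument, if given, applies to every record and wins over the
    header convention.
    """
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FastaFormatError(f"{path}: not valid FASTA: {exc}") from exc
    if not raw:
        # SeqIO silently yields nothing for junk input; distinguish by peeking
        with open(path) as fh:
            head = fh.read(1024).strip()
        if head and not head.startswith(">"):
            raise FastaFormatError(
                f"{path}: line 1 does not start with '>' (not FASTA)"
            )
        raise FastaFormatError(f"{path}: empty FASTA file")
    records = []
    for entry in raw:
        rec_id, header_label = _split_label(entry.id)
        records.append(
            SequenceRecord(rec_id, str(entry.seq), label or header_label)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, with_labels: bool = False) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name = f"{rec.id}|{rec.label}" if with_labels and rec.label else rec.id
            fh.write(f">{name}\n{rec.seq}\n")


def load_genome(path) -> dict[str, str]:
    """Load a (small) genome FASTA as a chrom -> normalised sequence dict."""
    return {rec.id: rec.seq for rec in read_fasta(path)}


def read_junction_table(path) -> list[JunctionSpec]:
    """Parse a BED-like TSV of junctions: chrom, site5, site3, strand, seq_id.

    Coordinates are 0-based.  A header row is tolerated and skipped.
    """
    specs: list[JunctionSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(fields)}"
                )
            chrom, s5, s3, strand, seq_id = fields[:5]
            if lineno == 1 and strand not in {"+", "-"} and not (_is_int(s5) and _is_int(s3)):
                continue  # header row
            if not (_is_int(s5) and _is_int(s3)):
                raise ValueError(f"{path}:{lineno}: non-integer coordinate {s5!r}/{s3!r}")
            try:
                specs.append(JunctionSpec(seq_id, chrom, int(s5), int(s3), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return specs


def write_junction_table(specs: Iterable[JunctionSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsite5\tsite3\tstrand\tseq_id\n")
        for j in specs:
            fh.write(f"{j.chrom}\t{j.site5}\t{j.site3}\t{j.strand}\t{j.seq_id}\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def write_feature_table(
    records: Sequence[SequenceRecord],
    vectors: Sequence[Mapping[str, float]],
    path,
) -> pd.DataFrame:
    """Write one row per record: id, optional label, then named features.

    All vectors must share an identical ordered schema; the column order of
    the first vector is the order written.  Round-trips losslessly through
    :func:`read_feature_table` (values written with 17 significant digits).
    """
    if len(records) != len(vectors):
        raise ValueError(f"{len(records)} records but {len(vectors)} vectors")
    schema: list[str] = list(vectors[0].keys()) if vectors else []
    for i, vec in enumerate(vectors):
        if list(vec.keys()) != schema:
            raise ValueError(f"vector {i} ({records[i].id}) does not match the schema")
    data = {"id": [r.id for r in records]}
    if any(r.label is not None for r in records):
        data["label"] = [r.label if r.label is not None else "" for r in records]
    for name in schema:
        data[name] = [vec[name] for vec in vectors]
    df = pd.DataFrame(data)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"{path}: feature table has no 'id' column")
    return df
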