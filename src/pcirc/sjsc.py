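"""Splice-junction sequence coding (SJSC).

The genomic context of a back-splice junction carries the RBP-binding and
splice-signal information that distinguishes circRNAs.  For each of a
candidate's two splice sites we take the 50 bp upstream and 50 bp downstream
window ``[site-50, site+50)`` from the genome (transcript orientation: on the
'-' strand the slice is reverse-complemented) and encode it position by
position with the integer hash

    A -> 1,  T -> -1,  C -> 2,  G -> -2,  N -> 0

so that complementary bases map to negated codes.  Both encoded windows are
concatenated, site5 first: 2 * 100 = 200 integers per candidate at the
default flank of 50.  lncRNA-like negatives, which have no back-splice,
use their transcript's genomic start and end as the two sites.
"""

from __future__ import annotations

from typing import Dict, Mapping

import numpy as np

from .sequence_io import JunctionSpec, reverse_complement

__all__ = [
    "CODING_HASH",
    "DEFAULT_FLANK",
    "sjsc_feature_names",
    "extract_window",
    "encode_sjsc",
    "decode_sjsc",
    "sjsc_block",
    "sjsc_block_from_sequence",
]

CODING_HASH: Dict[str, int] = {"A": 1, "T": -1, "C": 2, "G": -2, "N": 0}
_DECODE = {v: k for k, v in CODING_HASH.items()}
DEFAULT_FLANK = 50


def sjsc_feature_names(flank: int = DEFAULT_FLANK) -> tuple[str, ...]:
    return tuple(f"sjsc_{i}" for i in range(4 * flank))


def extract_window(
    genome: Mapping[str, str], chrom: str, site: int, strand: str, flank: int = DEFAULT_FLANK
) -> str:
    """Genomic window ``[site-flank, site+flank)``, N-padded at contig ends.

    On '-', the reverse complement is returned so that the window reads in
    transcript orientation (upstream first).
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    contig = genome[chrom]
    start, end = site - flank, site + flank
    left_pad = max(0, -start)
    right_pad = max(0, end - len(contig))
    window = "N" * left_pad + contig[max(0, start) : min(len(contig), end)] + "N" * right_pad
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return window


def encode_sjsc(window: str) -> np.ndarray:
    """Positionwise integer coding of a window; length preserved."""
    try:
        return np.array([CODING_HASH[c] for c in window], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unexpected character {exc.args[0]!r} in window") from None


def decode_sjsc(codes) -> str:
    """Inverse of :func:`encode_sjsc` (exact on {A,C,G,T,N})."""
    return "".join(_DECODE[int(c)] for c in codes)


def sjsc_block(
    genome: Mapping[str, str], junction: JunctionSpec, flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """Concatenated codes of the site5 and site3 windows (site5 first)."""
    w5 = extract_window(genome, junction.chrom, junction.site5, junction.strand, flank)
    w3 = extract_window(genome, junction.chrom, junction.site3, junction.strand, flank)
    return np.concatenate([encode_sjsc(w5), encode_sjsc(w3)])


def sjsc_block_from_sequence(seq: str, flank: int = DEFAULT_FLANK) -> np.ndarray:
    """Degraded FASTA-only fallback when no genome/coordinates are available.

    The candidate's own first and last ``flank`` nt stand in for the two
    junction windows, N-padded to the full window length on the genomic side.
    Callers should flag outputs produced this way.
    """
    head = seq[:flank].ljust(flank, "N")
    tail = seq[-flank:].rjust(flank, "N") if seq else "N" * flank
    w5 = "N" * flank + head   # genomic upstream of the transcript start is unknown
    w3 = tail + "N" * flank   # genomic downstream of the transcript end is unknown
    return np.concatenate([encode_sjsc(w5), encode_sjsc(w3)])
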