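"""Open-reading-frame features.

circRNAs carry shorter ORFs covering less of the transcript than lncRNAs,
so the feature pair is {ORF-coverage*10, ORF-length} of the optimal (longest)
ORF.  ORFs are searched in all six frames (3 frames x 2 strands) as maximal
ATG..stop spans with the stop codon included; spans without a terminating
stop before the sequence end are not counted, and sequences are treated as
linear (no ORF wraps the circRNA junction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .sequence_io import reverse_complement

__all__ = ["OrfHit", "find_orfs", "optimal_orf", "orf_feature_block", "ORF_FEATURE_NAMES"]

ORF_FEATURE_NAMES: tuple[str, ...] = ("ORF_coverage_x10", "ORF_length")

_STOPS = {"TAA", "TAG", "TGA"}
_START = "ATG"


@dataclass(frozen=True)
class OrfHit:
    """A maximal ATG..stop span; coordinates are on the reported strand
    (for '-', on the reverse complement of the input)."""

    start: int  # 0-based, inclusive
    end: int    # exclusive; includes the stop codon
    strand: str
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(seq: str) -> List[OrfHit]:
    """All maximal ORFs in six frames.

    Within one frame, only the first ATG following the previous stop opens a
    span; internal ATGs inside a reported span are not reported separately.
    Codons containing N are neither starts nor stops.
    """
    hits: List[OrfHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            open_start: Optional[int] = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if open_start is None:
                    if codon == _START:
                        open_start = pos
                elif codon in _STOPS:
                    hits.append(OrfHit(open_start, pos + 3, strand, frame))
                    open_start = None
    return hits


def optimal_orf(hits: Sequence[OrfHit]) -> Optional[OrfHit]:
    """Longest hit; ties broken by smaller start, then '+' before '-'."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.length, h.start, h.strand != "+"))


def orf_feature_block(seq: str) -> Dict[str, float]:
    """Feature pair {ORF-coverage*10, ORF-length} of the optimal ORF.

    Coverage is ORF length over transcript length, scaled by 10 into [0, 10].
    No ORF -> (0.0, 0).
    """
    if not seq:
        raise ValueError("empty sequence")
    best = optimal_orf(find_orfs(seq))
    length = best.length if best is not None else 0
    return {
        "ORF_coverage_x10": 10.0 * length / len(seq),
        "ORF_length": float(length),
    }
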