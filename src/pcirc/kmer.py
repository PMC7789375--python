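"""k-mer composition features.

For each k in 1..4, every length-k word over {A,C,G,T} is counted over all
overlapping windows (stride 1) and scaled as

    f_i = (x_i * k) / L

where x_i is the window count and L the full sequence length.  Note that the
scaling is the word's base coverage, not a probability, so values can exceed
1 (e.g. AA in AAAA gives 3*2/4 = 1.5); random-forest classification is
insensitive to this.  GC content is appended as a 341st feature.

Windows containing N contribute to no k-mer; L stays the full length.
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Dict, Mapping

__all__ = [
    "KS",
    "KMER_FEATURE_NAMES",
    "kmer_names",
    "count_kmers",
    "kmer_frequency",
    "gc_content",
    "kmer_feature_block",
]

KS = (1, 2, 3, 4)
_ALPHABET = "ACGT"


def kmer_names(k: int) -> list[str]:
    """All 4**k words of length k, lexicographic."""
    return ["".join(p) for p in product(_ALPHABET, repeat=k)]


#: fixed 341-name schema: k ascending, lexicographic within k, GC content last
KMER_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"k{k}_{name}" for k in KS for name in kmer_names(k)
) + ("GC_content",)


def count_kmers(seq: str, k: int) -> Dict[str, int]:
    """Count all overlapping k-mers of ``seq``; windows with N are skipped."""
    counts = dict.fromkeys(kmer_names(k), 0)
    if k > len(seq):
        warnings.warn(
            f"k={k} exceeds sequence length {len(seq)}; all counts zero",
            stacklevel=2,
        )
        return counts
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if word in counts:  # excludes windows containing N
            counts[word] += 1
    return counts


def kmer_frequency(count: int, k: int, L: int) -> float:
    """Scale a k-mer count to its feature value count*k/L."""
    if L <= 0:
        raise ValueError(f"sequence length must be positive, got {L}")
    return count * k / L


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    acgt = sum(seq.count(b) for b in _ALPHABET)
    if acgt == 0:
        warnings.warn("sequence contains no unambiguous bases; GC content 0.0", stacklevel=2)
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def kmer_feature_block(seq: str) -> Dict[str, float]:
    """The 341-entry k-mer block in the fixed :data:`KMER_FEATURE_NAMES` order."""
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    block: Dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short sequences: absent k's are 0
        for k in KS:
            counts = count_kmers(seq, k)
            for name in kmer_names(k):
                block[f"k{k}_{name}"] = kmer_frequency(counts[name], k, L)
        block["GC_content"] = gc_content(seq)
    return block
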