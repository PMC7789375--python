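"""Brute-force reference implementations used to cross-check the package.

These deliberately favour clarity over speed and share no code with the
implementation paths they verify.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_kmer_counts(seq: str, k: int) -> dict:
    """Sliding-window enumeration; windows containing N count nothing."""
    counts = {"".join(p): 0 for p in product("ACGT", repeat=k)}
    for i in range(max(0, len(seq) - k + 1)):
        w = seq[i : i + k]
        if "N" not in w:
            counts[w] += 1
    return counts


def brute_kmer_block(seq: str) -> dict:
    block = {}
    L = len(seq)
    for k in (1, 2, 3, 4):
        for name, x in brute_kmer_counts(seq, k).items():
            block[f"k{k}_{name}"] = x * k / L
    acgt = sum(1 for c in seq if c in "ACGT")
    gc = sum(1 for c in seq if c in "GC")
    block["GC_content"] = gc / acgt if acgt else 0.0
    return block


def brute_orf_spans(seq: str) -> set:
    """Every maximal (start, end, strand, frame) ATG..stop span, six frames.

    For each in-frame stop, the opener is the earliest ATG after the previous
    stop in that frame; spans include the stop codon.  Coordinates are on the
    scanned strand.
    """
    spans = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codon_starts = range(frame, len(s) - 2, 3)
            starts = [i for i in codon_starts if s[i : i + 3] == "ATG"]
            stops = [i for i in codon_starts if s[i : i + 3] in _STOPS]
            for i in starts:
                nxt = [j for j in stops if j > i]
                if not nxt:
                    continue
                stop = min(nxt)
                prev_stops = [j for j in stops if j < i]
                floor = max(prev_stops) if prev_stops else -1
                first_atg = min(a for a in starts if floor < a <= i)
                if i == first_atg:
                    spans.add((i, stop + 3, strand, frame))
    return spans


def brute_orf_block(seq: str) -> tuple:
    spans = brute_orf_spans(seq)
    if not spans:
        return (0.0, 0)
    longest = max(e - s for s, e, _, _ in spans)
    return (10.0 * longest / len(seq), longest)


def brute_metrics(TP: int, TN: int, FP: int, FN: int) -> dict:
    n = TP + TN + FP + FN
    recall = TP / (TP + FN) if TP + FN else 0.0
    precision = TP / (TP + FP) if TP + FP else 0.0
    accuracy = (TP + TN) / n
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    d = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(d) if d else 0.0
    return {"recall": recall, "precision": precision, "accuracy": accuracy, "f1": f1, "mcc": mcc}


def brute_greedy_dedup(records, identity_fn, threshold: float):
    """All-pairs identity matrix first, then longest-first greedy clustering.

    Returns the set of kept record ids.
    """
    n = len(records)
    ident = {}
    for i in range(n):
        for j in range(i + 1, n):
            ident[(i, j)] = ident[(j, i)] = identity_fn(records[i], records[j])
    order = sorted(range(n), key=lambda i: (-records[i].length, i))
    kept = []
    for i in order:
        if all(ident[(i, j)] <= threshold for j in kept):
            kept.append(i)
    return {records[i].id for i in kept}


def brute_tukey_kept(lengths, whisker: float = 1.5) -> list:
    """Indices kept by the box-whisker fence, quartiles by linear interpolation."""
    q1 = np.percentile(np.asarray(lengths, dtype=float), 25)
    q3 = np.percentile(np.asarray(lengths, dtype=float), 75)
    iqr = q3 - q1
    lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
    return [i for i, L in enumerate(lengths) if lo <= L <= hi]


def random_seq(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
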