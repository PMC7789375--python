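"""Dataset preparation: redundancy removal, length-outlier filtering, splitting.

Positive (circRNA) and negative (lncRNA) sets are made non-redundant at a 95%
identity threshold — first across the two sets, then within each set keeping
the longest representative — and sequences with outlying lengths are dropped
by the Tukey box-whisker rule before a seeded train/test split.

Identity is computed from a semi-global alignment (end gaps free; match 1,
mismatch 0, internal gap -1) as identical columns over the length of the
shorter sequence (the CD-HIT convention): a sequence contained in a longer
near-duplicate scores ~1 and is removed in favour of the longer one, while
free end gaps keep unrelated sequences of very different lengths from being
force-aligned end to end.  At the scale this package targets (hundreds to a
few thousand candidates) the exact all-pairs computation is affordable and
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .sequence_io import SequenceRecord

__all__ = [
    "FilterReport",
    "pairwise_identity",
    "dedup_within",
    "dedup_across",
    "length_outlier_filter",
    "split_train_test",
]

DEFAULT_IDENTITY_THRESHOLD = 0.95
TUKEY_WHISKER = 1.5


@dataclass
class FilterReport:
    """Bookkeeping for a filtering stage (counts and removed ids)."""

    n_input: int
    n_kept: int
    removed_ids: List[str] = field(default_factory=list)
    stage: str = ""

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": len(self.removed_ids),
            "removed_ids": list(self.removed_ids),
        }


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0  # free end gaps: containment-aware
    aligner.end_deletion_score = 0
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Alignment identity in [0, 1]: matches / length of the shorter sequence."""
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    if a.seq == b.seq:
        return 1.0
    aln = _aligner().align(a.seq, b.seq)[0]
    return aln.counts().identities / min(a.length, b.length)


def dedup_within(
    records: Sequence[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> Tuple[List[SequenceRecord], FilterReport]:
    """Greedy redundancy removal within one set, keeping the longest.

    Records are visited in descending length (ties: input order); a record is
    dropped when its identity with any already-kept record exceeds
    ``threshold``.  Idempotent.  Output preserves input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(range(len(records)), key=lambda i: (-records[i].length, i))
    kept_idx: List[int] = []
    removed: List[str] = []
    for i in order:
        if any(pairwise_identity(records[i], records[j]) > threshold for j in kept_idx):
            removed.append(records[i].id)
        else:
            kept_idx.append(i)
    kept = [records[i] for i in sorted(kept_idx)]
    return kept, FilterReport(len(records), len(kept), removed, stage="dedup_within")


def dedup_across(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> Tuple[List[SequenceRecord], List[SequenceRecord], FilterReport]:
    """Remove every cross-set pair with identity above ``threshold`` from both sets."""
    drop_a: set[int] = set()
    drop_b: set[int] = set()
    for i, ra in enumerate(set_a):
        for j, rb in enumerate(set_b):
            if pairwise_identity(ra, rb) > threshold:
                drop_a.add(i)
                drop_b.add(j)
    kept_a = [r for i, r in enumerate(set_a) if i not in drop_a]
    kept_b = [r for j, r in enumerate(set_b) if j not in drop_b]
    removed = [set_a[i].id for i in sorted(drop_a)] + [set_b[j].id for j in sorted(drop_b)]
    report = FilterReport(len(set_a) + len(set_b), len(kept_a) + len(kept_b), removed, stage="dedup_across")
    return kept_a, kept_b, report


def length_outlier_filter(
    records: Sequence[SequenceRecord],
    whisker: float = TUKEY_WHISKER,
) -> Tuple[List[SequenceRecord], FilterReport]:
    """Drop records with length outside the Tukey fences.

    Fences are ``[Q1 - whisker*IQR, Q3 + whisker*IQR]`` with quartiles by
    linear interpolation.  Fewer than 4 records pass through unchanged.
    """
    if len(records) < 4:
        warnings.warn("fewer than 4 records; length filter is a pass-through", stacklevel=2)
        return list(records), FilterReport(len(records), len(records), [], stage="length_filter")
    lengths = np.array([r.length for r in records], dtype=float)
    q1, q3 = np.percentile(lengths, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
    kept = [r for r in records if lo <= r.length <= hi]
    removed = [r.id for r in records if not (lo <= r.length <= hi)]
    return kept, FilterReport(len(records), len(kept), removed, stage="length_filter")


def split_train_test(
    pos: Sequence[SequenceRecord],
    neg: Sequence[SequenceRecord],
    n_per_class: int,
    seed: int,
) -> Tuple[List[SequenceRecord], List[SequenceRecord]]:
    """Seeded per-class sample without replacement for training; rest is test.

    Returns ``(train, test)``, each mixing both classes; the two are disjoint.
    """
    if len(pos) < n_per_class or len(neg) < n_per_class:
        raise ValueError(
            f"need {n_per_class} per class, have {len(pos)} positives / {len(neg)} negatives"
        )
    rng = np.random.default_rng(seed)
    train: List[SequenceRecord] = []
    test: List[SequenceRecord] = []
    for pool in (pos, neg):
        chosen = set(rng.choice(len(pool), size=n_per_class, replace=False).tolist())
        train.extend(pool[i] for i in range(len(pool)) if i in chosen)
        test.extend(pool[i] for i in range(len(pool)) if i not in chosen)
    return train, test
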