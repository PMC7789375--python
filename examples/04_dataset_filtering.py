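"""Redundancy and length filtering of a candidate set.

Plants near-duplicate sequences and gross length outliers, then runs the
cross-set and within-set 95%-identity dedup (keeping the longest
representative) and the Tukey box-whisker length filter.
"""

import numpy as np

from pcirc import (
    SequenceRecord,
    dedup_across,
    dedup_within,
    length_outlier_filter,
    split_train_test,
)

rng = np.random.default_rng(3)
bases = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(10)]

pos = [SequenceRecord(f"circ{i}", b, "positive") for i, b in enumerate(bases)]
pos.append(SequenceRecord("circ_dup", bases[0][:250], "positive"))      # contained duplicate
pos.append(SequenceRecord("circ_huge", "ACGT" * 2500, "positive"))      # length outlier
neg = [SequenceRecord(f"lnc{i}", "".join(rng.choice(list("ACGT"), size=300)), "negative")
       for i in range(10)]
neg.append(SequenceRecord("lnc_shared", bases[1], "negative"))          # cross-set duplicate

pos, neg, cross = dedup_across(pos, neg)
print("cross-set dedup removed:", cross.removed_ids)

pos, within = dedup_within(pos)
print("within-set dedup removed:", within.removed_ids, "(kept the longest of each pair)")

pos, lengths = length_outlier_filter(pos)
print("length filter removed:", lengths.removed_ids)

train, test = split_train_test(pos, neg, n_per_class=6, seed=0)
print(f"train={len(train)} test={len(test)} (disjoint, 6 per class in train)")
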