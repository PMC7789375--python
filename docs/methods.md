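# Methods

## Model

`pcirc` treats plant circRNA identification as supervised binary
classification of candidate transcript sequences: positives are circRNA
candidates, negatives lncRNA-like sequences. Each candidate is mapped to a
fixed 543-dimensional vector (341 k-mer + 2 ORF + 200 SJSC features) and
classified by a 100-tree random forest; class probability ≥ 0.5 calls
circRNA. The forest's insensitivity to feature scaling is relied on in two
places: the k-mer scaling below is not a probability, and the SJSC codes
are small signed integers.

### k-mer block

All 4+16+64+256 = 340 words for k = 1..4 are counted over overlapping
windows (stride 1) and scaled as f = x·k/L with L the full sequence
length. This scaling is the word's base coverage and can exceed 1 (AA in
AAAA gives 1.5); it is kept as-is rather than renormalised, since only
relative order matters to tree splits. For N-free sequences the k-block
sums to k(L−k+1)/L, which the tests assert to 1e−9. Windows containing N
count toward no word while L stays the full length — N's depress the block
sum rather than redistributing mass. Counting is forward-strand only.
GC content, computed over unambiguous bases only, is the 341st feature.
Feature order is fixed (k ascending, lexicographic within k, GC last) so
that persisted models have a stable schema. k stops at 4 because the
feature count grows as 4^k while per-word counts in 250–500 nt transcripts
become too sparse to be informative beyond that.

### ORF block

ORFs are maximal ATG…stop spans in all six frames (three frames on each
strand), stop codon included, codons containing N treated as neither start
nor stop. Two deliberate restrictions: spans with no in-frame stop before
the sequence end are not ORFs (determinism on truncated transcripts), and
sequences are linear — no ORF wraps the back-splice junction, since
wrap-around reading is not modelled here. The optimal ORF is the longest,
ties broken by smaller start then '+' strand before '−'. The feature pair
is {10·length/L, length}: coverage is scaled ×10 into [0, 10] to sit on a
comparable magnitude to the length feature's tree-split granularity.

### SJSC block

For each of the candidate's two splice sites the genomic window
[site − 50, site + 50) is taken (coordinates 0-based half-open, BED
convention; whether the site base itself falls up- or downstream of the
cut is a convention, and this one is documented rather than claimed
canonical). On the '−' strand the slice is reverse-complemented so windows
read in transcript orientation, making donor/acceptor context
strand-invariant. Positions beyond contig ends pad with N. Each window is
encoded positionwise with {A: 1, T: −1, C: 2, G: −2}; N → 0 is the unique
extension preserving the complement symmetry code(rc(w)) =
−reverse(code(w)), which the tests assert exactly. Both windows are
concatenated site5-first: 200 integers. The per-site window of 100
positions is configurable via `flank`. lncRNAs have no back-splice, so
their transcript's genomic start and end serve as the two sites; in
FASTA-only mode (no genome/junctions) the candidate's own first/last 50 nt
stand in, padded with N on the genomic side, and the feature table is
flagged `sjsc_mode="fasta_fallback"` — degraded but runnable.

## Dataset preparation

Redundancy removal runs cross-set first (any cross pair with identity
> 0.95 removes both members), then within-set greedily in descending
length order, dropping a record whose identity with an already-kept record
exceeds 0.95 — the longest representative of each near-duplicate cluster
survives. The threshold is strict (>), and the procedure is idempotent.

Identity is matches / length-of-shorter from a semi-global alignment
(end gaps free; match 1, mismatch 0, internal gap −1), computed exactly
with Biopython's PairwiseAligner. Free end gaps make the measure
containment-aware — a sequence contained in a longer near-duplicate scores
~1, which is what "keep the longest" needs — while keeping unrelated pairs
of very different lengths near the ~0.5 random baseline. A strict global
alignment with this match/mismatch scoring was rejected: its total gap
budget is fixed by the length difference, so internal gap "threading"
becomes free relative to end gaps and an unrelated short sequence can
reach ~100% identity against a long one. The all-pairs exact computation
is O(n²) alignments and is the intended regime (≤ a few thousand
candidates); callers with larger corpora can pre-filter with a dedicated
clustering tool and feed the survivors in.

Length outliers are removed by the Tukey box-whisker rule: keep lengths in
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear interpolation
(`numpy.percentile` default). The 1.5 multiplier is the standard whisker
constant. Fewer than 4 records pass through with a warning. The train/test
split samples n records per class without replacement under a seed; the
remainder forms a disjoint test set.

## Training and evaluation

Hyperparameters are fixed: RF `n_estimators=100`; KNN `n_neighbors=7,
weights='uniform', p=2`; GNB defaults; SVM `C=10, gamma=0.001,
kernel='rbf'` (probability estimates enabled so all four algorithms expose
a score). Everything else stays at scikit-learn defaults. Evaluation is
stratified ten-fold CV repeated ten times under one master seed
(`RepeatedStratifiedKFold`); per-fold confusion counts give Recall,
Precision, Accuracy, F1, MCC, fold metrics are averaged within each repeat
and then across repeats. Metrics with empty denominators are 0, including
MCC with any zero factor (the formula is undefined there; 0 is the
conventional neutral value). ROC and PR curves come from threshold sweeps
over the class-probability scores. The feature-combination grid evaluates
all 2³−1 block subsets per algorithm with the same protocol. Fold metrics
are averaged rather than pooling predictions across folds; with balanced
folds the two differ negligibly, and per-fold averaging matches the
repeated-CV reporting convention used throughout.

Model bundles persist the fitted estimator, the ordered feature schema,
hyperparameters and training metadata (seed, date, dataset hash) via
joblib with a format tag; loading verifies the tag and prediction checks
the incoming schema, reporting missing/extra columns.

## Synthetic fixtures

The generator emulates a curated circRNA/lncRNA corpus at desk scale.
Background sequence is i.i.d. with class GC composition 0.5 ∓ gc_shift/2
(positives AT-shifted). Defaults: 400 records per class, lengths uniform
in 250–500 nt (above the >200 nt regime of both classes, and long enough
for ±50 bp windows), `gc_shift=0.04` (a subtle composition bias),
`noise=0` (a noise fraction regenerates a record with the other class's
signal while keeping its label). Class ORF structure: positives are
rejection-free — any ORF longer than `pos_orf_max=30` nt is truncated by
an in-frame TAA planted at a random interior codon, iterating because a
stop planted on one strand can uncover an ORF on the other; negatives get
an embedded ATG + non-stop codons + stop span of ≥ `neg_orf_min=150` nt,
guaranteeing an optimal ORF at least that long. Every transcript occupies
a locus on a toy chromosome separated by 60 nt random spacers; positives
have the acceptor/donor motif pair (default AG/GT) planted in the genome
immediately outside the transcript — at offsets 48–49 of the site5 window
and 50–51 of the site3 window — so junction signal lives only in the SJSC
family while the transcript sequence itself is untouched. The null
generator produces the same records and then permutes labels under a
derived seed, preserving class sizes while breaking every
content–label association. All output is a deterministic function of the
seed.

What the fixtures do not emulate: intron/exon structure, repeats and
transposons, real splice-site position weight matrices, length–class
correlations, or sequencing artefacts. Passing tests therefore demonstrate
correctness of the feature extraction, protocol and machinery, and
recoverability of planted signal — not field accuracy on real plant data,
which depends on curated positive/negative corpora.

## Verification problem sizes

The test suite checks formulas against brute-force oracles (500 randomized
cases per family), the SJSC symmetry on 1000 windows, null calibration via
repeated ten-fold RF CV on a 400-record label-permuted set (accuracy
within 3 binomial standard errors of 0.5, i.e. ±0.075), signal recovery on
the 800-record default fixture (repeated ten-fold CV, accuracy ≥ 0.95;
observed ≈ 0.999), and the ORF-only grid ranking with 2 repeats per
combination — sizes chosen to keep the full suite and the acceptance
script each within a few minutes on one CPU while leaving the statistical
bands comfortably resolvable.

## Known limitations

- The classifier is only as transferable as its training corpus; the
  package ships no pretrained model.
- Back-splice junction discovery from chimeric reads is upstream and out
  of scope; junction coordinates must be supplied (or the degraded
  FASTA-only fallback accepted).
- The O(n²) exact dedup is not meant for tens of thousands of sequences.
- SVM probability calibration uses internal cross-validation
  (`SVC(probability=True)`), which is slower and slightly seed-sensitive;
  RF is the algorithm of record.
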