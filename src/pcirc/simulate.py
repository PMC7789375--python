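"""Synthetic circRNA-like / lncRNA-like datasets with planted, tunable signal.

The generator emulates the structure of a curated circRNA (positive) versus
lncRNA (negative) training corpus without any download: i.i.d. background
nucleotides with a class-specific GC composition, a class-separated optimal
ORF (positives carry only short ORFs, negatives a long embedded one), and a
toy genome in which every transcript occupies a locus so that splice-junction
windows can be extracted.  Positives get an AG acceptor dinucleotide planted
immediately upstream of the 5' splice site and a GT donor immediately
downstream of the 3' site; negatives use their transcript boundaries as
"sites" with no planted motif.

With a flank of 50, the planted acceptor sits at offsets 48-49 of the site5
window and the donor at offsets 50-51 of the site3 window.

Everything is a deterministic function of ``FixtureConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .orf import find_orfs, optimal_orf
from .sequence_io import (
    JunctionSpec,
    SequenceRecord,
    write_fasta,
    write_junction_table,
)

__all__ = ["FixtureConfig", "SyntheticDataset", "generate_dataset", "generate_null_dataset"]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SPACER = 60  # random background between loci on the toy genome
_CHROM = "chr1"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    ``gc_shift`` is the GC-composition offset between classes (positives at
    0.5 - shift/2, negatives at 0.5 + shift/2); ``noise`` is the fraction of
    records generated with the other class's signal while keeping their
    label.  ``junction_motif`` is the (acceptor, donor) pair planted at
    positive splice sites, or None for no junction signal.
    """

    n_pos: int = 400
    n_neg: int = 400
    length_range: Tuple[int, int] = (250, 500)
    pos_orf_max: int = 30
    neg_orf_min: int = 150
    gc_shift: float = 0.04
    junction_motif: Optional[Tuple[str, str]] = ("AG", "GT")
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo <= 200:
            raise ValueError("minimum length must exceed 200 nt so +/-50 bp windows fit")
        if lo > hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.pos_orf_max < 9:
            raise ValueError("pos_orf_max below 9 nt cannot be enforced")
        if not 6 <= self.neg_orf_min <= lo:
            raise ValueError("neg_orf_min must be between 6 and the minimum length")
        if not 0 <= self.gc_shift < 1:
            raise ValueError("gc_shift must be in [0, 1)")
        if self.junction_motif is not None and any(
            not m or set(m) - set("ACGT") for m in self.junction_motif
        ):
            raise ValueError("junction_motif parts must be non-empty ACGT strings")


@dataclass
class SyntheticDataset:
    records: List[SequenceRecord]
    genome: dict
    junctions: List[JunctionSpec]
    truth: pd.DataFrame
    config: FixtureConfig

    @property
    def pos_records(self) -> List[SequenceRecord]:
        return [r for r in self.records if r.label == "positive"]

    @property
    def neg_records(self) -> List[SequenceRecord]:
        return [r for r in self.records if r.label == "negative"]

    def write(self, outdir) -> None:
        """pos.fa / neg.fa / genome.fa / junctions.tsv / truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.pos_records, outdir / "pos.fa", with_labels=True)
        write_fasta(self.neg_records, outdir / "neg.fa", with_labels=True)
        genome_records = [SequenceRecord(name, seq) for name, seq in self.genome.items()]
        write_fasta(genome_records, outdir / "genome.fa")
        write_junction_table(self.junctions, outdir / "junctions.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _random_codon(rng: np.random.Generator, gc: float, allow_stop: bool = False) -> str:
    while True:
        codon = _random_seq(rng, 3, gc)
        if allow_stop or codon not in _STOPS:
            return codon


def _disrupt_long_orfs(
    seq: str, max_len: int, rng: np.random.Generator, limit: int = 2000
) -> str:
    """Truncate every ORF longer than ``max_len`` by an in-frame TAA stop.

    The codon to overwrite is drawn at random from the ORF interior: a stop
    planted on one strand can uncover an ORF on the other, and a fixed choice
    can cycle between the two.
    """
    for _ in range(limit):
        best = optimal_orf(find_orfs(seq))
        if best is None or best.length <= max_len:
            return seq
        codon = int(rng.integers(1, best.length // 3 - 1))  # interior, in-frame
        pos = best.start + 3 * codon
        if best.strand == "+":
            seq = seq[:pos] + "TAA" + seq[pos + 3 :]
        else:
            # hit coordinates live on the reverse complement
            end = len(seq) - pos
            seq = seq[: end - 3] + "TTA" + seq[end:]
    raise RuntimeError("ORF disruption did not converge")  # pragma: no cover


def _make_positive_seq(rng: np.random.Generator, length: int, gc: float, orf_max: int) -> str:
    return _disrupt_long_orfs(_random_seq(rng, length, gc), orf_max, rng)


def _make_negative_seq(
    rng: np.random.Generator, length: int, gc: float, orf_min: int
) -> str:
    seq = _random_seq(rng, length, gc)
    min_codons = -(-orf_min // 3)  # ceil; includes start+stop codons
    max_codons = min(length // 3, min_codons + 40)
    n_codons = int(rng.integers(min_codons, max_codons + 1))
    body = "ATG" + "".join(_random_codon(rng, gc) for _ in range(n_codons - 2))
    orf = body + rng.choice(["TAA", "TAG", "TGA"])
    start = int(rng.integers(0, length - len(orf) + 1))
    return seq[:start] + orf + seq[start + len(orf) :]


def generate_dataset(config: FixtureConfig = FixtureConfig()) -> SyntheticDataset:
    """Generate records, toy genome, junction table and truth table.

    Fully determined by ``config.seed``; running twice gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    pos_gc = 0.5 - config.gc_shift / 2
    neg_gc = 0.5 + config.gc_shift / 2

    labels = ["positive"] * config.n_pos + ["negative"] * config.n_neg
    records: List[SequenceRecord] = []
    generator_class: List[str] = []
    for i, label in enumerate(labels):
        flipped = config.noise > 0 and rng.random() < config.noise
        gen = ("negative" if label == "positive" else "positive") if flipped else label
        length = int(rng.integers(lo, hi + 1))
        if gen == "positive":
            seq = _make_positive_seq(rng, length, pos_gc, config.pos_orf_max)
        else:
            seq = _make_negative_seq(rng, length, neg_gc, config.neg_orf_min)
        records.append(SequenceRecord(f"seq_{i:05d}", seq, label))
        generator_class.append(gen)

    # lay every transcript on one toy chromosome with random spacers
    chunks: List[str] = []
    junctions: List[JunctionSpec] = []
    loci: List[Tuple[int, int]] = []
    cursor = 0
    for rec, gen in zip(records, generator_class):
        spacer = _random_seq(rng, _SPACER, 0.5)
        if gen == "positive" and config.junction_motif is not None:
            acceptor, donor = config.junction_motif
            spacer = spacer[: -len(acceptor)] + acceptor  # ends right before site5
            chunks.append(spacer)
            cursor += _SPACER
            start, end = cursor, cursor + rec.length
            chunks.append(rec.seq)
            cursor = end
            tail = _random_seq(rng, _SPACER, 0.5)
            chunks.append(donor + tail[len(donor) :])
            cursor += _SPACER
        else:
            chunks.append(spacer)
            cursor += _SPACER
            start, end = cursor, cursor + rec.length
            chunks.append(rec.seq)
            cursor = end
            chunks.append(_random_seq(rng, _SPACER, 0.5))
            cursor += _SPACER
        junctions.append(JunctionSpec(rec.id, _CHROM, start, end, "+"))
        loci.append((start, end))

    genome = {_CHROM: "".join(chunks)}
    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "label": [r.label for r in records],
            "generator_class": generator_class,
            "length": [r.length for r in records],
            "chrom": _CHROM,
            "start": [s for s, _ in loci],
            "end": [e for _, e in loci],
            "strand": "+",
        }
    )
    return SyntheticDataset(records, genome, junctions, truth, config)


def generate_null_dataset(config: FixtureConfig = FixtureConfig()) -> SyntheticDataset:
    """Same generator, but labels permuted independently of all signal.

    Class sizes are preserved; every association between a record's content
    and its label is broken, so any classifier's expected accuracy is 0.5.
    """
    ds = generate_dataset(replace(config, noise=0.0))
    rng = np.random.default_rng(
        int(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0]) % (2**31)
    )
    permuted = [ds.records[i].label for i in rng.permutation(len(ds.records))]
    records = [
        SequenceRecord(r.id, r.seq, lab) for r, lab in zip(ds.records, permuted)
    ]
    truth = ds.truth.copy()
    truth["label"] = permuted
    return SyntheticDataset(records, ds.genome, ds.junctions, truth, ds.config)
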