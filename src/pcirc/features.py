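"""Assembly of per-record feature vectors from the three feature families.

The full default schema, in fixed order, is

    341 k-mer features (k1_A .. k4_TTTT, GC_content)
  +   2 ORF features   (ORF_coverage_x10, ORF_length)
  + 200 SJSC codes     (sjsc_0 .. sjsc_199; 100 per splice site at flank 50)

Any subset of the three blocks can be requested, e.g. for feature-combination
experiments.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .kmer import KMER_FEATURE_NAMES, kmer_feature_block
from .orf import ORF_FEATURE_NAMES, orf_feature_block
from .sequence_io import JunctionSpec, SequenceRecord
from .sjsc import DEFAULT_FLANK, sjsc_block, sjsc_block_from_sequence, sjsc_feature_names

__all__ = ["BLOCKS", "feature_names", "block_columns", "build_feature_table"]

BLOCKS = ("kmer", "orf", "sjsc")


def feature_names(
    blocks: Sequence[str] = BLOCKS, flank: int = DEFAULT_FLANK
) -> list[str]:
    """Ordered column names for the requested feature blocks."""
    names: list[str] = []
    for block in blocks:
        if block == "kmer":
            names.extend(KMER_FEATURE_NAMES)
        elif block == "orf":
            names.extend(ORF_FEATURE_NAMES)
        elif block == "sjsc":
            names.extend(sjsc_feature_names(flank))
        else:
            raise ValueError(f"unknown feature block {block!r}; expected subset of {BLOCKS}")
    return names


def block_columns(columns: Iterable[str], block: str) -> list[str]:
    """The subset of ``columns`` belonging to one named block."""
    cols = list(columns)
    if block == "kmer":
        return [c for c in cols if c in set(KMER_FEATURE_NAMES)]
    if block == "orf":
        return [c for c in cols if c in set(ORF_FEATURE_NAMES)]
    if block == "sjsc":
        return [c for c in cols if c.startswith("sjsc_")]
    raise ValueError(f"unknown feature block {block!r}")


def build_feature_table(
    records: Sequence[SequenceRecord],
    genome: Optional[Mapping[str, str]] = None,
    junctions: Optional[Sequence[JunctionSpec]] = None,
    blocks: Sequence[str] = BLOCKS,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Feature matrix with one row per record, indexed by record id.

    A ``label`` column is included when any record carries one.  When the
    ``sjsc`` block is requested with a genome and junction table, windows are
    extracted from the genome; without them the degraded FASTA-only fallback
    (:func:`pcirc.sjsc.sjsc_block_from_sequence`) is used and the resulting
    frame carries ``df.attrs["sjsc_mode"] = "fasta_fallback"``.
    """
    if not blocks:
        raise ValueError("at least one feature block must be requested")
    junc_by_id: Dict[str, JunctionSpec] = {}
    sjsc_mode = "genome"
    if "sjsc" in blocks:
        if genome is not None and junctions is not None:
            junc_by_id = {j.seq_id: j for j in junctions}
            missing = [r.id for r in records if r.id not in junc_by_id]
            if missing:
                raise ValueError(f"no junction for record(s): {missing[:5]}")
        else:
            sjsc_mode = "fasta_fallback"

    rows = []
    for rec in records:
        row: Dict[str, float] = {}
        for block in blocks:
            if block == "kmer":
                row.update(kmer_feature_block(rec.seq))
            elif block == "orf":
                row.update(orf_feature_block(rec.seq))
            elif block == "sjsc":
                if sjsc_mode == "genome":
                    codes = sjsc_block(genome, junc_by_id[rec.id], flank)
                else:
                    codes = sjsc_block_from_sequence(rec.seq, flank)
                row.update(zip(sjsc_feature_names(flank), codes.astype(float)))
            else:
                raise ValueError(f"unknown feature block {block!r}")
        rows.append(row)

    df = pd.DataFrame(rows, columns=feature_names(blocks, flank), index=[r.id for r in records])
    df.index.name = "id"
    if any(r.label is not None for r in records):
        df.insert(0, "label", [r.label for r in records])
    df.attrs["sjsc_mode"] = sjsc_mode if "sjsc" in blocks else None
    return df
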