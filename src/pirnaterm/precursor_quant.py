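"""Precursor identification, count tables, size factors and fold changes.

A short-capped read is a piRNA precursor of a locus iff it lies on the
locus strand with its 5' end exactly at the precursor TSS (2 nt upstream
of the mature 21U 5'U) and is at least ``min_len`` nt long. Counts are
normalized either to reads mapping to a generic TSS annotation, to a
miRNA count table via median-of-ratios size factors, or to totals of
non-structural mapped reads; per-locus log2 fold changes use a mean-count
filter and a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AlignedRead, PiRNALocus

__all__ = [
    "PrecursorRecord",
    "identify_precursors",
    "tss_library_size",
    "count_table",
    "count_reads_at",
    "size_factors_median_of_ratios",
    "per_locus_log2fc",
    "total_abundance_relative",
    "nonstructural_total",
]


@dataclass(frozen=True)
class PrecursorRecord:
    """A capped read assigned to its locus."""

    locus_id: str
    length: int
    count: int
    sample_id: str = ""
    compartment: str = "whole"


def identify_precursors(
    reads: Iterable[AlignedRead],
    loci: Sequence[PiRNALocus],
    min_len: int = 18,
    slack: int = 0,
    sample_id: str = "",
    compartment: str = "whole",
) -> list[PrecursorRecord]:
    """Assign capped reads whose 5' end is exactly at a locus TSS.

    ``slack`` widens the 5'-end match to +/- that many nt (default 0, the
    strict "exactly 2 nt upstream" rule). Two loci sharing a TSS and
    strand make assignment ambiguous and raise.
    """
    tss_index: dict[tuple[str, str, int], PiRNALocus] = {}
    for locus in loci:
        for d in range(-slack, slack + 1):
            # slack is applied along the genome; direction is irrelevant to matching
            key = (locus.chrom, locus.strand, locus.tss_pos + d)
            if key in tss_index:
                raise ValueError(
                    f"loci {tss_index[key].locus_id!r} and {locus.locus_id!r} "
                    f"share TSS {key} (slack={slack})"
                )
            tss_index[key] = locus
    out: list[PrecursorRecord] = []
    for read in reads:
        locus = tss_index.get((read.chrom, read.strand, read.five_prime))
        if locus is None or read.length < min_len:
            continue
        out.append(PrecursorRecord(locus.locus_id, read.length, read.count, sample_id, compartment))
    return out


def tss_library_size(
    reads: Iterable[AlignedRead], tss_annotation: Iterable[tuple[str, str, int]]
) -> int:
    """Total multiplicity of reads whose 5' end lies at any annotated TSS."""
    tss_set = set(tss_annotation)
    if not tss_set:
        raise ValueError("empty TSS annotation")
    return sum(r.count for r in reads if (r.chrom, r.strand, r.five_prime) in tss_set)


def count_table(records: Iterable[PrecursorRecord], loci: Sequence[PiRNALocus] | None = None) -> pd.DataFrame:
    """Locus x sample table of precursor read counts."""
    rows: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.locus_id, rec.sample_id)
        rows[key] = rows.get(key, 0) + rec.count
    if not rows:
        return pd.DataFrame()
    ser = pd.Series(rows).unstack(fill_value=0)
    if loci is not None:
        ser = ser.reindex([loc.locus_id for loc in loci], fill_value=0)
    return ser


def count_reads_at(
    reads: Iterable[AlignedRead],
    features: Iterable[tuple[str, str, str, int]],
    length: int | None = None,
) -> pd.Series:
    """Per-feature counts of reads with 5' end at (chrom, strand, pos).

    ``features`` is an iterable of (feature_id, chrom, strand, position);
    ``length`` optionally restricts to reads of an exact length (e.g. the
    mature 21U / miRNA species).
    """
    index: dict[tuple[str, str, int], str] = {}
    for fid, chrom, strand, pos in features:
        index[(chrom, strand, pos)] = fid
    counts = {fid: 0 for fid in index.values()}
    for r in reads:
        if length is not None and r.length != length:
            continue
        fid = index.get((r.chrom, r.strand, r.five_prime))
        if fid is not None:
            counts[fid] += r.count
    return pd.Series(counts, dtype=int)


def size_factors_median_of_ratios(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    Per sample: the median over features with nonzero counts in every
    sample of count / geometric-mean-across-samples.
    """
    if table.shape[1] == 1:
        return pd.Series(1.0, index=table.columns)
    counts = table.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature with nonzero counts in all samples")
    sub = counts[nonzero]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return pd.Series(factors, index=table.columns)


def per_locus_log2fc(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    size_factors: Mapping[str, float],
    min_mean: float = 5.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((B + pc) / (A + pc)) of mean normalized counts per locus.

    Loci are kept when the mean normalized count across all samples of
    both conditions exceeds ``min_mean``.
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("mismatched feature sets between conditions")
    norm_a = table_a / pd.Series(size_factors).reindex(table_a.columns)
    norm_b = table_b / pd.Series(size_factors).reindex(table_b.columns)
    overall_mean = pd.concat([norm_a, norm_b], axis=1).mean(axis=1)
    keep = overall_mean > min_mean
    a = norm_a.loc[keep].mean(axis=1)
    b = norm_b.loc[keep].mean(axis=1)
    return np.log2((b + pseudocount) / (a + pseudocount))


def total_abundance_relative(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    size_factors: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per replicate-pair ratio of normalized totals (treatment / control).

    ``pairs`` lists (control_sample, treatment_sample) column names;
    ``size_factors`` defaults to 1 for every sample.
    """
    sf = pd.Series(size_factors) if size_factors is not None else pd.Series(1.0, index=table.columns)
    out = {}
    for ctrl, trt in pairs:
        for s in (ctrl, trt):
            if s not in table.columns:
                raise ValueError(f"unpaired sample {s!r} missing from table")
        out[trt] = (table[trt].sum() / sf[trt]) / (table[ctrl].sum() / sf[ctrl])
    return pd.Series(out)


def nonstructural_total(
    reads: Iterable[AlignedRead],
    structural: Iterable[tuple[str, str, int, int]] = (),
) -> int:
    """Total read multiplicity excluding reads overlapping structural RNAs.

    ``structural`` is an iterable of (chrom, strand, start, end) intervals
    (rRNA/tRNA/snRNA annotations); the exclusion list is an input, never
    hard-coded.
    """
    ivs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, strand, start, end in structural:
        ivs.setdefault((chrom, strand), []).append((start, end))
    total = 0
    for r in reads:
        spans = ivs.get((r.chrom, r.strand), ())
        if any(r.start < e and s < r.end for s, e in spans):
            continue
        total += r.count
    return total
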