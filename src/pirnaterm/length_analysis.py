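"""Length distributions and per-locus length statistics of piRNA precursors.

Two weighting schemes run through everything here: *reads* weights each
alignment by its multiplicity, *sequences* counts each distinct
(locus, length) species once. Since every precursor of a locus shares the
locus 5' end, a distinct (locus, length) pair stands in for a distinct
sequence. Medians follow the numpy midpoint convention (even-sized
samples average the two central values); read-weighted statistics are
computed on count-expanded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .precursor_quant import PrecursorRecord

__all__ = [
    "LengthDistribution",
    "LocusLengthStats",
    "length_distribution",
    "per_locus_length_stats",
    "length_shift",
    "detection_matrix",
    "trimming_bins",
    "weighted_median",
]


def weighted_median(values: Sequence[float] | np.ndarray, weights: Sequence[int] | np.ndarray) -> float:
    """Median of values repeated by integer weights (midpoint convention)."""
    values = np.asarray(values)
    weights = np.asarray(weights, dtype=int)
    if values.size == 0:
        raise ValueError("empty input")
    return float(np.median(np.repeat(values, weights)))


@dataclass
class LengthDistribution:
    """Histogram over integer lengths, raw and normalized to unit mass."""

    lengths: np.ndarray
    counts: np.ndarray
    weight_by: str

    @property
    def mass(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def mode(self) -> int:
        return int(self.lengths[np.argmax(self.counts)])

    def median(self) -> float:
        return weighted_median(self.lengths, self.counts)

    def as_series(self, normalized: bool = True) -> pd.Series:
        return pd.Series(self.mass if normalized else self.counts, index=self.lengths)


@dataclass(frozen=True)
class LocusLengthStats:
    locus_id: str
    median_seq: float
    mean_seq: float
    median_read: float
    mean_read: float


def _collapse(records: Iterable[PrecursorRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.locus_id, r.length, r.count) for r in records],
        columns=["locus_id", "length", "count"],
    )
    if df.empty:
        return df
    return df.groupby(["locus_id", "length"], as_index=False)["count"].sum()


def length_distribution(records: Iterable[PrecursorRecord], weight_by: str = "reads") -> LengthDistribution:
    """Length histogram weighted by reads or by distinct sequences."""
    if weight_by not in ("reads", "sequences"):
        raise ValueError(f"weight_by must be 'reads' or 'sequences', got {weight_by!r}")
    df = _collapse(records)
    if df.empty:
        raise ValueError("no records")
    w = df["count"] if weight_by == "reads" else pd.Series(1, index=df.index)
    hist = w.groupby(df["length"]).sum().sort_index()
    return LengthDistribution(hist.index.to_numpy(), hist.to_numpy(), weight_by)


def per_locus_length_stats(records: Iterable[PrecursorRecord]) -> list[LocusLengthStats]:
    """Median/mean precursor length per locus under both weightings."""
    df = _collapse(records)
    out: list[LocusLengthStats] = []
    for locus_id, grp in df.groupby("locus_id", sort=True):
        lengths = grp["length"].to_numpy()
        counts = grp["count"].to_numpy()
        expanded = np.repeat(lengths, counts)
        out.append(
            LocusLengthStats(
                locus_id=str(locus_id),
                median_seq=float(np.median(lengths)),
                mean_seq=float(np.mean(lengths)),
                median_read=float(np.median(expanded)),
                mean_read=float(np.mean(expanded)),
            )
        )
    return out


def length_shift(
    stats_a: Sequence[LocusLengthStats],
    stats_b: Sequence[LocusLengthStats],
    stat: str = "mean_read",
) -> pd.Series:
    """Per shared locus, statB - statA for the chosen statistic."""
    a = {s.locus_id: getattr(s, stat) for s in stats_a}
    b = {s.locus_id: getattr(s, stat) for s in stats_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared loci between the two stat sets")
    return pd.Series({lid: b[lid] - a[lid] for lid in shared})


def detection_matrix(records: Iterable[PrecursorRecord]) -> pd.DataFrame:
    """Binary loci x lengths matrix: 1 iff >= 1 precursor of that length."""
    df = _collapse(records)
    if df.empty:
        return pd.DataFrame()
    mat = df.pivot_table(index="locus_id", columns="length", values="count", aggfunc="sum")
    return (mat.fillna(0) > 0).astype(int)


def trimming_bins(
    chromatin_records: Iterable[PrecursorRecord],
    nucleoplasm_records: Iterable[PrecursorRecord],
    long_threshold: int = 38,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Nucleoplasmic median lengths binned by chromatin long-read fraction.

    Loci are binned (equal-width on [0, 1]) by the fraction of their
    chromatin-bound reads longer than ``long_threshold``; the returned
    frame has one row per locus present in both compartments with its
    long fraction, bin index (1-based) and nucleoplasmic median lengths
    under both weightings.
    """
    chrom = _collapse(chromatin_records)
    if chrom.empty:
        raise ValueError("no chromatin records")
    frac = (
        chrom.assign(long=lambda d: d["count"].where(d["length"] > long_threshold, 0))
        .groupby("locus_id")[["count", "long"]]
        .sum()
        .pipe(lambda d: d["long"] / d["count"])
    )
    nuc_stats = {s.locus_id: s for s in per_locus_length_stats(nucleoplasm_records)}
    shared = [lid for lid in frac.index if lid in nuc_stats]
    frac = frac.loc[shared]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(frac.to_numpy(), edges[1:-1], right=False) + 1, 1, n_bins)
    return pd.DataFrame(
        {
            "long_fraction": frac,
            "bin": bins,
            "nuc_median_read": [nuc_stats[lid].median_read for lid in shared],
            "nuc_median_seq": [nuc_stats[lid].median_seq for lid in shared],
        },
        index=pd.Index(shared, name="locus_id"),
    )
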