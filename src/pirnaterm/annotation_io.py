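"""Data model, file I/O and coordinate conventions for piRNA loci.

Coordinates are BED-style 0-based half-open throughout. A *C. elegans*
piRNA locus is anchored at the first nucleotide of the mature 21U-RNA (the
5' uridine, ``u5_pos``); the transcription start site of its short-capped
precursor lies exactly 2 nt upstream of that position on the locus strand.
Windowed analyses use strand-aware offset frames: offset 0 at the reference
nucleotide (TSS or 5'U), increasing downstream along the locus strand. A
read's "3' offset" is its half-open end in offset space, so that
``length == three_off - five_off``.

The termination signal of a locus is scored as the A/T fraction of the
sense strand within a configurable window downstream of the TSS — a simple
monotone surrogate for the low-melting-temperature (AT-rich) region that
promotes promoter-proximal Pol II pausing at these loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PiRNALocus",
    "AlignedRead",
    "LocusParseError",
    "load_loci",
    "write_loci_bed",
    "load_reads_bed",
    "write_reads_bed",
    "fetch_sense_window",
    "compute_termination_signal",
    "assign_signal_bins",
    "to_offset",
    "from_offset",
]

MOTIF_DEPENDENT = "motif_dependent"
MOTIF_INDEPENDENT = "motif_independent"

#: distance (nt) from the precursor TSS to the mature 21U 5' uridine
TSS_TO_U5 = 2


class LocusParseError(ValueError):
    """Raised for malformed locus annotation records."""


def _norm_strand(s: str) -> str:
    # tolerate the unicode minus that shows up in copy-pasted annotations
    if s in ("+",):
        return "+"
    if s in ("-", "−", "‒", "–"):
        return "-"
    raise ValueError(f"invalid strand {s!r}")


@dataclass
class PiRNALocus:
    """One 21U-RNA transcription unit."""

    locus_id: str
    chrom: str
    strand: str
    u5_pos: int
    motif_class: str = MOTIF_DEPENDENT
    signal_score: float | None = None
    signal_bin: int | None = None

    def __post_init__(self) -> None:
        self.strand = _norm_strand(self.strand)
        if self.u5_pos < 0:
            raise ValueError(f"negative u5_pos for locus {self.locus_id}")
        if self.signal_score is not None and not 0.0 <= self.signal_score <= 1.0:
            raise ValueError("signal_score must lie in [0, 1]")

    @property
    def tss_pos(self) -> int:
        """Genomic position of the precursor TSS, 2 nt upstream of the 5'U."""
        return self.u5_pos - TSS_TO_U5 if self.strand == "+" else self.u5_pos + TSS_TO_U5

    def ref_pos(self, frame: str) -> int:
        if frame == "tss":
            return self.tss_pos
        if frame == "u5":
            return self.u5_pos
        raise ValueError(f"unknown frame {frame!r} (expected 'tss' or 'u5')")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read/tag as a strand-aware half-open interval.

    ``count`` is the multiplicity of identical alignments collapsed into
    this record; ``library`` labels the 5'-end chemistry
    (``capped_short`` | ``fivep_small`` | ``cage``).
    """

    chrom: str
    strand: str
    start: int
    end: int
    count: int = 1
    library: str = "capped_short"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _norm_strand(self.strand))
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.count < 1:
            raise ValueError("count must be a positive integer")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# locus annotation I/O

_TSV_COLUMNS = ["locus_id", "chrom", "u5_pos", "strand", "motif_class"]


def load_loci(annotation_path: str | Path) -> list[PiRNALocus]:
    """Read a locus annotation as BED6(+motif class) or headered TSV.

    BED records span the mature 21U-RNA, so the 5'U is ``start`` on the
    plus strand and ``end - 1`` on the minus strand; the name column holds
    the locus id, the score column is ignored, and an optional 7th column
    carries the motif class. The TSV layout is
    ``locus_id chrom u5_pos strand motif_class`` with a header row.
    Duplicate locus ids are rejected.
    """
    path = Path(annotation_path)
    lines = path.read_text().splitlines()
    first = next((ln for ln in lines if ln.strip() and not ln.startswith(("#", "track"))), None)
    if first is None:
        raise LocusParseError(f"{path}: no records")
    is_tsv = first.split()[0] == "locus_id"

    loci: list[PiRNALocus] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        if is_tsv and line.split()[0] == "locus_id":
            continue
        fields = line.split()
        try:
            if is_tsv:
                if len(fields) < 5:
                    raise ValueError("expected 5 columns")
                locus_id, chrom, u5_s, strand, motif_class = fields[:5]
                u5_pos = int(u5_s)
            else:
                if len(fields) < 6:
                    raise ValueError("expected >= 6 BED columns")
                chrom, start_s, end_s, locus_id, _score, strand = fields[:6]
                start, end = int(start_s), int(end_s)
                if start < 0 or end <= start:
                    raise ValueError(f"bad interval [{start}, {end})")
                u5_pos = start if _norm_strand(strand) == "+" else end - 1
                motif_class = fields[6] if len(fields) > 6 else MOTIF_DEPENDENT
            locus = PiRNALocus(locus_id, chrom, strand, u5_pos, motif_class)
        except ValueError as exc:
            raise LocusParseError(f"{path}, line {lineno}: {exc}") from exc
        if locus.locus_id in seen:
            raise LocusParseError(f"{path}, line {lineno}: duplicate locus_id {locus.locus_id!r}")
        seen.add(locus.locus_id)
        loci.append(locus)
    return loci


def write_loci_bed(loci: Iterable[PiRNALocus], path: str | Path, u5_span: int = 21) -> None:
    """Write loci as BED6 + motif-class column (interval = mature 21U span)."""
    with open(path, "w") as fh:
        for loc in loci:
            if loc.strand == "+":
                start, end = loc.u5_pos, loc.u5_pos + u5_span
            else:
                start, end = loc.u5_pos - u5_span + 1, loc.u5_pos + 1
            fh.write(f"{loc.chrom}\t{start}\t{end}\t{loc.locus_id}\t0\t{loc.strand}\t{loc.motif_class}\n")


def load_reads_bed(path: str | Path, library: str = "capped_short") -> list[AlignedRead]:
    """Read alignments as BED6 with the score column holding multiplicity."""
    reads: list[AlignedRead] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise LocusParseError(f"{path}, line {lineno}: expected >= 6 BED columns")
        chrom, start, end, _name, count, strand = fields[:6]
        try:
            reads.append(AlignedRead(chrom, strand, int(start), int(end), int(count), library))
        except ValueError as exc:
            raise LocusParseError(f"{path}, line {lineno}: {exc}") from exc
    return reads


def write_reads_bed(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.library}\t{r.count}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# sequence access and termination-signal scoring


def fetch_sense_window(
    genome: Mapping[str, object], locus: PiRNALocus, window: tuple[int, int], frame: str = "tss"
) -> str:
    """Sense-strand sequence over a half-open offset window on the locus.

    ``genome`` is any mapping of contig name to a sliceable sequence
    (a plain dict of strings or a :class:`pyfaidx.Fasta`).
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    ref = locus.ref_pos(frame)
    contig = genome[locus.chrom]
    if locus.strand == "+":
        gstart, gend = ref + lo, ref + hi
    else:
        gstart, gend = ref - hi + 1, ref - lo + 1
    if gstart < 0 or gend > len(contig):
        raise ValueError(
            f"window {window} ({frame}-frame) of locus {locus.locus_id} extends past contig {locus.chrom}"
        )
    seq = str(contig[gstart:gend]).upper()
    if locus.strand == "-":
        seq = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
    return seq


def compute_termination_signal(
    locus: PiRNALocus,
    genome: Mapping[str, object],
    window: tuple[int, int] = (0, 50),
    frame: str = "tss",
) -> float:
    """Score the termination signal as the sense-strand A/T fraction.

    The default window [0, 50) in the TSS frame covers the whole short
    transcription unit; the alternative [27, 52) isolates the region
    downstream of the mature 21U-RNA. The score is stored on the locus.
    """
    seq = fetch_sense_window(genome, locus, window, frame)
    score = sum(1 for b in seq if b in "AT") / len(seq)
    locus.signal_score = score
    return score


def assign_signal_bins(loci: Sequence[PiRNALocus], n_bins: int) -> list[PiRNALocus]:
    """Assign equal-sized percentile bins of signal_score; bin 1 = weakest.

    Loci are rank-ordered by score (ties broken stably by input order, so
    tied scores at a boundary divide across bins to keep bins equal-sized).
    The degenerate all-identical case collapses to a single bin with a
    warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = [loc.signal_score for loc in loci]
    if any(s is None for s in scores):
        unscored = [loc.locus_id for loc, s in zip(loci, scores) if s is None]
        raise ValueError(f"unscored loci: {unscored[:5]}{'...' if len(unscored) > 5 else ''}")
    arr = np.asarray(scores, dtype=float)
    if np.unique(arr).size == 1:
        warnings.warn("all signal scores identical; assigning a single bin", stacklevel=2)
        for loc in loci:
            loc.signal_bin = 1
        return list(loci)
    order = np.argsort(arr, kind="stable")
    n = len(loci)
    for rank, idx in enumerate(order):
        loci[idx].signal_bin = int(rank * n_bins // n) + 1
    return list(loci)


# ---------------------------------------------------------------------------
# offset frames


def to_offset(read: AlignedRead, locus: PiRNALocus, frame: str = "tss") -> tuple[int, int] | None:
    """Map a read interval to (5' offset, half-open 3' offset) on the locus.

    Returns None when read and locus disagree in chromosome or strand.
    Offsets increase downstream along the locus strand; the u5 frame equals
    the tss frame minus 2.
    """
    if read.chrom != locus.chrom or read.strand != locus.strand:
        return None
    ref = locus.ref_pos(frame)
    if locus.strand == "+":
        return read.start - ref, read.end - ref
    return ref - (read.end - 1), ref - read.start + 1


def from_offset(
    locus: PiRNALocus,
    five_off: int,
    three_off: int,
    frame: str = "tss",
    count: int = 1,
    library: str = "capped_short",
) -> AlignedRead:
    """Inverse of :func:`to_offset`: build the genomic interval for offsets."""
    if three_off <= five_off:
        raise ValueError("three_off must exceed five_off")
    ref = locus.ref_pos(frame)
    if locus.strand == "+":
        start, end = ref + five_off, ref + three_off
    else:
        start, end = ref - three_off + 1, ref - five_off + 1
    return AlignedRead(locus.chrom, locus.strand, start, end, count, library)
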