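"""Synthetic datasets with the structure of the two-pause / Integrator-cleavage model.

The generator emulates the generative picture of piRNA transcription
termination at motif-dependent loci: Pol II initiates 2 nt upstream of the
mature 21U-RNA, pauses ~28 nt downstream of the TSS and either releases
there (the major short-capped precursor class) or proceeds to a second
pause ~48 nt downstream. Polymerases reaching the second pause are
terminated by Integrator cleavage of the nascent RNA at ~+38, releasing a
~38 nt capped product and leaving a 5'-monophosphate degradation fragment
whose 3' end sits near +58. AT-rich termination signals downstream of the
21U-RNA reduce the odds of reaching the second pause, coupling signal
strength negatively to cleavage-fragment yield.

Each library type the downstream modules consume can be simulated:

* chromatin-bound and nucleoplasmic short-capped reads (bimodal vs
  unimodal length mixtures),
* direct 5'P small-RNA libraries (mature 21U-RNAs, planted unannotated
  21U-RNAs, cleavage fragments, miRNA background for normalization),
* CAGE tag pairs (readthrough transcripts initiating at the -2 position
  with heavy-tailed per-CTSS counts plus genomic background tags).

Genotype presets reshape the model the way the corresponding mutants do:
``tfiis`` shifts both pause sites downstream (+2/+3 nt) and reduces
cleavage; ``ints11_kd`` depletes cleavage fragments, lowers precursor
abundance, extends a long upper tail of precursor lengths and increases
CAGE readthrough.

All randomness flows from ``SimulationConfig.seed``; every operation
derives an independent, purpose-keyed stream from it, so individual
library types are reproducible in isolation.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .annotation_io import (
    MOTIF_DEPENDENT,
    MOTIF_INDEPENDENT,
    AlignedRead,
    PiRNALocus,
    from_offset,
    write_loci_bed,
    write_reads_bed,
)

__all__ = [
    "SimulationConfig",
    "GenotypePreset",
    "PRESETS",
    "simulate_loci",
    "unannotated_sites",
    "mirna_positions",
    "simulate_capped_reads",
    "simulate_5p_reads",
    "simulate_released_products",
    "simulate_cage_pairs",
    "pause2_probability",
    "write_fixture_set",
]

MAIN_CONTIG = "chrS"
MIRNA_CONTIG = "chrMir"
MOTIF = "GTTTC"
#: tss-frame offset of the first motif base (upstream of the TSS)
MOTIF_OFFSET = -45
#: tss-frame window whose A/T fraction realizes the intended signal score
SIGNAL_WINDOW = (0, 50)

# purpose codes keying independent RNG streams off the single seed
_K_GENOME, _K_CAPPED, _K_5P, _K_CAGE, _K_UNANNOT, _K_RELEASED = 1, 2, 3, 4, 5, 6
_PRESET_CODE = {"wild_type": 0, "tfiis": 1, "ints11_kd": 2, "tfiis_ints11_kd": 3}
_COMP_CODE = {"chromatin": 0, "nucleoplasm": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-pause + cleavage generative model.

    Defaults are the wild-type study conditions: pause sites at 28/48 nt,
    cleavage geometry 38/58, a 0.75/0.25 pause-1/pause-2 split at the
    central termination-signal score, and a strong negative coupling of
    signal strength to pause-2 progression.
    """

    n_loci: int = 2000
    frac_motif_dependent: float = 0.8
    peak1_pos: int = 28
    peak1_sd: float = 1.5
    peak2_pos: int = 48
    peak2_sd: float = 1.5
    p_pause2_base: float = 0.25
    signal_coupling: float = -5.0
    signal_center: float = 0.6
    cleavage5_mu: int = 38
    cleavage5_sd: float = 1.5
    cleavage3_mu: int = 58
    cleavage3_sd: float = 1.5
    fragment_rate: float = 0.8
    readthrough_frac: float = 0.01
    cage_indep_frac: float = 0.45
    reads_per_locus_mean: float = 30.0
    mature_reads_per_locus_mean: float = 30.0
    mirna_count: int = 50
    mirna_reads_mean: float = 100.0
    unannot_21u_frac: float = 0.05
    tail_frac: float = 0.15
    n_background_ctss: int = 2000
    zipf_exponent: float = 2.25
    cage_len_mu: float = 450.0
    cage_len_sd: float = 80.0
    min_read_len: int = 18
    locus_pitch: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.peak2_pos <= self.peak1_pos:
            raise ValueError("peak2_pos must exceed peak1_pos")
        if self.cleavage3_mu <= self.cleavage5_mu:
            raise ValueError("cleavage3_mu must exceed cleavage5_mu")
        for name in (
            "frac_motif_dependent",
            "p_pause2_base",
            "fragment_rate",
            "readthrough_frac",
            "cage_indep_frac",
            "unannot_21u_frac",
            "tail_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_coupling > 0:
            raise ValueError("signal_coupling must be <= 0")


@dataclass(frozen=True)
class GenotypePreset:
    """Multiplicative/additive reshaping of the model for one genotype."""

    name: str
    peak1_shift: int = 0
    peak2_shift: int = 0
    fragment_rate_factor: float = 1.0
    precursor_abundance_factor: float = 1.0
    tail_extension_max: int = 0
    readthrough_factor: float = 1.0


PRESETS: dict[str, GenotypePreset] = {
    "wild_type": GenotypePreset("wild_type"),
    "tfiis": GenotypePreset(
        "tfiis",
        peak1_shift=2,
        peak2_shift=3,
        fragment_rate_factor=0.4,
        precursor_abundance_factor=1.5,
    ),
    "ints11_kd": GenotypePreset(
        "ints11_kd",
        fragment_rate_factor=0.2,
        precursor_abundance_factor=0.6,
        tail_extension_max=75,
        readthrough_factor=3.6,
    ),
    "tfiis_ints11_kd": GenotypePreset(
        "tfiis_ints11_kd",
        peak1_shift=2,
        peak2_shift=3,
        fragment_rate_factor=0.1,
        precursor_abundance_factor=0.9,
        tail_extension_max=75,
        readthrough_factor=10.0,
    ),
}


def _get_preset(preset: GenotypePreset | str) -> GenotypePreset:
    if isinstance(preset, str):
        return PRESETS[preset]
    return preset


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def pause2_probability(config: SimulationConfig, signal_score: float) -> float:
    """P(polymerase proceeds to the second pause | termination-signal score).

    Logistic in the score: log-odds equal the base log-odds plus
    ``signal_coupling * (score - signal_center)``, so stronger AT-rich
    signals (with negative coupling) make pause-2 progression rarer.
    """
    base = np.log(config.p_pause2_base / (1.0 - config.p_pause2_base))
    logit = base + config.signal_coupling * (signal_score - config.signal_center)
    return float(1.0 / (1.0 + np.exp(-logit)))


# ---------------------------------------------------------------------------
# genome + locus construction


def unannotated_sites(config: SimulationConfig) -> list[tuple[int, int]]:
    """Planted unannotated 21U start sites as (locus index, u5-frame offset).

    Offsets are drawn from the +/-5 nt neighbourhood of the annotated 5'U
    (excluding 0), restricted to offsets whose genomic base lies inside the
    signal window so the generator can force a T there. Deterministic given
    the config seed; the genome builder and the 5'P simulator share it.
    """
    rng = _rng(config, _K_UNANNOT)
    n_sites = int(round(config.unannot_21u_frac * config.n_loci))
    if n_sites == 0:
        return []
    idx = rng.choice(config.n_loci, size=n_sites, replace=False)
    deltas = rng.choice([-2, -1, 1, 2, 3, 4, 5], size=n_sites)
    return sorted((int(i), int(d)) for i, d in zip(idx, deltas))


def mirna_positions(config: SimulationConfig) -> list[tuple[str, str, str, int]]:
    """miRNA annotation for the background library: (id, chrom, strand, 5' pos)."""
    return [
        (f"mir{j}", MIRNA_CONTIG, "+", 1000 + 60 * j) for j in range(config.mirna_count)
    ]


def simulate_loci(config: SimulationConfig) -> tuple[dict[str, str], list[PiRNALocus]]:
    """Build a synthetic genome and its non-overlapping piRNA loci.

    Each motif-dependent locus carries a GTTTC core motif at a fixed
    upstream offset; the sense-strand A/T fraction of the signal window is
    planted to match a target score drawn uniformly on [0.2, 1.0], with a
    T forced at the 5'U (and at any planted unannotated 21U start). The
    realized A/T fraction is stored as ``signal_score``.
    """
    margin = 1000
    pitch = config.locus_pitch
    if pitch < 120:
        raise ValueError(f"locus_pitch {pitch} too short: loci would overlap (need >= 120)")
    rng = _rng(config, _K_GENOME)
    n = config.n_loci
    contig_len = 2 * margin + n * pitch
    bases = np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=contig_len)]

    n_md = int(round(config.frac_motif_dependent * n))
    md_idx = set(rng.choice(n, size=n_md, replace=False).tolist())
    strands = rng.choice(["+", "-"], size=n)
    targets = rng.uniform(0.2, 1.0, size=n)
    forced = {}  # locus index -> set of tss-frame offsets forced to T (sense)
    for i, delta in unannotated_sites(config):
        forced.setdefault(i, set()).add(2 + delta)

    loci: list[PiRNALocus] = []
    wlo, whi = SIGNAL_WINDOW
    wlen = whi - wlo
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(n):
        tss = margin + i * pitch + 60
        strand = strands[i]
        u5 = tss + 2 if strand == "+" else tss - 2
        force_t = {2} | forced.get(i, set())  # 5'U is always a T on the sense strand
        k = int(round(targets[i] * wlen))
        k = max(k, len(force_t))
        at_pos = set(force_t)
        free = [p for p in range(wlo, whi) if p not in at_pos]
        at_pos |= set(rng.permutation(free)[: k - len(at_pos)].tolist())
        window_seq = []
        for p in range(wlo, whi):
            if p in force_t:
                window_seq.append("T")
            elif p in at_pos:
                window_seq.append("AT"[rng.integers(0, 2)])
            else:
                window_seq.append("GC"[rng.integers(0, 2)])
        sense = "".join(window_seq)
        motif_class = MOTIF_DEPENDENT if i in md_idx else MOTIF_INDEPENDENT
        # write sense-strand stretches (motif + signal window) into the genome
        pieces = [(SIGNAL_WINDOW[0], sense)]
        if motif_class == MOTIF_DEPENDENT:
            pieces.append((MOTIF_OFFSET, MOTIF))
        for off, seq in pieces:
            if strand == "+":
                gstart = tss + off
                bases[gstart : gstart + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
            else:
                rc = seq[::-1].translate(comp)
                gend = tss - off + 1  # genomic position of offset `off` is tss - off
                bases[gend - len(seq) : gend] = np.frombuffer(rc.encode(), dtype="S1")
        loci.append(
            PiRNALocus(f"p{i}", MAIN_CONTIG, strand, u5, motif_class, signal_score=k / wlen)
        )

    mir_len = 2000 + 60 * config.mirna_count
    mir_bases = np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=mir_len)]
    genome = {
        MAIN_CONTIG: bases.tobytes().decode(),
        MIRNA_CONTIG: mir_bases.tobytes().decode(),
    }
    return genome, loci


# ---------------------------------------------------------------------------
# capped (precursor) libraries


def simulate_capped_reads(
    loci: Sequence[PiRNALocus],
    config: SimulationConfig,
    preset: GenotypePreset | str = "wild_type",
    compartment: str = "chromatin",
) -> list[AlignedRead]:
    """Short-capped precursor reads for one compartment.

    Chromatin reads mix the two pause components with the signal-coupled
    pause-2 probability; nucleoplasmic reads are released/trimmed products
    drawn from the pause-1 component only. Presets with a tail extension
    (Integrator knock-down) replace a fraction of reads with lengths
    uniform up to ``tail_extension_max``. All reads start at the locus TSS
    and are truncated at the library minimum length.
    """
    preset = _get_preset(preset)
    if compartment not in _COMP_CODE:
        raise ValueError(f"unknown compartment {compartment!r}")
    rng = _rng(config, _K_CAPPED, _PRESET_CODE.get(preset.name, 99), _COMP_CODE[compartment])
    out: list[AlignedRead] = []
    mean = config.reads_per_locus_mean * preset.precursor_abundance_factor
    for locus in loci:
        n = rng.poisson(mean)
        if n == 0:
            continue
        if compartment == "chromatin":
            p2 = pause2_probability(config, locus.signal_score or 0.0)
        else:
            p2 = 0.0
        at_pause2 = rng.random(n) < p2
        lengths = np.where(
            at_pause2,
            np.rint(rng.normal(config.peak2_pos + preset.peak2_shift, config.peak2_sd, n)),
            np.rint(rng.normal(config.peak1_pos + preset.peak1_shift, config.peak1_sd, n)),
        ).astype(int)
        if preset.tail_extension_max > 0:
            tail = rng.random(n) < config.tail_frac
            lo = config.peak2_pos + preset.peak2_shift + 1
            lengths[tail] = rng.integers(lo, preset.tail_extension_max + 1, size=int(tail.sum()))
        lengths = np.maximum(lengths, config.min_read_len)
        for length, cnt in zip(*np.unique(lengths, return_counts=True)):
            out.append(
                from_offset(locus, 0, int(length), frame="tss", count=int(cnt), library="capped_short")
            )
    return out


# ---------------------------------------------------------------------------
# 5'P libraries


def _cleavage_event_counts(
    rng: np.random.Generator,
    loci: Sequence[PiRNALocus],
    config: SimulationConfig,
    preset: GenotypePreset,
) -> np.ndarray:
    """Per-locus pause-2 (cleavage-eligible) event counts."""
    mean = config.reads_per_locus_mean * preset.precursor_abundance_factor
    p2 = np.array([pause2_probability(config, loc.signal_score or 0.0) for loc in loci])
    return rng.poisson(mean * p2)


def _draw_fragment_offsets(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cleavage fragment (5', 3') tss-frame offsets; pairs with 3' <= 5' redrawn."""
    five = np.rint(rng.normal(config.cleavage5_mu, config.cleavage5_sd, n)).astype(int)
    three = np.rint(rng.normal(config.cleavage3_mu, config.cleavage3_sd, n)).astype(int)
    bad = three <= five
    while bad.any():
        m = int(bad.sum())
        five[bad] = np.rint(rng.normal(config.cleavage5_mu, config.cleavage5_sd, m)).astype(int)
        three[bad] = np.rint(rng.normal(config.cleavage3_mu, config.cleavage3_sd, m)).astype(int)
        bad = three <= five
    return five, three


def simulate_5p_reads(
    loci: Sequence[PiRNALocus],
    config: SimulationConfig,
    preset: GenotypePreset | str = "wild_type",
) -> list[AlignedRead]:
    """A direct 5'-monophosphate small-RNA library.

    Mixture of (i) mature 21U-RNAs (21-mers at the annotated 5'U, plus
    21-mers at the planted unannotated starts), (ii) Integrator cleavage
    fragments emitted per pause-2 event with probability
    ``fragment_rate * fragment_rate_factor``, and (iii) background miRNA
    reads (22-mers on the miRNA contig) for size-factor normalization.
    """
    preset = _get_preset(preset)
    rng = _rng(config, _K_5P, _PRESET_CODE.get(preset.name, 99))
    out: list[AlignedRead] = []
    mature_mean = config.mature_reads_per_locus_mean * preset.precursor_abundance_factor

    for locus in loci:
        cnt = int(rng.poisson(mature_mean))
        if cnt > 0:
            out.append(from_offset(locus, 0, 21, frame="u5", count=cnt, library="fivep_small"))

    for i, delta in unannotated_sites(config):
        locus = loci[i]
        cnt = int(rng.poisson(0.3 * mature_mean))
        if cnt > 0:
            out.append(
                from_offset(locus, delta, delta + 21, frame="u5", count=cnt, library="fivep_small")
            )

    events = _cleavage_event_counts(rng, loci, config, preset)
    rate = min(1.0, config.fragment_rate * preset.fragment_rate_factor)
    n_frags = rng.binomial(events, rate)
    for locus, nf in zip(loci, n_frags):
        if nf == 0:
            continue
        five, three = _draw_fragment_offsets(rng, config, int(nf))
        uniq, counts = np.unique(np.stack([five, three], axis=1), axis=0, return_counts=True)
        for (f, t), c in zip(uniq, counts):
            out.append(
                from_offset(locus, int(f), int(t), frame="tss", count=int(c), library="fivep_small")
            )

    for _mid, chrom, strand, pos in mirna_positions(config):
        cnt = int(rng.poisson(config.mirna_reads_mean))
        if cnt > 0:
            out.append(AlignedRead(chrom, strand, pos, pos + 22, cnt, "fivep_small"))
    return out


def simulate_released_products(
    loci: Sequence[PiRNALocus],
    config: SimulationConfig,
    preset: GenotypePreset | str = "wild_type",
) -> list[AlignedRead]:
    """Capped products released by Integrator cleavage.

    One product per cleavage event, spanning the TSS to the cleavage 5'
    position, i.e. length distributed like the fragment 5' offset (~38 nt
    under defaults).
    """
    preset = _get_preset(preset)
    rng = _rng(config, _K_RELEASED, _PRESET_CODE.get(preset.name, 99))
    events = _cleavage_event_counts(rng, loci, config, preset)
    out: list[AlignedRead] = []
    for locus, n_ev in zip(loci, events):
        if n_ev == 0:
            continue
        five, _three = _draw_fragment_offsets(rng, config, int(n_ev))
        lengths = np.maximum(five, config.min_read_len)
        for length, cnt in zip(*np.unique(lengths, return_counts=True)):
            out.append(
                from_offset(locus, 0, int(length), frame="tss", count=int(cnt), library="capped_short")
            )
    return out


# ---------------------------------------------------------------------------
# CAGE


def simulate_cage_pairs(
    loci: Sequence[PiRNALocus],
    config: SimulationConfig,
    preset: GenotypePreset | str = "wild_type",
) -> list[AlignedRead]:
    """CAGE tag pairs as outer-span intervals (library ``cage``).

    A readthrough-emitting subset of loci produces tags whose 5' end sits
    at the -2 position of the u5 frame (the precursor TSS) with per-locus
    tag counts drawn from a discrete power law; pair spans are normal
    around ``cage_len_mu``. Background tags at random genomic positions
    carry the same heavy-tailed counts and provide the bulk of the CTSS
    count distribution used for power-law normalization.
    """
    preset = _get_preset(preset)
    rng = _rng(config, _K_CAGE, _PRESET_CODE.get(preset.name, 99))
    out: list[AlignedRead] = []
    p_md = min(1.0, config.readthrough_frac * preset.readthrough_factor)

    def emit_at(chrom: str, strand: str, five: int, n_tags: int) -> None:
        spans = np.maximum(
            100, np.rint(rng.normal(config.cage_len_mu, config.cage_len_sd, n_tags)).astype(int)
        )
        for span, cnt in zip(*np.unique(spans, return_counts=True)):
            if strand == "+":
                start, end = five, five + int(span)
            else:
                start, end = five - int(span) + 1, five + 1
            out.append(AlignedRead(chrom, strand, start, end, int(cnt), "cage"))

    for locus in loci:
        p = p_md if locus.motif_class == MOTIF_DEPENDENT else config.cage_indep_frac
        if rng.random() >= p:
            continue
        n_tags = min(int(rng.zipf(config.zipf_exponent)), 10_000)
        emit_at(locus.chrom, locus.strand, locus.tss_pos, n_tags)

    contig_len = 2000 + config.n_loci * config.locus_pitch
    for _ in range(config.n_background_ctss):
        pos = int(rng.integers(1000, contig_len - 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_tags = min(int(rng.zipf(config.zipf_exponent)), 10_000)
        emit_at(MAIN_CONTIG, strand, pos, n_tags)
    return out


# ---------------------------------------------------------------------------
# fixture sets


def _replicate_config(config: SimulationConfig, preset_name: str, rep: int) -> SimulationConfig:
    seed = int(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(100 + _PRESET_CODE.get(preset_name, 99), rep)
        ).generate_state(1)[0]
        % 2**31
    )
    return replace(config, seed=seed)


def write_fixture_set(
    outdir: str | Path,
    config: SimulationConfig,
    presets: Iterable[GenotypePreset | str] = ("wild_type", "tfiis", "ints11_kd", "tfiis_ints11_kd"),
    n_replicates: int = 2,
    force: bool = False,
) -> dict:
    """Write a complete fixture set (genome, loci, per-sample BEDs, manifest).

    Two replicates per preset and library type by default; replicate seeds
    are derived deterministically from the config seed, so re-running with
    the manifest's seeds reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (pass force=True to overwrite)")

    genome, loci = simulate_loci(config)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 60) + "\n")
    loci_bed = outdir / "loci.bed"
    write_loci_bed(loci, loci_bed)

    samples = []
    for preset in presets:
        preset = _get_preset(preset)
        for rep in range(1, n_replicates + 1):
            rep_cfg = _replicate_config(config, preset.name, rep)
            stem = f"{preset.name}_rep{rep}"

            capped_files = {}
            for comp in ("chromatin", "nucleoplasm"):
                path = outdir / f"{stem}_capped_{comp}.bed"
                write_reads_bed(simulate_capped_reads(loci, rep_cfg, preset, comp), path)
                capped_files[comp] = path.name
            samples.append(
                {
                    "sample": f"{stem}_capped",
                    "preset": preset.name,
                    "replicate": rep,
                    "library": "capped_short",
                    "seed": rep_cfg.seed,
                    "files": capped_files,
                }
            )

            path = outdir / f"{stem}_5p.bed"
            write_reads_bed(simulate_5p_reads(loci, rep_cfg, preset), path)
            samples.append(
                {
                    "sample": f"{stem}_5p",
                    "preset": preset.name,
                    "replicate": rep,
                    "library": "fivep_small",
                    "seed": rep_cfg.seed,
                    "files": {"reads": path.name},
                }
            )

            path = outdir / f"{stem}_cage.bed"
            write_reads_bed(simulate_cage_pairs(loci, rep_cfg, preset), path)
            samples.append(
                {
                    "sample": f"{stem}_cage",
                    "preset": preset.name,
                    "replicate": rep,
                    "library": "cage",
                    "seed": rep_cfg.seed,
                    "files": {"reads": path.name},
                }
            )

    manifest = {
        "genome": fasta.name,
        "loci": loci_bed.name,
        "seed": config.seed,
        "n_loci": config.n_loci,
        "samples": samples,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
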