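# Methods

## Coordinate conventions

All coordinates are BED-style 0-based half-open. A piRNA locus is
anchored at `u5_pos`, the genomic position of the mature 21U-RNA first
nucleotide (a uridine, hence a T on the sense strand); the precursor TSS
is exactly 2 nt upstream on the locus strand. Windowed operations work in
strand-aware *offset frames*: offset 0 at the reference nucleotide (TSS
or 5′U), increasing downstream. A read's "3′ offset" is its half-open end
in offset space, so `length = three_off − five_off` holds identically and
the cleavage arithmetic is internally consistent (5′ at +38, 3′ at +58,
length 20). The u5 frame equals the tss frame minus 2 everywhere. The
default frame is tss; every windowed operation takes an explicit frame
parameter because published figure conventions for the fragment window
mix the two frames, and the package deliberately exposes frame + window
as configuration rather than resolving that ambiguity.

## Termination-signal score

The signal associated with promoter-proximal pausing is an AT-rich
(low melting temperature) region downstream of the 21U-RNA. The package
scores it as the sense-strand A/T fraction over a configurable window,
default tss-frame [0, 50) (the whole short transcription unit), with
[27, 52) as the downstream-only alternative. The A/T fraction is a
monotone surrogate for melting temperature that requires no thermodynamic
tables and is invariant under reverse complementation, which the test
suite checks. Percentile bins of the score are equal-sized by
construction: loci are rank-ordered (ties broken stably by input order,
so tied scores at a boundary divide across bins); the degenerate
all-identical case collapses to one bin with a warning.

## The simulator

`synthetic_data` generates data with the statistical structure of the
two-pause / Integrator-cleavage model, not a kinetic simulation: lengths
and offsets are rounded draws from Normal mixtures, which is sufficient
to give every pipeline stage the structure it assumes. Defaults define
the simulated study conditions and were chosen once:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 2000 | reduced-scale stand-in for the >15,000 clustered loci |
| `frac_motif_dependent` | 0.8 | fraction of loci with the upstream GTTTC motif |
| `peak1_pos`, `peak1_sd` | 28 nt, 1.5 | first Pol II pause (release) component |
| `peak2_pos`, `peak2_sd` | 48 nt, 1.5 | second pause component |
| `p_pause2_base` | 0.25 | pause-2 weight at the central signal score (0.75/0.25 split) |
| `signal_coupling` | −5 | slope of pause-2 log-odds in the centred signal score |
| `cleavage5_mu/sd`, `cleavage3_mu/sd` | 38/1.5, 58/1.5 nt | cleavage-fragment 5′/3′ offsets (median length 20 nt) |
| `fragment_rate` | 0.8 | P(detectable 5′P fragment \| pause-2 event) |
| `reads_per_locus_mean` | 30 | ≈60,000 chromatin reads; ≈23,000 distinct (locus, length) sequences, so 3,000-sequence subsamples stay far from saturation |
| `readthrough_frac` | 0.01 | wild-type CAGE-emitting fraction of motif-dependent loci |
| `cage_indep_frac` | 0.45 | CAGE-emitting fraction of motif-independent loci |
| `unannot_21u_frac` | 0.05 | loci with a planted unannotated 21U start within ±5 nt |
| `zipf_exponent` | 2.25 | per-CTSS tag counts (reverse-cumulative exponent 1.25) |

The pause-2 probability is logistic:
`logit p = logit(p_pause2_base) + signal_coupling · (score − signal_center)`
with `signal_center = 0.6`, the midpoint of the simulated score range
[0.2, 1.0]. Centring makes `p_pause2_base` interpretable as the mixture
weight of a typical locus while preserving the negative coupling between
signal strength and pause-2 progression (hence cleavage-fragment yield).

Genotype presets: `wild_type` is the identity. `tfiis` shifts the pauses
+2/+3 nt, multiplies fragment yield by 0.4 and chromatin abundance by
1.5. `ints11_kd` multiplies fragment yield by 0.2 and abundance by 0.6,
extends an upper tail of precursor lengths (15% of reads drawn uniform up
to 75 nt) and raises readthrough 3.6-fold (to 3.6% of motif-dependent
loci). `tfiis_ints11_kd` combines both. Directions and approximate
magnitudes mirror the corresponding mutant observations.

Planted genome structure: each motif-dependent locus carries GTTTC at
tss-frame offset −45; the signal window's A/T fraction is planted to
match a target score drawn uniform on [0.2, 1.0] (a T is forced at the
5′U and at any planted unannotated start), so recomputing the score from
the emitted FASTA reproduces the generator's intent exactly. All
randomness derives from the single config seed through purpose-keyed
`SeedSequence` streams, so individual library types are reproducible in
isolation and fixture sets are byte-stable.

What the simulator does **not** model: sequencing error, quality scores,
multi-mapping, UMI duplication, polymerase kinetics beyond the
two-outcome mixture, chromatin context, or any correlation structure
between neighbouring loci. Passing tests therefore demonstrate that the
pipeline recovers the parameters of data with the assumed structure; they
do not validate the biological model itself against real libraries.

## Weighted bootstrap peak localization

Distinct precursor sequences (operationally: distinct (locus, length)
pairs, since all precursors of a locus share its 5′ end) are resampled
without replacement with inclusion probability increasing in read count,
implemented by exponential-keys sampling (keys `log U / w`, take the top
`n_sample`), which is distributionally identical to successive draws with
renormalization; an enumeration oracle verifies this on tiny populations.
Each resample of 3,000 sequences is smoothed with a Gaussian kernel
density evaluated on a 0.1-nt grid extended 3 bandwidths past the data;
the two strict local maxima with greatest density are retained, ordered
by position. Numerical choices:

- **Bandwidth** defaults to Silverman's rule with a floor of 1.0 nt.
  Lengths are integer-valued, and kernels narrower than the lattice
  spacing produce spurious integer-spaced ripples; the floor suppresses
  them while leaving the well-separated 28/48 modes untouched. Bandwidth
  is overridable, and peak positions are stable across bandwidths 1–3 nt
  in the test suite.
- A second maximum below 1% of the first is treated as a smoothing
  artifact (single-peaked resample); such resamples contribute nothing to
  the peak-2 distribution.
- Degenerate all-equal input yields a single peak at that value.

Default bootstrap size is 2,000 resamples; the acceptance runs use 200,
which already pins the peak medians to within ±0.05 nt at the simulated
depth.

## Precursor quantification

Precursor assignment demands an exact 5′-end match to the TSS (a slack
parameter exists, default 0). Median-of-ratios size factors are computed
from features with nonzero counts in all samples (single-sample tables
get factor 1). Fold changes use mean normalized counts per condition with
a +1 pseudocount, keeping loci whose mean normalized count across all
samples exceeds 5. The non-structural-read denominator takes the
structural-RNA exclusion list as an input interval set, never hard-coded.
Uniquely mapped input is assumed throughout.

## Length statistics

Medians use the numpy midpoint convention uniformly (even-sized samples
average the two central values); read-weighted statistics expand values
by their counts first. A single convention for both weightings keeps the
sequence-median of a two-species locus at the midpoint, matching the
hand-checked examples in the test suite. The trimming analysis bins loci
by the fraction of chromatin-bound reads longer than 38 nt, with
equal-width bins on [0, 1] (bin count configurable, default 5 — no
published bin count exists for this analysis).

## Cleavage-fragment pipeline

The filter cascade order is fixed: annotated mature removal → unannotated
21U detection → unannotated removal → profiling/collection; the suite
asserts each stage only removes reads. Mature removal discards reads
longer than 15 nt initiating exactly at a 5′U. Unannotated 21U detection
requires length-21 reads with total multiplicity ≥ 2 (configurable)
initiating within ±5 nt of an annotated 5′U on a genomic sense-strand T.
The multiplicity threshold is a total read count: with alignments
collapsed per unique interval, a 21-mer at a fixed position is a single
record, so "distinct reads" would be vacuous. Fragments are collected
with no minimum length. The per-bin detection trend is tested by
Spearman rank correlation between bin index and detected-locus count,
with a locus-level permutation null (locus-to-bin assignments shuffled,
bin sizes preserved): permuting loci rather than the five bin labels
gives the test resolution when detection saturates in the weak-signal
bins and ties their counts.

## CAGE analysis

Power-law normalization fits log reverse-cumulative count against log
count by least squares over distinct counts in the fit range (default
[5, 1000], needing ≥ 5 support points) and maps counts onto a reference
law with `alpha_ref = 1.25` scaled to 10⁶ tags
(`c_ref = total_ref·(alpha_ref−1)/alpha_ref`). The transform is strictly
monotone (rank-preserving) and reduces to a pure rescaling when the
fitted exponent equals the reference. The unweighted log-log fit is
tail-noisy at small sample sizes (the exponent is recovered to ±0.1 from
~20,000 heavy-tailed counts, with a mild downward bias below that); no
acceptance-grade quantity depends on the reference parameters, which are
recorded in the fit metadata. Replicates are merged by summing raw counts
before normalization. Fold changes at the −2 position include loci
nonzero in at least one condition and add 0.01 TPM to both sides.
Downsampling draws multinomial subsamples per depth (absolute counts, or
fractional floats in (0, 1] as a fraction of each library), averages
detected-locus counts across the two replicates within each of the 15
subsample indices, and errors on depths exceeding the library.
Template-free G-addition correction is out of scope; input CTSSs are
assumed pre-corrected.

## Known limitations

- The simulator's independence assumptions (per-locus Poisson depths,
  independent per-read outcomes) understate the overdispersion of real
  libraries; size-factor spread between simulated replicates is
  correspondingly small.
- "Unique sequence" ≡ (locus, length) ignores internal sequence variants
  (SNVs, untemplated additions), which real libraries contain.
- The CAGE background model plants tags at uniform random positions; it
  has no promoter architecture, so promoter-clustering analyses are out
  of scope by design.
- Peak localization reports empirical bootstrap distributions only; no
  analytic confidence intervals are attempted.
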