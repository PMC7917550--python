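# pirnaterm

Transcription-termination analysis at *Caenorhabditis elegans* piRNA loci.

*C. elegans* piRNAs (21U-RNAs) are transcribed by RNA polymerase II from
thousands of individual mini-genes: a short capped precursor initiates
exactly 2 nt upstream of the mature 21U first uridine and is terminated
within a few tens of nucleotides. This package re-implements, as a tested
and reusable pipeline, the computational analyses that characterize this
termination process:

- **Precursor quantification** — identifying short-capped reads whose 5′
  end lies exactly at the precursor TSS (u5 − 2 on the locus strand),
  count tables, median-of-ratios size factors, per-locus log₂ fold
  changes, and total-abundance ratios.
- **Length analysis** — read- and sequence-weighted length distributions,
  per-locus length statistics and shifts, binary detection matrices, and
  the chromatin-vs-nucleoplasm trimming analysis.
- **Pause-peak localization** — a weighted bootstrap: repeated subsamples
  of distinct precursor sequences drawn without replacement with
  probability proportional to read count, each smoothed with a Gaussian
  kernel density whose two dominant local maxima localize the two Pol II
  pause sites (~28 and ~48 nt downstream of the TSS).
- **Cleavage-fragment profiling** — the 5′-monophosphate filter cascade
  (mature 21U removal, unannotated-21U detection within ±5 nt and
  removal, end-offset CPM profiles, fragment collection in a +25..+50
  window) that isolates the 3′ degradation fragments left behind when the
  Integrator complex cleaves nascent precursors, plus their
  termination-signal stratification.
- **Termination-signal scoring** — windowed A/T fraction of the sense
  strand downstream of the TSS, a monotone surrogate for the low-melting-
  temperature region that promotes promoter-proximal pausing.
- **CAGE readthrough** — upstream CTSS counting at the −2 position,
  referent power-law normalization to tags-per-million, per-locus fold
  changes, paired-end fragment-length lower bounds, and detection
  saturation under multinomial downsampling.

A bundled generative simulator (`pirnaterm.synthetic_data`) emulates the
two-pause / Integrator-cleavage model — bimodal chromatin-bound precursor
lengths, unimodal nucleoplasmic lengths, genotype presets (*tfiis* pause
shifts, *ints-11* cleavage loss and readthrough), 5′P libraries with
mature 21U-RNAs, cleavage fragments and miRNA background, and
heavy-tailed CAGE counts — so every stage runs end-to-end without
external data.

## The model in brief

At a motif-dependent locus with termination-signal score *s* (A/T
fraction in a window downstream of the TSS), each initiating polymerase
reaches the second pause site with probability

σ( logit(p₂) + γ·(s − s₀) ),  γ ≤ 0,

and otherwise releases at the first pause. Pause-1 precursor lengths are
round(N(28, 1.5)); pause-2 lengths round(N(48, 1.5)). Each pause-2 event
is cleaved with probability *r*, producing a capped product of length
round(N(38, 1.5)) and a 5′P fragment spanning tss-frame offsets
round(N(38, 1.5)) to round(N(58, 1.5)) — median fragment length 20 nt.
Genotype presets reshape these parameters (e.g. *tfiis*: +2/+3 nt pause
shifts; *ints-11* knock-down: 5× fewer fragments, long precursor tail,
increased CAGE readthrough).

## Worked example

```sh
pirnaterm simulate --outdir fixtures --n-loci 300 --seed 3
# -> wrote 24 samples to fixtures   (2 replicates x 4 genotypes x 3 library types)

pirnaterm peaks --loci fixtures/loci.bed \
    --reads fixtures/wild_type_rep1_capped_chromatin.bed \
    --n-boot 50 --n-sample 1500 --seed 1 --out peaks.tsv
# -> median peak1 = 28.0 nt, median peak2 = 48.0 nt
```

The two medians are the bootstrap estimates of the two Pol II pause
positions on chromatin: the dominant ~28 nt release point, and the minor
~48 nt pause whose resolution requires Integrator cleavage.

```sh
pirnaterm fragments --loci fixtures/loci.bed \
    --reads fixtures/wild_type_rep1_5p.bed \
    --genome fixtures/genome.fa --out fragments.tsv
# -> 4 unannotated 21U sites; 2009 fragments
```

`fragments.tsv` lists each putative cleavage product with its TSS-frame
5′/3′ offsets and read count; under wild-type conditions the 5′ offsets
mode at +38, the 3′ offsets centre at +58, and the median length is
20 nt.

The same analyses are available as library functions
(`pirnaterm.peak_bootstrap.bootstrap_peaks`,
`pirnaterm.cleavage_fragments.collect_fragments`, …) for programmatic
use; see `docs/methods.md` for the underlying procedures and their
parameters.

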