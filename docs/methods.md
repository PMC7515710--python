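# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic axis.
"Downstream" is +1 bp on the `+` strand and −1 bp on `−`; every piece of
transcription-sense arithmetic goes through a single helper
(`tracks_io.downstream`). bedGraph carries no strand, so stranded tracks
are paired `*.plus.bedgraph` / `*.minus.bedgraph` files; minus-strand
values are stored at their forward-axis positions, never reversed. GFF3
(1-based closed) is converted on read and reconstructed on write so the
round trip is the identity.

## Primary TTS calling

A candidate position p for a transcription unit (TU) must satisfy, in
**every** replicate track:

* p lies 1…`window` nt downstream of the last base of the TU's stop codon
  (transcription sense; the stop codon's own bases are excluded;
  default `window` = 200);
* count(p) / count(p+1) > `ratio_min` (default 1.1, strict);
* count(p) − count(p+1) > `diff_min` (default 5, strict),

where p+1 is the next base downstream in transcription sense. The primary
TTS is the candidate maximising the summed −1/+1 difference across
replicates; at most one call is made per TU. Design choices where more
than one convention was defensible:

* **Replicate handling.** "Occurred in both replicates" is read strictly:
  the ratio and difference criteria must hold in each replicate
  individually, not merely show nonzero signal. The stricter reading
  suppresses one-library artefacts at some cost in sensitivity.
* **Zero +1 count.** The ratio is taken as +∞ (the criterion passes).
  This avoids pseudocounts, which would silently shift the absolute
  difference threshold.
* **Ties.** Equal summed differences resolve to the candidate closest to
  the stop codon, then the smallest forward coordinate — the shortest
  3′-UTR is the conservative primary isoform.
* The window is truncated (and the call flagged) at contig ends.

The ratio criterion is invariant under uniform scaling of all replicates;
the absolute-difference criterion deliberately is not — it is the floor
that keeps low-coverage noise from producing calls. Relaxing `diff_min`
can therefore only add called TUs, never remove them (tested).

## Terminator PFM and metaplot

PFM windows span −`upstream`…−1, +1…+`downstream` around the call (−1 *is*
the TTS; there is no position 0), taken in transcription sense
(reverse-complemented on `−`). The default (−30, +10) window comfortably
contains the ~23-nt U-rich tract that archaeal terminators show. Windows
crossing a contig edge (or containing N) are excluded and counted, so
every PFM column sums to `n_sequences` exactly.

The metaplot averages raw 3′-end counts per relative position
(−21…−1, +1…+20; 41 positions) over all calls and normalises by the −21
value; a zero at −21 is a hard error rather than a silent NaN. The
decrease statistic is 1 − normalized[+2]/normalized[−2]: ≈1 for clean
termination, ≤0 for read-through.

## U-tract counting

U-tracts are counted as **maximal** runs of ≥ n consecutive sense-strand
T (n = 5, 6, 7): a 7-T run contributes once to each of the U5/U6/U7
columns and is never decomposed into overlapping k-mers, which keeps the
columns interpretable and anti-monotone in n. `N` breaks a run. The
upstream window ends at the stop codon's last base (the stop codon belongs
to the gene-body side); the downstream window starts immediately after.
Downstream enrichment is tested with a two-sided exact binomial test of
the pooled downstream count against half the pooled total — a deliberate
minimal choice; no overlap masking of downstream genes is attempted, so in
dense genomes the downstream window can include the next ORF's start.

## TRT quantification and typing

FPKM uses the whole-track total mapped fragments as denominator, with
fragments inferred from coverage as sum(coverage)/read_length. Replicate
FPKMs are averaged within condition *before* the index is formed. The
index is NA — never pseudocounted — when any denominator FPKM is zero, so
every reported value is exactly the ratio-of-ratios formula; NA reasons
are kept. Note that per-feature FPKM *folds* between conditions carry the
depth-normalisation ratio of the two tracks, while the TRT index cancels
it exactly (tested as an invariance).

Typing has no universally stated operational rule, so one is defined
here: the read-through span is the maximal contiguous run downstream of
the TTS with depleted coverage ≥ `alpha` × the source TU's mean depleted
body coverage (`alpha` = 0.2); the first annotated TU the span reaches
with ≥ `min_overlap` bp overlap (25 bp) decides the label, mirroring the
notion of a transcript "extending into" a feature. Both knobs are exposed
on the CLI. Expression ranks round FPKM to the nearest integer and bin at
≤42 / 43–103 / 104–214 / 215–573 / >573, closing the printed gaps so the
bins partition [0, ∞).

## Half-life and qPCR

The default half-life method is `linear` (percent vs time, t½ where the
fitted line crosses 50%) because decay curves are conventionally read off
a linear regression plot; `log_linear` (ln percent vs time,
t½ = −ln2/slope) is the statistically natural model for first-order decay
and is what the recovery tests use. Non-decaying series return NA with a
reason instead of a negative half-life. Bulk time-courses subtract a
stable-RNA baseline before normalising the t = 0 remainder to 100%.
The qPCR fold is exactly 2^(−ΔΔCt); the input-Ct dilution adjustment is
caller-supplied, with an optional helper `adj = Ct − log2(dilution)`.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
transcription mechanism:

| parameter | default | meaning |
|---|---|---|
| `n_tus` | 200 | TUs, alternating strands |
| `tu_length_range` | 400–1200 bp | TU lengths |
| `igr_length_range` | 100–300 bp | intergenic gaps |
| `u_tract_length_range` | 5–8 nt | planted T-run ending at the true TTS |
| `tts_dist_range` | 20–180 nt | TTS distance past the stop codon |
| `termination_efficiency` | wt 0.9 / depleted 0.3 | fraction of transcripts ending at the TTS |
| `readthrough_decay` | 0.95 | geometric continuation of the 3′-end tail |
| `body_end_rate` | 0.02 /base | within-body 3′-end capture (degradation/processing background) |
| `background` | 0.05 /base | uniform genomic 3′-end noise |
| `depth` | 120 000 | expected transcript-derived 3′-end reads per track |
| `readthrough_fraction` | wt 0.12 / depleted 0.40 | IGR coverage as fraction of body |
| `body_fold` | wt 1.0 / depleted 1.2 | condition shift of body coverage |
| `coverage_depth`, `coverage_decay_tau` | 50×, 300 nt | body coverage scale, IGR decay length |

Expression is log-normal (sdlog 0.5); all counts are Poisson. Per-TU
intensities are scaled so the expected transcript-derived track total
equals `depth`; with the default geometry this puts the mean TTS pile-up
near 30–35 reads, enough for the calling criteria to be comfortably but
not trivially satisfiable. The within-body 3′-end background matters: it
is what gives the wild-type metaplot its upstream plateau, so that high
termination efficiency produces a >50% −2/+2 drop while a depleted
condition (efficiency 0.3) shows a negative one. The depleted
read-through fractions were chosen so the raw IGR coverage fold
(0.40 × 1.2 / 0.12 = 4) and body fold (1.2) bracket a median TRT index of
10/3. One RNG stream is derived per (track kind, condition, replicate)
from the master seed, so adding replicates never perturbs existing
tracks, and a fixed seed reproduces every file byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real libraries: fragment-level read simulation and
sequencing error, mappability artefacts, rRNA contamination, operon
structure beyond single-TTS TUs, secondary/alternative termination sites,
hairpin structure, and real expression covariance. Headline fractions
measured on real data (e.g. what share of TUs are read-through positive
in a depletion strain) depend on those properties and on external
aligner/quantifier choices; the synthetic pipeline validates the
*computations*, recovery behaviour, and invariances, not those published
magnitudes.

## Problem sizes

Defaults throughout target desk-scale validation: 200-TU genomes
(~180 kb), two conditions × two replicates, 100-seed Monte-Carlo loops
for the assay fits. The full test suite runs in well under a minute, and
`scripts/acceptance.py` in a few seconds.
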