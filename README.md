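# archterm

Tools for analysing transcription **termination** in compact prokaryotic
(especially archaeal) genomes from strand-specific sequencing tracks:

* **Primary TTS calling** from Term-seq 3′-end counts. Term-seq captures
  exact transcript 3′ ends, so a termination site appears as a sharp
  per-base pile-up. A site is called when, in **every** replicate, it lies
  within 200 nt downstream of the stop codon, the −1/+1 read ratio exceeds
  1.1, and the −1 minus +1 difference exceeds 5; among qualifying positions
  the one with the highest cross-replicate summed difference wins.
* **Terminator motif characterisation**: position frequency matrices and
  per-position U fractions around called TTSs, and counts of maximal
  U5/U6/U7 tracts (runs of ≥5/6/7 uridines, i.e. sense-strand T) in
  200-nt windows flanking stop codons, with an exact binomial test of
  downstream enrichment.
* **TTS metaplots**: mean 3′-end reads at −21…−1, +1…+20 around all called
  TTSs, normalised to the −21 position, and the −2/+2 decrease statistic
  that separates termination (large positive decrease) from read-through
  (small or negative).
* **Transcription read-through (TRT) analysis** between a wild-type and a
  termination-factor-depleted condition. With FPKM = fragments per kb of
  feature per million mapped fragments, each transcription unit (TU) and
  its downstream co-directional intergenic region (IGR) yield

  ```
  TRT_index = (FPKM_IGR^dep / FPKM_IGR^wt) / (FPKM_TU^dep / FPKM_TU^wt)
  ```

  A TU is read-through positive when TRT_index > 1 (strong when > 2), and
  events are typed by where depleted-condition coverage extends past the
  TTS: a convergent antisense TU (type I), the tandem co-directional TU
  (type II), only the IGR (type III), or — for a non-coding source RNA —
  the downstream TU (type IV).
* **Assay math**: mRNA half-life regression (linear and log-linear, with
  stable-RNA baseline subtraction for bulk time-courses) and ChIP-qPCR
  enrichment folds via 2^(−ΔΔCt).
* A **synthetic-data generator** that produces genomes, TU annotations with
  planted U-tract terminators, and replicate-structured Term-seq/coverage
  tracks with Poisson noise and known ground truth, so the whole pipeline
  can be exercised and validated without any external data.

Inputs are plain standard formats: FASTA, GFF3/BED6, paired plus/minus
bedGraphs, FASTQ; outputs are TSV/BED/JSON tables.

## Worked example

```sh
archterm run-all --seed 42 --out demo/
```

simulates the default study (200 TUs, wild-type vs depleted at termination
efficiencies 0.9 vs 0.3, 2 replicates each) and runs every stage. The run
report (`demo/run_report.json`) contains, among other numbers:

```
"call_tts": {"n_calls": 195}
"metaplot": {"tts_decrease": {"wt": 0.630, "depleted": -1.086}}
"trt":      {"pct_trt": 100.0, "median_igr_fold": 3.03, "median_body_fold": 0.91}
```

Reading these: 195 of 200 TUs received a primary TTS call from the
wild-type tracks (the misses are low-expression TUs whose −1/+1 difference
cannot clear the absolute threshold). Across the TTS the wild-type
metaplot drops by 63% between −2 and +2 — termination — while the depleted
profile *rises* (−109%), the read-through signature. Every TU is TRT
positive because the generator plants a genuine condition-dependent
read-through increase in every IGR; the IGR fold (3.0) exceeds the TU-body
fold (0.9), and their ratio is the median TRT index (≈3.3), which is
invariant to sequencing-depth normalisation by construction.

The same objects are available as a library:

```python
import archterm as at

ds = at.simulate_dataset(at.SimulationConfig(seed=42, n_tus=200))
calls = at.call_primary_tts([ds.termseq[("wt", r)] for r in range(2)], ds.tus)
pfm = at.extract_terminator_pfm(calls, ds.genome)
print(len(calls), pfm.t_fraction[pfm.positions.index(-1)])  # 195 1.0
```

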