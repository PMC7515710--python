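"""Synthetic genomes, TU annotations and read tracks with known ground truth.

The generator emulates the statistical structure that the termination-site
caller and the read-through (TRT) pipeline assume:

* transcription units (TUs) laid out on alternating strands with intergenic
  gaps, each ending in a stop codon followed by a planted sense-strand
  uridine tract (T-run on DNA) whose last base is the true TTS;
* Term-seq 3'-end count tracks: a pile-up at the true TTS with per-condition
  termination efficiency ``eff`` < 1, a geometric read-through tail
  downstream, a low within-body 3'-end background proportional to
  expression, and a uniform genomic background — all Poisson;
* coverage tracks: body-level coverage over the transcript plus
  condition-dependent read-through into the IGR decaying exponentially;
* replicate structure with one named RNG stream per
  (track kind, condition, replicate), so adding replicates never perturbs
  existing tracks;
* small decay time-courses for the half-life assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks_io import (GenomeSequence, StrandedTrack, TranscriptionUnit,
                        downstream, revcomp, write_annotation, write_fasta,
                        write_stranded_bedgraph)

TRUTH_COLUMNS = ["tu_id", "chrom", "strand", "true_tts", "u_len",
                 "eff_wt", "eff_dep", "rt_wt", "rt_dep", "abundance"]

# RNG stream tags (kept stable so seeds reproduce across versions)
_STREAM_GENOME = 0
_STREAM_TERMSEQ = 1
_STREAM_COVERAGE = 2
_STREAM_DECAY = 3


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` fixes every draw.

    Defaults describe a compact archaeal-like genome: a few hundred TUs of
    0.4-1.2 kb with 100-300 bp intergenic gaps, log-normal expression, high
    wild-type termination efficiency (0.9) dropping to 0.3 when the
    termination factor is depleted, and read-through fractions chosen so the
    depleted/wild-type IGR coverage fold is ~4 while TU bodies shift ~1.2x.
    """

    seed: int = 0
    n_tus: int = 200
    chrom_length: int | None = None  # computed from the layout when None
    chrom_name: str = "chr1"
    tu_length_range: tuple[int, int] = (400, 1200)
    igr_length_range: tuple[int, int] = (100, 300)
    tts_dist_range: tuple[int, int] = (20, 180)  # TTS distance past stop codon
    u_tract_length_range: tuple[int, int] = (5, 8)
    expression_meanlog: float = 0.0
    expression_sdlog: float = 0.5
    conditions: tuple[str, str] = ("wt", "depleted")
    termination_efficiency: dict = field(
        default_factory=lambda: {"wt": 0.9, "depleted": 0.3})
    readthrough_fraction: dict = field(
        default_factory=lambda: {"wt": 0.12, "depleted": 0.40})
    body_fold: dict = field(default_factory=lambda: {"wt": 1.0, "depleted": 1.2})
    depth: float = 120000.0          # expected Term-seq 3'-end reads per track
    replicates: int = 2
    readthrough_decay: float = 0.95  # geometric continuation prob of the 3'-end tail
    tail_cutoff: int = 60            # bases of explicit 3'-end tail
    body_end_rate: float = 0.02      # within-body 3'-end capture, fraction of TU reads/base
    background: float = 0.05         # uniform 3'-end background, expected counts/base
    coverage_depth: float = 50.0     # mean body coverage of an average TU
    coverage_decay_tau: float = 300.0  # nt, exponential IGR coverage decay
    noise: str | None = "poisson"
    read_length: int = 150
    noncoding_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tus < 1:
            raise ValueError("n_tus must be >= 1")
        for name, p in [("termination_efficiency", self.termination_efficiency),
                        ("readthrough_fraction", self.readthrough_fraction)]:
            for cond, v in p.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{cond}]={v} outside [0,1]")
        if not 0.0 < self.readthrough_decay < 1.0:
            raise ValueError("readthrough_decay must be in (0,1)")
        if self.noise not in (None, "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def condition_index(self, condition: str) -> int:
        return list(self.conditions).index(condition)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), *map(int, stream)])


def _draw(rng: np.random.Generator, mean: np.ndarray | float,
          config: SimulationConfig) -> np.ndarray:
    if config.noise == "poisson":
        return np.asarray(rng.poisson(mean), dtype=float)
    return np.asarray(mean, dtype=float) + 0.0


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeSequence, list[TranscriptionUnit], pd.DataFrame]:
    """Generate a genome with TUs on alternating strands and a planted
    T-run (RNA U-tract) ending at each TU's true TTS.

    Returns (genome, tus, truth) where ``truth`` is a DataFrame with one
    row per TU (true TTS, planted tract length, per-condition efficiencies
    and read-through fractions, relative abundance).
    """
    rng = _rng(config, _STREAM_GENOME)
    margin = 300
    tu_lo, tu_hi = config.tu_length_range
    igr_lo, igr_hi = config.igr_length_range

    # layout first, so a fixed chrom_length can be validated up front
    starts, lengths = [], []
    cursor = margin
    for _ in range(config.n_tus):
        length = int(rng.integers(tu_lo, tu_hi + 1))
        starts.append(cursor)
        lengths.append(length)
        cursor += length + int(rng.integers(igr_lo, igr_hi + 1))
    needed = starts[-1] + lengths[-1] + margin
    chrom_length = config.chrom_length or needed
    if chrom_length < needed:
        raise ValueError(
            f"chrom_length {chrom_length} too short for {config.n_tus} TUs "
            f"(need >= {needed})"
        )

    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_length)
    seq = np.char.decode(seq)

    tus: list[TranscriptionUnit] = []
    rows = []
    eff = config.termination_efficiency
    rt = config.readthrough_fraction
    abundance = rng.lognormal(config.expression_meanlog,
                              config.expression_sdlog, size=config.n_tus)
    u_lo, u_hi = config.u_tract_length_range
    d_lo, d_hi = config.tts_dist_range
    for i, (start, length) in enumerate(zip(starts, lengths)):
        strand = "+" if i % 2 == 0 else "-"
        end = start + length
        u_len = int(rng.integers(u_lo, u_hi + 1))
        dist = int(rng.integers(max(d_lo, u_len + 1), d_hi + 1))
        noncoding = bool(rng.random() < config.noncoding_fraction)
        if strand == "+":
            tts = end - 1
            sce = tts - dist
            seq[sce - 2:sce + 1] = list("TAA")
            seq[tts - u_len + 1:tts + 1] = "T"
        else:
            tts = start
            sce = tts + dist
            seq[sce:sce + 3] = list("TTA")      # revcomp of sense TAA
            seq[tts:tts + u_len] = "A"          # revcomp of sense T-run
        tus.append(TranscriptionUnit(
            f"TU{i:04d}", config.chrom_name, strand, start, end,
            stop_codon_end=sce, tts=tts, is_noncoding=noncoding))
        rows.append({"tu_id": f"TU{i:04d}", "chrom": config.chrom_name,
                     "strand": strand, "true_tts": tts, "u_len": u_len,
                     "eff_wt": eff["wt"], "eff_dep": eff["depleted"],
                     "rt_wt": rt["wt"], "rt_dep": rt["depleted"],
                     "abundance": abundance[i]})
    genome = GenomeSequence({config.chrom_name: "".join(seq)})
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return genome, tus, truth


# ---------------------------------------------------------------------------
# Term-seq 3'-end tracks
# ---------------------------------------------------------------------------

def _condition_column(condition: str) -> str:
    return {"wt": "eff_wt", "depleted": "eff_dep"}[condition]


def simulate_termseq(genome: GenomeSequence, tus: list[TranscriptionUnit],
                     truth: pd.DataFrame, condition: str, replicate: int,
                     config: SimulationConfig) -> StrandedTrack:
    """One replicate of strand-specific per-base 3'-end counts.

    Per-TU intensities ``lam`` are proportional to abundance and scaled so
    the expected transcript-derived total over the track equals ``depth``
    (the uniform genomic background adds on top).  Per TU:

    * at the true TTS: Poisson(lam * (eff + beta)),
    * d bases downstream: Poisson(lam * (1-eff) * ((1-p) p^(d-1) + beta p^d))
      — the geometric termination tail of read-through polymerases plus
      their within-body capture background,
    * inside the body: Poisson(lam * beta) per base,
    * everywhere: a uniform Poisson background.

    beta = ``body_end_rate``, p = ``readthrough_decay``.
    """
    rng = _rng(config, _STREAM_TERMSEQ, config.condition_index(condition), replicate)
    track = StrandedTrack(genome.lengths, kind="three_prime_end",
                          label=f"{condition}_rep{replicate}")
    share = truth["abundance"].to_numpy()
    eff_all = truth[_condition_column(condition)].to_numpy()
    truth_tts = dict(zip(truth["tu_id"], truth["true_tts"]))
    p = config.readthrough_decay
    beta = config.body_end_rate
    D = config.tail_cutoff
    # expected reads per unit lam, so total transcript-derived reads == depth
    n_body_all = np.array([abs(truth_tts[tu.tu_id] - tu.tss) for tu in tus])
    tail_total = (1 - eff_all) * ((1 - p ** D) * (1 + beta * p / (1 - p)))
    per_lam = beta * n_body_all + eff_all + beta + tail_total
    lam_all = config.depth * share / float((share * per_lam).sum())
    for tu, lam, eff in zip(tus, lam_all, eff_all):
        arr = track.get(tu.chrom, tu.strand)
        tts = truth_tts[tu.tu_id]
        # body background (TSS .. TTS-1 in sense)
        if tu.strand == "+":
            body = slice(tu.tss, tts)
        else:
            body = slice(tts + 1, tu.tss + 1)
        n_body = body.stop - body.start
        if n_body > 0:
            arr[body] += _draw(rng, np.full(n_body, lam * beta), config)
        arr[tts] += _draw(rng, lam * (eff + beta), config)
        d = np.arange(1, config.tail_cutoff + 1)
        tail_mean = lam * (1 - eff) * ((1 - p) * p ** (d - 1) + beta * p ** d)
        tail_counts = _draw(rng, tail_mean, config)
        for dist, c in zip(d, tail_counts):
            pos = downstream(tts, tu.strand, int(dist))
            if 0 <= pos < arr.size:
                arr[pos] += c
    if config.background > 0:
        for key, arr in track.values.items():
            arr += _draw(rng, np.full(arr.size, config.background), config)
    return track


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def simulate_coverage(genome: GenomeSequence, tus: list[TranscriptionUnit],
                      truth: pd.DataFrame, condition: str,
                      config: SimulationConfig,
                      replicate: int = 0) -> StrandedTrack:
    """One replicate of strand-specific per-base coverage.

    Body coverage over [TSS, TTS] scales with TU abundance and the
    per-condition body fold; downstream of the TTS coverage equals
    ``body * readthrough_fraction(condition) * exp(-(d-1)/tau)``.
    """
    rng = _rng(config, _STREAM_COVERAGE, config.condition_index(condition), replicate)
    track = StrandedTrack(genome.lengths, kind="coverage",
                          label=f"{condition}_rep{replicate}")
    share = truth["abundance"].to_numpy()
    body_all = config.coverage_depth * share / share.mean()
    body_all = body_all * config.body_fold[condition]
    rt_col = {"wt": "rt_wt", "depleted": "rt_dep"}[condition]
    rt_all = truth[rt_col].to_numpy()
    truth_tts = dict(zip(truth["tu_id"], truth["true_tts"]))
    tau = config.coverage_decay_tau
    for tu, body, rt in zip(tus, body_all, rt_all):
        arr = track.get(tu.chrom, tu.strand)
        span = min(int(6 * tau), arr.size)
        tts = truth_tts[tu.tu_id]
        if tu.strand == "+":
            sl = slice(tu.tss, tts + 1)
        else:
            sl = slice(tts, tu.tss + 1)
        arr[sl] += _draw(rng, np.full(sl.stop - sl.start, body), config)
        if rt > 0:
            d = np.arange(1, span + 1)
            mean = body * rt * np.exp(-(d - 1) / tau)
            mean = mean[mean >= 1e-3]
            vals = _draw(rng, mean, config)
            if tu.strand == "+":
                lo = tts + 1
                hi = min(lo + vals.size, arr.size)
                arr[lo:hi] += vals[:hi - lo]
            else:
                hi = tts  # exclusive
                lo = max(hi - vals.size, 0)
                arr[lo:hi] += vals[:hi - lo][::-1]
    return track


# ---------------------------------------------------------------------------
# Decay time-courses
# ---------------------------------------------------------------------------

def simulate_decay(t_half: float, times: list[float], noise_sd: float = 0.0,
                   seed: int = 0) -> list[tuple[float, float]]:
    """Percent-remaining time series for exponential decay with half-life
    ``t_half`` (minutes), Gaussian noise, clipped at 0."""
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    rng = np.random.default_rng([int(seed), _STREAM_DECAY])
    out = []
    for t in times:
        pct = 100.0 * 2.0 ** (-t / t_half)
        if noise_sd > 0:
            pct += rng.normal(0.0, noise_sd)
        out.append((float(t), max(pct, 0.0)))
    return out


# ---------------------------------------------------------------------------
# Dataset bundle / file output
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    tus: list[TranscriptionUnit]
    truth: pd.DataFrame
    termseq: dict[tuple[str, int], StrandedTrack]   # (condition, replicate)
    coverage: dict[tuple[str, int], StrandedTrack]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full study design: genome + annotation + per
    condition/replicate Term-seq and coverage tracks."""
    genome, tus, truth = simulate_genome(config)
    termseq, coverage = {}, {}
    for cond in config.conditions:
        for rep in range(config.replicates):
            termseq[(cond, rep)] = simulate_termseq(
                genome, tus, truth, cond, rep, config)
            coverage[(cond, rep)] = simulate_coverage(
                genome, tus, truth, cond, config, replicate=rep)
    return SimulatedDataset(config, genome, tus, truth, termseq, coverage)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write FASTA/GFF3/truth TSV and paired bedGraphs; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    write_fasta(ds.genome, outdir / "genome.fasta")
    manifest["genome"] = "genome.fasta"
    write_annotation(ds.tus, outdir / "tus.gff3")
    manifest["annotation"] = "tus.gff3"
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                    float_format="%.6g")
    manifest["truth"] = "truth.tsv"
    for (cond, rep), track in ds.termseq.items():
        stem = f"termseq_{cond}_rep{rep}"
        write_stranded_bedgraph(track, outdir / f"{stem}.plus.bedgraph",
                                outdir / f"{stem}.minus.bedgraph")
        manifest[stem] = f"{stem}.{{plus,minus}}.bedgraph"
    for (cond, rep), track in ds.coverage.items():
        stem = f"coverage_{cond}_rep{rep}"
        write_stranded_bedgraph(track, outdir / f"{stem}.plus.bedgraph",
                                outdir / f"{stem}.minus.bedgraph")
        manifest[stem] = f"{stem}.{{plus,minus}}.bedgraph"
    return manifest
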