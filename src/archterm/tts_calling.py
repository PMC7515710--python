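"""Primary TTS calling from replicate Term-seq 3'-end tracks.

A primary transcription termination site is called per TU from strand-specific
3'-end counts using four criteria: (i) the site lies within a fixed window
(default 200 nt) downstream of the TU's stop codon; (ii) the -1 site (the
candidate TTS) to +1 site (1 nt downstream) read ratio exceeds 1.1; (iii) the
-1 minus +1 read difference exceeds 5; (iv) among positions satisfying (ii)
and (iii) in EVERY replicate, the one with the highest summed -1/+1 difference
across replicates wins.  Ties go to the position closest to the stop codon
(the shortest, most conservative 3'-UTR), then to the smallest forward-axis
coordinate.

The module also extracts terminator windows into a position frequency matrix
(PFM) and computes the TTS metaplot (-21..-1, +1..+20; no position 0; -1 is
the TTS) normalized to the -21 position, with the -2/+2 decrease statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracks_io import (GenomeSequence, StrandedTrack, TranscriptionUnit,
                        downstream, revcomp)

BASES = "ACGT"


@dataclass
class TTSCall:
    """A called primary TTS with its per-replicate -1/+1 evidence."""

    tu_id: str
    chrom: str
    strand: str
    tts_pos: int          # genomic bp of the -1 site
    dist_to_stop: int     # nt downstream of the stop codon's last base
    minus1_counts: list[float]
    plus1_counts: list[float]
    window_truncated: bool = False

    @property
    def ratios(self) -> list[float]:
        return [m / p if p > 0 else float("inf")
                for m, p in zip(self.minus1_counts, self.plus1_counts)]

    @property
    def diffs(self) -> list[float]:
        return [m - p for m, p in zip(self.minus1_counts, self.plus1_counts)]

    @property
    def score(self) -> float:
        return float(sum(self.diffs))

    # BED-style interval accessors so calls can be written with write_bed
    @property
    def start(self) -> int:
        return self.tts_pos

    @property
    def end(self) -> int:
        return self.tts_pos + 1


@dataclass
class PositionFrequencyMatrix:
    """Base counts per position relative to the TTS (no position 0;
    -1 is the TTS itself).  Rows are A/C/G/T."""

    positions: list[int]
    counts: np.ndarray           # shape (4, n_positions), ints
    n_sequences: int
    n_excluded: int = 0

    @property
    def t_fraction(self) -> np.ndarray:
        return self.counts[BASES.index("T")] / max(self.n_sequences, 1)

    def column(self, position: int) -> np.ndarray:
        return self.counts[:, self.positions.index(position)]


@dataclass
class MetaplotProfile:
    """Average 3'-end reads at -21..-1, +1..+20 around called TTSs,
    normalized to the -21 value."""

    positions: list[int]
    mean_raw: np.ndarray
    normalized: np.ndarray
    n_sites: int = 0

    def at(self, position: int) -> float:
        return float(self.normalized[self.positions.index(position)])


def relative_positions(upstream: int, downstream_n: int) -> list[int]:
    """Axis labels -upstream..-1, +1..+downstream_n (no 0)."""
    return list(range(-upstream, 0)) + list(range(1, downstream_n + 1))


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_primary_tts(end_tracks: Sequence[StrandedTrack],
                     tus: Sequence[TranscriptionUnit],
                     window: int = 200, ratio_min: float = 1.1,
                     diff_min: float = 5.0) -> list[TTSCall]:
    """Call at most one primary TTS per TU from >=2 replicate 3'-end tracks.

    A candidate position must satisfy the ratio and difference criteria in
    every replicate; a +1 count of zero gives ratio +inf (passes the ratio
    criterion without perturbing the absolute-difference one).  The window
    starts at the base following the stop codon, in transcription sense, and
    is truncated (and the call flagged) at chromosome ends.
    """
    if len(end_tracks) < 2:
        raise ValueError("TTS calling requires >= 2 replicate tracks")
    calls: list[TTSCall] = []
    for tu in tus:
        if tu.stop_codon_end is None:
            continue
        arrs = [t.get(tu.chrom, tu.strand) for t in end_tracks]
        size = arrs[0].size
        dists = np.arange(1, window + 1)
        pos = (tu.stop_codon_end + dists if tu.strand == "+"
               else tu.stop_codon_end - dists)
        pos_dn = downstream(pos, tu.strand, 1)
        ok = (pos >= 0) & (pos < size) & (pos_dn >= 0) & (pos_dn < size)
        truncated = not ok.all()
        dists, pos, pos_dn = dists[ok], pos[ok], pos_dn[ok]
        if pos.size == 0:
            continue
        passing = np.ones(pos.size, dtype=bool)
        score = np.zeros(pos.size)
        evidence = []
        for arr in arrs:
            c1, c2 = arr[pos], arr[pos_dn]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_ok = np.where(c2 > 0, c1 > ratio_min * c2, c1 > 0)
            passing &= ratio_ok & (c1 - c2 > diff_min)
            score += c1 - c2
            evidence.append((c1, c2))
        if not passing.any():
            continue
        idx = np.flatnonzero(passing)
        # highest summed difference; positions are ordered by increasing
        # distance from the stop codon and argmax takes the first maximum,
        # so score ties resolve to the closest position (shortest 3'-UTR)
        best = idx[np.argmax(score[idx])]
        calls.append(TTSCall(
            tu_id=tu.tu_id, chrom=tu.chrom, strand=tu.strand,
            tts_pos=int(pos[best]), dist_to_stop=int(dists[best]),
            minus1_counts=[float(c1[best]) for c1, _ in evidence],
            plus1_counts=[float(c2[best]) for _, c2 in evidence],
            window_truncated=truncated))
    return calls


# ---------------------------------------------------------------------------
# Terminator PFM
# ---------------------------------------------------------------------------

def extract_terminator_window(call: TTSCall, genome: GenomeSequence,
                              upstream: int = 30, downstream_n: int = 10
                              ) -> str | None:
    """Transcription-sense sequence from -upstream..-1 (the TTS) to
    +1..+downstream_n; None when the window runs off the contig."""
    L = genome.lengths[call.chrom]
    if call.strand == "+":
        lo, hi = call.tts_pos - upstream + 1, call.tts_pos + downstream_n + 1
        if lo < 0 or hi > L:
            return None
        return genome.fetch(call.chrom, lo, hi)
    lo, hi = call.tts_pos - downstream_n, call.tts_pos + upstream
    if lo < 0 or hi > L:
        return None
    return revcomp(genome.fetch(call.chrom, lo, hi))


def extract_terminator_pfm(tts_calls: Sequence[TTSCall], genome: GenomeSequence,
                           upstream: int = 30, downstream_n: int = 10
                           ) -> PositionFrequencyMatrix:
    """Count bases per TTS-relative position over all calls.

    Sequences are taken in transcription sense (reverse-complemented on the
    minus strand); windows truncated by a contig edge are excluded and
    counted, so every PFM column sums to ``n_sequences``.
    """
    positions = relative_positions(upstream, downstream_n)
    counts = np.zeros((4, len(positions)), dtype=int)
    n_seq = n_excl = 0
    for call in tts_calls:
        window = extract_terminator_window(call, genome, upstream, downstream_n)
        if window is None or "N" in window:
            n_excl += 1
            continue
        n_seq += 1
        for j, base in enumerate(window):
            counts[BASES.index(base), j] += 1
    return PositionFrequencyMatrix(positions, counts, n_seq, n_excl)


# ---------------------------------------------------------------------------
# Metaplot
# ---------------------------------------------------------------------------

def metaplot(end_track: StrandedTrack, tts_calls: Sequence[TTSCall],
             upstream: int = 21, downstream_n: int = 20) -> MetaplotProfile:
    """Mean 3'-end counts per TTS-relative position (-21..-1, +1..+20),
    normalized by the -21 value.

    Calls whose window runs off the contig are excluded; a -21 mean of zero
    is an error (the profile cannot be normalized).
    """
    if not tts_calls:
        raise ValueError("metaplot requires at least one TTS call")
    positions = relative_positions(upstream, downstream_n)
    offsets = np.array([p + 1 if p < 0 else p for p in positions])
    # sense offset from the TTS: position -1 -> 0, -21 -> -20, +1 -> +1
    total = np.zeros(len(positions))
    n_sites = 0
    for call in tts_calls:
        arr = end_track.get(call.chrom, call.strand)
        pos = (call.tts_pos + offsets if call.strand == "+"
               else call.tts_pos - offsets)
        if pos.min() < 0 or pos.max() >= arr.size:
            continue
        total += arr[pos]
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no TTS call had a complete metaplot window")
    mean_raw = total / n_sites
    anchor = mean_raw[0]  # the -21 position
    if anchor == 0:
        raise ValueError("cannot normalize: mean read count at -21 is zero")
    return MetaplotProfile(positions, mean_raw, mean_raw / anchor, n_sites)


def tts_decrease(profile: MetaplotProfile) -> float:
    """Fractional read decrease across the TTS: 1 - normalized[+2]/normalized[-2].

    Positive values mean termination (reads drop downstream); negative values
    mean read-through.  A -2 value of zero is an error.
    """
    minus2 = profile.at(-2)
    if minus2 == 0:
        raise ValueError("normalized value at -2 is zero; decrease undefined")
    return 1.0 - profile.at(+2) / minus2
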