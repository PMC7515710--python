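"""Uridine-tract (U5/U6/U7) counting around stop codons.

RNA uridine corresponds to thymine on the sense DNA strand, so U-tracts are
counted as maximal runs of consecutive T in transcription-sense sequence.  A
run of 7 T's counts once for each of n=5, 6 and 7; it is never decomposed
into overlapping k-mers.  ``N`` breaks a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

from .tracks_io import GenomeSequence, TranscriptionUnit, revcomp

DEFAULT_NS = (5, 6, 7)


@dataclass
class FlankPair:
    """Transcription-sense windows flanking one gene's stop codon.

    The upstream window ends at the stop codon's last base (the stop codon
    belongs to the gene-body side); the downstream window begins immediately
    after.  ``truncated`` marks windows shortened by a contig edge.
    """

    gene_id: str
    upstream_seq: str
    downstream_seq: str
    truncated: bool = False


@dataclass
class UTractTable:
    """Pooled U-tract counts per run length with enrichment statistics."""

    n_genes: int
    n_skipped: int
    table: pd.DataFrame  # columns: n, up_count, down_count, ratio, p_value


def flank_windows(tus: Sequence[TranscriptionUnit], genome: GenomeSequence,
                  flank: int = 200) -> tuple[list[FlankPair], int]:
    """Extract the ``flank``-nt windows upstream and downstream of each
    gene's stop codon, in transcription sense.

    Genes without an annotated stop codon are skipped and counted; windows
    are truncated at contig edges and flagged.  Returns (pairs, n_skipped).
    """
    pairs: list[FlankPair] = []
    skipped = 0
    for tu in tus:
        sce = tu.stop_codon_end
        if sce is None:
            skipped += 1
            continue
        L = genome.lengths[tu.chrom]
        if tu.strand == "+":
            up_lo, up_hi = max(sce - flank + 1, 0), sce + 1
            dn_lo, dn_hi = sce + 1, min(sce + 1 + flank, L)
            up = genome.fetch(tu.chrom, up_lo, up_hi)
            down = genome.fetch(tu.chrom, dn_lo, dn_hi)
        else:
            up = revcomp(genome.fetch(tu.chrom, sce, min(sce + flank, L)))
            down = revcomp(genome.fetch(tu.chrom, max(sce - flank, 0), sce))
        truncated = len(up) < flank or len(down) < flank
        pairs.append(FlankPair(tu.tu_id, up, down, truncated))
    return pairs, skipped


def count_max_u_runs(seq: str, n: int) -> int:
    """Number of maximal runs of >= n consecutive T in ``seq``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(1 for base, run in groupby(seq.upper())
               if base == "T" and sum(1 for _ in run) >= n)


def u_tract_enrichment(tus: Sequence[TranscriptionUnit], genome: GenomeSequence,
                       flank: int = 200, ns: Sequence[int] = DEFAULT_NS
                       ) -> UTractTable:
    """Pool U-tract counts over all genes' upstream and downstream windows
    and test downstream enrichment.

    Per run length n the enrichment ratio is downstream/upstream (NaN when
    the upstream total is zero) and the p-value is a two-sided exact
    binomial test of the downstream count against half of the pooled total.
    """
    pairs, skipped = flank_windows(tus, genome, flank)
    if not pairs:
        raise ValueError("no gene had flanking windows")
    rows = []
    for n in ns:
        up = sum(count_max_u_runs(p.upstream_seq, n) for p in pairs)
        down = sum(count_max_u_runs(p.downstream_seq, n) for p in pairs)
        total = up + down
        ratio = down / up if up > 0 else float("nan")
        p_value = binomtest(down, total, 0.5).pvalue if total > 0 else float("nan")
        rows.append({"n": n, "up_count": up, "down_count": down,
                     "ratio": ratio, "p_value": p_value})
    return UTractTable(n_genes=len(pairs), n_skipped=skipped,
                       table=pd.DataFrame(rows))
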