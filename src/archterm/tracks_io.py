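"""Genomic file I/O, the coordinate model, IGR derivation, and raw-read QC.

Coordinate model
----------------
All internal coordinates are 0-based half-open on the forward genomic axis.
"Downstream" means +1 bp on the ``+`` strand and -1 bp on the ``-`` strand;
every piece of transcription-sense arithmetic in the package goes through
:func:`downstream` so the convention lives in exactly one place.

bedGraph files carry no strand, so stranded tracks are read and written as
paired files (``*.plus.bedgraph`` / ``*.minus.bedgraph``).  Minus-strand
values are stored at their forward-axis positions; nothing is reversed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class TrackIOError(ValueError):
    """Malformed or inconsistent genomic input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def downstream(pos: int, strand: str, offset: int = 1) -> int:
    """Genomic coordinate ``offset`` bases downstream of ``pos`` in
    transcription sense: +offset on the ``+`` strand, -offset on ``-``."""
    if strand == "+":
        return pos + offset
    if strand == "-":
        return pos - offset
    raise TrackIOError(f"invalid strand {strand!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Chromosome id -> uppercase nucleotide string."""

    records: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.records[chrom]
        if start < 0 or end > len(seq):
            raise TrackIOError(
                f"slice [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class TranscriptionUnit:
    """A stranded transcribed interval with its TSS/TTS anchors.

    ``stop_codon_end`` is the genomic coordinate of the last base of the stop
    codon of the TU's final ORF, in transcription sense.  ``tts`` may be None
    until annotated or called.
    """

    tu_id: str
    chrom: str
    strand: str
    start: int
    end: int
    stop_codon_end: int | None = None
    tts: int | None = None
    is_noncoding: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TrackIOError(f"{self.tu_id}: invalid strand {self.strand!r}")
        if self.start >= self.end:
            raise TrackIOError(f"{self.tu_id}: start {self.start} >= end {self.end}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        """Called/annotated TTS, falling back to the interval's 3' boundary."""
        if self.tts is not None:
            return self.tts
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class IGR:
    """Strand-specific intergenic region between two tandem TUs: from the
    upstream TU's TTS to the downstream co-directional TU's TSS."""

    igr_id: str
    chrom: str
    strand: str
    start: int
    end: int
    upstream_tu_id: str
    downstream_tu_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadQCReport:
    n_input: int = 0
    n_kept: int = 0
    n_discarded_truncated: int = 0
    n_discarded_n_fraction: int = 0
    n_discarded_low_quality: int = 0

    @property
    def n_discarded(self) -> int:
        return (self.n_discarded_truncated + self.n_discarded_n_fraction
                + self.n_discarded_low_quality)


class StrandedTrack:
    """Per-(chromosome, strand) arrays of non-negative per-base values.

    ``kind`` is ``"three_prime_end"`` (Term-seq 3'-end counts) or
    ``"coverage"``; ``label`` identifies condition/replicate.
    """

    def __init__(self, lengths: dict[str, int], kind: str = "three_prime_end",
                 label: str = "", dtype=float):
        self.kind = kind
        self.label = label
        self.values: dict[tuple[str, str], np.ndarray] = {
            (chrom, strand): np.zeros(length, dtype=dtype)
            for chrom, length in lengths.items() for strand in "+-"
        }

    @property
    def lengths(self) -> dict[str, int]:
        return {chrom: arr.size for (chrom, strand), arr in self.values.items()
                if strand == "+"}

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[(chrom, strand)]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Parse a FASTA file into an uppercased :class:`GenomeSequence`.

    Duplicate record ids and characters outside A/C/G/T/N are errors; the
    error message names the offending line.
    """
    path = Path(path)
    records: dict[str, str] = {}
    # line scan for precise error locations before handing off to SeqIO
    seen_header = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            seen_header = True
            continue
        if not seen_header:
            raise TrackIOError(f"{path}:{lineno}: sequence before any FASTA header")
        bad = set(line.upper()) - VALID_BASES
        if bad:
            raise TrackIOError(
                f"{path}:{lineno}: invalid characters {sorted(bad)} "
                "(only A/C/G/T/N allowed)"
            )
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise TrackIOError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise TrackIOError(f"{path}: no FASTA records found")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in genome.records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def qc_filter_reads(fastq_path: str | Path, out_path: str | Path,
                    original_length: int = 150) -> ReadQCReport:
    """Apply the raw-read quality filter and write the surviving reads.

    A read is discarded if (in this order, one reason per read):
    1. truncated to <= 1/3 of the original read length,
    2. >= 10% uncalled bases (N),
    3. >= 50% low-quality bases (Phred <= 5).
    """
    report = ReadQCReport()
    kept = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        report.n_input += 1
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations["phred_quality"]
        if len(seq) != len(quals):
            raise TrackIOError(f"{rec.id}: sequence/quality length mismatch")
        if len(seq) * 3 <= original_length:
            report.n_discarded_truncated += 1
        elif seq.count("N") >= 0.10 * len(seq):
            report.n_discarded_n_fraction += 1
        elif sum(q <= 5 for q in quals) >= 0.50 * len(seq):
            report.n_discarded_low_quality += 1
        else:
            report.n_kept += 1
            kept.append(rec)
    with open(out_path, "w") as fh:
        SeqIO.write(kept, fh, "fastq")
    return report


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED6)
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _GFF_ATTR.findall(text)}


def read_annotation(path: str | Path, fmt: str = "gff3") -> list[TranscriptionUnit]:
    """Read TUs from GFF3 (1-based closed, converted to 0-based half-open)
    or BED6 (passed through).  Strand is required for every record."""
    path = Path(path)
    tus: list[TranscriptionUnit] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        fields = line.split("\t")
        try:
            if fmt == "gff3":
                if len(fields) < 9:
                    raise TrackIOError("expected 9 GFF3 columns")
                chrom, _src, _type, start1, end1, _score, strand, _phase, attrs = fields[:9]
                start, end = int(start1) - 1, int(end1)
                a = _parse_gff_attributes(attrs)
                tu_id = a.get("ID") or a.get("Name") or f"feature_{lineno}"
                sce = int(a["stop_codon_end"]) if "stop_codon_end" in a else None
                tts = int(a["tts"]) if "tts" in a else None
                noncoding = a.get("noncoding", "0") in ("1", "true", "True")
            elif fmt == "bed":
                if len(fields) < 6:
                    raise TrackIOError("expected 6 BED columns")
                chrom, start_s, end_s, tu_id, _score, strand = fields[:6]
                start, end = int(start_s), int(end_s)
                sce = tts = None
                noncoding = False
            else:
                raise TrackIOError(f"unknown annotation format {fmt!r}")
            if strand not in "+-":
                raise TrackIOError(f"missing/invalid strand {strand!r}")
            if end <= start:
                raise TrackIOError(f"end {end} <= start {start}")
            tus.append(TranscriptionUnit(tu_id, chrom, strand, start, end,
                                         stop_codon_end=sce, tts=tts,
                                         is_noncoding=noncoding))
        except (TrackIOError, KeyError, ValueError) as exc:
            raise TrackIOError(f"{path}:{lineno}: {exc}") from exc
    return tus


def write_annotation(tus: Sequence[TranscriptionUnit], path: str | Path,
                     source: str = "archterm") -> None:
    """Write TUs as GFF3 (1-based closed); TSS/TTS anchors go in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tu in tus:
            attrs = [f"ID={tu.tu_id}"]
            if tu.stop_codon_end is not None:
                attrs.append(f"stop_codon_end={tu.stop_codon_end}")
            if tu.tts is not None:
                attrs.append(f"tts={tu.tts}")
            if tu.is_noncoding:
                attrs.append("noncoding=1")
            fh.write("\t".join([tu.chrom, source, "transcript",
                                str(tu.start + 1), str(tu.end), ".",
                                tu.strand, ".", ";".join(attrs)]) + "\n")


def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write objects with chrom/start/end/strand and an id as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "igr_id", None) or getattr(iv, "tu_id", ".")
            fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end),
                                name, "0", iv.strand]) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_bedgraph_into(path: str | Path, track: StrandedTrack, strand: str) -> None:
    covered: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise TrackIOError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if (chrom, strand) not in track.values:
            raise TrackIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        arr = track.get(chrom, strand)
        if start < 0 or end > arr.size or end <= start:
            raise TrackIOError(
                f"{path}:{lineno}: interval [{start},{end}) outside "
                f"{chrom} (length {arr.size})"
            )
        if value < 0:
            raise TrackIOError(f"{path}:{lineno}: negative value {value}")
        mask = covered.setdefault(chrom, np.zeros(arr.size, dtype=bool))
        seg = slice(start, end)
        clash = mask[seg] & (arr[seg] != value)
        if clash.any():
            raise TrackIOError(
                f"{path}:{lineno}: overlapping interval with conflicting values"
            )
        arr[seg] = value
        mask[seg] = True


def read_stranded_bedgraph(plus_path: str | Path, minus_path: str | Path,
                           genome: GenomeSequence | dict[str, int],
                           kind: str = "three_prime_end",
                           label: str = "") -> StrandedTrack:
    """Read paired plus/minus bedGraph files into a :class:`StrandedTrack`.

    Intervals are expanded to per-base values; uncovered bases are 0.
    """
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    track = StrandedTrack(lengths, kind=kind, label=label)
    _read_bedgraph_into(plus_path, track, "+")
    _read_bedgraph_into(minus_path, track, "-")
    return track


def _write_bedgraph(track: StrandedTrack, strand: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.lengths:
            arr = track.get(chrom, strand)
            if arr.size == 0:
                continue
            # run-length encode, skipping zero runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def write_stranded_bedgraph(track: StrandedTrack, plus_path: str | Path,
                            minus_path: str | Path) -> None:
    _write_bedgraph(track, "+", plus_path)
    _write_bedgraph(track, "-", minus_path)


# ---------------------------------------------------------------------------
# IGR derivation
# ---------------------------------------------------------------------------

def derive_igrs(tus: Sequence[TranscriptionUnit]) -> tuple[list[IGR], dict]:
    """Derive strand-specific IGRs between tandem same-strand TU pairs.

    For each pair of consecutive same-strand TUs the IGR runs from the base
    after the upstream TU's TTS to the downstream TU's TSS (exclusive), in
    transcription sense.  Pairs with no positive gap are skipped and counted;
    opposite-strand neighbours never define an IGR.

    Returns (igrs, report) where report counts skipped degenerate pairs.
    """
    igrs: list[IGR] = []
    report = {"n_pairs": 0, "n_skipped_overlap": 0}
    groups: dict[tuple[str, str], list[TranscriptionUnit]] = {}
    for tu in tus:
        groups.setdefault((tu.chrom, tu.strand), []).append(tu)
    for (chrom, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda t: t.start)
        if strand == "-":
            group = group[::-1]  # transcription order: right to left
        for up, down in zip(group, group[1:]):
            report["n_pairs"] += 1
            tts = up.three_prime_end
            tss = down.tss
            if strand == "+":
                start, end = tts + 1, tss
            else:
                start, end = tss + 1, tts
            if end - start < 1:
                report["n_skipped_overlap"] += 1
                continue
            igrs.append(IGR(f"{up.tu_id}|{down.tu_id}", chrom, strand,
                            start, end, up.tu_id, down.tu_id))
    return igrs, report
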