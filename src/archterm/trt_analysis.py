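"""Transcription read-through (TRT) quantification and classification.

For each TU paired with its downstream co-directional IGR, expression is
quantified as FPKM (fragments per kilobase of feature per million mapped
fragments) in a wild-type and a termination-factor-depleted condition, and
the read-through index is the ratio of ratios

    TRT_index = (FPKM_IGR_dep / FPKM_IGR_wt) / (FPKM_TU_dep / FPKM_TU_wt)

A TU shows read-through when TRT_index > 1 (strong when > 2).  Read-through
events are typed by where the depleted-condition coverage extends past the
TTS: into a convergent opposite-strand TU (type I), the tandem co-directional
TU (type II), only the IGR (type III), or — for a non-coding source RNA —
into the downstream TU (type IV).

Zero denominators yield NA records rather than pseudocounted values, so every
reported index is exactly the formula above; NA reasons are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import IGR, StrandedTrack, TranscriptionUnit, downstream

TRT_TYPES = ("I", "II", "III", "IV")


@dataclass
class FeatureExpression:
    feature_id: str
    feature_kind: str       # "TU" or "IGR"
    length: int             # nt
    fragments: float
    fpkm: float
    condition: str
    replicate: int = 0


@dataclass
class TRTRecord:
    tu_id: str
    igr_id: str
    fpkm_tu_wt: float
    fpkm_tu_dep: float
    fpkm_igr_wt: float
    fpkm_igr_dep: float
    trt_index: float | None = None
    is_trt: bool = False
    is_strong: bool = False
    trt_type: str = "none"   # I / II / III / IV / none / NA
    na_reason: str | None = None
    downstream_tu_id: str | None = None


@dataclass
class TRTSummary:
    n_tus: int
    n_trt: int
    pct_trt: float
    n_strong: int
    pct_strong: float
    n_na: int
    type_counts: dict[str, int]
    type_pct_all: dict[str, float]        # over all TUs
    type_pct_trt: dict[str, float]        # over TRT-positive TUs
    median_igr_fold: float
    median_body_fold: float
    median_downstream_tu_fold: float      # type II targets only; NaN if none


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def compute_fpkm(fragments: float, length_nt: int,
                 total_mapped_fragments: float) -> float:
    """fragments / (length in kb) / (total mapped fragments in millions)."""
    if length_nt < 1:
        raise ValueError("feature length must be >= 1 nt")
    if total_mapped_fragments < 1:
        raise ValueError("total mapped fragments must be >= 1")
    return fragments / (length_nt / 1e3) / (total_mapped_fragments / 1e6)


def fragments_from_coverage(track: StrandedTrack, feature,
                            read_length: int) -> float:
    """Fragment count implied by per-base coverage over a stranded interval:
    sum(coverage) / read_length.  ``feature`` needs chrom/strand/start/end."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    arr = track.get(feature.chrom, feature.strand)
    if feature.start < 0 or feature.end > arr.size:
        raise ValueError(
            f"{getattr(feature, 'tu_id', getattr(feature, 'igr_id', '?'))}: "
            f"interval [{feature.start},{feature.end}) off contig")
    return float(arr[feature.start:feature.end].sum()) / read_length


def total_fragments(track: StrandedTrack, read_length: int) -> float:
    """Total mapped fragments of a coverage track (whole-track sum)."""
    return max(track.total() / read_length, 1.0)


def quantify_features(track: StrandedTrack, tus: Sequence[TranscriptionUnit],
                      igrs: Sequence[IGR], read_length: int,
                      condition: str, replicate: int = 0
                      ) -> list[FeatureExpression]:
    """FPKM of every TU and IGR in one coverage track."""
    total = total_fragments(track, read_length)
    out = []
    for kind, features in (("TU", tus), ("IGR", igrs)):
        for f in features:
            fid = f.tu_id if kind == "TU" else f.igr_id
            frags = fragments_from_coverage(track, f, read_length)
            out.append(FeatureExpression(
                fid, kind, f.end - f.start, frags,
                compute_fpkm(frags, f.end - f.start, total),
                condition, replicate))
    return out


def average_fpkm(expressions: Sequence[FeatureExpression]
                 ) -> dict[tuple[str, str], float]:
    """(feature_id, condition) -> replicate-averaged FPKM."""
    acc: dict[tuple[str, str], list[float]] = {}
    for e in expressions:
        acc.setdefault((e.feature_id, e.condition), []).append(e.fpkm)
    return {key: float(np.mean(v)) for key, v in acc.items()}


# ---------------------------------------------------------------------------
# TRT index
# ---------------------------------------------------------------------------

def compute_trt_index(tu_id: str, igr_id: str,
                      fpkm_tu_wt: float, fpkm_tu_dep: float,
                      fpkm_igr_wt: float, fpkm_igr_dep: float,
                      trt_cut: float = 1.0, strong_cut: float = 2.0
                      ) -> TRTRecord:
    """Build a TRT record from the four (replicate-averaged) FPKMs.

    The index is NA when any of FPKM_IGR_wt, FPKM_TU_wt, FPKM_TU_dep is
    zero (a denominator of the ratio of ratios).
    """
    rec = TRTRecord(tu_id, igr_id, fpkm_tu_wt, fpkm_tu_dep,
                    fpkm_igr_wt, fpkm_igr_dep)
    zeros = [name for name, v in [("fpkm_igr_wt", fpkm_igr_wt),
                                  ("fpkm_tu_wt", fpkm_tu_wt),
                                  ("fpkm_tu_dep", fpkm_tu_dep)] if v == 0]
    if zeros:
        rec.trt_type = "NA"
        rec.na_reason = "zero denominator: " + ",".join(zeros)
        return rec
    rec.trt_index = (fpkm_igr_dep / fpkm_igr_wt) / (fpkm_tu_dep / fpkm_tu_wt)
    rec.is_trt = rec.trt_index > trt_cut
    rec.is_strong = rec.trt_index > strong_cut
    return rec


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _readthrough_span(tu: TranscriptionUnit, tts: int,
                      depleted_coverage: StrandedTrack,
                      alpha: float) -> tuple[int, int]:
    """Maximal contiguous run downstream of the TTS (transcription sense)
    with depleted coverage >= alpha * mean depleted body coverage.
    Returned as a forward-axis half-open interval (possibly empty)."""
    arr = depleted_coverage.get(tu.chrom, tu.strand)
    if tu.strand == "+":
        body = arr[tu.tss:tts + 1]
    else:
        body = arr[tts:tu.tss + 1]
    threshold = alpha * float(body.mean()) if body.size else 0.0
    pos = downstream(tts, tu.strand, 1)
    step = 1 if tu.strand == "+" else -1
    n = 0
    while 0 <= pos < arr.size and arr[pos] >= threshold > 0:
        n += 1
        pos += step
    if n == 0:
        return (tts + 1, tts + 1)
    if tu.strand == "+":
        return (tts + 1, tts + 1 + n)
    return (tts - n, tts)


def classify_trt(record: TRTRecord, tus: Sequence[TranscriptionUnit],
                 igrs: Sequence[IGR], depleted_coverage: StrandedTrack,
                 alpha: float = 0.2, min_overlap: int = 25) -> str:
    """Assign a read-through type (I-IV) to a TRT-positive record.

    The read-through span is walked downstream of the source TU's TTS in the
    depleted coverage; the first annotated TU the span reaches with at least
    ``min_overlap`` bp overlap decides: opposite strand -> I, same strand ->
    II; no TU reached -> III; a non-coding source whose span reaches any TU
    -> IV.  Records with ``is_trt`` false get "none"; a missing TTS gives
    "NA".  The label is stored on the record and returned.
    """
    if not record.is_trt:
        record.trt_type = "NA" if record.trt_type == "NA" else "none"
        return record.trt_type
    by_id = {t.tu_id: t for t in tus}
    tu = by_id[record.tu_id]
    if tu.tts is None:
        record.trt_type = "NA"
        record.na_reason = "TTS unset"
        return record.trt_type
    span = _readthrough_span(tu, tu.tts, depleted_coverage, alpha)
    hit = None
    candidates = []
    for other in tus:
        if other.tu_id == tu.tu_id or other.chrom != tu.chrom:
            continue
        overlap = min(span[1], other.end) - max(span[0], other.start)
        if overlap >= min_overlap:
            # sense distance from the TTS to where the span enters the TU
            entry = other.start if tu.strand == "+" else -(other.end - 1)
            candidates.append((entry, other))
    if candidates:
        hit = min(candidates)[1]
    if hit is None:
        record.trt_type = "III"
    elif tu.is_noncoding:
        record.trt_type = "IV"
    elif hit.strand != tu.strand:
        record.trt_type = "I"
    else:
        record.trt_type = "II"
        record.downstream_tu_id = hit.tu_id
    return record.trt_type


# ---------------------------------------------------------------------------
# Expression ranks
# ---------------------------------------------------------------------------

RANK_EDGES = (42, 103, 214, 573)  # inclusive upper FPKM bound of ranks 1-4


def expression_rank_bins(fpkm_values) -> np.ndarray:
    """Five expression ranks on rounded FPKM: 1: <=42, 2: 43-103,
    3: 104-214, 4: 215-573, 5: >573.  Partitions [0, inf)."""
    fpkm = np.asarray(fpkm_values, dtype=float)
    if (fpkm < 0).any():
        raise ValueError("FPKM values must be non-negative")
    rounded = np.floor(fpkm + 0.5)
    ranks = np.searchsorted(RANK_EDGES, rounded, side="left") + 1
    return ranks.astype(int)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def _median_or_nan(values: list[float]) -> float:
    return float(np.median(values)) if values else float("nan")


def summarize_trt(trt_records: Sequence[TRTRecord],
                  expressions: Sequence[FeatureExpression] | None = None
                  ) -> TRTSummary:
    """TRT counts/percentages, per-type percentages (over all TUs and over
    TRT-positive TUs) and median depleted/wild-type FPKM folds for IGRs, TU
    bodies, and (type II only) the downstream target TUs.

    Downstream-target folds need the per-condition expression table; when it
    is not supplied, that median is NaN.
    """
    if not trt_records:
        raise ValueError("summarize_trt requires >= 1 record")
    n = len(trt_records)
    n_trt = sum(r.is_trt for r in trt_records)
    n_strong = sum(r.is_strong for r in trt_records)
    n_na = sum(r.trt_type == "NA" for r in trt_records)
    type_counts = {t: sum(r.trt_type == t for r in trt_records)
                   for t in TRT_TYPES}
    igr_folds = [r.fpkm_igr_dep / r.fpkm_igr_wt for r in trt_records
                 if r.fpkm_igr_wt > 0]
    body_folds = [r.fpkm_tu_dep / r.fpkm_tu_wt for r in trt_records
                  if r.fpkm_tu_wt > 0]
    ds_folds: list[float] = []
    if expressions is not None:
        fpkm = average_fpkm(expressions)
        for r in trt_records:
            if r.trt_type == "II" and r.downstream_tu_id:
                wt = fpkm.get((r.downstream_tu_id, "wt"), 0.0)
                dep = fpkm.get((r.downstream_tu_id, "depleted"), 0.0)
                if wt > 0:
                    ds_folds.append(dep / wt)
    return TRTSummary(
        n_tus=n, n_trt=n_trt, pct_trt=100.0 * n_trt / n,
        n_strong=n_strong, pct_strong=100.0 * n_strong / n, n_na=n_na,
        type_counts=type_counts,
        type_pct_all={t: 100.0 * c / n for t, c in type_counts.items()},
        type_pct_trt={t: (100.0 * c / n_trt if n_trt else 0.0)
                      for t, c in type_counts.items()},
        median_igr_fold=_median_or_nan(igr_folds),
        median_body_fold=_median_or_nan(body_folds),
        median_downstream_tu_fold=_median_or_nan(ds_folds))


def records_to_frame(records: Sequence[TRTRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
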