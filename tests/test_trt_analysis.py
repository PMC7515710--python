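import numpy as np
import pytest

from archterm import SimulationConfig, StrandedTrack, TranscriptionUnit
from archterm.synthetic_data import simulate_coverage, simulate_genome
from archterm.tracks_io import derive_igrs
from archterm.trt_analysis import (TRTRecord, average_fpkm, classify_trt,
                                   compute_fpkm, compute_trt_index,
                                   expression_rank_bins,
                                   fragments_from_coverage, quantify_features,
                                   summarize_trt)


class TestFpkm:
    def test_definition(self):
        assert compute_fpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_zero_fragments(self):
        assert compute_fpkm(0, 500, 1_000_000) == 0.0

    def test_homogeneous_in_depth(self):
        assert compute_fpkm(100, 1000, 1e6) == \
            pytest.approx(compute_fpkm(200, 1000, 2e6))

    @pytest.mark.parametrize("length,total", [(0, 1e6), (1000, 0)])
    def test_degenerate_inputs_error(self, length, total):
        with pytest.raises(ValueError):
            compute_fpkm(10, length, total)


class TestFragmentsFromCoverage:
    def _track(self, n=1000, value=10.0):
        t = StrandedTrack({"chr1": n}, kind="coverage")
        t.get("chr1", "+")[:] = value
        return t

    def test_coverage_sum_over_read_length(self):
        tu = TranscriptionUnit("t", "chr1", "+", 100, 200)
        assert fragments_from_coverage(self._track(), tu, 50) == pytest.approx(20.0)

    def test_zero_interval(self):
        tu = TranscriptionUnit("t", "chr1", "+", 100, 200)
        assert fragments_from_coverage(self._track(value=0.0), tu, 50) == 0.0

    def test_off_contig_errors(self):
        tu = TranscriptionUnit("t", "chr1", "+", 900, 1100)
        with pytest.raises(ValueError, match="off contig"):
            fragments_from_coverage(self._track(), tu, 50)

    def test_matches_noiseless_generator_coverage(self):
        cfg = SimulationConfig(seed=9, n_tus=8, noise=None,
                               expression_sdlog=0.0, background=0.0)
        genome, tus, truth = simulate_genome(cfg)
        track = simulate_coverage(genome, tus, truth, "wt", cfg)
        for tu, row in zip(tus, truth.itertuples()):
            body = TranscriptionUnit(tu.tu_id, tu.chrom, tu.strand,
                                     min(tu.tss, row.true_tts),
                                     max(tu.tss, row.true_tts) + 1)
            frags = fragments_from_coverage(track, body, cfg.read_length)
            expected = cfg.coverage_depth * (body.end - body.start) / cfg.read_length
            assert frags == pytest.approx(expected, rel=0.05)


class TestTrtIndex:
    def test_printed_equation(self):
        rec = compute_trt_index("tu", "igr", 100, 120, 10, 40)
        assert rec.trt_index == pytest.approx((40 / 10) / (120 / 100))
        assert rec.trt_index == pytest.approx(10 / 3)
        assert rec.is_trt and rec.is_strong

    def test_null_is_exactly_one_and_not_flagged(self):
        rec = compute_trt_index("tu", "igr", 50, 50, 5, 5)
        assert rec.trt_index == 1.0
        assert not rec.is_trt  # strict >

    @pytest.mark.parametrize("kw", ["fpkm_tu_wt", "fpkm_tu_dep", "fpkm_igr_wt"])
    def test_zero_denominator_gives_na_with_reason(self, kw):
        vals = dict(fpkm_tu_wt=100, fpkm_tu_dep=120, fpkm_igr_wt=10,
                    fpkm_igr_dep=40)
        vals[kw] = 0
        rec = compute_trt_index("tu", "igr", **vals)
        assert rec.trt_index is None
        assert rec.trt_type == "NA"
        assert kw in rec.na_reason

    def test_zero_numerator_is_not_na(self):
        rec = compute_trt_index("tu", "igr", 100, 120, 10, 0)
        assert rec.trt_index == 0.0
        assert not rec.is_trt

    def test_invariant_under_per_condition_scaling(self):
        a = compute_trt_index("t", "i", 100, 120, 10, 40)
        b = compute_trt_index("t", "i", 100, 120 * 7.3, 10, 40 * 7.3)
        assert b.trt_index == pytest.approx(a.trt_index)

    def test_strictly_increasing_in_igr_depleted(self):
        indices = [compute_trt_index("t", "i", 100, 120, 10, v).trt_index
                   for v in (10, 20, 40, 80)]
        assert indices == sorted(indices)
        assert len(set(indices)) == 4


def geometry_fixture(strand, trt_type):
    """One read-through geometry: a source TU whose depleted coverage spans
    past its TTS toward a target laid out to produce the requested type."""
    L = 10000
    cov = StrandedTrack({"chr1": L}, kind="coverage")
    if strand == "+":
        src = TranscriptionUnit("src", "chr1", "+", 1000, 2000,
                                stop_codon_end=1850, tts=1999)
        arr = cov.get("chr1", "+")
        arr[1000:2000] = 10.0
        span_len = 40 if trt_type == "III" else 300
        arr[2000:2000 + span_len] = 5.0
        target_strand = "-" if trt_type == "I" else "+"
        target = TranscriptionUnit("target", "chr1", target_strand, 2150, 2700,
                                   tts=2150 if target_strand == "-" else 2699)
    else:
        src = TranscriptionUnit("src", "chr1", "-", 8000, 9000,
                                stop_codon_end=8150, tts=8000)
        arr = cov.get("chr1", "-")
        arr[8000:9000] = 10.0
        span_len = 40 if trt_type == "III" else 300
        arr[8000 - span_len:8000] = 5.0
        target_strand = "+" if trt_type == "I" else "-"
        target = TranscriptionUnit("target", "chr1", target_strand, 7300, 7850,
                                   tts=7849 if target_strand == "+" else 7300)
    src.is_noncoding = trt_type == "IV"
    return src, target, cov


class TestClassifyTrt:
    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize("trt_type", ["I", "II", "III", "IV"])
    def test_eight_geometry_suite(self, strand, trt_type):
        src, target, cov = geometry_fixture(strand, trt_type)
        rec = TRTRecord("src", "igr", 10, 12, 1, 4, trt_index=3.3, is_trt=True)
        label = classify_trt(rec, [src, target], [], cov)
        assert label == trt_type
        assert rec.trt_type == trt_type
        if trt_type == "II":
            assert rec.downstream_tu_id == "target"

    def test_not_trt_is_none(self):
        src, target, cov = geometry_fixture("+", "II")
        rec = TRTRecord("src", "igr", 10, 10, 1, 1, trt_index=0.9, is_trt=False)
        assert classify_trt(rec, [src, target], [], cov) == "none"

    def test_missing_tts_is_na(self):
        src, target, cov = geometry_fixture("+", "II")
        src.tts = None
        rec = TRTRecord("src", "igr", 10, 12, 1, 4, trt_index=3.3, is_trt=True)
        assert classify_trt(rec, [src, target], [], cov) == "NA"

    def test_first_feature_reached_wins(self):
        # an opposite-strand TU sits before the co-directional one
        src, _, cov = geometry_fixture("+", "II")
        near = TranscriptionUnit("near", "chr1", "-", 2100, 2400, tts=2100)
        far = TranscriptionUnit("far", "chr1", "+", 2500, 2900, tts=2899)
        rec = TRTRecord("src", "igr", 10, 12, 1, 4, trt_index=3.3, is_trt=True)
        assert classify_trt(rec, [src, near, far], [], cov) == "I"

    def test_min_overlap_gate(self):
        src, target, cov = geometry_fixture("+", "II")
        # span is 2000..2299; a 10 bp touch at the span end is not enough
        target.start, target.end = 2290, 2700
        rec = TRTRecord("src", "igr", 10, 12, 1, 4, trt_index=3.3, is_trt=True)
        assert classify_trt(rec, [src, target], [], cov, min_overlap=25) == "III"


class TestExpressionRanks:
    @pytest.mark.parametrize("fpkm,rank", [
        (0, 1), (41.7, 1), (42.4, 1), (42.6, 2), (103, 2), (104, 3),
        (214, 3), (215, 4), (573, 4), (574, 5), (10000, 5),
    ])
    def test_bin_edges_on_rounded_fpkm(self, fpkm, rank):
        assert expression_rank_bins([fpkm])[0] == rank

    def test_negative_fpkm_errors(self):
        with pytest.raises(ValueError):
            expression_rank_bins([-1.0])

    def test_partitions_nonnegative_axis(self):
        values = np.linspace(0, 2000, 4001)
        ranks = expression_rank_bins(values)
        assert set(ranks) == {1, 2, 3, 4, 5}
        assert (np.diff(ranks) >= 0).all()  # monotone, so exactly one rank each


class TestSummarize:
    def _rec(self, igr_wt, igr_dep, tu_wt=10, tu_dep=12, trt_type="II"):
        rec = compute_trt_index("t", "i", tu_wt, tu_dep, igr_wt, igr_dep)
        rec.trt_type = trt_type if rec.is_trt else "none"
        return rec

    def test_median_fold(self):
        recs = [self._rec(1, 2), self._rec(1, 4), self._rec(1, 8)]
        s = summarize_trt(recs)
        assert s.median_igr_fold == pytest.approx(4.0)

    def test_all_negative_records(self):
        recs = [self._rec(10, 1), self._rec(10, 2)]
        s = summarize_trt(recs)
        assert s.pct_trt == 0.0
        assert all(v == 0 for v in s.type_counts.values())

    def test_synthetic_folds_recovered(self):
        # depleted/wt with configured IGR raw fold 4 and body fold 1.2;
        # FPKM folds carry the whole-track depth normalization, which the
        # TRT index cancels
        cfg = SimulationConfig(seed=13, n_tus=80)
        genome, tus, truth = simulate_genome(cfg)
        igrs, _ = derive_igrs(tus)
        tracks = {c: simulate_coverage(genome, tus, truth, c, cfg)
                  for c in ("wt", "depleted")}
        exprs = []
        for cond, track in tracks.items():
            exprs.extend(quantify_features(track, tus, igrs,
                                           cfg.read_length, cond))
        fpkm = average_fpkm(exprs)
        by_tu = {i.upstream_tu_id: i for i in igrs}
        recs = [compute_trt_index(t.tu_id, by_tu[t.tu_id].igr_id,
                                  fpkm[(t.tu_id, "wt")],
                                  fpkm[(t.tu_id, "depleted")],
                                  fpkm[(by_tu[t.tu_id].igr_id, "wt")],
                                  fpkm[(by_tu[t.tu_id].igr_id, "depleted")])
                for t in tus if t.tu_id in by_tu]
        s = summarize_trt(recs)
        igr_raw_fold = (cfg.readthrough_fraction["depleted"]
                        * cfg.body_fold["depleted"]
                        / cfg.readthrough_fraction["wt"])
        body_raw_fold = cfg.body_fold["depleted"]
        norm = (tracks["depleted"].total() / tracks["wt"].total())
        assert s.median_igr_fold == pytest.approx(igr_raw_fold / norm, rel=0.15)
        assert s.median_body_fold == pytest.approx(body_raw_fold / norm, rel=0.15)
        index = [r.trt_index for r in recs if r.trt_index is not None]
        assert np.median(index) == pytest.approx(igr_raw_fold / body_raw_fold,
                                                 rel=0.15)
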