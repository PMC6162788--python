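"""Focal filter cascade rules, stringency and recurrence."""

from __future__ import annotations

import numpy as np
import pandas as pd

from lncfocal.annotation import Exon, FlankingPair, LncGene
from lncfocal.focalfilter import (
    ExclusionTracks,
    FilterConfig,
    FocalCall,
    apply_filters,
    classify_stringency,
    recurrence_summary,
)
from oracles import brute_filter_calls, random_filter_case

CFG = FilterConfig()


def base_scene(lnc_mean=-3.0, up_mean=-0.1, down_mean=-0.1):
    """One lncRNA [40k,44k) with flank exons at [20k,20.5k) and [60k,60.5k);
    segments: background / lnc / background."""
    gene = LncGene(
        gene_id="L1",
        chrom="chr1",
        start=40_000,
        end=44_000,
        exons=(Exon("chr1", 40_000, 40_400), Exon("chr1", 43_600, 44_000)),
    )
    pair = FlankingPair(
        lnc_gene_id="L1",
        chrom="chr1",
        lnc_start=40_000,
        lnc_end=44_000,
        upstream_pc="PU.1",
        downstream_pc="PD.1",
        upstream_flank_exons=(Exon("chr1", 20_000, 20_500),),
        downstream_flank_exons=(Exon("chr1", 60_000, 60_500),),
    )
    segments = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 0, "end": 39_000, "n_probes": 20, "mean_lr": up_mean},
            {"chrom": "chr1", "start": 39_900, "end": 44_100, "n_probes": 12, "mean_lr": lnc_mean},
            {"chrom": "chr1", "start": 45_000, "end": 100_000, "n_probes": 20, "mean_lr": down_mean},
        ]
    )
    return segments, {"L1": gene}, {"L1": pair}


def run(segments, genes, flanking, tracks=None, cfg=CFG):
    tracks = tracks or ExclusionTracks()
    return apply_filters(segments, genes, flanking, tracks, cfg)


class TestFilterRules:
    def test_loss_with_neutral_flanks_is_called(self):
        calls, log = run(*base_scene())
        assert len(calls) == 1
        c = calls[0]
        assert (c.lnc_gene_id, c.direction, c.stringency) == ("L1", "loss", "stringent")
        assert c.high_confidence
        assert log.consistent()

    def test_subthreshold_amplitude_discarded(self):
        calls, log = run(*base_scene(lnc_mean=-1.4))
        assert calls == []
        assert log.below_t_focal == 1

    def test_too_many_known_variants_discarded(self):
        segments, genes, flanking = base_scene()
        variants = [("chr1", 39_950 + i * 100, 39_950 + i * 100 + 50) for i in range(4)]
        tracks = ExclusionTracks(known_variants=variants)
        calls, log = run(segments, genes, flanking, tracks)
        assert calls == []
        assert log.too_many_variants == 1

    def test_three_variants_still_called(self):
        segments, genes, flanking = base_scene()
        variants = [("chr1", 39_950 + i * 100, 39_950 + i * 100 + 50) for i in range(3)]
        calls, _ = run(segments, genes, flanking, ExclusionTracks(known_variants=variants))
        assert len(calls) == 1

    def test_segment_contained_in_segdup_discarded(self):
        segments, genes, flanking = base_scene()
        tracks = ExclusionTracks(segdups=[("chr1", 39_000, 50_000)])
        calls, log = run(segments, genes, flanking, tracks)
        assert calls == []
        assert log.segdup_contained == 1

    def test_partial_gain_discarded_full_gain_called(self):
        # partial: the gene's probes split into two segments inside the span
        gene = LncGene(
            gene_id="L1",
            chrom="chr1",
            start=40_000,
            end=44_000,
            exons=(
                Exon("chr1", 40_000, 40_400),
                Exon("chr1", 41_800, 42_200),
                Exon("chr1", 43_600, 44_000),
            ),
        )
        pair = FlankingPair(
            lnc_gene_id="L1", chrom="chr1", lnc_start=40_000, lnc_end=44_000,
            upstream_pc="PU.1", downstream_pc="PD.1",
            upstream_flank_exons=(Exon("chr1", 20_000, 20_500),),
            downstream_flank_exons=(Exon("chr1", 60_000, 60_500),),
        )
        partial = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 39_000, "n_probes": 20, "mean_lr": 0.0},
                {"chrom": "chr1", "start": 40_000, "end": 42_200, "n_probes": 6, "mean_lr": 2.0},
                {"chrom": "chr1", "start": 43_600, "end": 100_000, "n_probes": 20, "mean_lr": 0.0},
            ]
        )
        calls, log = run(partial, {"L1": gene}, {"L1": pair})
        assert calls == []
        assert log.gain_not_containing == 1
        full = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 39_000, "n_probes": 20, "mean_lr": 0.0},
                {"chrom": "chr1", "start": 40_000, "end": 44_000, "n_probes": 8, "mean_lr": 2.0},
                {"chrom": "chr1", "start": 60_000, "end": 100_000, "n_probes": 20, "mean_lr": 0.0},
            ]
        )
        calls, _ = run(full, {"L1": gene}, {"L1": pair})
        assert len(calls) == 1
        assert calls[0].direction == "gain"

    def test_flank_exon_overlap_discards(self):
        segments, genes, flanking = base_scene()
        segments.loc[1, "start"] = 20_300  # lnc segment now reaches the up flank exon
        calls, log = run(segments, genes, flanking)
        assert calls == []
        assert log.flank_exon_overlap == 1

    def test_insufficient_flank_contrast_discards(self):
        calls, log = run(*base_scene(lnc_mean=-1.6, up_mean=-1.3))
        assert calls == []
        assert log.flank_contrast == 1

    def test_no_flank_segment_suppressed_and_logged(self):
        segments, genes, flanking = base_scene()
        segments = segments.iloc[[1]].reset_index(drop=True)  # only the lnc segment
        calls, log = run(segments, genes, flanking)
        assert calls == []
        assert log.no_flank_segment == 1
        assert log.messages


class TestStringency:
    def _call(self, up, down):
        return FocalCall(
            sample="S", lnc_gene_id="L1", chrom="chr1", start=0, end=1,
            n_probes=5, mean_lr=-3.0, direction="loss", high_confidence=True,
            stringency="standard", flank_up_lr=up, flank_down_lr=down,
        )

    def test_neutral_flanks_are_stringent(self):
        assert classify_stringency(self._call(-0.05, 0.10)) == "stringent"

    def test_stacked_event_is_standard(self):
        assert classify_stringency(self._call(-0.80, -0.05)) == "standard"

    def test_boundary_is_strict(self):
        assert classify_stringency(self._call(0.35, 0.0)) == "standard"

    def test_missing_side_ignored(self):
        assert classify_stringency(self._call(None, 0.1)) == "stringent"


class TestRecurrence:
    def test_single_lnc_three_samples(self):
        calls = pd.DataFrame(
            {
                "sample": ["A", "B", "C"],
                "lnc_gene_id": ["L1"] * 3,
                "direction": ["loss"] * 3,
                "high_confidence": [True, False, True],
            }
        )
        table, hist = recurrence_summary(calls)
        assert hist == {3: 1}
        assert table.iloc[0]["n_high_conf"] == 2

    def test_empty_calls(self):
        table, hist = recurrence_summary(pd.DataFrame(columns=["sample", "lnc_gene_id", "direction", "high_confidence"]))
        assert table.empty and hist == {}

    def test_planted_recurrence_histogram(self):
        rows = []
        for i in range(5):  # 5 lncRNAs in one sample each
            rows.append(("S1", f"L{i}", "loss", False))
        for i in range(5, 7):  # 2 lncRNAs in two samples each
            rows.append(("S1", f"L{i}", "gain", False))
            rows.append(("S2", f"L{i}", "gain", False))
        calls = pd.DataFrame(rows, columns=["sample", "lnc_gene_id", "direction", "high_confidence"])
        _, hist = recurrence_summary(calls)
        assert hist == {1: 5, 2: 2}


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(8)
        for _ in range(150):
            case = random_filter_case(rng)
            tracks = ExclusionTracks(
                segdups=case["segdups"], known_variants=case["variants"]
            )
            calls, log = apply_filters(
                pd.DataFrame(case["segments"]), case["lnc_genes"], case["flanking"],
                tracks, case["config"],
            )
            got = {
                (c.lnc_gene_id, c.chrom, c.start, c.end, c.direction, c.stringency)
                for c in calls
            }
            exp = brute_filter_calls(
                case["segments"], case["lnc_genes"], case["flanking"],
                case["segdups"], case["variants"], case["config"],
            )
            assert got == exp
            assert log.consistent()

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        case = random_filter_case(rng)
        tracks = ExclusionTracks(segdups=case["segdups"], known_variants=case["variants"])
        df = pd.DataFrame(case["segments"])
        c1, _ = apply_filters(df, case["lnc_genes"], case["flanking"], tracks, case["config"])
        c2, _ = apply_filters(
            df.sample(frac=1.0, random_state=3), case["lnc_genes"], case["flanking"],
            tracks, case["config"],
        )
        key = lambda c: (c.lnc_gene_id, c.start, c.end)
        assert sorted(map(key, c1)) == sorted(map(key, c2))

    def test_monotone_under_threshold_tightening(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            case = random_filter_case(rng)
            tracks = ExclusionTracks(segdups=case["segdups"], known_variants=case["variants"])
            df = pd.DataFrame(case["segments"])
            cfg = case["config"]
            base, _ = apply_filters(df, case["lnc_genes"], case["flanking"], tracks, cfg)
            tighter = FilterConfig(
                t_focal=cfg.t_focal + 0.3,
                t_high=cfg.t_high + 0.3,
                max_variants=max(0, cfg.max_variants - 1),
                flank_delta=cfg.flank_delta + 0.2,
                t_neutral=cfg.t_neutral,
            )
            tight, _ = apply_filters(df, case["lnc_genes"], case["flanking"], tracks, tighter)
            assert len(tight) <= len(base)
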