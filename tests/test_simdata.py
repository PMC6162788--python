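"""Synthetic genome, copy-number, signal, qPCR and corpus generators."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from lncfocal import io as lio
from lncfocal.annotation import assign_flanking, is_intergenic
from lncfocal.simdata import (
    SimConfig,
    SimulationError,
    simulate_annotation,
    simulate_copy_number,
    simulate_corpus,
    simulate_probe_signals,
    simulate_qpcr,
)
from lncfocal.probedesign import design_probes
from lncfocal.textmine import build_tdm, word_enrichment_test


class TestSimulateAnnotation:
    def test_same_seed_byte_identical_gff3(self, small_sim_config, tmp_path):
        for name in ("a.gff3", "b.gff3"):
            lio.write_gff3(simulate_annotation(small_sim_config), tmp_path / name)
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_no_lnc_genes_when_disabled(self, small_sim_config):
        config = dataclasses.replace(small_sim_config, n_lnc_genes=0)
        ts = simulate_annotation(config)
        assert all(t.biotype == "protein_coding" for t in ts)

    def test_all_lncs_are_intergenic(self, small_sim_config):
        ts = simulate_annotation(small_sim_config)
        pcs = [t for t in ts if t.biotype == "protein_coding"]
        lncs = [t for t in ts if t.biotype == "lncRNA"]
        assert len(lncs) == small_sim_config.n_lnc_genes
        assert all(is_intergenic(t, pcs) for t in lncs)

    def test_genome_too_small_raises(self, small_sim_config):
        config = dataclasses.replace(small_sim_config, chrom_length=100_000)
        with pytest.raises(SimulationError, match="bp"):
            simulate_annotation(config)

    def test_round_trip_through_gff3(self, small_sim_config, tmp_path):
        ts = simulate_annotation(small_sim_config)
        lio.write_gff3(ts, tmp_path / "x.gff3")
        back = lio.read_gff3(tmp_path / "x.gff3")
        orig = {(t.id, t.gene_id, t.biotype, t.exons) for t in ts}
        rt = {(t.id, t.gene_id, t.biotype, t.exons) for t in back}
        assert orig == rt


class TestSimulateCopyNumber:
    def test_zero_events_is_diploid_everywhere(self, small_sim_config):
        config = dataclasses.replace(
            small_sim_config, n_focal_del=0, n_focal_amp=0
        )
        ts = simulate_annotation(config)
        truth = simulate_copy_number(ts, config)
        assert all(not ivs for ivs in truth.intervals.values())
        assert truth.copy_number("S01", "chr1", 1_000_000) == 2

    def test_focal_event_contains_lnc_and_avoids_flank_exons(self, small_sim_config):
        ts = simulate_annotation(small_sim_config)
        truth = simulate_copy_number(ts, small_sim_config)
        flanking, _ = assign_flanking(ts)
        assert len(truth.focal_events()) == 4
        for ev in truth.focal_events():
            pair = flanking[ev.lnc_gene_id]
            assert ev.start <= pair.lnc_start and pair.lnc_end <= ev.end
            for side in ("up", "down"):
                exon = pair.nearest_flank_exon(side)
                if exon is not None:
                    assert ev.end <= exon.start or exon.end <= ev.start

    def test_stacked_event_nests_cn0_in_cn1(self, small_sim_config):
        config = dataclasses.replace(
            small_sim_config, n_focal_del=0, n_focal_amp=0, n_stacked=1
        )
        ts = simulate_annotation(config)
        truth = simulate_copy_number(ts, config)
        ev = truth.focal_events()[0]
        ivs = truth.intervals[ev.sample]
        outer = [iv for iv in ivs if iv[3] == 1]
        inner = [iv for iv in ivs if iv[3] == 0]
        assert len(outer) == 1 and len(inner) == 1
        assert outer[0][1] <= inner[0][1] and inner[0][2] <= outer[0][2]
        # lookup resolves to the innermost event
        mid = (inner[0][1] + inner[0][2]) // 2
        assert truth.copy_number(ev.sample, ev.chrom, mid) == 0


class TestSimulateProbeSignals:
    def test_noise_free_log_ratios_exact(self, small_sim_config):
        config = dataclasses.replace(small_sim_config, probe_sigma=0.0)
        ts = simulate_annotation(config)
        flanking, _ = assign_flanking(ts)
        design = design_probes(ts, flanking)
        truth = simulate_copy_number(ts, config)
        signals = simulate_probe_signals(design, truth, config)
        for sample, df in signals.items():
            for row in df.itertuples():
                cn = truth.copy_number(sample, row.chrom, row.position)
                expected = math.log2(max(cn, config.cn_floor) / 2.0)
                assert row.log_ratio == pytest.approx(expected, abs=0)
        # the three copy-number archetypes appear with their exact ratios
        values = set()
        for df in signals.values():
            values.update(np.round(df["log_ratio"], 6))
        assert 0.0 in values  # CN 2
        assert 2.0 in values  # CN 8 amplification
        assert round(math.log2(0.05), 6) in values  # CN 0 at floor 0.1


class TestSimulateQpcr:
    def test_noise_free_cq_values(self, small_sim_config):
        config = dataclasses.replace(small_sim_config, cq_sigma=0.0)
        ts = simulate_annotation(config)
        flanking, _ = assign_flanking(ts)
        truth = simulate_copy_number(ts, config)
        events, planted = simulate_qpcr(truth, config, flanking)
        assert len(events) == 4
        for ev in events:
            cn = planted[ev.event_id]
            ab = float(np.mean(ev.cq["aberration"]))
            if cn == 0:
                assert ab > config.cq_ceiling
            else:
                assert ab == pytest.approx(
                    config.base_cq - math.log2(cn / 2.0)
                )
            # diploid flanks and control at base Cq
            assert float(np.mean(ev.cq["up_flank"])) == pytest.approx(config.base_cq)
            assert float(np.mean(ev.control_cq["aberration"])) == pytest.approx(
                config.base_cq
            )


class TestSimulateCorpus:
    def test_planted_word_recoverable(self):
        config = SimConfig(seed=5, n_docs_scna=67, n_docs_non_scna=67)
        scna, non, planted = simulate_corpus(config, enriched=True)
        tdm = build_tdm([scna, non], stopwords=[])
        assert "cancer" in planted
        p = word_enrichment_test("cancer", tdm)
        assert p < 1e-4

    def test_null_has_no_planted_signal(self):
        config = SimConfig(seed=6, n_docs_scna=40, n_docs_non_scna=40)
        scna, non, _ = simulate_corpus(config, enriched=False)
        tdm = build_tdm([scna, non], stopwords=[])
        assert word_enrichment_test("cancer", tdm) > 0.001

    def test_zero_documents_rejected(self):
        config = SimConfig(n_docs_scna=0)
        with pytest.raises(SimulationError):
            simulate_corpus(config)

    def test_deterministic(self):
        config = SimConfig(seed=9, n_docs_scna=5, n_docs_non_scna=5)
        a = simulate_corpus(config)
        b = simulate_corpus(config)
        assert a[0].documents == b[0].documents
        assert a[1].documents == b[1].documents
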