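"""Synthetic genomes, copy-number landscapes, probe signals, qPCR and corpora.

Every pipeline stage is testable without external data: this module plants a
known truth (gene placement, copy-number events, qPCR copy states, enriched
words) and emits the same containers and file formats the pipeline consumes.

The copy-number model is deliberately simple: a diploid background (CN 2),
arm-level events spanning chromosome fractions, focal events covering one
intergenic lncRNA gene (span plus a margin, always stopping short of the
flanking protein-coding exons), and stacked events nesting a focal
homozygous deletion (CN 0) inside an arm-level heterozygous deletion (CN 1).
Probe log2 ratios are log2(max(CN, cn_floor)/2) plus Gaussian noise; the
copy-number floor keeps homozygous-deletion ratios at the finite
high-magnitude values real arrays produce (~ -4.3 at floor 0.1). qPCR Cq
values follow Cq = base - log2(max(CN, floor)/2) + noise with a much smaller
floor, so a true CN 0 lands above the no-amplification ceiling. Sequence
content, hybridisation physics and GC waves are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    Exon,
    FlankingPair,
    Transcript,
    assign_flanking,
)
from .probedesign import ProbeDesign
from .qpcr import QpcrEvent
from .textmine import Corpus


class SimulationError(ValueError):
    pass


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults model a desk-scale genome: 5 chromosomes of 10 Mb carrying 100
    protein-coding and 50 intergenic lncRNA genes, a 5-sample panel with 10
    planted focal deletions (CN 0) and 10 focal amplifications (CN 8), and
    noise-free probes (sigma in log2 units; set 0.25 for a realistic array).
    """

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    n_pc_genes: int = 100
    n_lnc_genes: int = 50
    pc_exon_count: tuple[int, int] = (4, 8)
    pc_exon_length: tuple[int, int] = (120, 300)
    lnc_exon_count: tuple[int, int] = (2, 4)
    lnc_exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (800, 3000)
    min_gene_gap: int = 20_000
    # copy-number events
    n_samples: int = 5
    n_focal_del: int = 10
    n_focal_amp: int = 10
    n_arm_level: int = 0
    n_stacked: int = 0
    cn_del: int = 0
    cn_amp: int = 8
    focal_margin: int = 500
    # probe signal
    probe_sigma: float = 0.0
    cn_floor: float = 0.1
    # exclusion tracks
    n_segdups: int = 5
    n_variants: int = 30
    track_interval_length: tuple[int, int] = (5_000, 50_000)
    # qPCR
    base_cq: float = 25.0
    cq_sigma: float = 0.15
    n_replicates: int = 3
    qpcr_cn_floor: float = 0.001
    cq_ceiling: float = 35.0
    # corpus
    vocab_size: int = 500
    tokens_per_doc: int = 150
    n_docs_scna: int = 127
    n_docs_non_scna: int = 2257
    planted_words: tuple[tuple[str, float], ...] = (("cancer", 5.0),)
    planted_base_rate: float = 0.002


@dataclass(slots=True)
class PlantedEvent:
    sample: str
    kind: str  # "focal_lnc" | "arm_level" | "stacked"
    chrom: str
    start: int
    end: int
    cn: int
    lnc_gene_id: str | None = None
    direction: str | None = None  # for lncRNA-targeted events


@dataclass(slots=True)
class TruthSet:
    """Planted truth: ordered CN intervals per sample (later entries
    override earlier ones where they overlap) and the planted events."""

    intervals: dict[str, list[tuple[str, int, int, int]]] = field(
        default_factory=dict
    )
    events: list[PlantedEvent] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def copy_number(self, sample: str, chrom: str, position: int) -> int:
        cn = 2
        for c, s, e, value in self.intervals.get(sample, ()):
            if c == chrom and s <= position < e:
                cn = value
        return cn

    def focal_events(self) -> list[PlantedEvent]:
        return [e for e in self.events if e.kind in ("focal_lnc", "stacked")]


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    root = np.random.SeedSequence(config.seed)
    # stable named streams so each generator is independently reproducible
    streams = ["annotation", "copy_number", "tracks", "signals", "qpcr", "corpus"]
    children = root.spawn(len(streams))
    return np.random.default_rng(children[streams.index(stream)])


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    biotype: str,
    chrom: str,
    start: int,
    config: SimConfig,
) -> Transcript:
    if biotype == "protein_coding":
        n_lo, n_hi = config.pc_exon_count
        l_lo, l_hi = config.pc_exon_length
    else:
        n_lo, n_hi = config.lnc_exon_count
        l_lo, l_hi = config.lnc_exon_length
    n_exons = int(rng.integers(n_lo, n_hi + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for k in range(n_exons):
        length = int(rng.integers(l_lo, l_hi + 1))
        exons.append(Exon(chrom=chrom, start=pos, end=pos + length, strand=strand))
        pos += length
        if k < n_exons - 1:
            pos += int(rng.integers(*config.intron_length))
    return Transcript(
        id=f"{gene_id}.1", gene_id=gene_id, biotype=biotype, exons=tuple(exons)
    )


def _gene_body_length(rng: np.random.Generator, biotype: str, config: SimConfig) -> int:
    # generous upper bound used only for feasibility checks
    if biotype == "protein_coding":
        return config.pc_exon_count[1] * (
            config.pc_exon_length[1] + config.intron_length[1]
        )
    return config.lnc_exon_count[1] * (
        config.lnc_exon_length[1] + config.intron_length[1]
    )


def simulate_annotation(config: SimConfig) -> list[Transcript]:
    """Seeded placement of protein-coding and intergenic lncRNA genes.

    Genes are interleaved along each chromosome with protein-coding genes at
    both ends, so every lncRNA has both neighbours; inter-gene gaps share the
    chromosome's free space. Deterministic for a fixed seed.
    """
    rng = _rng(config, "annotation")
    n_chrom = config.n_chromosomes
    pc_per = [config.n_pc_genes // n_chrom] * n_chrom
    lnc_per = [config.n_lnc_genes // n_chrom] * n_chrom
    for i in range(config.n_pc_genes % n_chrom):
        pc_per[i] += 1
    for i in range(config.n_lnc_genes % n_chrom):
        lnc_per[i] += 1

    transcripts: list[Transcript] = []
    pc_idx = lnc_idx = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        if lnc_per[c] > 0 and pc_per[c] < 2:
            raise SimulationError(
                f"{chrom}: need >= 2 protein-coding genes to flank lncRNAs"
            )
        labels = ["pc"] * (pc_per[c] - 2) + ["lnc"] * lnc_per[c]
        rng.shuffle(labels)
        labels = ["pc"] + labels + ["pc"] if pc_per[c] >= 2 else ["pc"] * pc_per[c]
        max_body = max(
            _gene_body_length(rng, "protein_coding", config),
            _gene_body_length(rng, "lncRNA", config),
        )
        budget = config.chrom_length - len(labels) * (max_body + config.min_gene_gap)
        if budget < 0:
            raise SimulationError(
                f"{chrom}: chromosome too small; needs >= "
                f"{len(labels) * (max_body + config.min_gene_gap)} bp"
            )
        extra = rng.dirichlet(np.ones(len(labels) + 1)) * budget
        pos = int(config.min_gene_gap + extra[0])
        for k, label in enumerate(labels):
            if label == "pc":
                pc_idx += 1
                t = _make_gene(
                    rng, f"PC{pc_idx:04d}", "protein_coding", chrom, pos, config
                )
            else:
                lnc_idx += 1
                t = _make_gene(rng, f"LNC{lnc_idx:04d}", "lncRNA", chrom, pos, config)
            transcripts.append(t)
            pos = t.end + config.min_gene_gap + int(extra[k + 1])
    return transcripts


def simulate_tracks(
    transcripts: Sequence[Transcript],
    config: SimConfig,
    decoy_events: Sequence[PlantedEvent] = (),
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Random segmental-duplication and known-variant interval sets.

    Tracks are placed in inter-gene space so they do not interfere with
    planted focal events; ``decoy_events`` optionally drops > max_variants
    variant intervals onto specific events to exercise the variant rule.
    """
    rng = _rng(config, "tracks")
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        gene_spans.setdefault(t.chrom, []).append((t.start, t.end))
    chroms = sorted(gene_spans)

    def place(n: int) -> list[tuple[str, int, int]]:
        out = []
        attempts = 0
        while len(out) < n and attempts < 50 * max(1, n):
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(*config.track_interval_length))
            start = int(rng.integers(0, max(1, config.chrom_length - length)))
            if any(
                start < ge and gs < start + length
                for gs, ge in gene_spans.get(chrom, ())
            ):
                continue
            out.append((chrom, start, start + length))
        return out

    segdups = place(config.n_segdups)
    variants = place(config.n_variants)
    for ev in decoy_events:
        # four variant intervals inside the event interval: rule 3 trigger
        width = max(10, (ev.end - ev.start) // 6)
        for k in range(4):
            s = ev.start + k * width
            variants.append((ev.chrom, s, min(ev.end, s + width)))
    return segdups, variants


def simulate_copy_number(
    transcripts: Sequence[Transcript], config: SimConfig
) -> TruthSet:
    """Plant the configured copy-number events on distinct lncRNA genes.

    Focal events cover the lncRNA gene span plus a margin clipped to stop
    short of both nearest flanking exons; a lncRNA too close to a flank exon
    for any positive margin is skipped and the event re-assigned (logged).
    Stacked events nest the focal CN-0 deletion inside a CN-1 interval that
    also covers both flanking genes.
    """
    rng = _rng(config, "copy_number")
    flanking, _ = assign_flanking(transcripts)
    truth = TruthSet()
    samples = [f"S{k + 1:02d}" for k in range(config.n_samples)]
    for s in samples:
        truth.intervals[s] = []

    # arm-level events first (focal/stacked may override locally)
    for k in range(config.n_arm_level):
        sample = samples[k % len(samples)]
        chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        frac = float(rng.uniform(0.3, 0.6))
        width = int(frac * config.chrom_length)
        if rng.random() < 0.5:
            start, end = 0, width
        else:
            start, end = config.chrom_length - width, config.chrom_length
        cn = 1 if rng.random() < 0.5 else 3
        truth.intervals[sample].append((chrom, start, end, cn))
        truth.events.append(
            PlantedEvent(
                sample=sample, kind="arm_level", chrom=chrom, start=start, end=end, cn=cn
            )
        )

    candidates = [gid for gid in sorted(flanking)]
    rng.shuffle(candidates)
    queue = list(candidates)

    def focal_interval(gid: str, margin: int) -> tuple[str, int, int] | None:
        pair = flanking[gid]
        lo_limit = 0
        hi_limit = config.chrom_length
        up = pair.nearest_flank_exon("up")
        down = pair.nearest_flank_exon("down")
        if up is not None:
            lo_limit = up.end + 1
        if down is not None:
            hi_limit = down.start - 1
        start = max(lo_limit, pair.lnc_start - margin)
        end = min(hi_limit, pair.lnc_end + margin)
        if start > pair.lnc_start or end < pair.lnc_end or start >= end:
            return None
        return pair.chrom, start, end

    def next_gene(sample: str) -> tuple[str, tuple[str, int, int]] | None:
        while queue:
            gid = queue.pop()
            iv = focal_interval(gid, config.focal_margin)
            if iv is None:
                truth.log.append(f"reassigned\t{gid}\ttoo_close_to_flank")
                continue
            chrom, s, e = iv
            if any(
                c == chrom and s < ee and ss < e
                for c, ss, ee, _ in truth.intervals[sample]
            ):
                truth.log.append(f"reassigned\t{gid}\tcollision_in_{sample}")
                continue
            return gid, iv
        return None

    specs = (
        [("focal_lnc", config.cn_del, "loss")] * config.n_focal_del
        + [("focal_lnc", config.cn_amp, "gain")] * config.n_focal_amp
        + [("stacked", 0, "loss")] * config.n_stacked
    )
    for k, (kind, cn, direction) in enumerate(specs):
        sample = samples[k % len(samples)]
        picked = next_gene(sample)
        if picked is None:
            raise SimulationError("not enough eligible lncRNA genes for events")
        gid, (chrom, start, end) = picked
        if kind == "stacked":
            pair = flanking[gid]
            # outer CN-1 interval covering both flanking genes
            pcs = {t.id: t for t in transcripts if t.biotype == "protein_coding"}
            outer_start = max(0, start - 2 * config.min_gene_gap)
            outer_end = min(config.chrom_length, end + 2 * config.min_gene_gap)
            if pair.upstream_pc and pair.upstream_pc in pcs:
                outer_start = min(outer_start, pcs[pair.upstream_pc].start - 1000)
            if pair.downstream_pc and pair.downstream_pc in pcs:
                outer_end = max(outer_end, pcs[pair.downstream_pc].end + 1000)
            truth.intervals[sample].append((chrom, outer_start, outer_end, 1))
            truth.intervals[sample].append((chrom, start, end, 0))
        else:
            truth.intervals[sample].append((chrom, start, end, cn))
        truth.events.append(
            PlantedEvent(
                sample=sample,
                kind=kind,
                chrom=chrom,
                start=start,
                end=end,
                cn=cn,
                lnc_gene_id=gid,
                direction=direction,
            )
        )
    return truth


def simulate_probe_signals(
    design: ProbeDesign,
    truth: TruthSet,
    config: SimConfig,
) -> dict[str, pd.DataFrame]:
    """Per-sample probe signal tables from the planted copy numbers.

    log_ratio = log2(max(CN, cn_floor)/2) + Normal(0, sigma), with the CN
    looked up at the probe midpoint (CN 2 outside all truth intervals).
    """
    rng = _rng(config, "signals")
    probes = sorted(design.probes.values(), key=lambda p: (p.chrom, p.start, p.end))
    out: dict[str, pd.DataFrame] = {}
    for sample in sorted(truth.intervals):
        rows = []
        for i, p in enumerate(probes):
            cn = truth.copy_number(sample, p.chrom, p.midpoint)
            lr = float(np.log2(max(cn, config.cn_floor) / 2.0))
            rows.append(
                {
                    "probe_id": f"P{i + 1:06d}",
                    "chrom": p.chrom,
                    "position": p.midpoint,
                    "log_ratio": lr,
                }
            )
        df = pd.DataFrame(rows)
        if config.probe_sigma > 0:
            df["log_ratio"] += rng.normal(0.0, config.probe_sigma, size=len(df))
        out[sample] = df
    return out


def _cq(cn: float, config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    base = config.base_cq - np.log2(max(cn, config.qpcr_cn_floor) / 2.0)
    return base + rng.normal(0.0, config.cq_sigma, size=n)


def simulate_qpcr(
    truth: TruthSet,
    config: SimConfig,
    flanking: Mapping[str, FlankingPair] | None = None,
) -> tuple[list[QpcrEvent], dict[str, int]]:
    """Replicate Cq tables for every planted lncRNA-targeted event.

    The aberration assay sits inside the event interval; flank assays sit on
    the nearest flanking exons (copy number from the truth at that point).
    The control sample is diploid for every assay. Returns the events and
    the planted aberration copy number per event id.
    """
    rng = _rng(config, "qpcr")
    events: list[QpcrEvent] = []
    planted_cn: dict[str, int] = {}
    for k, ev in enumerate(truth.focal_events()):
        eid = f"E{k + 1:03d}"
        mid = (ev.start + ev.end) // 2
        roles: dict[str, int | float] = {"aberration": ev.cn}
        if flanking is not None and ev.lnc_gene_id in flanking:
            pair = flanking[ev.lnc_gene_id]
            for side, role in (("up", "up_flank"), ("down", "down_flank")):
                exon = pair.nearest_flank_exon(side)
                if exon is not None:
                    roles[role] = truth.copy_number(
                        ev.sample, exon.chrom, (exon.start + exon.end) // 2
                    )
        else:
            roles["up_flank"] = truth.copy_number(ev.sample, ev.chrom, ev.start - 1)
            roles["down_flank"] = truth.copy_number(ev.sample, ev.chrom, ev.end + 1)
        cq = {r: _cq(cn, config, rng, config.n_replicates) for r, cn in roles.items()}
        control = {r: _cq(2, config, rng, config.n_replicates) for r in roles}
        events.append(
            QpcrEvent(
                event_id=eid,
                direction=ev.direction or "loss",
                cq=cq,
                control_cq=control,
                cq_ceiling=config.cq_ceiling,
            )
        )
        planted_cn[eid] = ev.cn
    return events, planted_cn


def simulate_copy_state_panel(
    copy_numbers: Sequence[int],
    config: SimConfig,
    seed_offset: int = 0,
) -> tuple[list[QpcrEvent], list[str]]:
    """Cq data for a panel of loci with planted copy numbers (diploid flanks).

    Used to benchmark copy-state classification; returns the events and the
    true copy-state labels (CN 0 -> homozygous_del, 1 -> het_del, 2 ->
    neutral, > 2 -> gain).
    """
    rng = np.random.default_rng([config.seed, 104729, seed_offset])
    events = []
    labels = []
    for k, cn in enumerate(copy_numbers):
        roles = {"aberration": cn, "up_flank": 2, "down_flank": 2}
        cq = {r: _cq(c, config, rng, config.n_replicates) for r, c in roles.items()}
        control = {r: _cq(2, config, rng, config.n_replicates) for r in roles}
        direction = "gain" if cn > 2 else "loss"
        events.append(
            QpcrEvent(
                event_id=f"CS{k + 1:03d}",
                direction=direction,
                cq=cq,
                control_cq=control,
                cq_ceiling=config.cq_ceiling,
            )
        )
        labels.append(
            "homozygous_del"
            if cn == 0
            else "het_del"
            if cn == 1
            else "neutral"
            if cn == 2
            else "gain"
        )
    return events, labels


def _word(i: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = []
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out.append(letters[r])
    return "tok" + "".join(reversed(out))


def simulate_corpus(
    config: SimConfig, enriched: bool = True
) -> tuple[Corpus, Corpus, dict[str, float]]:
    """Two corpora drawn word-by-word from group-specific multinomials.

    Background words follow a Zipf-like distribution; each planted word gets
    ``planted_base_rate`` in the non-SCNA group and that rate times its
    multiplier in the SCNA group (multiplier 1 when ``enriched`` is False,
    the null calibration setting).
    """
    rng = _rng(config, "corpus")
    if config.n_docs_scna < 1 or config.n_docs_non_scna < 1:
        raise SimulationError("each corpus needs >= 1 document")
    vocab = [_word(i) for i in range(config.vocab_size)]
    base = 1.0 / (np.arange(config.vocab_size) + 1.0)
    planted = {w: (m if enriched else 1.0) for w, m in config.planted_words}

    def probs(group: str) -> tuple[list[str], np.ndarray]:
        words = list(vocab)
        p = list(base / base.sum() * (1.0 - config.planted_base_rate * len(planted) * 5))
        for w, mult in planted.items():
            rate = config.planted_base_rate * (mult if group == "scna" else 1.0)
            words.append(w)
            p.append(rate)
        arr = np.asarray(p)
        return words, arr / arr.sum()

    corpora = []
    for group, n_docs in (
        ("scna", config.n_docs_scna),
        ("non_scna", config.n_docs_non_scna),
    ):
        words, p = probs(group)
        docs = []
        for _ in range(n_docs):
            draw = rng.choice(len(words), size=config.tokens_per_doc, p=p)
            docs.append(" ".join(words[i] for i in draw))
        corpora.append(Corpus(label=group, documents=docs))
    return corpora[0], corpora[1], planted


def noisy_config(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: same genome conditions, new seed."""
    return replace(config, seed=seed)
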