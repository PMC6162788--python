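"""Filter cascade turning segments into focal lncRNA copy-number calls.

A segment becomes a focal call for a lncRNA gene only if every rule holds:

1. the segment overlaps at least one exon of the lncRNA;
2. the segment is not fully contained within a segmental duplication;
3. the segment overlaps at most ``max_variants`` known germline CNV intervals;
4. |mean log-ratio| >= ``t_focal`` (homozygous deletions / amplifications);
5. for gains, the segment's probe-support interval contains the entire
   lncRNA gene span (partial amplifications are discarded);
6. the segment overlaps none of the flanking protein-coding flank exons;
7. for each existing flank, the |mean log-ratio| of the lncRNA segment
   exceeds that of the nearest segment covering the flank's nearest exon by
   at least ``flank_delta``.

Calls whose flanking segments are both copy-number neutral
(|mean| < ``t_neutral``) form the stringent subset; the remainder captures
superimposed events such as a homozygous deletion nested in a larger
heterozygous deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import FlankingPair, LncGene

CALL_COLUMNS = [
    "sample",
    "lnc_gene_id",
    "chrom",
    "start",
    "end",
    "n_probes",
    "mean_lr",
    "direction",
    "high_confidence",
    "stringency",
    "flank_up_lr",
    "flank_down_lr",
]


@dataclass(slots=True)
class FilterConfig:
    t_focal: float = 1.5
    t_high: float = 2.5
    max_variants: int = 3
    flank_delta: float = 0.5
    t_neutral: float = 0.35

    def __post_init__(self) -> None:
        if not self.t_focal < self.t_high:
            raise ValueError("t_focal must be < t_high")
        if not self.t_neutral < self.t_focal:
            raise ValueError("t_neutral must be < t_focal")


@dataclass(slots=True)
class ExclusionTracks:
    """Segmental-duplication and known-variant interval sets (half-open)."""

    segdups: list[tuple[str, int, int]] = field(default_factory=list)
    known_variants: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in [*self.segdups, *self.known_variants]:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")

    def trees(self) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
        def build(intervals: Iterable[tuple[str, int, int]]):
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            return trees

        return build(self.segdups), build(self.known_variants)


@dataclass(slots=True)
class FocalCall:
    sample: str
    lnc_gene_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_lr: float
    direction: str  # "loss" | "gain"
    high_confidence: bool
    stringency: str  # "standard" | "stringent"
    flank_up_lr: float | None
    flank_down_lr: float | None


@dataclass(slots=True)
class FilterLog:
    """Per-rule attrition. ``candidates`` counts (segment, lncRNA) pairs
    passing rule 1; every candidate is either retained or attributed to the
    first rule that discarded it."""

    n_segments: int = 0
    candidates: int = 0
    segdup_contained: int = 0
    too_many_variants: int = 0
    below_t_focal: int = 0
    gain_not_containing: int = 0
    flank_exon_overlap: int = 0
    flank_contrast: int = 0
    no_flank_segment: int = 0
    retained: int = 0
    messages: list[str] = field(default_factory=list)

    def consistent(self) -> bool:
        discards = (
            self.segdup_contained
            + self.too_many_variants
            + self.below_t_focal
            + self.gain_not_containing
            + self.flank_exon_overlap
            + self.flank_contrast
            + self.no_flank_segment
        )
        return self.candidates == self.retained + discards


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _support_bounds(segments: pd.DataFrame) -> pd.DataFrame:
    """Extend segment bounds to the probe-support interval.

    Segment coordinates run probe-to-probe; the true event boundary lies
    somewhere between the outermost member probe and the adjacent probe of
    the neighbouring segment, so the support interval extends each bound to
    that midpoint (unbounded at chromosome extremes). Used only for the
    gain full-containment rule.
    """
    out = segments.copy()
    out["support_start"] = -math.inf
    out["support_end"] = math.inf
    for chrom, idx in segments.groupby("chrom").groups.items():
        rows = segments.loc[idx].sort_values("start")
        starts = rows["start"].to_numpy()
        ends = rows["end"].to_numpy()
        sup_start = [-math.inf] + [
            (ends[k - 1] - 1 + starts[k]) / 2 for k in range(1, len(rows))
        ]
        sup_end = [
            (ends[k] - 1 + starts[k + 1]) / 2 for k in range(len(rows) - 1)
        ] + [math.inf]
        out.loc[rows.index, "support_start"] = sup_start
        out.loc[rows.index, "support_end"] = sup_end
    return out


def _nearest_flank_segment(
    pair: FlankingPair,
    side: str,
    segments: pd.DataFrame,
) -> float | None:
    """mean_lr of the segment covering the flank exon nearest the lncRNA.

    Among segments overlapping that exon, the one with the greatest overlap
    wins; ties go to the segment nearer the lncRNA. None when no segment
    covers the exon.
    """
    exon = pair.nearest_flank_exon(side)
    if exon is None:
        return None
    best = None
    best_key = None
    for row in segments.itertuples():
        if row.chrom != exon.chrom:
            continue
        ov = _overlap_len(row.start, row.end, exon.start, exon.end)
        if ov <= 0:
            continue
        if side == "up":
            dist_to_lnc = max(0, pair.lnc_start - row.end)
        else:
            dist_to_lnc = max(0, row.start - pair.lnc_end)
        key = (-ov, dist_to_lnc, row.start)
        if best_key is None or key < best_key:
            best_key = key
            best = row.mean_lr
    return best


def apply_filters(
    segments: pd.DataFrame,
    lnc_genes: Mapping[str, LncGene],
    flanking: Mapping[str, FlankingPair],
    tracks: ExclusionTracks,
    config: FilterConfig | None = None,
    sample: str = "sample",
) -> tuple[list[FocalCall], FilterLog]:
    """Apply the full cascade to one sample's segment table.

    A segment overlapping exons of multiple lncRNA genes is evaluated once
    per gene; the emitted call set is independent of input segment order.
    """
    config = config or FilterConfig()
    log = FilterLog(n_segments=len(segments))
    segdup_trees, variant_trees = tracks.trees()
    segments = segments.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    supported = _support_bounds(segments)
    calls: list[FocalCall] = []

    for gid in sorted(lnc_genes):
        gene = lnc_genes[gid]
        pair = flanking.get(gid)
        for row in supported.itertuples():
            if row.chrom != gene.chrom:
                continue
            # rule 1: overlaps >= 1 lncRNA exon
            if not any(e.overlaps(row.start, row.end) for e in gene.exons):
                continue
            log.candidates += 1
            # rule 2: not fully contained within a segmental duplication
            tree = segdup_trees.get(row.chrom)
            if tree is not None and any(
                iv.begin <= row.start and row.end <= iv.end
                for iv in tree.overlap(row.start, row.end)
            ):
                log.segdup_contained += 1
                continue
            # rule 3: <= max_variants known-variant overlaps
            vtree = variant_trees.get(row.chrom)
            n_var = len(vtree.overlap(row.start, row.end)) if vtree is not None else 0
            if n_var > config.max_variants:
                log.too_many_variants += 1
                continue
            # rule 4: amplitude
            if abs(row.mean_lr) < config.t_focal:
                log.below_t_focal += 1
                continue
            direction = "gain" if row.mean_lr > 0 else "loss"
            # rule 5: gains must contain the entire gene span
            if direction == "gain" and not (
                row.support_start <= gene.start and gene.end <= row.support_end
            ):
                log.gain_not_containing += 1
                continue
            # rule 6: no overlap with any flank exon
            flank_exons = (
                [*pair.upstream_flank_exons, *pair.downstream_flank_exons]
                if pair
                else []
            )
            if any(
                e.chrom == row.chrom and e.overlaps(row.start, row.end)
                for e in flank_exons
            ):
                log.flank_exon_overlap += 1
                continue
            # rule 7: flank contrast on every evaluable side
            flank_lrs: dict[str, float | None] = {"up": None, "down": None}
            evaluable = 0
            ok = True
            for side in ("up", "down"):
                if pair is None or not pair.flank_exons(side):
                    continue
                flank_lr = _nearest_flank_segment(pair, side, segments)
                flank_lrs[side] = flank_lr
                if flank_lr is None:
                    continue
                evaluable += 1
                if abs(row.mean_lr) - abs(flank_lr) < config.flank_delta:
                    ok = False
            if evaluable == 0:
                log.no_flank_segment += 1
                log.messages.append(
                    f"no_flank_segment\t{sample}\t{gid}\t{row.chrom}:{row.start}-{row.end}"
                )
                continue
            if not ok:
                log.flank_contrast += 1
                continue
            log.retained += 1
            call = FocalCall(
                sample=sample,
                lnc_gene_id=gid,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                n_probes=int(row.n_probes),
                mean_lr=float(row.mean_lr),
                direction=direction,
                high_confidence=abs(row.mean_lr) > config.t_high,
                stringency="standard",
                flank_up_lr=flank_lrs["up"],
                flank_down_lr=flank_lrs["down"],
            )
            call.stringency = classify_stringency(call, config)
            calls.append(call)
    return calls, log


def classify_stringency(call: FocalCall, config: FilterConfig | None = None) -> str:
    """Stringent iff every existing flank segment is copy-number neutral.

    Neutrality is |mean_lr| < t_neutral, strictly; a flank sitting exactly at
    the threshold keeps the call in the standard class (superimposed events).
    """
    config = config or FilterConfig()
    flanks = [lr for lr in (call.flank_up_lr, call.flank_down_lr) if lr is not None]
    if flanks and all(abs(lr) < config.t_neutral for lr in flanks):
        return "stringent"
    return "standard"


def calls_to_frame(calls: Sequence[FocalCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "lnc_gene_id": c.lnc_gene_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_probes": c.n_probes,
                "mean_lr": c.mean_lr,
                "direction": c.direction,
                "high_confidence": c.high_confidence,
                "stringency": c.stringency,
                "flank_up_lr": c.flank_up_lr,
                "flank_down_lr": c.flank_down_lr,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def recurrence_summary(
    calls: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-lncRNA recurrence across samples, plus the sample-count histogram.

    Returns a table (lnc_gene_id, n_samples, n_loss, n_gain, n_high_conf) and
    the histogram {affected-sample count: number of lncRNAs}.
    """
    if calls.empty:
        return (
            pd.DataFrame(
                columns=["lnc_gene_id", "n_samples", "n_loss", "n_gain", "n_high_conf"]
            ),
            {},
        )
    rows = []
    for gid, sub in calls.groupby("lnc_gene_id"):
        rows.append(
            {
                "lnc_gene_id": gid,
                "n_samples": sub["sample"].nunique(),
                "n_loss": int((sub["direction"] == "loss").sum()),
                "n_gain": int((sub["direction"] == "gain").sum()),
                "n_high_conf": int(sub["high_confidence"].sum()),
            }
        )
    table = pd.DataFrame(rows).sort_values("lnc_gene_id").reset_index(drop=True)
    hist = table["n_samples"].value_counts().sort_index()
    return table, {int(k): int(v) for k, v in hist.items()}


def call_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """lncRNA x sample matrix of signed categories for heatmap export.

    +1 gain / -1 loss, doubled (+-2) for high-confidence calls; 0 = no call.
    """
    if calls.empty:
        return pd.DataFrame()
    coded = calls.assign(
        code=[
            (1 if d == "gain" else -1) * (2 if h else 1)
            for d, h in zip(calls["direction"], calls["high_confidence"])
        ]
    )
    return (
        coded.pivot_table(
            index="lnc_gene_id", columns="sample", values="code", aggfunc="sum"
        )
        .fillna(0)
        .astype(int)
    )
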