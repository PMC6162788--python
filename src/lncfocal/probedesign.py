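"""Tiered probe selection for lncRNA exons and their flanking exons.

The targeted array design aims for two probes per lncRNA exon, falling back
to progressively extended exon neighbourhoods (100/300/500 bp, plus a relaxed
500 bp tier) when an exon cannot accommodate them, at least 10 probes per
transcript for transcripts with few exons, and two probes on each of the two
nearest exons of both flanking protein-coding genes.

Candidate generation is a deterministic coordinate tiling (probe sequence
thermodynamics is out of scope); the relaxed tier admits tiling phases the
strict tiers skip. Selection minimises distance to the exon, preferring lower
tiers, with deterministic tie-breaks, and never selects the same genomic
coordinates twice across overlapping exons or transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import Exon, FlankingPair, Transcript

TIERS = ("exon", "ext100", "ext300", "ext500", "ext500_relaxed")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}


@dataclass(frozen=True, order=True, slots=True)
class ProbeCandidate:
    chrom: str
    start: int
    end: int
    tier: str = "exon"
    distance_to_exon: int = 0

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(slots=True)
class ProbeConfig:
    """Tiling and selection parameters.

    probe_length/tile_step in bp; ``extensions`` are the neighbourhood
    half-widths of the fallback tiers; the relaxed tier re-tiles the widest
    window at a phase offset (default half a step) so it admits candidates
    the strict tiers reject.
    """

    probe_length: int = 60
    tile_step: int | None = None  # default: probe_length // 2
    extensions: tuple[int, ...] = (100, 300, 500)
    relaxed_offset: int | None = None  # default: step // 2
    probes_per_exon: int = 2
    min_probes_per_transcript: int = 10
    few_exon_threshold: int = 5
    flank_probes_per_gene: int = 2

    @property
    def step(self) -> int:
        return self.tile_step if self.tile_step is not None else self.probe_length // 2

    @property
    def offset(self) -> int:
        return self.relaxed_offset if self.relaxed_offset is not None else max(1, self.step // 2)


@dataclass(slots=True)
class ProbeDesign:
    """Selected probes with per-transcript and per-exon provenance."""

    probes: dict[tuple[str, int, int], ProbeCandidate] = field(default_factory=dict)
    per_exon: dict[Exon, list[ProbeCandidate]] = field(default_factory=dict)
    per_transcript: dict[str, int] = field(default_factory=dict)
    flank_probes: dict[tuple[str, str], list[ProbeCandidate]] = field(
        default_factory=dict
    )  # (lnc_gene_id, side) -> probes
    uncovered_exons: list[Exon] = field(default_factory=list)
    report: list[str] = field(default_factory=list)

    def add(self, probe: ProbeCandidate) -> bool:
        """Insert into the global set; False if coordinates already present."""
        if probe.coords in self.probes:
            return False
        self.probes[probe.coords] = probe
        return True


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def _tile(
    chrom: str,
    w_start: int,
    w_end: int,
    exon: Exon,
    tier: str,
    length: int,
    step: int,
) -> list[ProbeCandidate]:
    w_start = max(0, w_start)
    out = []
    for s in range(w_start, w_end - length + 1, step):
        out.append(
            ProbeCandidate(
                chrom=chrom,
                start=s,
                end=s + length,
                tier=tier,
                distance_to_exon=_interval_distance(s, s + length, exon.start, exon.end),
            )
        )
    return out


def generate_candidates(exon: Exon, config: ProbeConfig) -> list[ProbeCandidate]:
    """Deterministic tiling of all five tiers for one exon.

    An exon shorter than the probe length yields an empty exon tier; the
    extension tiers are still produced.
    """
    L, step = config.probe_length, config.step
    out: list[ProbeCandidate] = []
    out += _tile(exon.chrom, exon.start, exon.end, exon, "exon", L, step)
    for ext in config.extensions:
        out += _tile(
            exon.chrom, exon.start - ext, exon.end + ext, exon, f"ext{ext}", L, step
        )
    wide = config.extensions[-1] if config.extensions else 0
    out += _tile(
        exon.chrom,
        exon.start - wide + config.offset,
        exon.end + wide,
        exon,
        f"ext{wide}_relaxed",
        L,
        step,
    )
    return out


def _rank_key(c: ProbeCandidate) -> tuple:
    # lower tier first, then nearest, then leftmost
    return (c.distance_to_exon, TIER_RANK.get(c.tier, len(TIERS)), c.start, c.end)


def _select_for_exon(
    exon: Exon,
    ranked: Sequence[ProbeCandidate],
    design: ProbeDesign,
    quota: int,
) -> None:
    chosen = design.per_exon.setdefault(exon, [])
    for cand in ranked:
        if len(chosen) >= quota:
            break
        if cand.coords in design.probes:
            # already selected for an overlapping exon: counts for this exon
            # but is not re-selected
            if design.probes[cand.coords] not in chosen:
                chosen.append(design.probes[cand.coords])
            continue
        design.add(cand)
        chosen.append(cand)


def select_probes(
    transcripts: Sequence[Transcript],
    catalogue: Iterable[Exon],
    candidates: Mapping[Exon, Sequence[ProbeCandidate]],
    config: ProbeConfig | None = None,
    design: ProbeDesign | None = None,
) -> ProbeDesign:
    """Two probes per catalogue exon, plus fill-up for few-exon transcripts.

    Exons are processed in coordinate order and transcripts in id order, so
    the outcome is invariant to input ordering. Probes already selected for an
    overlapping exon are attributed but never duplicated. Transcripts with
    fewer than ``few_exon_threshold`` exons receive extra candidates
    round-robin across their exons, nearest-first, until they reach
    ``min_probes_per_transcript`` probes or candidates are exhausted.
    """
    config = config or ProbeConfig()
    design = design or ProbeDesign()
    ranked_by_exon = {
        exon: sorted(candidates.get(exon, ()), key=_rank_key)
        for exon in sorted(catalogue)
    }

    for exon, ranked in ranked_by_exon.items():
        if not ranked:
            design.uncovered_exons.append(exon)
            design.report.append(
                f"uncovered_exon\t{exon.chrom}:{exon.start}-{exon.end}"
            )
            design.per_exon.setdefault(exon, [])
            continue
        _select_for_exon(exon, ranked, design, config.probes_per_exon)

    def transcript_probes(t: Transcript) -> set[tuple[str, int, int]]:
        coords: set[tuple[str, int, int]] = set()
        for e in t.exons:
            coords.update(p.coords for p in design.per_exon.get(e, ()))
        return coords

    # fill-up stage for few-exon transcripts
    for t in sorted(transcripts, key=lambda t: t.id):
        if len(t.exons) >= config.few_exon_threshold:
            continue
        have = transcript_probes(t)
        if len(have) >= config.min_probes_per_transcript:
            continue
        queues = {
            e: [c for c in ranked_by_exon.get(e, ()) if c.coords not in have]
            for e in t.exons
        }
        exhausted = False
        while len(have) < config.min_probes_per_transcript and not exhausted:
            exhausted = True
            for e in t.exons:
                q = queues[e]
                while q and (q[0].coords in design.probes or q[0].coords in have):
                    # taken meanwhile (e.g. by a sibling exon's fill-up)
                    if q[0].coords in design.probes and q[0].coords not in have:
                        probe = design.probes[q[0].coords]
                        design.per_exon[e].append(probe)
                        have.add(probe.coords)
                    q.pop(0)
                if len(have) >= config.min_probes_per_transcript:
                    break
                if q:
                    cand = q.pop(0)
                    design.add(cand)
                    design.per_exon[e].append(cand)
                    have.add(cand.coords)
                    exhausted = False
        if len(have) < config.min_probes_per_transcript:
            design.report.append(
                f"underfilled_transcript\t{t.id}\t{len(have)}"
            )

    for t in transcripts:
        design.per_transcript[t.id] = len(transcript_probes(t))
    return design


def select_flank_probes(
    pair: FlankingPair,
    candidates: Mapping[Exon, Sequence[ProbeCandidate]],
    config: ProbeConfig | None = None,
    design: ProbeDesign | None = None,
) -> ProbeDesign:
    """Per flanking gene, the two candidates nearest the lncRNA span.

    Candidates are pooled over the (<= 2) flank exons of each side and ranked
    by distance to the lncRNA span; ties go to the leftmost coordinate. An
    absent flanking gene yields an empty list for that side; a side with
    fewer than the requested probes is recorded in the report.
    """
    config = config or ProbeConfig()
    design = design or ProbeDesign()
    for side in ("up", "down"):
        exons = pair.flank_exons(side)
        chosen: list[ProbeCandidate] = []
        pool: list[ProbeCandidate] = []
        seen: set[tuple[str, int, int]] = set()
        for e in exons:
            for c in candidates.get(e, ()):
                if c.coords not in seen:
                    seen.add(c.coords)
                    pool.append(c)
        pool.sort(
            key=lambda c: (
                _interval_distance(c.start, c.end, pair.lnc_start, pair.lnc_end),
                c.start,
                c.end,
                TIER_RANK.get(c.tier, len(TIERS)),
            )
        )
        for cand in pool:
            if len(chosen) >= config.flank_probes_per_gene:
                break
            if cand.coords in design.probes:
                existing = design.probes[cand.coords]
                if existing not in chosen:
                    chosen.append(existing)
                continue
            design.add(cand)
            chosen.append(cand)
        if exons and len(chosen) < config.flank_probes_per_gene:
            design.report.append(
                f"underfilled_flank\t{pair.lnc_gene_id}\t{side}\t{len(chosen)}"
            )
        design.flank_probes[(pair.lnc_gene_id, side)] = chosen
    return design


def design_probes(
    transcripts: Sequence[Transcript],
    flanking: Mapping[str, FlankingPair],
    config: ProbeConfig | None = None,
) -> ProbeDesign:
    """Full design: lncRNA exon probes plus flank probes, one global set."""
    config = config or ProbeConfig()
    lnc = [t for t in transcripts if t.biotype == "lncRNA"]
    from .annotation import dedupe_exons

    catalogue = dedupe_exons(lnc)
    candidates = {e: generate_candidates(e, config) for e in catalogue}
    design = select_probes(lnc, catalogue, candidates, config)
    flank_exons = {
        e
        for pair in flanking.values()
        for side in ("up", "down")
        for e in pair.flank_exons(side)
    }
    flank_candidates = {e: generate_candidates(e, config) for e in flank_exons}
    for gid in sorted(flanking):
        select_flank_probes(flanking[gid], flank_candidates, config, design)
    return design


def coverage_report(
    design: ProbeDesign,
    transcripts: Sequence[Transcript],
    flanking: Mapping[str, FlankingPair] | None = None,
) -> dict[str, float]:
    """Design-level coverage summary.

    Fractions of transcripts with >= min probes and with zero probes, the
    fraction of lncRNA genes whose both existing flank sides carry the full
    probe quota, and the total unique probe count.
    """
    lnc = [t for t in transcripts if t.biotype == "lncRNA"]
    n = len(lnc)
    counts = [design.per_transcript.get(t.id, 0) for t in lnc]
    at_least = sum(1 for c in counts if c >= 10) / n if n else 0.0
    zero = sum(1 for c in counts if c == 0) / n if n else 0.0
    flank_ok = 0.0
    if flanking:
        ok = 0
        for gid, pair in flanking.items():
            sides = [s for s in ("up", "down") if pair.flank_exons(s)]
            if sides and all(
                len(design.flank_probes.get((gid, s), ())) >= 2 for s in sides
            ):
                ok += 1
        flank_ok = ok / len(flanking) if flanking else 0.0
    return {
        "frac_transcripts_ge10": at_least,
        "frac_transcripts_zero": zero,
        "frac_lnc_flanks_full": flank_ok,
        "n_unique_probes": float(len(design.probes)),
    }
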