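"""Exon catalogue construction and flanking-gene assignment.

The calling strategy targets intergenic lncRNA exons and the nearest exons of
their flanking protein-coding genes. This module builds the non-redundant
exon catalogue from transcript annotation, decides which lncRNAs are
intergenic, and assigns to each lncRNA its nearest upstream and downstream
protein-coding neighbours together with the flanking exons used for probe
design and for the focal filter's flank contrast.

Coordinates are 0-based half-open (BED convention) throughout; GFF3 input is
converted on read by :mod:`lncfocal.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


class _RevStr(str):
    """String with reversed ordering, for mixed-direction sort keys."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


@dataclass(frozen=True, order=True, slots=True)
class Exon:
    """A genomic exon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("exon chromosome name must be non-empty")
        if self.start >= self.end:
            raise AnnotationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open interval overlap (>= 1 bp shared)."""
        return self.start < end and start < self.end


@dataclass(slots=True)
class Transcript:
    """A transcript: ordered non-overlapping exons on one chromosome/strand."""

    id: str
    gene_id: str
    biotype: str  # "lncRNA" or "protein_coding"
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise AnnotationError(f"transcript {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.id}: exons span multiple chromosomes/strands"
            )
        prev_end = None
        for e in self.exons:
            if prev_end is not None and e.start < prev_end:
                raise AnnotationError(
                    f"transcript {self.id}: exons overlap or are unsorted"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Transcript span start (first exon start)."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        """Transcript span end (last exon end)."""
        return self.exons[-1].end


@dataclass(slots=True)
class FlankingPair:
    """Nearest protein-coding neighbours of one lncRNA gene.

    ``upstream`` means genomically left (smaller coordinates) irrespective of
    strand. Flank exons are the <= 2 exons of each neighbour genomically
    nearest the lncRNA span; they never overlap the lncRNA span because the
    neighbours are chosen strictly outside it.
    """

    lnc_gene_id: str
    chrom: str
    lnc_start: int
    lnc_end: int
    upstream_pc: str | None = None
    downstream_pc: str | None = None
    upstream_flank_exons: tuple[Exon, ...] = ()
    downstream_flank_exons: tuple[Exon, ...] = ()

    def flank_exons(self, side: str) -> tuple[Exon, ...]:
        if side == "up":
            return self.upstream_flank_exons
        if side == "down":
            return self.downstream_flank_exons
        raise ValueError(f"side must be 'up' or 'down', got {side!r}")

    def nearest_flank_exon(self, side: str) -> Exon | None:
        """The single flank exon closest to the lncRNA on one side."""
        exons = self.flank_exons(side)
        if not exons:
            return None
        if side == "up":
            return max(exons, key=lambda e: e.end)
        return min(exons, key=lambda e: e.start)


@dataclass(slots=True)
class LncGene:
    """Per-gene aggregate of lncRNA transcripts: span and unique exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[Exon, ...]
    transcript_ids: tuple[str, ...] = field(default_factory=tuple)


def dedupe_exons(transcripts: Iterable[Transcript]) -> set[Exon]:
    """Build the non-redundant exon catalogue.

    Each distinct (chrom, start, end, strand) tuple appears exactly once.
    Overlapping-but-distinct exons are kept separate: duplicate signal over
    overlapping exons is instead resolved at probe selection.
    """
    out: set[Exon] = set()
    for t in transcripts:
        out.update(t.exons)
    return out


def exon_to_transcripts(
    transcripts: Iterable[Transcript],
) -> dict[Exon, list[str]]:
    """Map each catalogue exon to the sorted ids of transcripts carrying it."""
    mapping: dict[Exon, list[str]] = {}
    for t in transcripts:
        for e in t.exons:
            mapping.setdefault(e, []).append(t.id)
    return {e: sorted(ids) for e, ids in mapping.items()}


def _nearest_exons(t: Transcript, side: str, k: int = 2) -> tuple[Exon, ...]:
    """The k exons of ``t`` genomically nearest a locus on the given side.

    ``side == 'up'`` means ``t`` lies upstream (left) of the locus, so its
    rightmost exons are nearest; symmetric for 'down'.
    """
    if side == "up":
        ranked = sorted(t.exons, key=lambda e: (-e.end, -e.start))
    else:
        ranked = sorted(t.exons, key=lambda e: (e.start, e.end))
    return tuple(sorted(ranked[:k]))


def find_flanking_span(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    pc_transcripts: Sequence[Transcript],
    n_flank_exons: int = 2,
) -> FlankingPair:
    """Assign nearest up/downstream protein-coding neighbours to a span.

    Upstream neighbour: the protein-coding transcript on the same chromosome
    with the greatest span end <= ``start``; downstream: the least span start
    >= ``end``. Ties broken by (nearer inner edge, then transcript id) for
    determinism. Missing neighbours are left as ``None`` (reported downstream,
    never silently dropped).
    """
    upstream: Transcript | None = None
    downstream: Transcript | None = None

    def up_key(t: Transcript):
        # prefer greater end; tie: nearer gene body (greater start); tie: id
        return (t.end, t.start, _RevStr(t.id))

    def down_key(t: Transcript):
        # prefer smaller start; tie: smaller end; tie: id
        return (t.start, t.end, t.id)

    for t in pc_transcripts:
        if t.chrom != chrom:
            continue
        if t.end <= start and (upstream is None or up_key(t) > up_key(upstream)):
            upstream = t
        if t.start >= end and (downstream is None or down_key(t) < down_key(downstream)):
            downstream = t
    return FlankingPair(
        lnc_gene_id=gene_id,
        chrom=chrom,
        lnc_start=start,
        lnc_end=end,
        upstream_pc=upstream.id if upstream else None,
        downstream_pc=downstream.id if downstream else None,
        upstream_flank_exons=_nearest_exons(upstream, "up", n_flank_exons)
        if upstream
        else (),
        downstream_flank_exons=_nearest_exons(downstream, "down", n_flank_exons)
        if downstream
        else (),
    )


def find_flanking(
    lnc: Transcript, pc_transcripts: Sequence[Transcript]
) -> FlankingPair:
    """Flanking assignment for a single lncRNA transcript (span-based)."""
    return find_flanking_span(
        lnc.gene_id, lnc.chrom, lnc.start, lnc.end, pc_transcripts
    )


def is_intergenic(lnc: Transcript, pc_transcripts: Sequence[Transcript]) -> bool:
    """True iff no lncRNA exon overlaps any protein-coding transcript span.

    Intronic lncRNAs are excluded too (the span, not just exons, is tested):
    they offer no meaningful flanking-exon contrast for focal calling.
    """
    for pc in pc_transcripts:
        if pc.chrom != lnc.chrom:
            continue
        for e in lnc.exons:
            if e.overlaps(pc.start, pc.end):
                return False
    return True


def build_lnc_genes(transcripts: Iterable[Transcript]) -> dict[str, LncGene]:
    """Aggregate lncRNA transcripts per gene (span + unique sorted exons)."""
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        if t.biotype == "lncRNA":
            by_gene.setdefault(t.gene_id, []).append(t)
    out: dict[str, LncGene] = {}
    for gid, ts in sorted(by_gene.items()):
        exons = sorted(dedupe_exons(ts))
        out[gid] = LncGene(
            gene_id=gid,
            chrom=ts[0].chrom,
            start=min(t.start for t in ts),
            end=max(t.end for t in ts),
            exons=tuple(exons),
            transcript_ids=tuple(sorted(t.id for t in ts)),
        )
    return out


def assign_flanking(
    transcripts: Iterable[Transcript],
) -> tuple[dict[str, FlankingPair], list[str]]:
    """Flanking pairs for every intergenic lncRNA gene.

    Returns the per-gene pairs and a report of lncRNA genes that are not
    intergenic or that lack one or both neighbours.
    """
    ts = list(transcripts)
    pcs = [t for t in ts if t.biotype == "protein_coding"]
    lnc_genes = build_lnc_genes(ts)
    lnc_by_id = {t.id: t for t in ts if t.biotype == "lncRNA"}
    pairs: dict[str, FlankingPair] = {}
    report: list[str] = []
    for gid, gene in lnc_genes.items():
        members = [lnc_by_id[tid] for tid in gene.transcript_ids]
        if not all(is_intergenic(t, pcs) for t in members):
            report.append(f"{gid}\tnot_intergenic")
            continue
        pair = find_flanking_span(gid, gene.chrom, gene.start, gene.end, pcs)
        if pair.upstream_pc is None:
            report.append(f"{gid}\tno_upstream_pc")
        if pair.downstream_pc is None:
            report.append(f"{gid}\tno_downstream_pc")
        pairs[gid] = pair
    return pairs, report
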