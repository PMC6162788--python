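"""File-format adapters: GFF3, BED, and the pipeline's TSV/JSON tables.

All genomic coordinates are 0-based half-open in memory (BED convention);
GFF3 is converted on read and write. Writers are deterministic so that
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import yaml

from .annotation import Exon, FlankingPair, Transcript
from .probedesign import ProbeCandidate, ProbeDesign
from .segmentation import SEGMENT_COLUMNS, SIGNAL_COLUMNS


# ---------------------------------------------------------------- GFF3

def write_gff3(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write gene/transcript/exon features (1-based inclusive on disk)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(by_gene):
        ts = sorted(by_gene[gid], key=lambda t: t.id)
        chrom = ts[0].chrom
        strand = ts[0].strand
        g_start = min(t.start for t in ts)
        g_end = max(t.end for t in ts)
        biotype = ts[0].biotype
        lines.append(
            f"{chrom}\tlncfocal\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={gid};biotype={biotype}"
        )
        for t in ts:
            lines.append(
                f"{chrom}\tlncfocal\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\tID={t.id};Parent={gid};biotype={t.biotype}"
            )
            for k, e in enumerate(t.exons):
                lines.append(
                    f"{chrom}\tlncfocal\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={t.id}.exon{k + 1};Parent={t.id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Transcript]:
    """Read transcripts with exons from a GFF3 file (via gffutils)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[Transcript] = []
    for feat in db.features_of_type(("transcript", "mRNA")):
        exons = []
        for ex in db.children(feat, featuretype="exon", order_by="start"):
            exons.append(
                Exon(
                    chrom=ex.seqid,
                    start=ex.start - 1,
                    end=ex.end,
                    strand=ex.strand if ex.strand in ("+", "-") else "+",
                )
            )
        gene_id = feat.attributes.get("Parent", [feat.id])[0]
        biotype = feat.attributes.get("biotype", ["lncRNA"])[0]
        out.append(
            Transcript(id=feat.id, gene_id=gene_id, biotype=biotype, exons=tuple(exons))
        )
    return sorted(out, key=lambda t: t.id)


# ----------------------------------------------------------------- BED

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain interval BED (first three columns)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed_intervals(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed_transcripts(path: str | Path, biotype: str = "lncRNA") -> list[Transcript]:
    """BED12 (blocks as exons) or BED6 (single-exon) transcript reader."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
        if len(f) >= 12:
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                Exon(chrom=chrom, start=start + o, end=start + o + s, strand=strand)
                for o, s in zip(offsets, sizes)
            )
        else:
            exons = (Exon(chrom=chrom, start=start, end=end, strand=strand),)
        out.append(Transcript(id=name, gene_id=name, biotype=biotype, exons=exons))
    return out


# ------------------------------------------------------------ catalogue

def write_catalogue(
    exon_transcripts: Mapping[Exon, Sequence[str]], path: str | Path
) -> None:
    """Non-redundant exon catalogue TSV."""
    rows = []
    for k, exon in enumerate(sorted(exon_transcripts)):
        rows.append(
            {
                "chrom": exon.chrom,
                "start": exon.start,
                "end": exon.end,
                "strand": exon.strand,
                "exon_id": f"X{k + 1:06d}",
                "transcript_ids": ",".join(exon_transcripts[exon]),
            }
        )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "exon_id", "transcript_ids"]
    ).to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> dict[Exon, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        Exon(chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand): str(
            r.transcript_ids
        ).split(",")
        for r in df.itertuples()
    }


# --------------------------------------------------------- flank report

def _fmt_exons(exons: Sequence[Exon]) -> str:
    return ";".join(f"{e.chrom}:{e.start}-{e.end}:{e.strand}" for e in exons) or "."


def _parse_exons(text: str) -> tuple[Exon, ...]:
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(";"):
        chrom, span, strand = part.rsplit(":", 2)
        start, end = span.split("-")
        out.append(Exon(chrom=chrom, start=int(start), end=int(end), strand=strand))
    return tuple(out)


FLANK_COLUMNS = [
    "lnc_gene_id",
    "chrom",
    "lnc_start",
    "lnc_end",
    "upstream_pc",
    "downstream_pc",
    "upstream_flank_exons",
    "downstream_flank_exons",
]


def write_flank_report(
    pairs: Mapping[str, FlankingPair], path: str | Path
) -> None:
    rows = [
        {
            "lnc_gene_id": p.lnc_gene_id,
            "chrom": p.chrom,
            "lnc_start": p.lnc_start,
            "lnc_end": p.lnc_end,
            "upstream_pc": p.upstream_pc or ".",
            "downstream_pc": p.downstream_pc or ".",
            "upstream_flank_exons": _fmt_exons(p.upstream_flank_exons),
            "downstream_flank_exons": _fmt_exons(p.downstream_flank_exons),
        }
        for _, p in sorted(pairs.items())
    ]
    pd.DataFrame(rows, columns=FLANK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_flank_report(path: str | Path) -> dict[str, FlankingPair]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[r.lnc_gene_id] = FlankingPair(
            lnc_gene_id=r.lnc_gene_id,
            chrom=r.chrom,
            lnc_start=int(r.lnc_start),
            lnc_end=int(r.lnc_end),
            upstream_pc=None if r.upstream_pc == "." else r.upstream_pc,
            downstream_pc=None if r.downstream_pc == "." else r.downstream_pc,
            upstream_flank_exons=_parse_exons(str(r.upstream_flank_exons)),
            downstream_flank_exons=_parse_exons(str(r.downstream_flank_exons)),
        )
    return out


# --------------------------------------------------------------- probes

def write_probes_bed(design: ProbeDesign, path: str | Path) -> None:
    rows = []
    for coords in sorted(design.probes):
        p = design.probes[coords]
        rows.append(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tier}|{p.distance_to_exon}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_probes_bed(path: str | Path) -> list[ProbeCandidate]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name = line.split("\t")[:4]
        tier, dist = name.rsplit("|", 1)
        out.append(
            ProbeCandidate(
                chrom=chrom,
                start=int(start),
                end=int(end),
                tier=tier,
                distance_to_exon=int(dist),
            )
        )
    return out


# ------------------------------------------------------- signal tables

def write_signals(signals: pd.DataFrame, path: str | Path) -> None:
    signals[SIGNAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_signals(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[SIGNAL_COLUMNS]


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    cols = (["sample"] if "sample" in segments.columns else []) + SEGMENT_COLUMNS
    segments[cols].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ Cq tables

CQ_COLUMNS = ["event_id", "assay_role", "sample", "replicate", "cq"]


def write_cq_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows[CQ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cq_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[CQ_COLUMNS]


# ---------------------------------------------------------- JSON / YAML

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> dict:
    """Plain key: value configuration (YAML subset)."""
    loaded = yaml.safe_load(Path(path).read_text())
    return loaded or {}
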