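"""Independent brute-force oracles and randomized case generators.

Everything here is deliberately naive (exhaustive scans, rational
arithmetic, no index structures) and coded directly from the rule
definitions, so it constitutes an independent check of the package's
implementations rather than a re-use of them.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np

from lncfocal.annotation import Exon, FlankingPair, LncGene
from lncfocal.focalfilter import FilterConfig


# ------------------------------------------------ least-squares changepoints

def least_squares_changepoints(x: np.ndarray, k: int) -> list[int]:
    """Exhaustive least-squares optimal breakpoints for a known count k."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: int, b: int) -> float:
        s = S[b] - S[a]
        return (S2[b] - S2[a]) - s * s / (b - a)

    if k == 0:
        return []
    if k == 1:
        best, arg = math.inf, []
        for b in range(1, n):
            v = sse(0, b) + sse(b, n)
            if v < best - 1e-12:
                best, arg = v, [b]
        return arg
    if k == 2:
        best, arg = math.inf, []
        for b1 in range(1, n - 1):
            left = sse(0, b1)
            for b2 in range(b1 + 1, n):
                v = left + sse(b1, b2) + sse(b2, n)
                if v < best - 1e-12:
                    best, arg = v, [b1, b2]
        return arg
    raise ValueError("oracle supports k <= 2")


def random_cbs_instance(rng: np.random.Generator) -> tuple[np.ndarray, list[int], bool]:
    """A piecewise-constant signal with <= 2 breakpoints and jump >= 1.

    k = 1 is a step, k = 2 a spike on a flat background (the shape focal
    events produce). Half the instances are noise-free. Returns the signal,
    the true breakpoints and the noise-free flag.
    """
    n = int(rng.integers(30, 101))
    k = int(rng.integers(0, 3))
    jump = float(rng.uniform(1.0, 3.0)) * (1 if rng.random() < 0.5 else -1)
    noise_free = bool(rng.random() < 0.5)
    sigma = 0.0 if noise_free else 0.2
    x = np.zeros(n)
    min_piece = 8
    if k == 1:
        b = int(rng.integers(min_piece, n - min_piece + 1))
        x[b:] = jump
        bps = [b]
    elif k == 2:
        b1 = int(rng.integers(min_piece, n - 2 * min_piece + 1))
        b2 = int(rng.integers(b1 + min_piece, n - min_piece + 1))
        x[b1:b2] = jump
        bps = [b1, b2]
    else:
        bps = []
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, size=n)
    return x, bps, noise_free


# --------------------------------------------------- filter cascade oracle

def brute_filter_calls(
    segments: list[dict],
    lnc_genes: dict[str, LncGene],
    flanking: dict[str, FlankingPair],
    segdups: list[tuple[str, int, int]],
    variants: list[tuple[str, int, int]],
    config: FilterConfig,
) -> set[tuple]:
    """Naive rule-by-rule evaluation of the focal filter cascade.

    Returns the set of (lnc_gene_id, chrom, start, end, direction,
    stringency) tuples that survive every rule; plain O(n*m) scans
    throughout.
    """

    def ov(a0, a1, b0, b1):
        return max(0, min(a1, b1) - max(a0, b0))

    # probe-support bounds from the neighbouring segments on each chromosome
    support = {}
    by_chrom: dict[str, list[dict]] = {}
    for s in segments:
        by_chrom.setdefault(s["chrom"], []).append(s)
    for chrom, rows in by_chrom.items():
        rows = sorted(rows, key=lambda r: r["start"])
        for i, r in enumerate(rows):
            lo = -math.inf if i == 0 else (rows[i - 1]["end"] - 1 + r["start"]) / 2
            hi = (
                math.inf
                if i == len(rows) - 1
                else (r["end"] - 1 + rows[i + 1]["start"]) / 2
            )
            support[(chrom, r["start"], r["end"])] = (lo, hi)

    uniq_variants = set(variants)
    calls = set()
    for gid, gene in lnc_genes.items():
        pair = flanking.get(gid)
        for seg in segments:
            if seg["chrom"] != gene.chrom:
                continue
            # (1) overlaps >= 1 lncRNA exon
            if not any(
                ov(seg["start"], seg["end"], e.start, e.end) > 0 for e in gene.exons
            ):
                continue
            # (2) not contained in any segdup
            if any(
                c == seg["chrom"] and s <= seg["start"] and seg["end"] <= e
                for c, s, e in segdups
            ):
                continue
            # (3) <= max_variants distinct known-variant overlaps
            n_var = sum(
                1
                for c, s, e in uniq_variants
                if c == seg["chrom"] and ov(seg["start"], seg["end"], s, e) > 0
            )
            if n_var > config.max_variants:
                continue
            # (4) amplitude
            if abs(seg["mean_lr"]) < config.t_focal:
                continue
            direction = "gain" if seg["mean_lr"] > 0 else "loss"
            # (5) gains contain the whole gene span (probe-support interval)
            lo, hi = support[(seg["chrom"], seg["start"], seg["end"])]
            if direction == "gain" and not (lo <= gene.start and gene.end <= hi):
                continue
            # (6) no flank exon overlap
            flank_exons = []
            if pair is not None:
                flank_exons = [*pair.upstream_flank_exons, *pair.downstream_flank_exons]
            if any(
                e.chrom == seg["chrom"] and ov(seg["start"], seg["end"], e.start, e.end) > 0
                for e in flank_exons
            ):
                continue
            # (7) flank contrast per evaluable side
            flank_lrs = []
            n_evaluable = 0
            passed = True
            for side in ("up", "down"):
                exon = pair.nearest_flank_exon(side) if pair else None
                if exon is None:
                    continue
                covering = [
                    s
                    for s in segments
                    if s["chrom"] == exon.chrom
                    and ov(s["start"], s["end"], exon.start, exon.end) > 0
                ]
                if not covering:
                    continue

                def key(s):
                    if side == "up":
                        dist = max(0, pair.lnc_start - s["end"])
                    else:
                        dist = max(0, s["start"] - pair.lnc_end)
                    return (
                        -ov(s["start"], s["end"], exon.start, exon.end),
                        dist,
                        s["start"],
                    )

                nearest = min(covering, key=key)
                n_evaluable += 1
                flank_lrs.append(nearest["mean_lr"])
                if abs(seg["mean_lr"]) - abs(nearest["mean_lr"]) < config.flank_delta:
                    passed = False
            if n_evaluable == 0 or not passed:
                continue
            stringency = (
                "stringent"
                if flank_lrs and all(abs(v) < config.t_neutral for v in flank_lrs)
                else "standard"
            )
            calls.add(
                (gid, seg["chrom"], seg["start"], seg["end"], direction, stringency)
            )
    return calls


def random_filter_case(rng: np.random.Generator) -> dict:
    """A random segment/annotation/track configuration for the filter."""
    chrom = "chr1"
    length = 200_000
    # contiguous, non-overlapping segments with jittered means
    n_seg = int(rng.integers(4, 12))
    cuts = np.sort(rng.choice(np.arange(1_000, length, 500), size=n_seg - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    segments = []
    for i in range(n_seg):
        mean = float(rng.choice([0.0, 0.2, -0.3, 1.6, -1.8, 2.8, -3.5, 0.5]))
        mean += float(rng.normal(0, 0.1))
        segments.append(
            {
                "chrom": chrom,
                "start": bounds[i],
                "end": bounds[i + 1],
                "n_probes": int(rng.integers(2, 30)),
                "mean_lr": mean,
            }
        )

    lnc_genes: dict[str, LncGene] = {}
    flanking: dict[str, FlankingPair] = {}
    n_genes = int(rng.integers(1, 5))
    for g in range(n_genes):
        span_start = int(rng.integers(0, length - 6_000))
        span_end = span_start + int(rng.integers(1_000, 6_000))
        n_ex = int(rng.integers(1, 4))
        ex_bounds = np.sort(
            rng.choice(np.arange(span_start, span_end, 50), size=2 * n_ex, replace=False)
        )
        exons = []
        for k in range(n_ex):
            s, e = int(ex_bounds[2 * k]), int(ex_bounds[2 * k + 1])
            if s == e:
                e += 10
            exons.append(Exon(chrom=chrom, start=s, end=min(e, span_end), strand="+"))
        exons[0] = Exon(chrom=chrom, start=span_start, end=exons[0].end, strand="+")
        exons[-1] = Exon(
            chrom=chrom, start=exons[-1].start, end=span_end, strand="+"
        )
        gid = f"G{g}"
        lnc_genes[gid] = LncGene(
            gene_id=gid, chrom=chrom, start=span_start, end=span_end, exons=tuple(exons)
        )
        up_exons, down_exons = (), ()
        up_id = down_id = None
        if rng.random() < 0.85 and span_start > 2_000:
            w = int(rng.integers(100, 500))
            s = int(rng.integers(0, max(1, span_start - w - 500)))
            up_exons = (Exon(chrom=chrom, start=s, end=s + w, strand="+"),)
            up_id = f"PCup{g}"
        if rng.random() < 0.85 and span_end < length - 2_000:
            w = int(rng.integers(100, 500))
            s = int(rng.integers(span_end + 500, length - w))
            down_exons = (Exon(chrom=chrom, start=s, end=s + w, strand="+"),)
            down_id = f"PCdn{g}"
        flanking[gid] = FlankingPair(
            lnc_gene_id=gid,
            chrom=chrom,
            lnc_start=span_start,
            lnc_end=span_end,
            upstream_pc=up_id,
            downstream_pc=down_id,
            upstream_flank_exons=up_exons,
            downstream_flank_exons=down_exons,
        )

    def random_track(n_max: int) -> list[tuple[str, int, int]]:
        out = []
        for _ in range(int(rng.integers(0, n_max))):
            s = int(rng.integers(0, length - 100))
            out.append((chrom, s, s + int(rng.integers(100, 30_000))))
        return out

    config = FilterConfig(
        t_focal=float(rng.uniform(1.0, 2.0)),
        t_high=float(rng.uniform(2.4, 3.0)),
        max_variants=int(rng.integers(0, 4)),
        flank_delta=float(rng.uniform(0.2, 0.8)),
        t_neutral=float(rng.uniform(0.1, 0.6)),
    )
    return {
        "segments": segments,
        "lnc_genes": lnc_genes,
        "flanking": flanking,
        "segdups": random_track(4),
        "variants": random_track(8),
        "config": config,
    }


# ----------------------------------------------------------- Fisher oracle

def enum_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of all tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= obs:
            total += pk
    return float(total)


# ---------------------------------------------------- flanking / probes

def brute_nearest_pc(
    lnc_start: int,
    lnc_end: int,
    pc_spans: list[tuple[str, int, int]],
) -> tuple[str | None, str | None]:
    """Exhaustive nearest-neighbour scan over (id, start, end) spans."""
    ups = [(i, s, e) for i, s, e in pc_spans if e <= lnc_start]
    downs = [(i, s, e) for i, s, e in pc_spans if s >= lnc_end]
    up = down = None
    if ups:
        best = max((e, s) for _, s, e in ups)
        up = min(i for i, s, e in ups if (e, s) == best)
    if downs:
        best = min((s, e) for _, s, e in downs)
        down = min(i for i, s, e in downs if (s, e) == best)
    return up, down
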