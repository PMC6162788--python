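"""Flank-normalised qPCR validation of focal copy-number calls.

Each tested event carries one assay on the aberration locus and up to two
assays on the nearest exons of the flanking protein-coding genes. The
relative quantity versus a flank is the delta-delta-Cq contrast

    rq = 2 ** -[(Cq_ab - Cq_flank)_sample - (Cq_ab - Cq_flank)_control]

with replicate Cq values aggregated by arithmetic mean and per-replicate
log2 rq retained (replicates paired by index) for a one-sample t-test
against 0. Amplification efficiency is fixed at perfect doubling. A flank
whose mean Cq exceeds the no-amplification ceiling (default 35 cycles) is a
dropout: the flank itself is homozygously deleted and the side yields no rq.

An event is confirmed focal when both flanks give an rq on the expected side
of one (gain: > 1, loss: < 1), significantly; confirmed on one side when
exactly one flank qualifies. The same machinery screens a cohort of healthy
individuals for germline variants via rq-threshold copy states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

FLANK_ROLES = {"up": "up_flank", "down": "down_flank"}
VERDICTS = ("confirmed_focal", "confirmed_one_side", "not_confirmed", "indeterminate")
COPY_STATES = ("homozygous_del", "het_del", "neutral", "gain")


@dataclass(slots=True)
class QpcrConfig:
    cq_ceiling: float = 35.0
    alpha: float = 0.05
    require_significance: bool = True
    # rq thresholds of the population-screen copy states
    het_del_max: float = 0.75
    neutral_max: float = 1.5
    hom_del_max: float = 0.25


@dataclass(slots=True)
class QpcrEvent:
    """Replicate Cq values for one aberration locus in one sample.

    ``cq`` and ``control_cq`` map assay roles ("aberration", "up_flank",
    "down_flank") to replicate Cq arrays; the control is the reference
    genomic DNA at copy number 2.
    """

    event_id: str
    direction: str  # "loss" | "gain"
    cq: dict[str, np.ndarray]
    control_cq: dict[str, np.ndarray]
    high_confidence: bool = False
    cq_ceiling: float = 35.0

    def __post_init__(self) -> None:
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"direction must be loss/gain, got {self.direction!r}")
        self.cq = {k: np.asarray(v, dtype=float) for k, v in self.cq.items()}
        self.control_cq = {
            k: np.asarray(v, dtype=float) for k, v in self.control_cq.items()
        }
        for table in (self.cq, self.control_cq):
            if "aberration" not in table:
                raise ValueError(f"event {self.event_id}: missing aberration assay")
            for role, values in table.items():
                if values.size < 1 or np.any(values <= 0):
                    raise ValueError(
                        f"event {self.event_id}: invalid Cq replicates for {role}"
                    )


@dataclass(slots=True)
class SideResult:
    rq: float | None
    p: float | None
    log2_rq_reps: np.ndarray | None
    dropout: bool = False


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test of log2 rq against 0.

    Degenerate replicate sets (a single replicate, or zero variance) fall
    back to 0/1 according to whether the common value differs from 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0.0:
        return 0.0 if abs(float(np.mean(values))) > 0 else 1.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def relative_quantity(
    event: QpcrEvent, side: str, config: QpcrConfig | None = None
) -> SideResult:
    """Relative quantity of the aberration locus versus one flank.

    Exactly 1.0 when the sample's delta-Cq equals the control's. Invariant
    to adding a constant to all of a sample's Cq values. The flank is a
    dropout when its mean sample Cq exceeds the ceiling.
    """
    config = config or QpcrConfig()
    role = FLANK_ROLES[side]
    if role not in event.cq or role not in event.control_cq:
        return SideResult(rq=None, p=None, log2_rq_reps=None)
    flank = event.cq[role]
    if float(np.mean(flank)) > event.cq_ceiling:
        return SideResult(rq=None, p=None, log2_rq_reps=None, dropout=True)
    ab = event.cq["aberration"]
    ctrl_contrast = float(
        np.mean(event.control_cq["aberration"]) - np.mean(event.control_cq[role])
    )
    rq = 2.0 ** -((float(np.mean(ab)) - float(np.mean(flank))) - ctrl_contrast)
    k = min(ab.size, flank.size)
    log2_reps = -((ab[:k] - flank[:k]) - ctrl_contrast)
    return SideResult(
        rq=float(rq), p=_one_sample_p(log2_reps), log2_rq_reps=log2_reps
    )


def event_rqs(
    event: QpcrEvent, config: QpcrConfig | None = None
) -> dict[str, SideResult]:
    return {side: relative_quantity(event, side, config) for side in ("up", "down")}


def classify_event(
    event: QpcrEvent,
    rqs: Mapping[str, SideResult] | None = None,
    config: QpcrConfig | None = None,
) -> str:
    """Verdict for one tested event.

    confirmed_focal: both rqs defined, both on the expected side of one and
    significant; confirmed_one_side: exactly one qualifying side;
    indeterminate: both flanks dropped out; not_confirmed otherwise.
    """
    config = config or QpcrConfig()
    rqs = rqs if rqs is not None else event_rqs(event, config)
    results = [rqs["up"], rqs["down"]]
    if all(r.rq is None and r.dropout for r in results):
        return "indeterminate"

    def qualifies(r: SideResult) -> bool:
        if r.rq is None:
            return False
        right_side = r.rq > 1.0 if event.direction == "gain" else r.rq < 1.0
        if not right_side:
            return False
        if config.require_significance:
            return r.p is not None and r.p < config.alpha
        return True

    n_defined = sum(r.rq is not None for r in results)
    n_qual = sum(qualifies(r) for r in results)
    if n_defined == 2 and n_qual == 2:
        return "confirmed_focal"
    if n_qual == 1:
        return "confirmed_one_side"
    return "not_confirmed"


def validation_summary(
    verdicts: Sequence[str],
    directions: Sequence[str],
    high_confidence: Sequence[bool] | None = None,
) -> dict[str, float]:
    """Confirmation rates over tested events.

    "Confirmed" on >= 1 side means confirmed_focal or confirmed_one_side.
    Rates are also split by direction and recomputed on the high-confidence
    subset (|mean log-ratio| above the high threshold in the array data).
    """
    n = len(verdicts)
    if n == 0:
        return {}
    verdicts = list(verdicts)
    confirmed = [v in ("confirmed_focal", "confirmed_one_side") for v in verdicts]
    focal = [v == "confirmed_focal" for v in verdicts]
    out = {
        "n_tested": float(n),
        "confirmed_any_rate": sum(confirmed) / n,
        "confirmed_focal_rate": sum(focal) / n,
    }
    for d in ("loss", "gain"):
        idx = [i for i, dd in enumerate(directions) if dd == d]
        if idx:
            out[f"confirmed_any_rate_{d}"] = sum(confirmed[i] for i in idx) / len(idx)
            out[f"confirmed_focal_rate_{d}"] = sum(focal[i] for i in idx) / len(idx)
    if high_confidence is not None:
        idx = [i for i, h in enumerate(high_confidence) if h]
        if idx:
            out["n_high_confidence"] = float(len(idx))
            out["confirmed_any_rate_high_conf"] = (
                sum(confirmed[i] for i in idx) / len(idx)
            )
            out["confirmed_focal_rate_high_conf"] = (
                sum(focal[i] for i in idx) / len(idx)
            )
    return out


def classify_copy_state(
    event: QpcrEvent, config: QpcrConfig | None = None
) -> str:
    """Copy state of one individual at one locus, from rq thresholds.

    Aberration Cq above the ceiling means no template: homozygous deletion.
    Otherwise the rq (geometric mean over defined flanks) maps to
    homozygous_del (< 0.25), het_del [0.25, 0.75), neutral [0.75, 1.5), or
    gain (>= 1.5).
    """
    config = config or QpcrConfig()
    if float(np.mean(event.cq["aberration"])) > event.cq_ceiling:
        return "homozygous_del"
    rqs = [r.rq for r in event_rqs(event, config).values() if r.rq is not None]
    if not rqs:
        raise ValueError(f"event {event.event_id}: no evaluable flank")
    rq = 2.0 ** float(np.mean(np.log2(rqs)))
    if rq < config.hom_del_max:
        return "homozygous_del"
    if rq < config.het_del_max:
        return "het_del"
    if rq < config.neutral_max:
        return "neutral"
    return "gain"


def population_screen(
    cohort: Mapping[str, Mapping[str, QpcrEvent]],
    config: QpcrConfig | None = None,
) -> tuple[dict[tuple[str, str], str], dict[str, dict[str, float]]]:
    """Copy states across a cohort, per individual per locus.

    ``cohort`` maps individual -> locus -> QpcrEvent (each event already
    carries the shared control Cq values; a missing control raises).
    Returns the per-(individual, locus) states and a per-locus frequency
    table over the copy-state categories.
    """
    config = config or QpcrConfig()
    states: dict[tuple[str, str], str] = {}
    per_locus: dict[str, list[str]] = {}
    for indiv in sorted(cohort):
        for locus in sorted(cohort[indiv]):
            event = cohort[indiv][locus]
            if not event.control_cq:
                raise ValueError(f"{indiv}/{locus}: missing control Cq")
            state = classify_copy_state(event, config)
            states[(indiv, locus)] = state
            per_locus.setdefault(locus, []).append(state)
    freqs = {
        locus: {
            s: sum(1 for x in obs if x == s) / len(obs) for s in COPY_STATES
        }
        for locus, obs in per_locus.items()
    }
    return states, freqs
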