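"""Scoring of called CNVs against planted truth (overlap-based)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall
from .intervals import GenomicInterval


@dataclass(frozen=True)
class TruthEvent:
    """One carried CNV in one sample."""

    sample_id: str
    interval: GenomicInterval
    type: str
    copy_number: int


@dataclass
class CallScore:
    sensitivity: float
    precision: float
    n_truth: int
    n_calls: int
    n_truth_hit: int
    n_calls_true: int
    cn_mae: float  # mean |estimated - true| CN over matched calls with CN


def carried_events(truth, samplesheet, carriers) -> list[TruthEvent]:
    """Expand planted CNVs x carrier matrix into per-sample truth events."""
    out = []
    for sid in samplesheet.sample_ids:
        for i in carriers.columns:
            if carriers.loc[sid, i]:
                t = truth[i]
                out.append(TruthEvent(sid, t.interval, t.type, t.copy_number))
    return out


def score_calls(
    calls: Sequence[CnvCall],
    events: Sequence[TruthEvent],
    require_type: bool = True,
) -> CallScore:
    """Overlap-match calls to truth events within each sample.

    A truth event is recovered when some call of the same sample (and type,
    unless ``require_type=False``) overlaps it by >= 1 bp; a call is a true
    positive when it overlaps some truth event of its sample.  CN error is
    averaged over true-positive calls carrying a copy-number estimate,
    against the truth CN of the best-overlapping event.
    """
    by_sample: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    n_truth_hit = 0
    for ev in events:
        if any(
            c.sample_id == ev.sample_id
            and (not require_type or c.type == ev.type)
            and c.interval.overlaps(ev.interval)
            for c in calls
        ):
            n_truth_hit += 1
    n_calls_true = 0
    cn_errors = []
    for c in calls:
        matches = [
            ev for ev in by_sample.get(c.sample_id, [])
            if (not require_type or c.type == ev.type)
            and c.interval.overlaps(ev.interval)
        ]
        if matches:
            n_calls_true += 1
            if not np.isnan(c.copy_number):
                best = max(
                    matches,
                    key=lambda ev: min(c.interval.end, ev.interval.end)
                    - max(c.interval.start, ev.interval.start),
                )
                cn_errors.append(abs(c.copy_number - best.copy_number))
    n_truth = len(events)
    n_calls = len(calls)
    return CallScore(
        sensitivity=n_truth_hit / n_truth if n_truth else float("nan"),
        precision=n_calls_true / n_calls if n_calls else float("nan"),
        n_truth=n_truth,
        n_calls=n_calls,
        n_truth_hit=n_truth_hit,
        n_calls_true=n_calls_true,
        cn_mae=float(np.mean(cn_errors)) if cn_errors else float("nan"),
    )
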