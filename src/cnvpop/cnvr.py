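"""CNVR construction: cross-sample merging, classification and frequency
spectrum.

CNV calls from all samples merge into copy-number-variation regions (CNVRs)
by single-linkage >= 1 bp overlap — the connected components of the overlap
graph across samples and call types.  A CNVR whose members are all deletions
is class ``deletion``, all duplications ``duplication``, and a mixture is
``complex``.  Each CNVR carries a per-sample presence vector and a frequency
category:

=========  ==========================================
singleton  exactly one carrier
low        >1 carrier, frequency < 20%
medium     20% <= frequency <= 80%
high       80% < frequency < 100%
common     carried by every sample
=========  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calls import DEL, DUP, CnvCall
from .intervals import GenomicInterval

__all__ = [
    "Cnvr",
    "merge_to_cnvrs",
    "classify_cnvr",
    "freq_category",
    "frequency_spectrum",
    "presence_matrix",
    "filter_singletons",
    "cnvrs_to_frame",
]

CATEGORIES = ("singleton", "low", "medium", "high", "common")


@dataclass
class Cnvr:
    """A merged copy-number-variation region across samples."""

    interval: GenomicInterval
    member_calls: list[CnvCall]

    @property
    def cnvr_class(self) -> str:
        return classify_cnvr(self.member_calls)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(c.sample_id for c in self.member_calls)

    def presence(self, sample_ids: Sequence[str]) -> np.ndarray:
        present = self.samples
        return np.array([1 if s in present else 0 for s in sample_ids], dtype=int)

    def frequency(self, n_samples: int) -> float:
        return len(self.samples) / n_samples

    def category(self, n_samples: int) -> str:
        return freq_category(len(self.samples), n_samples)

    @property
    def id(self) -> str:
        return self.interval.region_string()


def merge_to_cnvrs(calls: Iterable[CnvCall]) -> list[Cnvr]:
    """Merge all samples' CNV calls into CNVRs by >= 1 bp overlap.

    Single-linkage chaining: any two calls that overlap by at least one base
    (on the same chromosome, regardless of sample or type) belong to the
    same CNVR, and the CNVR interval is the union span of its members.
    Abutting half-open intervals do not merge.  Empty input gives [].
    """
    pool = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start,
                                        c.interval.end, c.sample_id))
    cnvrs: list[Cnvr] = []
    current: list[CnvCall] = []
    cur_chrom: str | None = None
    cur_end = -1
    for c in pool:
        if current and c.interval.chrom == cur_chrom and c.interval.start < cur_end:
            current.append(c)
            cur_end = max(cur_end, c.interval.end)
        else:
            if current:
                cnvrs.append(_finish(current))
            current = [c]
            cur_chrom = c.interval.chrom
            cur_end = c.interval.end
    if current:
        cnvrs.append(_finish(current))
    return cnvrs


def _finish(members: list[CnvCall]) -> Cnvr:
    iv = GenomicInterval(
        members[0].interval.chrom,
        min(c.interval.start for c in members),
        max(c.interval.end for c in members),
    )
    return Cnvr(iv, list(members))


def classify_cnvr(member_calls: Sequence[CnvCall]) -> str:
    """``deletion`` if all members are DEL, ``duplication`` if all DUP,
    ``complex`` for a mixture."""
    if not member_calls:
        raise ValueError("CNVR must have at least one member call")
    types = {c.type for c in member_calls}
    if types == {DEL}:
        return "deletion"
    if types == {DUP}:
        return "duplication"
    return "complex"


def freq_category(n_carriers: int, n_samples: int) -> str:
    """Frequency-spectrum category of a CNVR.

    A single carrier is a singleton regardless of panel size; ``common``
    requires every sample; the 20% and 80% boundaries belong to ``medium``.
    """
    if n_carriers < 1:
        raise ValueError("CNVR must have at least one carrier")
    if n_carriers > n_samples:
        raise ValueError("more carriers than samples")
    if n_carriers == 1:
        return "singleton"
    if n_carriers == n_samples:
        return "common"
    f = n_carriers / n_samples
    if f < 0.20:
        return "low"
    if f <= 0.80:
        return "medium"
    return "high"


def frequency_spectrum(
    cnvrs: Sequence[Cnvr], sample_ids: Sequence[str]
) -> tuple[pd.Series, dict[str, int]]:
    """Per-CNVR category plus counts per category (categories partition the
    CNVR set)."""
    if len(sample_ids) < 2:
        raise ValueError("frequency spectrum needs >= 2 samples")
    n = len(sample_ids)
    cats = pd.Series({c.id: c.category(n) for c in cnvrs}, dtype=object)
    counts = {k: int((cats == k).sum()) for k in CATEGORIES}
    return cats, counts


def presence_matrix(cnvrs: Sequence[Cnvr], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Binary samples x CNVRs matrix; columns are 1-based region strings."""
    data = {c.id: c.presence(sample_ids) for c in cnvrs}
    mat = pd.DataFrame(data, index=list(sample_ids))
    if not mat.empty and (mat.sum(axis=0) == 0).any():
        raise AssertionError("all-zero CNVR column; merge invariant violated")
    return mat


def filter_singletons(cnvrs: Sequence[Cnvr], n_samples: int) -> list[Cnvr]:
    """Drop CNVRs carried by exactly one sample."""
    return [c for c in cnvrs if c.category(n_samples) != "singleton"]


def cnvrs_to_frame(cnvrs: Sequence[Cnvr], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Summary table: interval, class, carrier count, frequency, category."""
    n = len(sample_ids)
    rows = []
    for c in cnvrs:
        rows.append((c.interval.chrom, c.interval.start, c.interval.end, c.id,
                     c.cnvr_class, len(c.samples), c.frequency(n), c.category(n)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cnvr_id",
                                       "cnvr_class", "n_carriers", "frequency",
                                       "freq_category"])
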