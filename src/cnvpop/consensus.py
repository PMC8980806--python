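"""Multi-caller deletion consensus.

Deletions shorter than 50 bp are discarded, the remaining calls from up to
four callers are single-linkage clustered within each sample by >= 1 bp
overlap, and only clusters supported by at least two distinct callers are
retained.  The consensus interval is the union span of the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calls import DEL, CnvCall
from .intervals import GenomicInterval, overlap_length

__all__ = [
    "SupportCluster",
    "filter_min_length",
    "cluster_and_vote",
    "consensus_deletions",
]

MIN_DEL_LENGTH = 50
MIN_SUPPORT = 2


@dataclass
class SupportCluster:
    """A chained cluster of overlapping deletion calls from one sample."""

    sample_id: str
    member_calls: list[CnvCall]
    merged_interval: GenomicInterval

    @property
    def callers(self) -> frozenset[str]:
        return frozenset(c.source for c in self.member_calls)

    @property
    def support(self) -> int:
        return len(self.callers)


def filter_min_length(calls: Iterable[CnvCall], min_len: int = MIN_DEL_LENGTH) -> list[CnvCall]:
    """Drop deletions shorter than ``min_len`` bp (default 50)."""
    return [c for c in calls if c.length >= min_len]


def _reciprocal_ok(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    ov = overlap_length(a, b)
    return ov > 0 and ov >= frac * a.length and ov >= frac * b.length


def cluster_and_vote(
    caller_calls: Mapping[str, Sequence[CnvCall]],
    min_support: int = MIN_SUPPORT,
    min_reciprocal: float = 0.0,
) -> list[SupportCluster]:
    """Cluster one sample's deletion calls across callers and vote.

    Calls chain by single linkage under >= 1 bp overlap (or, when
    ``min_reciprocal`` > 0, reciprocal overlap of at least that fraction of
    both members).  A cluster survives when it unites calls from at least
    ``min_support`` distinct callers — two calls from one caller are not
    support.  Result order and content are independent of caller input order.
    """
    pool: list[CnvCall] = []
    sample_ids = set()
    for caller in sorted(caller_calls):
        for c in caller_calls[caller]:
            if c.type != DEL:
                raise ValueError("consensus voting expects deletion calls only")
            pool.append(c)
            sample_ids.add(c.sample_id)
    if len(sample_ids) > 1:
        raise ValueError("cluster_and_vote works within one sample at a time")
    pool.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end,
                             c.source))
    clusters: list[SupportCluster] = []
    if min_reciprocal <= 0.0:
        # single linkage under any-overlap == plane-sweep chaining
        current: list[CnvCall] = []
        cur_end = -1
        cur_chrom = None
        for c in pool:
            if current and c.interval.chrom == cur_chrom and c.interval.start < cur_end:
                current.append(c)
                cur_end = max(cur_end, c.interval.end)
            else:
                if current:
                    clusters.append(_make_cluster(current))
                current = [c]
                cur_chrom = c.interval.chrom
                cur_end = c.interval.end
        if current:
            clusters.append(_make_cluster(current))
    else:
        # union-find for reciprocal-overlap linkage
        parent = list(range(len(pool)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if pool[j].interval.chrom != pool[i].interval.chrom:
                    break
                if pool[j].interval.start >= pool[i].interval.end:
                    break
                if _reciprocal_ok(pool[i].interval, pool[j].interval, min_reciprocal):
                    parent[find(j)] = find(i)
        groups: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(pool):
            groups.setdefault(find(i), []).append(c)
        clusters = [_make_cluster(g) for g in groups.values()]
        clusters.sort(key=lambda cl: (cl.merged_interval.chrom,
                                      cl.merged_interval.start))
    return [cl for cl in clusters if cl.support >= min_support]


def _make_cluster(members: list[CnvCall]) -> SupportCluster:
    chrom = members[0].interval.chrom
    iv = GenomicInterval(
        chrom,
        min(c.interval.start for c in members),
        max(c.interval.end for c in members),
    )
    return SupportCluster(members[0].sample_id, list(members), iv)


def consensus_deletions(
    caller_sets: Mapping[str, Sequence[CnvCall]],
    min_len: int = MIN_DEL_LENGTH,
    min_support: int = MIN_SUPPORT,
    min_reciprocal: float = 0.0,
    cn_tracks: Mapping[str, pd.DataFrame] | None = None,
) -> list[CnvCall]:
    """Length-filter, cluster and vote every sample's deletions.

    ``caller_sets`` maps caller name to its calls over all samples.  When
    ``cn_tracks`` (sample id -> per-window copy-number frame from the
    read-depth caller) is given, consensus deletions receive the mean window
    copy number inside the interval; otherwise copy number is ``nan``.
    """
    by_sample: dict[str, dict[str, list[CnvCall]]] = {}
    for caller, calls in caller_sets.items():
        for c in filter_min_length(calls, min_len):
            by_sample.setdefault(c.sample_id, {}).setdefault(caller, []).append(c)
    out: list[CnvCall] = []
    for sid in sorted(by_sample):
        clusters = cluster_and_vote(by_sample[sid], min_support, min_reciprocal)
        for cl in clusters:
            cn = math.nan
            if cn_tracks is not None and sid in cn_tracks:
                t = cn_tracks[sid]
                iv = cl.merged_interval
                sel = t.loc[
                    (t["chrom"] == iv.chrom)
                    & (t["start"] >= iv.start)
                    & (t["end"] <= iv.end),
                    "copy_number",
                ]
                if len(sel):
                    cn = float(sel.mean())
            out.append(CnvCall(sid, cl.merged_interval, DEL, cn, "consensus"))
    return out
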