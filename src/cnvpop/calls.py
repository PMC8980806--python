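"""Per-sample CNV call records and their tab-separated serialization."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval

DUP = "DUP"
DEL = "DEL"

__all__ = ["CnvCall", "DUP", "DEL", "calls_to_frame", "frame_to_calls",
           "write_calls", "read_calls"]


@dataclass(frozen=True)
class CnvCall:
    """A duplication or deletion in one sample.

    ``copy_number`` is the estimated absolute copy number (diploid = 2); it
    is ``nan`` when the producing method gives no dosage estimate (e.g. a
    split-read caller).  ``source`` names the producing caller.
    """

    sample_id: str
    interval: GenomicInterval
    type: str
    copy_number: float = math.nan
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.type not in (DUP, DEL):
            raise ValueError(f"call type must be DUP or DEL, got {self.type!r}")
        if not math.isnan(self.copy_number) and self.copy_number < 0:
            raise ValueError(f"negative copy number: {self.copy_number}")

    @property
    def length(self) -> int:
        return self.interval.length


_COLUMNS = ["chrom", "start", "end", "sample_id", "type", "copy_number", "source"]


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    rows = [
        (c.interval.chrom, c.interval.start, c.interval.end,
         c.sample_id, c.type, c.copy_number, c.source)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> list[CnvCall]:
    return [
        CnvCall(
            sample_id=str(r.sample_id),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            type=str(r.type),
            copy_number=float(r.copy_number),
            source=str(r.source),
        )
        for r in frame.itertuples(index=False)
    ]


def write_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[CnvCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t"))
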