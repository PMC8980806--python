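"""Genomic interval data model and interval/annotation file I/O.

All coordinates are held internally as 0-based half-open ``[start, end)``,
the BED convention.  Two other dialects are converted on the way in/out:

``bed``
    0-based half-open, tab separated (BED3+).
``onebased``
    1-based fully-closed region strings ``chrom:start-end`` as commonly
    printed in prose and figures (so a 1 kb region reads ``chr1:50500-51499``).
``gff3``
    1-based fully-closed, read-only; only ``gene`` features are loaded.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "SampleSheet",
    "overlap_length",
    "parse_region",
    "format_region",
    "read_intervals",
    "write_intervals",
    "read_gff3_genes",
]

_REGION_RE = re.compile(r"^([^:\s]+):(\d+)-(\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open 0-based interval on one chromosome.

    ``name`` carries an optional feature identifier (gene id, BED name
    column); it does not take part in ordering or equality.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def region_string(self) -> str:
        """1-based fully-closed display form, e.g. ``chr1:50500-51499``."""
        return format_region(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap of two intervals; 0 on different chroms.

    Abutting half-open intervals (``a.end == b.start``) do not overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def parse_region(text: str, name: str | None = None) -> GenomicInterval:
    """Parse a 1-based fully-closed ``chrom:start-end`` region string."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    chrom, start1, end1 = m.group(1), int(m.group(2)), int(m.group(3))
    start0 = start1 - 1
    if start0 < 0:
        raise ValueError(f"1-based coordinate must be >= 1 in {text!r}")
    if end1 <= start0:
        raise ValueError(f"empty or inverted region {text!r}")
    return GenomicInterval(chrom, start0, end1, name=name)


def format_region(iv: GenomicInterval) -> str:
    """Format as a 1-based fully-closed region string."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


_DIALECTS = ("bed", "onebased", "gff3")


def read_intervals(path: str | Path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read intervals from ``path`` in the given dialect.

    Returns intervals in internal 0-based half-open coordinates.  Lines
    starting with ``#``, ``track`` or ``browser`` are skipped.  Malformed
    lines raise :class:`ValueError` naming the 1-based line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "gff3":
        return read_gff3_genes(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                out.append(_parse_line(line, dialect))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def _parse_line(line: str, dialect: str) -> GenomicInterval:
    fields = line.split("\t")
    if dialect == "bed":
        if len(fields) < 3:
            raise ValueError(f"BED line needs >=3 columns, got {len(fields)}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        return GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name=name)
    # onebased: region string in column 1, optional name in column 2
    name = fields[1] if len(fields) > 1 and fields[1] else None
    return parse_region(fields[0], name=name)


def write_intervals(
    records: Iterable[GenomicInterval], path: str | Path, dialect: str = "bed"
) -> None:
    """Write intervals to ``path``; inverse of :func:`read_intervals`.

    An empty record list produces a file holding only the header comment.
    """
    if dialect not in ("bed", "onebased"):
        raise ValueError(f"cannot write dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "bed":
            fh.write("#chrom\tstart\tend\tname\n")
            for iv in records:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")
        else:
            fh.write("#region\tname\n")
            for iv in records:
                fh.write(f"{format_region(iv)}\t{iv.name or ''}\n".rstrip() + "\n")


def read_gff3_genes(path: str | Path) -> list[GenomicInterval]:
    """Load ``gene`` features from a GFF3 file as internal intervals.

    The gene identifier is taken from the ``gene_id``, ``ID`` or ``Name``
    attribute, in that order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GenomicInterval] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = None
        for key in ("gene_id", "ID", "Name"):
            if key in feat.attributes:
                gid = feat.attributes[key][0]
                break
        if feat.end <= feat.start - 1:
            raise ValueError(f"{path}: empty gene feature at {feat.seqid}:{feat.start}")
        genes.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, name=gid))
    return genes


def write_gff3_genes(genes: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write gene intervals as a minimal GFF3 file (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in genes:
            gid = iv.name or f"{iv.chrom}_{iv.start}"
            fh.write(
                f"{iv.chrom}\tcnvpop\tgene\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={gid};gene_id={gid}\n"
            )


class SampleSheet:
    """Sample metadata: sample id, breed, and wild/domestic group.

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``sample_id``, ``breed`` and ``group`` (``wild`` or ``domestic``).
    """

    GROUPS = ("wild", "domestic")

    def __init__(self, frame) -> None:
        import pandas as pd

        required = {"sample_id", "breed", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["sample_id", "breed", "group"]].reset_index(drop=True)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        bad = set(frame["group"]) - set(self.GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        ngroup = frame.groupby("breed")["group"].nunique()
        if (ngroup > 1).any():
            raise ValueError(
                f"breeds mapped to more than one group: {ngroup[ngroup > 1].index.tolist()}"
            )
        self.frame: "pd.DataFrame" = frame

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        import pandas as pd

        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.frame["breed"]:
            seen.setdefault(b, None)
        return list(seen)

    def breed_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["breed"].iloc[0]

    def samples_of_breed(self, breed: str) -> list[str]:
        return self.frame.loc[self.frame["breed"] == breed, "sample_id"].tolist()

    def samples_of_group(self, group: str) -> list[str]:
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    @property
    def wild_breeds(self) -> list[str]:
        return [b for b in self.breeds if self.group_of_breed(b) == "wild"]

    @property
    def domestic_breeds(self) -> list[str]:
        return [b for b in self.breeds if self.group_of_breed(b) == "domestic"]

    def group_of_breed(self, breed: str) -> str:
        row = self.frame.loc[self.frame["breed"] == breed]
        if row.empty:
            raise KeyError(breed)
        return row["group"].iloc[0]

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleSheet({len(self)} samples, {len(self.breeds)} breeds)"
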