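"""Gene-level annotation of CNVRs and scan regions by >= 1 bp overlap."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, overlap_length

__all__ = ["overlap_genes", "summarize_candidates"]


def _gene_trees(genes: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # data is the gene's index: interval payloads must be unique even for
    # distinct genes sharing an identical span
    for k, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, k)
    return trees


def overlap_genes(
    regions: Sequence[GenomicInterval], genes: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """All (region, gene) pairs overlapping by at least 1 bp.

    Strand-agnostic, full gene span.  Returns columns ``region_id, chrom,
    start, end, gene_id, overlap_bp``; each pair appears exactly once.
    """
    trees = _gene_trees(genes)
    rows = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(r.start, r.end)):
            g = genes[hit.data]
            ov = overlap_length(r, g)
            if ov >= 1:
                rows.append((r.region_string(), r.chrom, r.start, r.end,
                             g.name or str(g), ov))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                       "gene_id", "overlap_bp"])


def summarize_candidates(
    scan_regions: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Deduplicated gene lists per analysis with region provenance.

    ``scan_regions`` maps an analysis label (e.g. ``domestication`` or
    ``breed_specific:SILK``) to its candidate regions.  A gene hit by
    several regions of one analysis is listed once in the per-analysis gene
    set but keeps one provenance row per region.
    """
    frames = []
    for analysis, regions in scan_regions.items():
        ann = overlap_genes(list(regions), genes)
        if ann.empty:
            continue
        ann.insert(0, "analysis", analysis)
        frames.append(ann)
    if not frames:
        return pd.DataFrame(columns=["analysis", "region_id", "chrom", "start",
                                     "end", "gene_id", "overlap_bp"])
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(["analysis", "region_id", "gene_id"]).reset_index(
        drop=True
    )
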