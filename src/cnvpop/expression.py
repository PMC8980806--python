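"""Differential-expression filtering and copy-number dosage correlation.

The differential-expression table (gene, adjusted p, fold change, per-breed
mean expression) is produced upstream (or simulated); this module applies
the standard filters (adjusted p < 0.01, fold change beyond 1.5x in either
direction) and correlates per-breed mean copy number with per-breed mean
expression across breeds.  Significance of the Pearson coefficient uses the
two-sided t transform with n - 2 degrees of freedom; at n = 5 breeds the
p < 0.05 criterion corresponds to |r| > 0.878.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, SampleSheet, parse_region

logger = logging.getLogger(__name__)

__all__ = ["filter_degs", "breed_mean_cn", "correlate_cn_expression"]


def filter_degs(
    records: pd.DataFrame, padj_max: float = 0.01, fc_min: float = 1.5
) -> pd.DataFrame:
    """Keep differentially expressed genes: adjusted p below ``padj_max``
    and fold change beyond ``fc_min`` in either direction.

    The fold-change filter is direction-symmetric: a gene passes when
    ``max(FC, 1/FC) > fc_min``, so 2-fold down-regulation (FC = 0.5)
    qualifies like 2-fold up-regulation.  Records missing ``padj`` or
    ``fold_change`` are skipped with a warning.
    """
    req = {"gene_id", "padj", "fold_change"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    ok = records["padj"].notna() & records["fold_change"].notna()
    if (~ok).any():
        logger.warning("skipping %d DEG records with missing fields", (~ok).sum())
    r = records.loc[ok]
    fc = r["fold_change"].astype(float)
    eff = np.maximum(fc, 1.0 / fc)
    return r.loc[(r["padj"] < padj_max) & (eff > fc_min)].reset_index(drop=True)


def breed_mean_cn(
    cn: pd.DataFrame,
    gene_regions: Sequence[GenomicInterval],
    samplesheet: SampleSheet,
) -> pd.DataFrame:
    """Per-breed mean copy number of each gene.

    For every gene, windows of the copy-number matrix overlapping the gene
    span are averaged per sample, then averaged within each breed.  Genes
    with no overlapping window are excluded with a log entry.  Returns a
    genes x breeds frame.
    """
    win_ivs = [parse_region(c) for c in cn.columns]
    rows = {}
    for g in gene_regions:
        cols = [c for c, w in zip(cn.columns, win_ivs) if w.overlaps(g)]
        if not cols:
            logger.info("gene %s overlaps no copy-number window; excluded",
                        g.name or str(g))
            continue
        per_sample = cn[cols].mean(axis=1)
        means = {}
        for breed in samplesheet.breeds:
            sids = samplesheet.samples_of_breed(breed)
            means[breed] = float(per_sample.loc[sids].mean())
        rows[g.name or str(g)] = means
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_cn_expression(
    cn_by_breed: pd.DataFrame,
    degs: pd.DataFrame,
    breeds: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of breed-mean copy number vs breed-mean expression.

    Operates on genes present in both tables, across the breeds shared by
    both (optionally restricted to ``breeds``).  Requires >= 3 breeds.
    Genes with zero variance in either vector are flagged undefined.
    Returns columns ``gene_id, r, p_value, n_breeds, significant``.
    """
    expr_breeds = [c for c in degs.columns
                   if c not in ("gene_id", "padj", "fold_change")]
    shared = [b for b in expr_breeds if b in cn_by_breed.columns]
    if breeds is not None:
        shared = [b for b in shared if b in set(breeds)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 breeds with both CN and expression, got {shared}")
    degs = degs.set_index("gene_id")
    rows = []
    for gid in degs.index:
        if gid not in cn_by_breed.index:
            continue
        x = cn_by_breed.loc[gid, shared].to_numpy(float)
        y = degs.loc[gid, shared].to_numpy(float)
        n = len(shared)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gid, np.nan, np.nan, n, False))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((gid, float(r), float(p), n, bool(p < alpha)))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p_value", "n_breeds",
                                       "significant"])
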