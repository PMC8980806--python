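"""Population statistics over CNV genotypes.

Three analyses:

* PCA of the binary CNVR presence/absence matrix (population stratification);
* Vst, an FST analogue for copy number:

      Vst = (sigma_T^2 - (n1*sigma_1^2 + n2*sigma_2^2) / (n1 + n2)) / sigma_T^2

  where ``sigma_T^2`` is the variance of the pooled copy numbers and
  ``sigma_1^2``/``sigma_2^2`` the within-population variances.  With
  population (divide-by-n) variances, Vst is 0 for identically distributed
  groups and provably confined to [0, 1]; it is undefined when the pooled
  variance is zero;
* two genome scans on the per-window copy-number matrix: the
  wild-versus-domestic scan keeping the top fraction of Vst values, and the
  breed-specificity scan requiring all six pairwise Vst values of one breed
  against every other population to clear a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .intervals import GenomicInterval, SampleSheet, parse_region

__all__ = [
    "PcaResult",
    "VstResult",
    "ScanResult",
    "pca_presence",
    "vst",
    "vst_series",
    "domestication_scan",
    "breed_specific_scan",
    "merge_window_runs",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    variance_explained: np.ndarray  # fraction per component
    loadings: pd.DataFrame          # features x components


@dataclass(frozen=True)
class VstResult:
    group_a: str
    group_b: str
    n1: int
    n2: int
    sigma2_T: float
    sigma2_1: float
    sigma2_2: float
    vst: float | None  # None when sigma2_T == 0 (undefined)


@dataclass
class ScanResult:
    """Windows selected by a Vst scan, with the per-window statistics."""

    table: pd.DataFrame             # window id -> vst (and comparison columns)
    threshold: float
    selected_windows: list[GenomicInterval]
    regions: list[GenomicInterval] = field(default_factory=list)


def pca_presence(matrix: pd.DataFrame, n_components: int = 4) -> PcaResult:
    """Column-centered covariance PCA of the presence/absence matrix.

    Uses a full SVD with a deterministic sign convention: the
    largest-magnitude loading of each component is made positive.  The 0/1
    cells are left unscaled — they are already on a common scale.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples")
    if (matrix.sum(axis=0) == 0).any():
        raise ValueError("presence matrix has all-zero columns")
    k_max = min(matrix.shape)
    if n_components > k_max:
        raise ValueError(f"n_components={n_components} exceeds min(dim)={k_max}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(float))
    loadings = pca.components_.T  # features x components
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
    )


def vst(
    values_a: Sequence[float],
    values_b: Sequence[float],
    ddof: int = 0,
    group_a: str = "A",
    group_b: str = "B",
) -> VstResult:
    """Vst between two populations' copy numbers at one window.

    ``ddof=0`` (population variances, the default) guarantees Vst in [0, 1]
    and exact 0 for equal group distributions; ``ddof=1`` (sample variances)
    is available for comparison but can leave the unit interval.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 samples")
    pooled = np.concatenate([a, b])
    s2t = float(np.var(pooled, ddof=ddof))
    s21 = float(np.var(a, ddof=ddof))
    s22 = float(np.var(b, ddof=ddof))
    if s2t == 0.0:
        v: float | None = None
    else:
        v = (s2t - (n1 * s21 + n2 * s22) / (n1 + n2)) / s2t
        if ddof == 0:
            v = float(np.clip(v, 0.0, 1.0))  # guard tiny float excursions
    return VstResult(group_a, group_b, n1, n2, s2t, s21, s22, v)


def vst_series(
    cn: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    ddof: int = 0,
) -> pd.Series:
    """Vectorized per-window Vst between two sample sets.

    ``cn`` is the samples x windows copy-number matrix.  Windows with zero
    pooled variance get NaN (undefined).
    """
    a = cn.loc[list(samples_a)].to_numpy(float)
    b = cn.loc[list(samples_b)].to_numpy(float)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 samples")
    pooled = np.vstack([a, b])
    s2t = pooled.var(axis=0, ddof=ddof)
    s21 = a.var(axis=0, ddof=ddof)
    s22 = b.var(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (s2t - (n1 * s21 + n2 * s22) / (n1 + n2)) / s2t
    v = np.where(s2t == 0.0, np.nan, v)
    if ddof == 0:
        v = np.clip(v, 0.0, 1.0)
    return pd.Series(v, index=cn.columns, name="vst")


def _windows_from_ids(ids: Sequence[str]) -> list[GenomicInterval]:
    return [parse_region(w) for w in ids]


def merge_window_runs(windows: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting windows into maximal regions."""
    out: list[GenomicInterval] = []
    for w in sorted(windows):
        if out and out[-1].chrom == w.chrom and w.start <= out[-1].end:
            out[-1] = GenomicInterval(w.chrom, out[-1].start, max(out[-1].end, w.end))
        else:
            out.append(w)
    return out


def domestication_scan(
    cn: pd.DataFrame,
    samplesheet: SampleSheet,
    top_fraction: float = 0.01,
    ddof: int = 0,
) -> ScanResult:
    """Wild-versus-domestic Vst scan keeping the top ``top_fraction``.

    The domestic group pools all domestic breeds.  The threshold is the
    ``1 - top_fraction`` quantile of the *defined* Vst values; windows at or
    above the threshold (ties included) are selected and merged into
    candidate regions.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    wild = samplesheet.samples_of_group("wild")
    domestic = samplesheet.samples_of_group("domestic")
    v = vst_series(cn, wild, domestic, ddof=ddof)
    defined = v.dropna()
    if defined.empty:
        raise ValueError("all Vst values are undefined (no copy-number variance)")
    threshold = float(np.quantile(defined.to_numpy(), 1.0 - top_fraction))
    sel_ids = defined.index[defined >= threshold].tolist()
    table = v.to_frame()
    table["selected"] = table.index.isin(sel_ids)
    windows = _windows_from_ids(sel_ids)
    return ScanResult(table, threshold, windows, merge_window_runs(windows))


def breed_specific_scan(
    cn: pd.DataFrame,
    samplesheet: SampleSheet,
    vst_threshold: float = 0.4,
    ddof: int = 0,
) -> dict[str, ScanResult]:
    """All-pairwise Vst scan for breed-specific copy-number regions.

    For each domestic breed, every other population (the remaining domestic
    breeds plus the wild one) is compared in turn; a window is
    breed-specific only when *all* pairwise Vst values exceed
    ``vst_threshold``.  Windows with any undefined comparison are excluded
    (conservative).  Contiguous qualifying windows merge into regions.
    """
    breeds = samplesheet.breeds
    out: dict[str, ScanResult] = {}
    for breed in samplesheet.domestic_breeds:
        focal = samplesheet.samples_of_breed(breed)
        table = pd.DataFrame(index=cn.columns)
        for other in breeds:
            if other == breed:
                continue
            v = vst_series(cn, focal, samplesheet.samples_of_breed(other), ddof=ddof)
            table[f"vst_vs_{other}"] = v
        ok = (table > vst_threshold).all(axis=1) & table.notna().all(axis=1)
        table["specific"] = ok
        windows = _windows_from_ids(table.index[ok].tolist())
        out[breed] = ScanResult(table, vst_threshold, windows,
                                merge_window_runs(windows))
    return out
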