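"""Read-depth CNV caller.

The caller follows the classic whole-genome shotgun read-depth recipe:

1. normalize window depth against GC content (LOESS or binned medians);
2. estimate a robust genome-wide depth mean/sd by iterative sigma trimming;
3. scan 5 kb windows sliding in 1 kb steps over the non-masked window
   budget, declaring a duplication (deletion) core wherever at least six of
   seven consecutive windows sit above mean + 4 sd (below mean - 4 sd);
4. refine core boundaries with non-overlapping 1 kb windows at a looser
   mean +/- 2 sd threshold, extending outward through contiguous qualifying
   windows and trimming non-qualifying edges;
5. estimate the absolute copy number of each call as
   2 x mean(normalized depth of interior 1 kb windows) / genome mean.

"Non-masked" means ``masked_fraction <= 0.5``.  Sliding 5 kb windows are
built from runs of five consecutive surviving 1 kb windows (the unmasked
sequence budget), so a masked block simply shortens the local run rather
than shifting the grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import DEL, DUP, CnvCall
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "DepthStats",
    "DepthCallerParams",
    "gc_normalize",
    "estimate_depth_stats",
    "sliding_windows",
    "call_segments",
    "refine_boundaries",
    "estimate_copy_number",
    "run_depth_caller",
    "cn_track",
]

MASKED_MAX = 0.5  # a window is usable when masked_fraction <= this


@dataclass(frozen=True)
class DepthStats:
    """Robust genome-wide depth mean and sd over trimmed usable windows."""

    mean: float
    sd: float
    n_windows_used: int


@dataclass
class DepthCallerParams:
    """Tunables of the read-depth caller (defaults follow the standard
    5 kb / 1 kb two-stage recipe)."""

    gc_method: str = "loess"          # or "binned_median"
    loess_span: float = 0.3
    gc_binwidth: float = 0.01
    trim_sd: float = 3.0
    agg_windows: int = 5              # 1 kb windows per sliding window (5 kb)
    heptad: int = 7
    min_hits: int = 6
    core_sd: float = 4.0
    refine_sd: float = 2.0
    min_call_windows: int = 1


def _usable(windows: pd.DataFrame) -> pd.Series:
    return windows["masked_fraction"] <= MASKED_MAX


def gc_normalize(
    windows: pd.DataFrame,
    method: str = "loess",
    span_or_binwidth: float | None = None,
    exclude_sd: float = 3.0,
) -> pd.DataFrame:
    """Set ``norm_depth`` by dividing out the fitted depth-vs-GC trend.

    ``norm_depth_i = raw_depth_i * (global trimmed mean) / f(gc_i)`` where
    ``f`` is a LOESS fit (``method="loess"``, span = ``span_or_binwidth``,
    default 0.3) or a GC-binned median curve (``method="binned_median"``,
    bin width default 0.01).  Only non-masked windows inform the fit; all
    windows receive a normalized value.

    Candidate CNV windows are excluded from the fitting set before the fit:
    a window is kept only when its 5-window rolling raw depth stays within
    30% (or ``exclude_sd`` robust sds of the ratio, if larger) of a wide
    201-window rolling median.  The wide median tracks the slowly varying
    GC baseline while a CNV shifts the local ratio by ~50% per copy, so the
    exclusion needs no GC fit of its own — fitting first and excluding by
    residual is self-masking, because a CNV that dominates a sparse GC
    stratum bends the curve far enough to normalize itself away.  The
    output gains a boolean ``fit_used`` column marking the fitting set (the
    depth-null windows), which downstream null statistics should be
    estimated on.
    """
    if method not in ("loess", "binned_median"):
        raise ValueError(f"unknown GC normalization method {method!r}")
    use = _usable(windows)
    if not use.any():
        raise ValueError("all windows are masked; cannot normalize")
    if use.sum() < 100:
        warnings.warn("fewer than 100 usable windows; GC fit may be unstable")
    gc = windows.loc[use, "gc"].to_numpy(float)
    depth = windows.loc[use, "raw_depth"].to_numpy(float)
    gmean = estimate_depth_stats(depth, min_windows=10).mean

    out = windows.copy()

    def fit_curve(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if method == "loess":
            from statsmodels.nonparametric.smoothers_lowess import lowess

            span = 0.3 if span_or_binwidth is None else span_or_binwidth
            fit = lowess(y, x, frac=span, return_sorted=True)
            return fit[:, 0], fit[:, 1]
        binwidth = 0.01 if span_or_binwidth is None else span_or_binwidth
        bins = np.round(x / binwidth).astype(int)
        fx_list, fy_list = [], []
        for b in np.unique(bins):
            sel = bins == b
            fx_list.append(b * binwidth)
            fy_list.append(np.median(y[sel]))
        return np.asarray(fx_list), np.asarray(fy_list)

    floor = max(1e-6, 0.05 * gmean)
    chrom_use = pd.Series(windows.loc[use, "chrom"].to_numpy())
    grouped = pd.Series(depth).groupby(chrom_use)
    local = grouped.transform(
        lambda s: s.rolling(5, center=True, min_periods=1).mean()
    ).to_numpy()
    baseline = grouped.transform(
        lambda s: s.rolling(201, center=True, min_periods=51).median()
    ).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(baseline > 0, local / baseline, 1.0)
    dev = np.abs(ratio - 1.0)
    mad_sd = 1.4826 * np.median(np.abs(ratio - np.median(ratio)))
    cut = max(0.30, exclude_sd * mad_sd)
    fitting = dev <= cut
    if fitting.sum() < max(100, 0.2 * gc.size):
        fitting = np.ones(gc.size, dtype=bool)

    if np.ptp(gc) < 1e-9:
        warnings.warn("degenerate GC range; identity normalization applied")
        out["norm_depth"] = out["raw_depth"].astype(float)
        out["fit_used"] = False
        out.loc[use[use].index[fitting], "fit_used"] = True
        return out

    fx, fy = fit_curve(gc[fitting], depth[fitting])

    # second pass: with f now essentially unbiased, CNVs whose wide-median
    # baseline was itself contaminated (two events within the baseline
    # span) still show in normalized depth; drop them and refit.
    f_fit = np.maximum(np.interp(gc, fx, fy), floor)
    norm_fit = depth * gmean / f_fit
    rolled = (
        pd.Series(norm_fit)
        .groupby(chrom_use)
        .transform(lambda s: s.rolling(5, center=True, min_periods=1).mean())
        .to_numpy()
    )
    med = np.median(rolled[fitting])
    rmad = 1.4826 * np.median(np.abs(rolled[fitting] - med))
    if rmad > 0:
        refined = fitting & (np.abs(rolled - med) <= exclude_sd * rmad)
        if refined.sum() >= max(100, 0.2 * gc.size):
            fitting = refined
            fx, fy = fit_curve(gc[fitting], depth[fitting])

    f_all = np.maximum(np.interp(out["gc"].to_numpy(float), fx, fy), floor)
    out["norm_depth"] = out["raw_depth"].to_numpy(float) * gmean / f_all
    out["fit_used"] = False
    out.loc[use[use].index[fitting], "fit_used"] = True
    return out


def estimate_depth_stats(
    values: np.ndarray | pd.Series,
    trim_sd: float = 3.0,
    max_iter: int = 20,
    min_windows: int = 30,
) -> DepthStats:
    """Iteratively sigma-trimmed mean/sd of window depths.

    Each pass centres on the median with a MAD-derived scale and drops
    windows beyond ``trim_sd`` scales, until the retained set stabilizes (or
    ``max_iter`` passes); the returned mean/sd are the plain moments of the
    final set.  The robust centre keeps the estimate anchored on the diploid
    mode even when CNV-carrying windows are a sizeable minority of the
    genome, which a mean/sd-seeded trim cannot guarantee.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_windows:
        raise ValueError(f"need >= {min_windows} windows, got {x.size}")
    keep = np.ones(x.size, dtype=bool)
    for _ in range(max_iter):
        m = np.median(x[keep])
        s = 1.4826 * np.median(np.abs(x[keep] - m))
        if s == 0:
            break
        new = np.abs(x - m) <= trim_sd * s
        if new.sum() < min_windows:
            break
        if np.array_equal(new, keep):
            break
        keep = new
    m, s = float(x[keep].mean()), float(x[keep].std())
    return DepthStats(mean=m, sd=s, n_windows_used=int(keep.sum()))


def sliding_windows(windows_1kb: pd.DataFrame, agg: int = 5) -> pd.DataFrame:
    """Aggregate runs of ``agg`` consecutive usable 1 kb windows into sliding
    windows (step one 1 kb window).

    Input must carry ``norm_depth``.  Masked windows are dropped first; the
    aggregate interval spans from the first to the last member window.
    """
    if "norm_depth" not in windows_1kb:
        raise ValueError("run gc_normalize first (norm_depth missing)")
    w = windows_1kb.loc[_usable(windows_1kb)].sort_values(["chrom", "start"])
    has_fit = "fit_used" in w.columns
    out = []
    for chrom, grp in w.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["norm_depth"].to_numpy(float)
        clean = grp["fit_used"].to_numpy(bool) if has_fit else np.ones(len(grp), bool)
        n = len(grp)
        if n < agg:
            continue
        kern = np.ones(agg)
        means = np.convolve(vals, kern / agg, mode="valid")
        all_clean = np.convolve(clean.astype(int), kern, mode="valid") == agg
        for i in range(n - agg + 1):
            out.append((chrom, starts[i], ends[i + agg - 1], means[i], all_clean[i]))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "norm_depth", "clean"])


def _merge_index_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def call_segments(
    windows_slide: pd.DataFrame,
    stats: DepthStats,
    heptad: int = 7,
    min_hits: int = 6,
    n_sd: float = 4.0,
) -> list[tuple[str, int, int, str]]:
    """Detect duplication/deletion cores with the >=6-of-7 heptad rule.

    A heptad is ``heptad`` consecutive sliding windows; it qualifies when at
    least ``min_hits`` of them lie beyond ``mean +/- n_sd * sd`` in the same
    direction.  Heptads sharing windows merge; the core spans the first to
    the last exceeding window of the merged run.  Returns
    ``(chrom, start, end, type)`` tuples.
    """
    hi_thr = stats.mean + n_sd * stats.sd
    lo_thr = stats.mean - n_sd * stats.sd
    cores: list[tuple[str, int, int, str]] = []
    for chrom, grp in windows_slide.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        vals = grp["norm_depth"].to_numpy(float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n = len(grp)
        if n < heptad:
            continue
        for typ, flag in ((DUP, vals > hi_thr), (DEL, vals < lo_thr)):
            counts = np.convolve(flag.astype(int), np.ones(heptad, int), "valid")
            qual = np.nonzero(counts >= min_hits)[0]
            if qual.size == 0:
                continue
            spans = _merge_index_spans([(int(i), int(i) + heptad - 1) for i in qual])
            for s, e in spans:
                idx = np.nonzero(flag[s:e + 1])[0] + s
                first, last = int(idx[0]), int(idx[-1])
                cores.append((chrom, int(starts[first]), int(ends[last]), typ))
    cores.sort()
    return cores


def refine_boundaries(
    core: tuple[str, int, int, str],
    windows_1kb: pd.DataFrame,
    stats: DepthStats,
    n_sd: float = 2.0,
) -> GenomicInterval | None:
    """Refine a core's boundaries with 1 kb windows at ``mean +/- n_sd*sd``.

    Edges extend outward through contiguous (in the non-masked window list)
    qualifying windows and shrink past non-qualifying edge windows.  Returns
    ``None`` when refinement empties the call.
    """
    chrom, cstart, cend, typ = core
    w = windows_1kb.loc[
        _usable(windows_1kb) & (windows_1kb["chrom"] == chrom)
    ].sort_values("start")
    if w.empty:
        return None
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    vals = w["norm_depth"].to_numpy(float)
    if typ == DUP:
        flag = vals > stats.mean + n_sd * stats.sd
    else:
        flag = vals < stats.mean - n_sd * stats.sd
    inside = np.nonzero((starts < cend) & (ends > cstart))[0]
    if inside.size == 0:
        return None
    qual_inside = inside[flag[inside]]
    if qual_inside.size == 0:
        logger.info("refinement dropped %s core %s:%d-%d", typ, chrom, cstart, cend)
        return None
    left, right = int(qual_inside[0]), int(qual_inside[-1])
    while left - 1 >= 0 and flag[left - 1]:
        left -= 1
    while right + 1 < len(flag) and flag[right + 1]:
        right += 1
    return GenomicInterval(chrom, int(starts[left]), int(ends[right]))


def estimate_copy_number(
    interval: GenomicInterval, windows_1kb: pd.DataFrame, stats: DepthStats
) -> float:
    """Absolute copy number: 2 x mean interior 1 kb normalized depth over
    the genome mean.  ``nan`` when no usable interior window exists."""
    w = windows_1kb.loc[
        _usable(windows_1kb)
        & (windows_1kb["chrom"] == interval.chrom)
        & (windows_1kb["start"] >= interval.start)
        & (windows_1kb["end"] <= interval.end)
    ]
    if w.empty or stats.mean <= 0:
        return math.nan
    return float(2.0 * w["norm_depth"].mean() / stats.mean)


def cn_track(windows_1kb: pd.DataFrame, stats: DepthStats) -> pd.DataFrame:
    """Per-window copy-number track over usable 1 kb windows."""
    w = windows_1kb.loc[_usable(windows_1kb), ["chrom", "start", "end", "norm_depth"]]
    out = w.copy()
    out["copy_number"] = 2.0 * out.pop("norm_depth") / stats.mean
    return out.reset_index(drop=True)


def _merge_same_type(calls: list[CnvCall]) -> list[CnvCall]:
    """Union overlapping refined calls of the same type (adjacent cores can
    refine into overlapping intervals)."""
    out: list[CnvCall] = []
    for c in sorted(calls, key=lambda c: (c.type, c.interval.chrom, c.interval.start)):
        if (
            out
            and out[-1].type == c.type
            and out[-1].interval.chrom == c.interval.chrom
            and c.interval.start < out[-1].interval.end
        ):
            prev = out[-1]
            iv = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, c.interval.end),
            )
            out[-1] = CnvCall(prev.sample_id, iv, prev.type, math.nan, prev.source)
        else:
            out.append(c)
    return out


def run_depth_caller(
    windows_1kb: pd.DataFrame,
    sample_id: str,
    params: DepthCallerParams | None = None,
) -> tuple[list[CnvCall], pd.DataFrame]:
    """Run the full read-depth pipeline on one sample's 1 kb windows.

    Returns ``(calls, cn_track)`` where calls carry ``source="rd"`` and the
    track is the per-1kb-window copy-number matrix row consumed by the
    population statistics.
    """
    params = params or DepthCallerParams()
    norm = gc_normalize(
        windows_1kb,
        method=params.gc_method,
        span_or_binwidth=params.loess_span if params.gc_method == "loess"
        else params.gc_binwidth,
    )
    use = _usable(norm)
    null1 = use & norm.get("fit_used", pd.Series(True, index=norm.index))
    stats1 = estimate_depth_stats(norm.loc[null1, "norm_depth"],
                                  trim_sd=params.trim_sd)
    slide = sliding_windows(norm, agg=params.agg_windows)
    null5 = slide["clean"] if "clean" in slide else pd.Series(True, index=slide.index)
    stats5 = estimate_depth_stats(slide.loc[null5, "norm_depth"],
                                  trim_sd=params.trim_sd)
    cores = call_segments(
        slide, stats5, heptad=params.heptad, min_hits=params.min_hits,
        n_sd=params.core_sd,
    )
    raw_calls: list[CnvCall] = []
    for core in cores:
        iv = refine_boundaries(core, norm, stats1, n_sd=params.refine_sd)
        if iv is None:
            continue
        raw_calls.append(CnvCall(sample_id, iv, core[3], math.nan, "rd"))
    merged = _merge_same_type(raw_calls)
    calls: list[CnvCall] = []
    for c in merged:
        cn = estimate_copy_number(c.interval, norm, stats1)
        if math.isnan(cn):
            logger.info("no usable interior window for %s; call flagged", c.interval)
        elif (c.type == DUP and cn <= 2.0) or (c.type == DEL and cn >= 2.0):
            logger.info("dropping %s call %s with inconsistent CN %.2f",
                        c.type, c.interval, cn)
            continue
        calls.append(CnvCall(sample_id, c.interval, c.type, cn, "rd"))
    track = cn_track(norm, stats1)
    return calls, track
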