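"""Synthetic whole-genome resequencing inputs with planted CNV truth.

Everything the downstream pipeline consumes can be generated here: a genome
layout (chromosome sizes, repeat-masked blocks, a smooth GC profile, gene
models), planted CNVs with per-breed carrier frequencies, per-sample windowed
read depth with GC bias and overdispersion, per-caller deletion call sets
with caller-specific error behaviour, and a differential-expression table
with a tunable copy-number dosage correlation.

Depth is modelled at the window level: the number of sequenced bases falling
in a window is negative-binomial with mean

    mean_depth * (cn / 2) * g(gc) * window_bp

where ``cn`` is the sample's local copy number and ``g`` a unimodal
multiplicative GC-efficiency curve.  ``dispersion`` adds variance
``d * mean^2`` on top of the Poisson term, so ``dispersion=0`` degenerates to
near-Poisson base counts.  Read-level simulation (FASTQ) is deliberately out
of scope — nothing downstream looks below window resolution.

Determinism: every stochastic step derives its generator from the master
seed plus stable per-sample / per-caller tags (CRC32 of the name), so adding
a sample or caller never reshuffles the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calls import DEL, DUP, CnvCall
from .intervals import GenomicInterval, SampleSheet

__all__ = [
    "GenomeLayout",
    "TruthCnv",
    "CallerProfile",
    "CnvDesign",
    "DEFAULT_PROFILES",
    "default_samplesheet",
    "generate_genome",
    "plant_cnvs",
    "assign_carriers",
    "simulate_depth",
    "simulate_caller_calls",
    "simulate_expression",
    "expected_cn_matrix",
    "kb_windows",
]

# label constants
NEUTRAL = "neutral"
COMMON = "common"
DOMESTICATION = "domestication_diff"
BREED_SPECIFIC = "breed_specific"  # stored as "breed_specific:<BREED>"


@dataclass
class GenomeLayout:
    """Chromosome sizes, masked blocks, per-kb GC profile and gene models."""

    chrom_sizes: dict[str, int]
    masked_regions: list[GenomicInterval]
    gc_profile: dict[str, np.ndarray]  # per-kilobase GC fraction
    genes: list[GenomicInterval]

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    def gc_of(self, chrom: str, start: int, end: int) -> float:
        prof = self.gc_profile[chrom]
        i0, i1 = start // 1000, max(start // 1000 + 1, -(-end // 1000))
        return float(np.mean(prof[i0:min(i1, len(prof))]))


@dataclass(frozen=True)
class TruthCnv:
    """A planted CNV with per-breed carrier frequencies.

    ``copy_number`` is the carrier's absolute copy number (0 or 1 for DEL,
    >= 3 for DUP); non-carriers stay diploid.  ``label`` records the
    frequency architecture class: ``neutral``, ``common``,
    ``domestication_diff`` or ``breed_specific:<BREED>``.
    """

    interval: GenomicInterval
    type: str
    copy_number: int
    carrier_frequency: Mapping[str, float]
    label: str = NEUTRAL

    def __post_init__(self) -> None:
        if self.type == DEL and self.copy_number not in (0, 1):
            raise ValueError("DEL copy number must be 0 or 1")
        if self.type == DUP and self.copy_number < 3:
            raise ValueError("DUP copy number must be >= 3")
        for b, f in self.carrier_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carrier frequency for {b} outside [0,1]: {f}")


@dataclass(frozen=True)
class CallerProfile:
    """Behavioural profile of a simulated deletion caller."""

    name: str
    boundary_jitter_sd: float = 0.0  # bp
    fnr: float = 0.0
    fpr_per_mb: float = 0.0
    min_detectable_len: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnr <= 1.0:
            raise ValueError("fnr must be in [0,1]")
        if self.boundary_jitter_sd < 0 or self.fpr_per_mb < 0:
            raise ValueError("jitter and fpr must be non-negative")


#: Default caller error profiles.  The four callers differ qualitatively the
#: way read-depth, depth-segmentation, read-pair and split-read methods do:
#: the read-depth caller only sees large events, the split-read caller sees
#: the smallest events with near-bp boundary precision, and the read-pair /
#: split-read callers trade sensitivity for a higher false-positive load —
#: preserving the ordering "rd callers report fewest deletions, split-read
#: callers the most".
DEFAULT_PROFILES: dict[str, CallerProfile] = {
    "mrfast": CallerProfile("mrfast", boundary_jitter_sd=500, fnr=0.10,
                            fpr_per_mb=0.05, min_detectable_len=5000),
    "cnvnator": CallerProfile("cnvnator", boundary_jitter_sd=250, fnr=0.15,
                              fpr_per_mb=0.5, min_detectable_len=500),
    "breakdancer": CallerProfile("breakdancer", boundary_jitter_sd=150, fnr=0.10,
                                 fpr_per_mb=2.0, min_detectable_len=100),
    "pindel": CallerProfile("pindel", boundary_jitter_sd=10, fnr=0.10,
                            fpr_per_mb=2.0, min_detectable_len=50),
}


@dataclass
class CnvDesign:
    """Counts and parameters of the planted CNV architecture.

    ``n_breed_specific`` is the number of CNVs planted per domestic breed.
    ``anchor_to_genes`` centres domestication-differentiated and
    breed-specific CNVs on gene models so that annotation and expression
    stages have guaranteed overlaps to work with.
    """

    n_neutral: int = 30
    n_common: int = 5
    n_domestication: int = 4
    n_breed_specific: int = 2
    length_range: tuple[int, int] = (10_000, 100_000)
    domestication_length_range: tuple[int, int] | None = None
    breed_specific_length_range: tuple[int, int] | None = None
    dup_fraction: float = 0.5  # among neutral CNVs
    neutral_freq_range: tuple[float, float] = (0.1, 0.8)
    neutral_freq_jitter: float = 0.05  # per-breed drift around the shared frequency
    breed_specific_freq: float = 0.95
    min_gap: int = 20_000
    anchor_to_genes: bool = True


def default_samplesheet() -> SampleSheet:
    """A 51-bird panel: 4 wild red jungle fowl plus six domestic breeds
    (8 XH, 8 LXG, 8 YOU, 9 SILK, 8 RW, 6 WL)."""
    breeds = [("RJF", "wild", 4), ("XH", "domestic", 8), ("LXG", "domestic", 8),
              ("YOU", "domestic", 8), ("SILK", "domestic", 9),
              ("RW", "domestic", 8), ("WL", "domestic", 6)]
    rows = []
    for breed, group, n in breeds:
        for i in range(1, n + 1):
            rows.append((f"{breed}_{i:02d}", breed, group))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "breed", "group"]))


def _tag(name: str) -> int:
    """Stable 32-bit tag for seeding from a string."""
    return zlib.crc32(name.encode())


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


# ---------------------------------------------------------------------------
# genome layout


def generate_genome(
    n_chroms: int = 1,
    chrom_len: int = 10_000_000,
    masked_fraction: float = 0.10,
    n_genes: int = 100,
    seed: int = 0,
) -> GenomeLayout:
    """Generate a genome layout with masked blocks, GC profile and genes.

    The GC profile is a smoothed (autocorrelated) per-kilobase track clipped
    to [0.3, 0.7].  Masked blocks are kilobase-aligned (a 1 kb window is
    either fully masked or fully clean) and drawn as 10-100 kb clusters,
    emulating repeat clusters and deserts rather than a fine dust of short
    repeats.  Genes are mutually non-overlapping.
    """
    if n_chroms < 1 or chrom_len < 100_000:
        raise ValueError("need >=1 chromosome of >=100 kb")
    if not 0.0 <= masked_fraction < 0.5:
        raise ValueError("masked_fraction must be in [0, 0.5)")
    rng = _rng(seed, _tag("genome"))
    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chroms)}

    gc_profile: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        nkb = size // 1000
        raw = gaussian_filter1d(rng.standard_normal(nkb), sigma=50.0)
        sd = raw.std() or 1.0
        gc_profile[chrom] = np.clip(0.5 + 0.08 * raw / sd, 0.3, 0.7)

    masked: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        nkb = size // 1000
        target_kb = int(round(masked_fraction * nkb))
        taken = np.zeros(nkb, dtype=bool)
        got = 0
        attempts = 0
        while got < target_kb and attempts < 100 * max(1, target_kb):
            attempts += 1
            block = int(rng.integers(10, 101))  # 10-100 kb masked blocks
            pos = int(rng.integers(0, max(1, nkb - block)))
            if taken[pos:pos + block].any():
                continue
            taken[pos:pos + block] = True
            masked.append(GenomicInterval(chrom, pos * 1000, (pos + block) * 1000))
            got += block
    masked.sort()

    genes: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    gi = 0
    attempts = 0
    while gi < n_genes and attempts < 200 * max(1, n_genes):
        attempts += 1
        chrom = list(chrom_sizes)[int(rng.integers(0, n_chroms))]
        size = chrom_sizes[chrom]
        glen = int(rng.integers(2_000, 30_001))
        start = int(rng.integers(0, size - glen))
        if any(start < e and s < start + glen for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + glen))
        gi += 1
        genes.append(GenomicInterval(chrom, start, start + glen, name=f"gene{gi:04d}"))
    if gi < n_genes:
        raise ValueError("genome too small to place the requested genes")
    genes.sort()
    return GenomeLayout(chrom_sizes, masked, gc_profile, genes)


# ---------------------------------------------------------------------------
# planted truth


def _masked_kb_set(layout: GenomeLayout) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {c: set() for c in layout.chrom_sizes}
    for iv in layout.masked_regions:
        out[iv.chrom].update(range(iv.start // 1000, -(-iv.end // 1000)))
    return out


def plant_cnvs(
    layout: GenomeLayout,
    samplesheet: SampleSheet,
    design: CnvDesign | None = None,
    seed: int = 0,
) -> list[TruthCnv]:
    """Plant CNVs according to the frequency-architecture design.

    Placement avoids masked regions and keeps ``design.min_gap`` bp between
    planted CNVs so that distinct truth events never merge into one CNVR.
    Raises :class:`ValueError` when the genome cannot host the request.
    """
    design = design or CnvDesign()
    rng = _rng(seed, _tag("plant"))
    breeds = samplesheet.breeds
    wild = set(samplesheet.wild_breeds)
    domestic = [b for b in breeds if b not in wild]
    masked_kb = _masked_kb_set(layout)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_sizes}

    def free(chrom: str, start: int, end: int) -> bool:
        if any(start - design.min_gap < e and s < end + design.min_gap
               for s, e in placed[chrom]):
            return False
        kbs = range(start // 1000, -(-end // 1000))
        return not any(k in masked_kb[chrom] for k in kbs)

    def place(length: int, anchor: GenomicInterval | None = None) -> GenomicInterval:
        chroms = list(layout.chrom_sizes)
        for _ in range(5000):
            if anchor is not None:
                mid = (anchor.start + anchor.end) // 2
                start = max(0, mid - length // 2)
                chrom = anchor.chrom
                if start + length > layout.chrom_sizes[chrom]:
                    anchor = None
                    continue
                if free(chrom, start, start + length):
                    placed[chrom].append((start, start + length))
                    return GenomicInterval(chrom, start, start + length)
                anchor = None  # fall back to random placement
                continue
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = layout.chrom_sizes[chrom]
            start = int(rng.integers(0, size - length))
            if free(chrom, start, start + length):
                placed[chrom].append((start, start + length))
                return GenomicInterval(chrom, start, start + length)
        raise ValueError("genome too small to place requested CNVs without overlap")

    def rand_len(rng_range: tuple[int, int] | None = None) -> int:
        lo, hi = rng_range or design.length_range
        return int(rng.integers(lo, hi + 1))

    truth: list[TruthCnv] = []

    # common: carried by everyone, duplications (the ubiquitous high-copy class)
    for _ in range(design.n_common):
        cn = int(rng.integers(3, 7))
        truth.append(TruthCnv(place(rand_len()), DUP, cn,
                              {b: 1.0 for b in breeds}, COMMON))

    # domestication-differentiated: fixed in the wild group, absent in
    # domestic breeds (wild CN ~ 4, domestic CN ~ 2), anchored on genes
    perm = rng.permutation(len(layout.genes))
    gene_pool = [layout.genes[i] for i in perm]
    for i in range(design.n_domestication):
        anchor = gene_pool.pop() if (design.anchor_to_genes and gene_pool) else None
        freq = {b: (1.0 if b in wild else 0.0) for b in breeds}
        truth.append(TruthCnv(
            place(rand_len(design.domestication_length_range), anchor),
            DUP, 4, freq, DOMESTICATION,
        ))

    # breed-specific: near-fixed in exactly one domestic breed
    for breed in domestic:
        for _ in range(design.n_breed_specific):
            anchor = gene_pool.pop() if (design.anchor_to_genes and gene_pool) else None
            freq = {b: (design.breed_specific_freq if b == breed else 0.0)
                    for b in breeds}
            cn = 4 if rng.random() < 0.5 else 1
            typ = DUP if cn >= 3 else DEL
            truth.append(TruthCnv(
                place(rand_len(design.breed_specific_length_range), anchor),
                typ, cn, freq, f"{BREED_SPECIFIC}:{breed}",
            ))

    # neutral: a shared ancestral frequency per CNV with small per-breed
    # drift jitter (independent per-breed frequencies would plant genuine
    # breed differentiation, which neutral loci must not carry)
    lo, hi = design.neutral_freq_range
    for _ in range(design.n_neutral):
        f0 = float(rng.uniform(lo, hi))
        freq = {
            b: float(np.clip(f0 + rng.normal(0, design.neutral_freq_jitter), 0, 1))
            for b in breeds
        }
        if rng.random() < design.dup_fraction:
            typ, cn = DUP, int(rng.integers(3, 6))
        else:
            typ, cn = DEL, int(rng.integers(0, 2))
        truth.append(TruthCnv(place(rand_len()), typ, cn, freq, NEUTRAL))

    truth.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return truth


def assign_carriers(
    truth: Sequence[TruthCnv], samplesheet: SampleSheet, seed: int
) -> pd.DataFrame:
    """Draw carrier status per sample per CNV (boolean samples x CNVs).

    The draw for a sample depends only on the master seed and the sample id,
    so depth simulation and caller simulation agree on who carries what, and
    adding a sample never changes another sample's genotype.
    """
    n = len(truth)
    mat = np.zeros((len(samplesheet), n), dtype=bool)
    for si, (sid, breed) in enumerate(
        zip(samplesheet.frame["sample_id"], samplesheet.frame["breed"])
    ):
        r = _rng(seed, _tag("carriers"), _tag(sid))
        u = r.random(n)
        freqs = np.array([t.carrier_frequency.get(breed, 0.0) for t in truth])
        mat[si] = u < freqs
    return pd.DataFrame(mat, index=samplesheet.sample_ids,
                        columns=range(n))


def truth_to_frame(truth: Sequence[TruthCnv]) -> pd.DataFrame:
    rows = []
    for t in truth:
        freq = ";".join(f"{b}={f!r}" for b, f in t.carrier_frequency.items())
        rows.append((t.interval.chrom, t.interval.start, t.interval.end,
                     t.type, t.copy_number, t.label, freq))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "type",
                                       "copy_number", "label", "carrier_frequency"])


def frame_to_truth(frame: pd.DataFrame) -> list[TruthCnv]:
    out = []
    for r in frame.itertuples(index=False):
        freq = {}
        for part in str(r.carrier_frequency).split(";"):
            b, f = part.split("=")
            freq[b] = float(f)
        out.append(TruthCnv(GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                            str(r.type), int(r.copy_number), freq, str(r.label)))
    return out


# ---------------------------------------------------------------------------
# depth simulation


def gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal multiplicative GC-efficiency curve, peak 1+strength at GC 0.5
    falling to 1 at GC 0.3/0.7 (max/min ratio = 1 + strength)."""
    g = 1.0 + strength * (1.0 - ((np.asarray(gc) - 0.5) / 0.2) ** 2)
    return np.maximum(g, 1.0)


def _window_grid(layout: GenomeLayout, window: int) -> pd.DataFrame:
    rows = []
    masked_kb = _masked_kb_set(layout)
    for chrom, size in layout.chrom_sizes.items():
        prof = layout.gc_profile[chrom]
        n = size // window
        for i in range(n):
            start, end = i * window, (i + 1) * window
            i0, i1 = start // 1000, end // 1000
            gc = float(np.mean(prof[i0:max(i1, i0 + 1)]))
            kbs = range(i0, max(i1, i0 + 1))
            mfrac = sum(1 for k in kbs if k in masked_kb[chrom]) / max(1, len(kbs))
            rows.append((chrom, start, end, gc, mfrac))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "masked_fraction"])


def _local_cn(grid: pd.DataFrame, carried: Sequence[TruthCnv]) -> np.ndarray:
    """Per-window copy number for one sample: 2 plus overlap-weighted dosage
    of every carried CNV."""
    cn = np.full(len(grid), 2.0)
    if not carried:
        return cn
    chrom = grid["chrom"].to_numpy()
    start = grid["start"].to_numpy()
    end = grid["end"].to_numpy()
    for t in carried:
        m = chrom == t.interval.chrom
        ov = (np.minimum(end, t.interval.end) - np.maximum(start, t.interval.start))
        frac = np.clip(ov, 0, None) / (end - start)
        cn = np.where(m, cn + frac * (t.copy_number - 2.0), cn)
    return np.maximum(cn, 0.0)


def simulate_depth(
    layout: GenomeLayout,
    truth: Sequence[TruthCnv],
    sample_id: str,
    breed: str,
    mean_depth: float = 10.0,
    window: int = 1000,
    gc_bias_strength: float = 0.3,
    dispersion: float = 0.05,
    seed: int = 0,
    carried: Sequence[TruthCnv] | None = None,
) -> pd.DataFrame:
    """Simulate windowed read depth for one sample.

    Returns a frame with columns ``chrom, start, end, raw_depth, gc,
    masked_fraction``.  If ``carried`` is None, carrier status is drawn here
    from each CNV's per-breed frequency with the same per-sample stream used
    by :func:`assign_carriers`.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    grid = _window_grid(layout, window)
    if carried is None:
        r = _rng(seed, _tag("carriers"), _tag(sample_id))
        u = r.random(len(truth))
        freqs = np.array([t.carrier_frequency.get(breed, 0.0) for t in truth]) \
            if truth else np.zeros(0)
        carried = [t for t, ui, f in zip(truth, u, freqs) if ui < f]
    cn = _local_cn(grid, list(carried))
    g = gc_bias_curve(grid["gc"].to_numpy(), gc_bias_strength)
    wlen = (grid["end"] - grid["start"]).to_numpy()
    mean_bases = mean_depth * (cn / 2.0) * g * wlen

    rng = _rng(seed, _tag("depth"), _tag(sample_id))
    if dispersion == 0:
        bases = rng.poisson(mean_bases)
    else:
        # NB with variance m + d*m^2: size r = 1/d, p = r/(r+m)
        r_param = 1.0 / dispersion
        m = np.maximum(mean_bases, 1e-9)
        bases = rng.negative_binomial(r_param, r_param / (r_param + m))
    out = grid.copy()
    out["raw_depth"] = bases / wlen
    return out[["chrom", "start", "end", "raw_depth", "gc", "masked_fraction"]]


# ---------------------------------------------------------------------------
# caller simulation


def simulate_caller_calls(
    truth: Sequence[TruthCnv],
    samplesheet: SampleSheet,
    profiles: Mapping[str, CallerProfile] | None = None,
    layout: GenomeLayout | None = None,
    seed: int = 0,
    carriers: pd.DataFrame | None = None,
) -> dict[str, list[CnvCall]]:
    """Simulate per-caller deletion call sets for every sample.

    Only the deletion subset of the truth is visible to callers.  A carried
    deletion of length >= ``min_detectable_len`` is reported with probability
    ``1 - fnr`` with Gaussian boundary jitter; false positives arrive as a
    Poisson(fpr_per_mb x genome Mb) shower of random intervals per sample.
    """
    profiles = dict(profiles or DEFAULT_PROFILES)
    if carriers is None:
        carriers = assign_carriers(truth, samplesheet, seed)
    del_idx = [i for i, t in enumerate(truth) if t.type == DEL]
    genome_mb = (layout.total_bp / 1e6) if layout is not None else 0.0
    chroms = list(layout.chrom_sizes.items()) if layout is not None else []

    out: dict[str, list[CnvCall]] = {name: [] for name in profiles}
    for name, prof in profiles.items():
        calls = out[name]
        for sid in samplesheet.sample_ids:
            rng = _rng(seed, _tag("caller"), _tag(name), _tag(sid))
            for i in del_idx:
                t = truth[i]
                if not carriers.loc[sid, i]:
                    continue
                if t.interval.length < prof.min_detectable_len:
                    continue
                if rng.random() < prof.fnr:
                    continue
                js = int(round(rng.normal(0, prof.boundary_jitter_sd))) \
                    if prof.boundary_jitter_sd > 0 else 0
                je = int(round(rng.normal(0, prof.boundary_jitter_sd))) \
                    if prof.boundary_jitter_sd > 0 else 0
                start = max(0, t.interval.start + js)
                end = t.interval.end + je
                if layout is not None:
                    end = min(end, layout.chrom_sizes[t.interval.chrom])
                if end <= start:
                    end = start + 1
                calls.append(CnvCall(sid, GenomicInterval(t.interval.chrom, start, end),
                                     DEL, math.nan, name))
            if genome_mb > 0 and prof.fpr_per_mb > 0:
                n_fp = rng.poisson(prof.fpr_per_mb * genome_mb)
                for _ in range(n_fp):
                    total = sum(s for _, s in chroms)
                    pick = rng.integers(0, total)
                    acc = 0
                    for chrom, size in chroms:
                        if pick < acc + size:
                            break
                        acc += size
                    length = int(rng.integers(200, 5001))
                    start = int(rng.integers(0, max(1, size - length)))
                    calls.append(CnvCall(sid, GenomicInterval(chrom, start, start + length),
                                         DEL, math.nan, name))
    return out


# ---------------------------------------------------------------------------
# window copy-number truth (for scan-level tests and scoring)


def kb_windows(
    layout: GenomeLayout,
    within: Sequence[GenomicInterval] | None = None,
    window: int = 1000,
    drop_masked: bool = True,
) -> list[GenomicInterval]:
    """Tile the genome (or the given regions) with fixed windows."""
    grid = _window_grid(layout, window)
    if drop_masked:
        grid = grid[grid["masked_fraction"] <= 0.5]
    ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
           for r in grid.itertuples(index=False)]
    if within is None:
        return ivs
    keep = []
    for iv in ivs:
        if any(iv.overlaps(w) for w in within):
            keep.append(iv)
    return keep


def expected_cn_matrix(
    truth: Sequence[TruthCnv],
    samplesheet: SampleSheet,
    windows: Sequence[GenomicInterval],
    carriers: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample copy number of each window given the planted genotypes.

    This is the genotype-level dosage the depth caller tries to estimate;
    optional Gaussian noise emulates estimation error.  Columns are 1-based
    region strings, rows sample ids.
    """
    grid = pd.DataFrame(
        [(w.chrom, w.start, w.end) for w in windows],
        columns=["chrom", "start", "end"],
    )
    mat = np.zeros((len(samplesheet), len(windows)))
    for si, sid in enumerate(samplesheet.sample_ids):
        carried = [truth[i] for i in carriers.columns if carriers.loc[sid, i]]
        mat[si] = _local_cn(grid, carried)
    if noise_sd > 0:
        rng = _rng(seed, _tag("cnnoise"))
        mat = np.maximum(mat + rng.normal(0, noise_sd, mat.shape), 0.0)
    cols = [w.region_string() for w in windows]
    return pd.DataFrame(mat, index=samplesheet.sample_ids, columns=cols)


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    truth: Sequence[TruthCnv],
    genes: Sequence[GenomicInterval],
    samplesheet: SampleSheet,
    dosage_r: float = -0.9,
    n_de_genes: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a differential-expression table with dosage correlation.

    Genes overlapping domestication-differentiated CNVs become DE genes
    (adjusted p < 0.01, fold change beyond 1.5x in the direction of the
    expression shift); their per-breed mean expression is constructed so the
    Pearson correlation with the per-breed mean copy number equals
    ``dosage_r`` exactly (the noise component is orthogonalized against the
    dosage).  All other genes get null p-values and near-1 fold changes.

    Returns columns ``gene_id, padj, fold_change`` plus one mean-expression
    column per breed.
    """
    if not -1.0 <= dosage_r <= 1.0:
        raise ValueError("dosage_r must be in [-1, 1]")
    breeds = samplesheet.breeds
    wild = set(samplesheet.wild_breeds)
    diff_cnvs = [t for t in truth if t.label == DOMESTICATION]
    de_candidates = []
    for g in genes:
        hits = [t for t in diff_cnvs if t.interval.overlaps(g)]
        if hits:
            de_candidates.append((g, hits[0]))
    if n_de_genes is None:
        n_de_genes = len(de_candidates)
    if n_de_genes > len(de_candidates):
        raise ValueError(
            f"n_de_genes={n_de_genes} exceeds the {len(de_candidates)} genes "
            "overlapping domestication-differentiated CNVs"
        )
    rng = _rng(seed, _tag("expression"))
    de_set = {g.name for g, _ in de_candidates[:n_de_genes]}

    rows = []
    for g in genes:
        gid = g.name or str(g)
        hit = next((t for gg, t in de_candidates if gg.name == g.name), None)
        if gid in de_set and hit is not None:
            # per-breed dosage from the truth genotype frequencies
            x = np.array([2.0 + hit.carrier_frequency.get(b, 0.0)
                          * (hit.copy_number - 2.0) for b in breeds])
            zx = x - x.mean()
            sx = np.sqrt((zx ** 2).sum())
            eps = rng.standard_normal(len(breeds))
            if sx > 0:
                zx = zx / sx
                eps = eps - (eps @ zx) * zx  # orthogonalize
                eps = eps - eps.mean()
            se = np.sqrt((eps ** 2).sum())
            ze = eps / se if se > 0 else eps
            y = dosage_r * zx + math.sqrt(max(0.0, 1 - dosage_r ** 2)) * ze
            expr = 100.0 + 25.0 * y * math.sqrt(len(breeds))
            expr = np.maximum(expr, 0.0)
            wild_mean = np.mean([e for b, e in zip(breeds, expr) if b in wild])
            dom_mean = np.mean([e for b, e in zip(breeds, expr) if b not in wild])
            fc = float(rng.uniform(1.6, 4.0))
            if dom_mean < wild_mean:
                fc = 1.0 / fc
            padj = float(rng.uniform(1e-8, 0.009))
        else:
            expr = 100.0 + rng.normal(0, 10.0, len(breeds))
            expr = np.maximum(expr, 0.0)
            fc = float(rng.uniform(1 / 1.45, 1.45))
            padj = float(rng.uniform(0.02, 1.0))
        rows.append([gid, padj, fc, *expr])
    return pd.DataFrame(rows, columns=["gene_id", "padj", "fold_change", *breeds])
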