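"""End-to-end orchestration: simulate -> call -> consensus -> CNVR ->
population scans -> annotation -> expression correlation.

Every stage is a pure function of its inputs and the configuration; the
master seed expands into per-stage, per-sample streams (see
:mod:`cnvpop.simulate`), so the whole run is reproducible bit for bit and
adding a sample does not reshuffle the others.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import cnvr as cnvr_mod
from . import consensus as cons
from . import depth as depth_mod
from . import popgen
from . import simulate as sim
from .calls import DEL, DUP, calls_to_frame, write_calls
from .config import RunConfig, validate_config
from .expression import breed_mean_cn, correlate_cn_expression, filter_degs
from .intervals import GenomicInterval, SampleSheet, parse_region, write_gff3_genes
from .score import carried_events, score_calls

logger = logging.getLogger(__name__)

__all__ = ["run_all", "worked_example", "build_cn_matrix"]

#: The three per-sample deletions of the canonical CNVR-merge example
#: (1-based fully-closed region strings).
WORKED_EXAMPLE_DELETIONS = [
    ("sample1", "chr1:50500-51499"),
    ("sample2", "chr1:50600-52199"),
    ("sample3", "chr1:53000-53999"),
]


def worked_example() -> list[str]:
    """Merge the canonical three-deletion example into CNVRs.

    Three samples carry deletions chr1:50500-51499, chr1:50600-52199 and
    chr1:53000-53999; the >= 1 bp overlap rule merges the first two and
    leaves the third alone, giving CNVRs chr1:50500-52199 and
    chr1:53000-53999 (region strings are 1-based fully-closed).
    """
    from .calls import CnvCall

    calls = [
        CnvCall(sid, parse_region(region), DEL, source="example")
        for sid, region in WORKED_EXAMPLE_DELETIONS
    ]
    regions = cnvr_mod.merge_to_cnvrs(calls)
    return [r.id for r in regions]


def build_cn_matrix(
    cn_tracks: dict[str, pd.DataFrame],
    restrict_to: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Stack per-sample 1 kb copy-number tracks into a samples x windows
    matrix, optionally keeping only windows overlapping ``restrict_to``
    (typically the CNVR set).  Columns are 1-based region strings."""
    frames = {}
    for sid, track in cn_tracks.items():
        idx = [
            GenomicInterval(r.chrom, int(r.start), int(r.end)).region_string()
            for r in track.itertuples(index=False)
        ]
        frames[sid] = pd.Series(track["copy_number"].to_numpy(), index=idx)
    mat = pd.DataFrame(frames).T
    mat = mat.dropna(axis=1)  # keep windows present in every sample
    if restrict_to is not None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in restrict_to:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        keep = []
        for col in mat.columns:
            w = parse_region(col)
            if any(w.overlaps(iv) for iv in by_chrom.get(w.chrom, ())):
                keep.append(col)
        mat = mat[keep]
    return mat


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run report.

    Writes per-stage TSV outputs under ``outdir`` (defaults to
    ``config.outdir``).  Any stage failure raises with the stage name;
    outputs of completed stages remain on disk.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    seed = config.seed

    def stage(name):
        logger.info("stage: %s", name)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    g = config.genome
    layout = sim.generate_genome(g.n_chroms, g.chrom_len, g.masked_fraction,
                                 g.n_genes, seed=seed)
    sheet = sim.default_samplesheet()
    sheet.to_tsv(out / "samples.tsv")
    truth = sim.plant_cnvs(layout, sheet, config.design, seed=seed)
    sim.truth_to_frame(truth).to_csv(out / "truth_cnvs.tsv", sep="\t", index=False)
    write_gff3_genes(layout.genes, out / "genes.gff3")
    carriers = sim.assign_carriers(truth, sheet, seed)
    report["n_samples"] = len(sheet)
    report["n_truth_cnvs"] = len(truth)

    # --- depth simulation + read-depth caller -----------------------------
    stage("call-depth")
    ds = config.depth_sim
    rd_calls = []
    cn_tracks: dict[str, pd.DataFrame] = {}
    for sid, breed in zip(sheet.frame["sample_id"], sheet.frame["breed"]):
        carried = [truth[i] for i in carriers.columns if carriers.loc[sid, i]]
        windows = sim.simulate_depth(
            layout, truth, sid, breed, mean_depth=ds.mean_depth, window=ds.window,
            gc_bias_strength=ds.gc_bias_strength, dispersion=ds.dispersion,
            seed=seed, carried=carried,
        )
        calls, track = depth_mod.run_depth_caller(windows, sid, config.caller)
        rd_calls.extend(calls)
        cn_tracks[sid] = track
    write_calls(rd_calls, out / "rd_calls.tsv")
    report["n_rd_calls"] = len(rd_calls)
    report["n_rd_dup"] = sum(1 for c in rd_calls if c.type == DUP)
    report["n_rd_del"] = sum(1 for c in rd_calls if c.type == DEL)

    # --- simulated companion callers + consensus --------------------------
    stage("consensus")
    profiles = {k: v for k, v in config.profiles.items() if k != "mrfast"}
    caller_sets = sim.simulate_caller_calls(truth, sheet, profiles, layout,
                                            seed=seed, carriers=carriers)
    # the read-depth caller stands in for the duplication-aware rd method's
    # deletion set, completing the four-caller panel
    caller_sets["rd"] = [c for c in rd_calls if c.type == DEL]
    for name, calls in caller_sets.items():
        write_calls(calls, out / f"caller_{name}.tsv")
    cc = config.consensus
    consensus = cons.consensus_deletions(
        caller_sets, min_len=cc.min_del_length, min_support=cc.min_support,
        min_reciprocal=cc.min_reciprocal, cn_tracks=cn_tracks,
    )
    write_calls(consensus, out / "consensus_deletions.tsv")
    report["n_consensus_deletions"] = len(consensus)

    # --- CNVR construction ------------------------------------------------
    stage("build-cnvr")
    dup_calls = [c for c in rd_calls if c.type == DUP]
    cnvrs = cnvr_mod.merge_to_cnvrs(dup_calls + consensus)
    cnvr_table = cnvr_mod.cnvrs_to_frame(cnvrs, sheet.sample_ids)
    cnvr_table.to_csv(out / "cnvrs.tsv", sep="\t", index=False)
    presence = cnvr_mod.presence_matrix(cnvrs, sheet.sample_ids)
    presence.to_csv(out / "presence_matrix.tsv", sep="\t")
    cats, counts = cnvr_mod.frequency_spectrum(cnvrs, sheet.sample_ids)
    report["n_cnvrs"] = len(cnvrs)
    report["cnvr_classes"] = dict(cnvr_table["cnvr_class"].value_counts())
    report["freq_spectrum"] = counts
    nonsingleton = cnvr_mod.filter_singletons(cnvrs, len(sheet))
    report["n_cnvrs_nonsingleton"] = len(nonsingleton)

    # --- population statistics -------------------------------------------
    stage("popgen")
    if presence.shape[1] >= config.popgen.n_components:
        pca = popgen.pca_presence(presence, n_components=config.popgen.n_components)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        report["pca_variance_explained"] = [
            round(float(v), 4) for v in pca.variance_explained
        ]
    cn_matrix = build_cn_matrix(cn_tracks, restrict_to=[c.interval for c in cnvrs])
    cn_matrix.to_csv(out / "cn_matrix.tsv", sep="\t")
    report["n_cn_windows"] = cn_matrix.shape[1]
    dom = popgen.domestication_scan(cn_matrix, sheet,
                                    top_fraction=config.popgen.top_fraction)
    dom.table.to_csv(out / "vst_domestication.tsv", sep="\t")
    report["domestication_threshold"] = round(dom.threshold, 4)
    report["n_domestication_windows"] = len(dom.selected_windows)
    breed_scans = popgen.breed_specific_scan(
        cn_matrix, sheet, vst_threshold=config.popgen.vst_threshold
    )
    report["breed_specific_regions"] = {
        b: len(s.regions) for b, s in breed_scans.items()
    }

    # --- annotation -------------------------------------------------------
    stage("annotate")
    cnvr_ann = ann.overlap_genes([c.interval for c in nonsingleton], layout.genes)
    cnvr_ann.to_csv(out / "cnvr_genes.tsv", sep="\t", index=False)
    scan_regions = {"domestication": dom.regions}
    for b, s in breed_scans.items():
        scan_regions[f"breed_specific:{b}"] = s.regions
    candidates = ann.summarize_candidates(scan_regions, layout.genes)
    candidates.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    report["n_cnvr_genes"] = int(cnvr_ann["gene_id"].nunique()) if len(cnvr_ann) else 0
    report["n_candidate_genes"] = (
        int(candidates["gene_id"].nunique()) if len(candidates) else 0
    )

    # --- expression correlation ------------------------------------------
    stage("correlate")
    expr = sim.simulate_expression(truth, layout.genes, sheet,
                                   dosage_r=config.deg.dosage_r, seed=seed)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    degs = filter_degs(expr, padj_max=config.deg.padj_max, fc_min=config.deg.fc_min)
    report["n_degs"] = len(degs)
    deg_genes = [g for g in layout.genes if g.name in set(degs["gene_id"])]
    corr = pd.DataFrame()
    if deg_genes and cn_matrix.shape[1]:
        cn_by_breed = breed_mean_cn(cn_matrix, deg_genes, sheet)
        if len(cn_by_breed) and len(cn_by_breed.columns) >= 3:
            corr = correlate_cn_expression(cn_by_breed, degs)
            corr.to_csv(out / "cn_expression_correlation.tsv", sep="\t", index=False)
    report["n_correlated_genes"] = len(corr)
    if len(corr):
        sig = corr.loc[corr["significant"]]
        report["n_significant_correlations"] = int(len(sig))
        report["n_negative_significant"] = int((sig["r"] < 0).sum())

    # --- truth scoring ----------------------------------------------------
    stage("score")
    events = carried_events(truth, sheet, carriers)
    big = [e for e in events
           if e.interval.length >= 10_000]  # events the rd caller can see
    rd_score = score_calls(rd_calls, big)
    report["rd_sensitivity"] = round(rd_score.sensitivity, 4)
    report["rd_precision"] = round(rd_score.precision, 4)
    del_events = [e for e in events if e.type == DEL]
    cons_score = score_calls(consensus, del_events)
    report["consensus_sensitivity"] = round(cons_score.sensitivity, 4)
    report["consensus_precision"] = round(cons_score.precision, 4)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=int)
    return report
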