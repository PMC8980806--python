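"""Synthetic-data generator: determinism, dosage model, caller error model."""

import numpy as np
import pandas as pd
import pytest

from cnvpop import simulate as sim
from cnvpop.calls import DEL, DUP
from cnvpop.intervals import GenomicInterval


class TestGenerateGenome:
    def test_parameter_echo_and_masking(self):
        layout = sim.generate_genome(1, 10_000_000, 0.1, 100, seed=1)
        assert layout.chrom_sizes == {"chr1": 10_000_000}
        masked_bp = sum(iv.length for iv in layout.masked_regions)
        assert masked_bp == pytest.approx(1_000_000, rel=0.1)
        assert len(layout.genes) == 100

    def test_deterministic_for_seed(self):
        a = sim.generate_genome(2, 1_000_000, 0.1, 20, seed=3)
        b = sim.generate_genome(2, 1_000_000, 0.1, 20, seed=3)
        assert a.masked_regions == b.masked_regions
        assert a.genes == b.genes
        for c in a.chrom_sizes:
            np.testing.assert_array_equal(a.gc_profile[c], b.gc_profile[c])
        c = sim.generate_genome(2, 1_000_000, 0.1, 20, seed=4)
        assert a.masked_regions != c.masked_regions

    def test_no_masking(self):
        layout = sim.generate_genome(1, 1_000_000, 0.0, 10, seed=1)
        assert layout.masked_regions == []

    def test_gc_profile_bounded(self, small_layout):
        for prof in small_layout.gc_profile.values():
            assert prof.min() >= 0.3 and prof.max() <= 0.7

    def test_genes_non_overlapping(self, small_layout):
        by_chrom = {}
        for g in sorted(small_layout.genes):
            prev = by_chrom.get(g.chrom)
            if prev is not None:
                assert g.start >= prev.end
            by_chrom[g.chrom] = g

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            sim.generate_genome(1, 1_000_000, 0.6, 10, seed=1)
        with pytest.raises(ValueError):
            sim.generate_genome(0, 1_000_000, 0.1, 10, seed=1)


class TestPlantCnvs:
    def test_common_cnvs_fixed_everywhere(self, small_layout, samplesheet):
        design = sim.CnvDesign(n_neutral=0, n_common=10, n_domestication=0,
                               n_breed_specific=0)
        truth = sim.plant_cnvs(small_layout, samplesheet, design, seed=2)
        assert len(truth) == 10
        for t in truth:
            assert t.type == DUP
            assert all(f == 1.0 for f in t.carrier_frequency.values())

    def test_breed_specific_frequency_architecture(self, small_layout, samplesheet):
        design = sim.CnvDesign(n_neutral=0, n_common=0, n_domestication=0,
                               n_breed_specific=1, length_range=(5_000, 20_000))
        truth = sim.plant_cnvs(small_layout, samplesheet, design, seed=2)
        assert len(truth) == 6  # one per domestic breed
        for t in truth:
            breed = t.label.split(":")[1]
            assert t.carrier_frequency[breed] >= 0.9
            assert all(f <= 0.05 for b, f in t.carrier_frequency.items()
                       if b != breed)

    def test_avoids_masked_and_respects_gap(self, small_layout, samplesheet):
        design = sim.CnvDesign(n_neutral=15, n_common=0, n_domestication=0,
                               n_breed_specific=0, length_range=(5_000, 20_000))
        truth = sim.plant_cnvs(small_layout, samplesheet, design, seed=5)
        for t in truth:
            for m in small_layout.masked_regions:
                assert not t.interval.overlaps(m)
        ivs = sorted(t.interval for t in truth)
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end >= design.min_gap

    def test_deterministic(self, small_layout, samplesheet):
        d = sim.CnvDesign(n_neutral=5, n_common=2, n_domestication=1,
                          n_breed_specific=0, length_range=(5_000, 20_000))
        t1 = sim.plant_cnvs(small_layout, samplesheet, d, seed=9)
        t2 = sim.plant_cnvs(small_layout, samplesheet, d, seed=9)
        assert [x.interval for x in t1] == [x.interval for x in t2]
        assert [x.carrier_frequency for x in t1] == [x.carrier_frequency for x in t2]

    def test_too_small_genome_raises(self, samplesheet):
        layout = sim.generate_genome(1, 500_000, 0.0, 5, seed=1)
        design = sim.CnvDesign(n_neutral=50, n_common=0, n_domestication=0,
                               n_breed_specific=0)
        with pytest.raises(ValueError, match="too small"):
            sim.plant_cnvs(layout, samplesheet, design, seed=1)

    def test_truth_frame_round_trip(self, small_layout, samplesheet):
        d = sim.CnvDesign(n_neutral=5, n_common=1, n_domestication=1,
                          n_breed_specific=1, length_range=(5_000, 20_000))
        truth = sim.plant_cnvs(small_layout, samplesheet, d, seed=9)
        back = sim.frame_to_truth(sim.truth_to_frame(truth))
        assert back == truth


class TestAssignCarriers:
    def test_stable_per_sample(self, small_layout, samplesheet):
        d = sim.CnvDesign(n_neutral=10, n_common=0, n_domestication=0,
                          n_breed_specific=0, length_range=(5_000, 20_000))
        truth = sim.plant_cnvs(small_layout, samplesheet, d, seed=3)
        full = sim.assign_carriers(truth, samplesheet, seed=3)
        # dropping samples does not change the remaining rows
        sub_frame = samplesheet.frame.iloc[:10]
        from cnvpop.intervals import SampleSheet

        sub = sim.assign_carriers(truth, SampleSheet(sub_frame), seed=3)
        pd.testing.assert_frame_equal(full.loc[sub.index], sub)

    def test_frequency_zero_and_one(self, small_layout, samplesheet):
        iv = GenomicInterval("chr1", 100_000, 150_000)
        always = sim.TruthCnv(iv, DUP, 4, {b: 1.0 for b in samplesheet.breeds})
        iv2 = GenomicInterval("chr1", 200_000, 250_000)
        never = sim.TruthCnv(iv2, DUP, 4, {b: 0.0 for b in samplesheet.breeds})
        carriers = sim.assign_carriers([always, never], samplesheet, seed=0)
        assert carriers[0].all()
        assert not carriers[1].any()


class TestSimulateDepth:
    def test_degenerate_noise(self, small_layout):
        win = sim.simulate_depth(small_layout, [], "s", "RJF", mean_depth=100,
                                 gc_bias_strength=0.0, dispersion=0.0, seed=1)
        cv = win["raw_depth"].std() / win["raw_depth"].mean()
        assert cv < 0.02

    def test_dosage_model_cn4(self, small_layout, samplesheet):
        iv = GenomicInterval("chr1", 1_000_000, 1_100_000)
        cnv = sim.TruthCnv(iv, DUP, 4, {b: 1.0 for b in samplesheet.breeds})
        win = sim.simulate_depth(small_layout, [cnv], "s", "RJF", mean_depth=50,
                                 gc_bias_strength=0.0, dispersion=0.0, seed=2,
                                 carried=[cnv])
        inside = win[(win.start >= iv.start) & (win.end <= iv.end)]
        outside = win[(win.end <= iv.start) | (win.start >= iv.end)]
        assert inside["raw_depth"].mean() == pytest.approx(
            2 * outside["raw_depth"].mean(), rel=0.02
        )

    def test_mean_matches_target_large_n(self, small_layout):
        # law of large numbers over >= 1000 neutral windows
        win = sim.simulate_depth(small_layout, [], "s", "RJF", mean_depth=10,
                                 gc_bias_strength=0.0, dispersion=0.05, seed=7)
        assert len(win) >= 1000
        assert win["raw_depth"].mean() == pytest.approx(10.0, rel=0.01)

    def test_gc_bias_curve_ratio(self):
        gc = np.linspace(0.3, 0.7, 101)
        g = sim.gc_bias_curve(gc, 0.4)
        assert g.max() / g.min() == pytest.approx(1.4, rel=1e-6)
        assert g.argmax() == 50  # peak at GC 0.5

    def test_deterministic(self, small_layout):
        a = sim.simulate_depth(small_layout, [], "s", "RJF", seed=5)
        b = sim.simulate_depth(small_layout, [], "s", "RJF", seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateCallerCalls:
    @pytest.fixture()
    def del_truth(self, small_layout, samplesheet):
        design = sim.CnvDesign(n_neutral=20, n_common=0, n_domestication=0,
                               n_breed_specific=0, length_range=(2_000, 10_000),
                               dup_fraction=0.0, neutral_freq_range=(1.0, 1.0),
                               neutral_freq_jitter=0.0, min_gap=5_000)
        return sim.plant_cnvs(small_layout, samplesheet, design, seed=4)

    def test_perfect_callers_report_exact_truth(self, del_truth, small_layout,
                                                samplesheet):
        profiles = {n: sim.CallerProfile(n) for n in ("a", "b")}
        sets = sim.simulate_caller_calls(del_truth, samplesheet, profiles,
                                         small_layout, seed=1)
        expected = {(s, t.interval) for s in samplesheet.sample_ids
                    for t in del_truth}
        for name, calls in sets.items():
            got = {(c.sample_id, c.interval) for c in calls}
            assert got == expected

    def test_fnr_one_gives_empty(self, del_truth, small_layout, samplesheet):
        profiles = {"dead": sim.CallerProfile("dead", fnr=1.0)}
        sets = sim.simulate_caller_calls(del_truth, samplesheet, profiles,
                                         small_layout, seed=1)
        assert sets["dead"] == []

    def test_binomial_detection_rate(self, small_layout, samplesheet):
        # 100 planted deletions carried by one sample, fnr=0.2:
        # expected reported true calls = 80 +/- binomial noise
        layout = sim.generate_genome(1, 10_000_000, 0.0, 10, seed=3)
        design = sim.CnvDesign(n_neutral=100, n_common=0, n_domestication=0,
                               n_breed_specific=0, length_range=(2_000, 5_000),
                               dup_fraction=0.0, neutral_freq_range=(1.0, 1.0),
                               neutral_freq_jitter=0.0, min_gap=5_000)
        truth = sim.plant_cnvs(layout, samplesheet, design, seed=3)
        profiles = {"c": sim.CallerProfile("c", fnr=0.2)}
        sets = sim.simulate_caller_calls(truth, samplesheet, profiles, layout,
                                         seed=3)
        sid = samplesheet.sample_ids[0]
        n = sum(1 for c in sets["c"] if c.sample_id == sid)
        # 4 sigma of Binomial(100, 0.8)
        assert abs(n - 80) <= 16

    def test_min_detectable_length_filters(self, del_truth, small_layout,
                                           samplesheet):
        profiles = {"big": sim.CallerProfile("big", min_detectable_len=10**7)}
        sets = sim.simulate_caller_calls(del_truth, samplesheet, profiles,
                                         small_layout, seed=1)
        assert sets["big"] == []

    def test_false_positive_rate(self, samplesheet):
        layout = sim.generate_genome(1, 10_000_000, 0.0, 10, seed=5)
        profiles = {"fp": sim.CallerProfile("fp", fpr_per_mb=2.0)}
        sets = sim.simulate_caller_calls([], samplesheet, profiles, layout, seed=5)
        per_sample = pd.Series([c.sample_id for c in sets["fp"]]).value_counts()
        # Poisson(20) per sample, averaged over 51 samples
        assert per_sample.reindex(samplesheet.sample_ids).fillna(0).mean() == \
            pytest.approx(20, rel=0.15)


class TestSimulateExpression:
    @pytest.fixture()
    def dom_setup(self, small_layout, samplesheet):
        design = sim.CnvDesign(n_neutral=0, n_common=0, n_domestication=4,
                               n_breed_specific=0, length_range=(10_000, 30_000))
        truth = sim.plant_cnvs(small_layout, samplesheet, design, seed=6)
        return truth

    def _dosage(self, t, breeds):
        return np.array([2.0 + t.carrier_frequency[b] * (t.copy_number - 2)
                         for b in breeds])

    @pytest.mark.parametrize("r", [1.0, -1.0, 0.0, -0.6])
    def test_realized_correlation(self, dom_setup, small_layout, samplesheet, r):
        truth = dom_setup
        expr = sim.simulate_expression(truth, small_layout.genes, samplesheet,
                                       dosage_r=r, seed=8)
        breeds = samplesheet.breeds
        de = expr[expr["padj"] < 0.01]
        assert len(de) >= 1
        for _, row in de.iterrows():
            gene = next(g for g in small_layout.genes if g.name == row.gene_id)
            hit = next(t for t in truth if t.interval.overlaps(gene))
            x = self._dosage(hit, breeds)
            y = row[breeds].to_numpy(float)
            realized = np.corrcoef(x, y)[0, 1]
            assert realized == pytest.approx(r, abs=1e-6)

    def test_de_genes_pass_filters_others_fail(self, dom_setup, small_layout,
                                               samplesheet):
        expr = sim.simulate_expression(dom_setup, small_layout.genes, samplesheet,
                                       dosage_r=-0.9, seed=8)
        de = expr[expr["padj"] < 0.01]
        rest = expr[expr["padj"] >= 0.01]
        assert (np.maximum(de["fold_change"], 1 / de["fold_change"]) > 1.5).all()
        assert (np.maximum(rest["fold_change"], 1 / rest["fold_change"]) < 1.5).all()
        assert (rest["padj"] >= 0.02).all()

    def test_too_many_de_genes_raises(self, dom_setup, small_layout, samplesheet):
        with pytest.raises(ValueError, match="exceeds"):
            sim.simulate_expression(dom_setup, small_layout.genes, samplesheet,
                                    n_de_genes=10**4, seed=8)


class TestExpectedCnMatrix:
    def test_dosage_values(self, small_layout, samplesheet):
        iv = GenomicInterval("chr1", 1_000_000, 1_050_000)
        cnv = sim.TruthCnv(iv, DUP, 4, {b: 1.0 for b in samplesheet.breeds})
        carriers = sim.assign_carriers([cnv], samplesheet, seed=0)
        windows = sim.kb_windows(small_layout, within=[iv])
        cn = sim.expected_cn_matrix([cnv], samplesheet, windows, carriers)
        inside_cols = [w.region_string() for w in windows
                       if iv.contains(w)]
        assert (cn[inside_cols].to_numpy() == 4.0).all()
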