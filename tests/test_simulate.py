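"""Determinism, planted rates, and NB structure of the synthetic generator."""

import numpy as np
import pytest

from tfscreen import SimConfig, simulate
from tfscreen.assign import AssignmentConfig, assign_peak
from tfscreen.diffexpr import size_factors
from tfscreen.genome import read_bed, read_gff3
from tfscreen.simulate import (
    CobindBlocks,
    SimTruth,
    make_annotation,
    make_binding,
    make_cobinding_sets,
    make_counts,
    plant_induced_sets,
    write_fixtures,
)


class TestAnnotation:
    def test_same_seed_is_reproducible(self):
        cfg = SimConfig(seed=42, n_genes=80)
        assert make_annotation(cfg).genes == make_annotation(cfg).genes

    def test_gene_count_uniqueness_and_disjointness(self):
        ann = make_annotation(SimConfig(seed=1, n_genes=200))
        assert len(ann) == 200
        ivals = sorted((g.start, g.end) for g in ann.genes)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivals, ivals[1:]))

    def test_zero_regulator_fraction(self):
        ann = make_annotation(SimConfig(seed=1, n_genes=60, frac_regulators=0.0))
        assert all(g.func_class == "other" for g in ann.genes)

    def test_overcrowded_chromosome_fails_loudly(self):
        with pytest.raises(ValueError, match="chrom_len"):
            make_annotation(SimConfig(seed=0, n_genes=500, chrom_len=200_000))


class TestBinding:
    def test_boundary_rates_pin_the_bound_set_to_truth(self):
        cfg = SimConfig(seed=5, n_genes=100, induced_bound_rate=1.0,
                        background_bound_rate=0.0, decoy_frac=0.0)
        ann = make_annotation(cfg)
        truth = plant_induced_sets(ann, cfg)
        make_binding(ann, truth, cfg)
        # anchor is forced bound even when it falls outside the rate draw
        assert truth.bound == truth.induced_wt | {truth.planted_top_candidate}

    def test_every_planted_peak_recovers_its_source_gene(self, default_sim):
        acfg = AssignmentConfig(default_sim.config.window_bp)
        by_name = {}
        for p in default_sim.peaks:
            if p.name and p.name.startswith("peak_"):
                by_name[p.name[len("peak_"):]] = p
        assert set(by_name) == default_sim.truth.bound
        for gene_id, peak in by_name.items():
            assert gene_id in assign_peak(peak, default_sim.annotation, acfg).genes

    def test_decoys_are_far_from_every_gene(self, default_sim):
        w = default_sim.config.window_bp
        decoys = [p for p in default_sim.peaks if p.name and p.name.startswith("decoy")]
        assert len(decoys) == default_sim.truth.n_decoys > 0
        for d in decoys:
            assert default_sim.annotation.query("chr1", d.start - w, d.end + w) == []

    def test_background_bound_rate_converges_across_seeds(self):
        rate = SimConfig().background_bound_rate
        realized = []
        trials = 0
        for seed in range(60):
            cfg = SimConfig(seed=seed, n_genes=150, decoy_frac=0.0)
            ann = make_annotation(cfg)
            truth = plant_induced_sets(ann, cfg)
            make_binding(ann, truth, cfg)
            non_induced = {g.gene_id for g in ann.genes} - truth.induced_wt
            non_induced.discard(truth.planted_top_candidate)
            realized.append(len(truth.bound & non_induced))
            trials += len(non_induced)
        se = np.sqrt(rate * (1 - rate) / trials)
        assert abs(sum(realized) / trials - rate) < 3 * se


class TestCounts:
    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimConfig(seed=2, n_genes=300, dispersion=1e-9, n_reps=30,
                        lfc_range=(0.0, 0.0), n_induced_wt=0, n_induced_null=0,
                        libsize_factor_range=(1.0, 1.0))
        ann = make_annotation(cfg)
        truth = plant_induced_sets(ann, cfg)
        counts = make_counts(ann, truth, cfg).counts.to_numpy()[:, :30]
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_nonpositive_dispersion_rejected(self):
        cfg = SimConfig(dispersion=-0.5)
        with pytest.raises(ValueError, match="dispersion"):
            cfg.validate()

    def test_planted_fold_change_is_recovered_by_normalized_means(self):
        # induced fraction kept at the default ~10%: median-of-ratios
        # normalization is biased when a large share of genes move one way
        errs = []
        for seed in range(8):
            cfg = SimConfig(seed=seed, n_genes=400, n_reps=6, lfc_range=(2.0, 2.0))
            ann = make_annotation(cfg)
            truth = plant_induced_sets(ann, cfg)
            truth.planted_top_candidate = None  # plain genes only: all lfc exactly 2
            cm = make_counts(ann, truth, cfg)
            wt = cm.subset_genotype("wt")
            f = size_factors(wt.counts)
            norm = wt.counts / f
            stim = norm.loc[:, [s.sample_id for s in wt.design if s.treatment == "stimulated"]]
            untr = norm.loc[:, [s.sample_id for s in wt.design if s.treatment == "untreated"]]
            for g in truth.induced_wt:
                errs.append(stim.loc[g].mean() / untr.loc[g].mean())
        assert np.mean(errs) == pytest.approx(4.0, rel=0.1)

    def test_genotype_specificity_of_planted_effects(self, default_sim):
        cm = default_sim.counts
        truth = default_sim.truth
        null = cm.subset_genotype("null")
        norm = null.counts / size_factors(null.counts)
        stim = norm.loc[:, [s.sample_id for s in null.design if s.treatment == "stimulated"]]
        untr = norm.loc[:, [s.sample_id for s in null.design if s.treatment == "untreated"]]
        wt_only = sorted(truth.induced_wt - truth.induced_null)
        ratios = stim.loc[wt_only].mean(axis=1) / untr.loc[wt_only].mean(axis=1)
        assert abs(np.log2(ratios).mean()) < 0.3
        both = sorted(truth.induced_null)
        ratios_null = stim.loc[both].mean(axis=1) / untr.loc[both].mean(axis=1)
        assert np.log2(ratios_null).mean() > 0.7


class TestCobindingSets:
    def test_degenerate_rates_make_blocks_identical(self):
        cfg = SimConfig(seed=3)
        cfg.cobind = CobindBlocks(within_rate=1.0, between_rate=0.0)
        sets, blocks = make_cobinding_sets(cfg)
        by_factor = {s.factor: s.peaks for s in sets}
        assert by_factor["TF1"] == by_factor["TF2"]
        assert by_factor["TF3"] == by_factor["TF4"]
        assert not set(map(tuple, ((p.start, p.end) for p in by_factor["TF1"]))) & set(
            map(tuple, ((p.start, p.end) for p in by_factor["TF3"]))
        )

    def test_inverted_rates_rejected(self):
        cfg = SimConfig()
        cfg.cobind = CobindBlocks(within_rate=0.2, between_rate=0.5)
        with pytest.raises(ValueError, match="within_rate"):
            cfg.validate()

    def test_same_seed_reproduces_peak_sets(self):
        cfg = SimConfig(seed=9)
        s1, _ = make_cobinding_sets(cfg)
        s2, _ = make_cobinding_sets(cfg)
        assert [(s.factor, s.peaks) for s in s1] == [(s.factor, s.peaks) for s in s2]


class TestFixtureRoundTrip:
    def test_written_fixtures_reload_identically(self, default_sim, tmp_path):
        paths = write_fixtures(default_sim, str(tmp_path))
        ann = read_gff3(paths["annotation"])
        assert ann.genes == default_sim.annotation.genes
        peaks = read_bed(paths["peaks"])
        assert peaks.peaks == default_sim.peaks.peaks
        from tfscreen.diffexpr import read_counts_tsv

        cm = read_counts_tsv(paths["counts"], paths["design"])
        assert (cm.counts.to_numpy() == default_sim.counts.counts.to_numpy()).all()
        assert cm.design == default_sim.counts.design
        truth = SimTruth.from_json(paths["truth"])
        assert truth.induced_wt == default_sim.truth.induced_wt
        assert truth.bound == default_sim.truth.bound

    def test_simulation_is_a_pure_function_of_config(self):
        a = simulate(SimConfig(seed=8, n_genes=120))
        b = simulate(SimConfig(seed=8, n_genes=120))
        assert a.annotation.genes == b.annotation.genes
        assert a.peaks.peaks == b.peaks.peaks
        assert (a.counts.counts == b.counts.counts).all().all()
        assert a.truth.bound == b.truth.bound
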