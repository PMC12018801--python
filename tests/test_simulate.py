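import numpy as np
import pandas as pd
import pytest

from dynaqtl.simulate import (
    FieldDesign,
    QtlSpec,
    TraceParams,
    assign_gene_intervals,
    plant_qtl,
    simulate_fluorescence_traces,
    simulate_founder_expression,
    simulate_founder_genomes,
    simulate_founder_snps,
    simulate_magic_rils,
    simulate_phenotype_table,
    uniform_marker_map,
)


class TestFounderGenomes:
    def test_forced_polymorphism_two_founders(self):
        gmap = uniform_marker_map(1, 1)
        panel = simulate_founder_genomes(2, gmap, maf_range=(0.5, 0.5), seed=1)
        assert panel.alleles[0, 0] != panel.alleles[1, 0]

    def test_seed_determinism(self, small_map):
        a = simulate_founder_genomes(8, small_map, seed=7).alleles
        b = simulate_founder_genomes(8, small_map, seed=7).alleles
        assert np.array_equal(a, b)

    def test_maf_within_range_by_direct_count(self):
        gmap = uniform_marker_map(1, 500)
        panel = simulate_founder_genomes(8, gmap, maf_range=(0.2, 0.5), seed=3)
        counts = panel.alleles.sum(axis=0)
        maf = np.minimum(counts, 8 - counts) / 8.0
        assert (maf >= 0.2).all() and (maf <= 0.5).all()

    def test_invalid_maf_range(self, small_map):
        with pytest.raises(ValueError):
            simulate_founder_genomes(8, small_map, maf_range=(0.0, 0.6), seed=1)


class TestMagicRils:
    def test_no_recombination_single_founder(self, panel):
        rils, mosaics = simulate_magic_rils(
            panel, n_rils=20, breakpoint_rate_per_morgan=0.0, seed=5
        )
        for m in mosaics:
            assert m.n_breakpoints() == 0
        # observed alleles equal the start founder's at every marker
        for r, m in enumerate(mosaics):
            for c in panel.gmap.chromosomes:
                idx = panel.gmap.marker_indices(c)
                f = int(m.chromosomes[c].founders[0])
                assert np.array_equal(rils.alleles[r, idx], panel.alleles[f, idx])

    def test_noise_free_alleles_match_mosaic(self, panel):
        rils, mosaics = simulate_magic_rils(
            panel, n_rils=30, genotyping_error=0.0, missing_rate=0.0, seed=6
        )
        for r, m in enumerate(mosaics):
            for c in panel.gmap.chromosomes:
                idx = panel.gmap.marker_indices(c)
                bp = panel.gmap.chrom_view(c)["bp"].to_numpy(dtype=float)
                f_at = m.chromosomes[c].founder_at(bp)
                assert np.array_equal(rils.alleles[r, idx], panel.alleles[f_at, idx])

    def test_breakpoint_count_poisson_oracle(self):
        gmap = uniform_marker_map(1, 50, chrom_length_cm=100.0)  # 1 Morgan
        panel = simulate_founder_genomes(8, gmap, seed=8)
        _, mosaics = simulate_magic_rils(
            panel, n_rils=200, breakpoint_rate_per_morgan=2.0, seed=9
        )
        counts = np.array([m.n_breakpoints() for m in mosaics])
        se = np.sqrt(2.0 / 200)  # Poisson(2) mean over 200 RILs
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_parameter_validation(self, panel):
        with pytest.raises(ValueError):
            simulate_magic_rils(panel, n_rils=5, n_self_generations=0, seed=1)


class TestPlantQtl:
    def test_zero_effects_zero_values(self, panel, rils_and_mosaics):
        _, mosaics = rils_and_mosaics
        spec = QtlSpec("1", 50_000_000, {f: 0.0 for f in panel.founder_ids}, 0.0)
        assert np.all(plant_qtl(mosaics, spec, panel) == 0.0)

    def test_fixed_founder_value(self):
        gmap = uniform_marker_map(1, 10)
        panel = simulate_founder_genomes(2, gmap, seed=1, founder_ids=["A", "B"])
        _, mosaics = simulate_magic_rils(panel, n_rils=5, breakpoint_rate_per_morgan=0.0, seed=2)
        spec = QtlSpec("1", 50_000_000, {"A": 1.0, "B": -1.0}, 0.0)
        vals = plant_qtl(mosaics, spec, panel)
        starts = [m.chromosomes["1"].founders[0] for m in mosaics]
        expect = np.where(np.array(starts) == 0, 1.0, -1.0)
        assert np.array_equal(vals, expect)

    def test_off_map_position_error(self, panel, rils_and_mosaics):
        _, mosaics = rils_and_mosaics
        spec = QtlSpec("1", 10**10, {f: 0.0 for f in panel.founder_ids}, 0.0)
        with pytest.raises(ValueError, match="outside map span"):
            plant_qtl(mosaics, spec, panel)

    def test_variance_explained_realized_r2(self):
        """Planted 20% QTL yields realized R² near 0.2 on entry means."""
        gmap = uniform_marker_map(2, 60)
        panel = simulate_founder_genomes(8, gmap, seed=1)
        effects = {f: 1.0 for f in panel.founder_ids}
        effects[panel.founder_ids[3]] = -7.0
        spec = QtlSpec("1", 75_000_000, effects, 0.2)
        r2s = []
        for seed in range(20):
            _, mosaics = simulate_magic_rils(panel, n_rils=300, seed=100 + seed)
            g = plant_qtl(mosaics, spec, panel, other_variance=1.0)
            rng = np.random.default_rng(500 + seed)
            pheno = g + rng.normal(0.0, 1.0, len(g))
            r2s.append(np.corrcoef(g, pheno)[0, 1] ** 2)
        assert 0.15 <= np.median(r2s) <= 0.25


class TestPhenotypeTable:
    def test_all_variances_zero(self):
        g = np.array([0.1, -0.2, 0.3])
        tab = simulate_phenotype_table(
            g, ["a", "b", "c"], {}, FieldDesign(years=("2021",), n_reps=1), mean=0.7, seed=1
        )
        got = tab.set_index("genotype")["value"]
        assert np.allclose(got[["a", "b", "c"]], 0.7 + g)

    def test_pure_genotype_variance_replicates_identical(self):
        tab = simulate_phenotype_table(
            np.zeros(10),
            [f"g{i}" for i in range(10)],
            {"genotype": 1.0},
            FieldDesign(years=("2021",), n_reps=2),
            seed=2,
        )
        per_geno = tab.groupby("genotype")["value"].nunique()
        assert (per_geno == 1).all()

    def test_anova_heritability_oracle(self):
        """One-way ANOVA variance shares recover the design components."""
        vc = {"genotype": 0.5, "residual": 0.5}
        tab = simulate_phenotype_table(
            np.zeros(300),
            [f"g{i}" for i in range(300)],
            vc,
            FieldDesign(n_reps=2),
            seed=3,
        )
        wide = tab.pivot_table(index="genotype", columns=["year", "rep"], values="value")
        r = wide.shape[1]
        msb = r * wide.mean(axis=1).var(ddof=1)
        msw = wide.var(axis=1, ddof=1).mean()
        sg = (msb - msw) / r
        h2 = sg / (sg + msw)
        assert abs(h2 - 0.5) < 0.05

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotype_table(np.zeros(2), ["a", "b"], {"genotype": -1.0}, seed=1)


class TestFluorescenceTraces:
    def test_closed_form_npq_at_600s(self):
        p = TraceParams(a_ind=2.0, b_ind=0.02)
        tr = simulate_fluorescence_traces({"s": p}, noise_sd=0.0)[0]
        t, _f, fmp = tr.light_pulses[-1]
        assert t == 600
        npq = 2.0 * (1 - np.exp(-0.02 * 600))
        assert np.isclose(fmp, p.fm / (1 + npq))
        assert np.isclose(fmp, p.fm / 3.0, rtol=1e-5)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError, match="Fm > Fo"):
            simulate_fluorescence_traces({"s": TraceParams(fo=900, fm=800)})
        with pytest.raises(ValueError, match="positive"):
            simulate_fluorescence_traces({"s": TraceParams(b_ind=0.0)})

    def test_seed_determinism(self):
        a = simulate_fluorescence_traces({"s": TraceParams()}, noise_sd=0.05, seed=4)[0]
        b = simulate_fluorescence_traces({"s": TraceParams()}, noise_sd=0.05, seed=4)[0]
        assert a.light_pulses == b.light_pulses and a.dark_pulses == b.dark_pulses


class TestFounderExpression:
    def test_seed_determinism(self):
        eff = {"A": 1.0, "B": -1.0}
        a = simulate_founder_expression(["g1", "g2"], "g1", eff, seed=5)
        b = simulate_founder_expression(["g1", "g2"], "g1", eff, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_near_poisson_group_means_ordered(self):
        """Huge dispersion (near-Poisson) + large slope orders founder means."""
        eff = {"A": -2.0, "B": -1.0, "C": 1.0, "D": 2.0}
        counts = simulate_founder_expression(
            ["g1"], "g1", eff, baseline_mean=2000.0, dispersion=1e6,
            n_replicates=10, slope=1.0, seed=6,
        )
        means = {f: counts[[c for c in counts if c.startswith(f + "_")]].loc["g1"].mean() for f in eff}
        ordered = sorted(eff, key=eff.get)
        vals = [means[f] for f in ordered]
        assert vals == sorted(vals)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_founder_expression(["g1"], "g2", {"A": 0.0}, seed=1)
        with pytest.raises(ValueError):
            simulate_founder_expression(["g1"], "g1", {"A": 0.0}, dispersion=0.0, seed=1)


class TestRegionHelpers:
    def test_gene_intervals_disjoint_within_region(self):
        genes = assign_gene_intervals([f"g{i}" for i in range(50)], "2", (1_000_000, 2_000_000), seed=7)
        assert (genes["start"] >= 1_000_000).all() and (genes["end"] <= 2_000_000).all()
        s = genes.sort_values("start")
        assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_founder_snps_polymorphic_and_causal_unique(self, panel):
        snps = simulate_founder_snps(
            panel, "1", (60_000_000, 90_000_000), n_snps=200,
            causal_bp=75_000_000, causal_carriers=["F7"], seed=8,
        )
        pat = snps[panel.founder_ids].to_numpy()
        assert ((pat.sum(axis=1) > 0) & (pat.sum(axis=1) < 8)).all()
        causal = snps["snp"].str.startswith("snp_causal")
        assert causal.sum() == 1
        cpat = pat[causal.to_numpy()][0]
        dup = (pat == cpat).all(axis=1) | (pat == 1 - cpat).all(axis=1)
        assert dup.sum() == 1  # only the causal SNP itself
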