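"""Synthetic-study generator: design layout, determinism, planted structure."""

import warnings

import numpy as np
import pandas as pd
import pytest

from paoscope.synth import (
    SynthParams,
    default_archetypes,
    gen_design,
    gen_env,
    gen_function_table,
    gen_otu_table,
    gen_spectra,
)


class TestDesign:
    @pytest.mark.parametrize(
        "n_blocks,n_reps,n_expected",
        [(6, 6, 24), (1, 1, 4), (2, 3, 12)],
    )
    def test_counts(self, n_blocks, n_reps, n_expected):
        d = gen_design(n_blocks, n_reps)
        assert len(d) == n_expected
        assert (d.groupby("treatment").size() == n_reps).all()

    def test_blocks_cover_every_treatment(self):
        d = gen_design(2, 3)
        for _, grp in d.groupby("treatment"):
            assert set(grp["block"]) == {1, 2}

    def test_four_treatment_combinations(self):
        d = gen_design(6, 6)
        combos = set(zip(d["warming"], d["clipping"]))
        assert combos == {(0, 0), (0, 1), (1, 0), (1, 1)}
        assert not d.duplicated(["treatment", "replicate"]).any()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_design(0, 6)
        with pytest.raises(ValueError):
            gen_design(6, 0)


class TestOtuTable:
    def test_determinism(self, default_design):
        p = SynthParams(seed=11)
        t1, _ = gen_otu_table(default_design, p)
        t2, _ = gen_otu_table(default_design, p)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_depth_and_nonnegativity(self, small_study):
        counts = small_study["table"].counts
        assert (counts.sum(axis=0) == small_study["params"].depth).all()
        assert (counts.to_numpy() >= 0).all()

    def test_relative_abundance_sums_to_one(self, small_study):
        rel = small_study["table"].relative_abundance()
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)

    def test_pao_count_param_validated(self):
        with pytest.raises(ValueError):
            SynthParams(n_taxa=10, n_pao_taxa=20)

    def test_null_effect_gives_small_beta(self, default_design):
        """With zero planted effects the warming coefficient is within 2 SE of 0."""
        from paoscope.community import filter_otus, require_pao_genes
        from paoscope.diversity import fit_lmm, shannon

        p = SynthParams(
            seed=3,
            warming_pao_shannon=0.0,
            warming_bulk_shannon=0.0,
            warming_pao_abund_mult=1.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, _ = gen_otu_table(default_design, p)
            fn = gen_function_table(t, p)
            ft, _ = filter_otus(t)
            pao = require_pao_genes(ft, fn)
            rel = pao.relative_abundance()
            h = rel.apply(lambda c: shannon(c.to_numpy()), axis=0)
            eff = fit_lmm(
                h[default_design.sample_id].to_numpy(),
                default_design.set_index("sample_id", drop=False),
            )
        assert abs(eff[0].beta) < 2 * eff[0].se

    def test_planted_shannon_targets_realized(self, small_study):
        """Measured per-sample PAO Shannon tracks the planted targets."""
        from paoscope.diversity import shannon

        truth, table = small_study["truth"], small_study["table"]
        pao_taxa = truth["pao_taxa"]
        rel = table.relative_abundance().loc[pao_taxa]
        for sid, target in list(truth["h_pao_targets"].items())[:6]:
            assert shannon(rel[sid].to_numpy()) == pytest.approx(target, abs=0.12)


class TestFunctionTable:
    def test_planted_paos_have_all_genes(self, small_study):
        fn, truth = small_study["functions"], small_study["truth"]
        assert fn.genes.loc[truth["pao_taxa"]].all().all()

    def test_redundancy_extremes(self, small_study):
        from paoscope.diversity import functional_redundancy

        table = small_study["table"]
        # redundancy 1: every taxon contributes to every category -> FR = mean f
        fn1 = gen_function_table(table, SynthParams(seed=1, redundancy=1.0))
        contrib = fn1.contributions
        expected = contrib.mean(axis=0).mean()
        assert functional_redundancy(contrib) == pytest.approx(expected, rel=1e-9)
        # redundancy 0: one taxon per category -> FR = mean of the single f's
        fn0 = gen_function_table(table, SynthParams(seed=1, redundancy=0.0))
        per_cat = fn0.contributions.sum(axis=0)  # single contributor each
        assert (fn0.contributions > 0).sum(axis=0).eq(1).all()
        assert functional_redundancy(fn0.contributions) == pytest.approx(
            per_cat.mean(), rel=1e-9
        )


class TestSpectra:
    def test_default_design_cell_count(self):
        d = gen_design(1, 1)  # 4 samples
        p = SynthParams(seed=0, cells_per_drop=5, n_drops=2)
        s = gen_spectra(d, params=p)
        assert s.intensities.shape == (4 * 2 * 5, 1601)
        assert np.isclose(s.wavenumbers[0], 400.0)
        assert np.isclose(s.wavenumbers[-1], 2000.0)

    def test_zero_noise_single_archetype_identical(self):
        d = gen_design(1, 1).head(1)
        arch = default_archetypes(1)
        p = SynthParams(
            seed=0, cells_per_drop=4, n_drops=1,
            spectra_noise_sd=0.0, band_jitter_sd=0.0, baseline_scale=0.0,
        )
        s = gen_spectra(d, archetypes=arch, params=p)
        assert np.allclose(s.intensities, s.intensities[0])

    def test_band_outside_grid_rejected(self):
        from paoscope.synth import Band, SpectrumArchetype

        with pytest.raises(ValueError):
            SpectrumArchetype("bad", [Band(2100.0, 5.0, 1.0)])
        with pytest.raises(ValueError):
            SpectrumArchetype("bad", [Band(900.0, -1.0, 1.0)])

    def test_warming_biomarker_directions(self):
        """Warming raises glycogen/PHA band mass, lowers polyP/FA."""
        from paoscope.raman import quantify_biomarkers

        d = gen_design(1, 2)
        p = SynthParams(seed=5, cells_per_drop=30, n_drops=1)
        s = gen_spectra(d, params=p)
        means = {}
        for w in (0, 1):
            sub = s.intensities[s.meta.warming.to_numpy() == w]
            levels = [quantify_biomarkers(s.wavenumbers, y) for y in sub]
            means[w] = {k: np.mean([lv[k] for lv in levels]) for k in levels[0]}
        assert means[1]["glycogen"] > means[0]["glycogen"]
        assert means[1]["pha"] > means[0]["pha"]
        assert means[1]["polyp"] < means[0]["polyp"]
        assert means[1]["fa"] < means[0]["fa"]

    def test_seeded_reproducibility(self):
        d = gen_design(1, 1)
        p = SynthParams(seed=9, cells_per_drop=3, n_drops=1)
        s1 = gen_spectra(d, params=p)
        s2 = gen_spectra(d, params=p)
        assert np.array_equal(s1.intensities, s2.intensities)
        assert s1.meta.equals(s2.meta)


class TestEnv:
    def test_zero_noise_exact_linear(self, default_design):
        p = SynthParams(seed=0, env_noise_scale=0.0)
        env = gen_env(default_design, p)
        from paoscope.synth import DEFAULT_ENV_COEFS

        w = default_design["warming"].to_numpy(float)
        c = default_design["clipping"].to_numpy(float)
        for var, (b0, bw, bc, _) in DEFAULT_ENV_COEFS.items():
            assert np.allclose(env[var].to_numpy(), b0 + bw * w + bc * c)

    def test_warming_raises_soil_temperature(self, default_design):
        env = gen_env(default_design, SynthParams(seed=1))
        r = np.corrcoef(default_design["warming"], env["soil_T"])[0, 1]
        assert r > 0

    def test_gpp_identity(self, default_design):
        env = gen_env(default_design, SynthParams(seed=2))
        assert np.allclose(env["ER"] - env["NEE"], env["GPP"], atol=1e-9)

    def test_reproducible(self, default_design):
        e1 = gen_env(default_design, SynthParams(seed=4))
        e2 = gen_env(default_design, SynthParams(seed=4))
        pd.testing.assert_frame_equal(e1, e2)
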