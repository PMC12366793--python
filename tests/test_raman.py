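"""Raman preprocessing, biomarker quantification, PAO confirmation, OPUs."""

import numpy as np
import pandas as pd
import pytest

from paoscope.raman import (
    SpectraSet,
    cluster_opus,
    confirm_pao,
    estimate_noise,
    opu_abundance,
    preprocess_set,
    preprocess_spectrum,
    quantify_biomarkers,
)

GRID = np.arange(400.0, 2000.5, 1.0)


def gauss(center, width, amp=1.0):
    return amp * np.exp(-0.5 * ((GRID - center) / width) ** 2)


def spectra_set(mat, meta=None):
    mat = np.atleast_2d(mat)
    meta = meta if meta is not None else pd.DataFrame(
        {"sample_id": ["s0"] * mat.shape[0]},
        index=[f"c{i}" for i in range(mat.shape[0])],
    )
    return SpectraSet(wavenumbers=GRID, intensities=mat, meta=meta)


class TestPreprocess:
    def test_bin_count_267(self):
        centers, binned = preprocess_spectrum(GRID, gauss(900, 10) + 0.1)
        assert len(centers) == 267 == len(binned)

    def test_unit_norm(self):
        _, binned = preprocess_spectrum(GRID, gauss(900, 10) + 0.2)
        assert np.linalg.norm(binned) == pytest.approx(1.0, abs=1e-9)

    def test_flat_zero_spectrum_error(self):
        with pytest.raises(ValueError, match="normalize"):
            preprocess_spectrum(GRID, np.zeros_like(GRID))

    def test_grid_gap_error(self):
        w = np.concatenate([GRID[:100], GRID[120:]])
        y = np.ones_like(w)
        with pytest.raises(ValueError, match="gap"):
            preprocess_spectrum(w, y)

    def test_bin_normalize_idempotent(self):
        """Re-binning + renormalizing an already binned spectrum is exact."""
        c1, b1 = preprocess_spectrum(GRID, gauss(700, 8) + gauss(1500, 12))
        c2, b2 = preprocess_spectrum(c1, b1, baseline=False)
        assert np.allclose(c1, c2)
        assert np.allclose(b1, b2, atol=1e-12)

    def test_full_idempotence_close(self):
        """A second full pass (incl. ALS baseline) changes little."""
        c1, b1 = preprocess_spectrum(GRID, gauss(700, 8) + gauss(1500, 12) + 0.3)
        _, b2 = preprocess_spectrum(c1, b1)
        assert np.max(np.abs(b1 - b2)) < 5e-3

    def test_baseline_recovery_within_2pct(self):
        """Flat offset + Gaussian: the band area survives baseline removal."""
        raw = 0.5 + gauss(900, 8, amp=2.0)
        c, b = preprocess_spectrum(GRID, raw, normalize=False)
        craw, braw = preprocess_spectrum(GRID, gauss(900, 8, amp=2.0),
                                         baseline=False, normalize=False)
        mask = (c > 850) & (c < 950)
        assert np.trapezoid(b[mask], c[mask]) == pytest.approx(
            np.trapezoid(braw[mask], craw[mask]), rel=0.02
        )


class TestBiomarkers:
    def test_isolated_polyp_band(self):
        c, b = preprocess_spectrum(GRID, gauss(695, 4, 2.0), baseline=False)
        levels = quantify_biomarkers(c, b)
        assert levels["polyp"] > 0
        for name, val in levels.items():
            if name != "polyp":
                assert val < 0.01 * levels["polyp"]

    def test_linearity_without_normalization(self):
        y = gauss(695, 4, 1.0)
        c, b1 = preprocess_spectrum(GRID, y, baseline=False, normalize=False)
        _, b2 = preprocess_spectrum(GRID, 2 * y, baseline=False, normalize=False)
        l1 = quantify_biomarkers(c, b1)["polyp"]
        l2 = quantify_biomarkers(c, b2)["polyp"]
        assert l2 == pytest.approx(2 * l1, rel=1e-6)

    def test_band_outside_grid_error(self):
        with pytest.raises(ValueError):
            quantify_biomarkers(GRID, np.ones_like(GRID), bands={"x": [(2100, 2200)]})

    def test_white_noise_null(self):
        """Pure-noise biomarker areas are tiny next to a real band's area."""
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            y = np.abs(rng.normal(0, 0.01, len(GRID)))
            vals.append(quantify_biomarkers(GRID, y)["polyp"])
        signal = quantify_biomarkers(GRID, gauss(695, 4, 1.0))["polyp"]
        assert np.mean(vals) < 0.05 * signal


class TestConfirmPao:
    def test_all_zero_false(self):
        assert not confirm_pao({m: 0.0 for m in ("polyp", "pha", "peptidoglycan", "amide")})

    def test_pha_only_false(self):
        levels = {"polyp": 0.0, "pha": 5.0, "peptidoglycan": 0.0, "amide": 0.0}
        assert not confirm_pao(levels)

    def test_generator_archetype_confirms(self):
        from paoscope.synth import SynthParams, gen_design, gen_spectra

        p = SynthParams(seed=0, cells_per_drop=5, n_drops=1)
        s = gen_spectra(gen_design(1, 1).head(1), params=p)
        y = s.intensities[0]
        thr = 3 * estimate_noise(y) * 12  # 3x noise over a ~12 cm^-1 window
        levels = quantify_biomarkers(s.wavenumbers, y)
        assert confirm_pao(levels, thr)


class TestOpuClustering:
    def test_identical_spectra_single_opu(self):
        mat = np.tile(gauss(900, 10) + 0.1, (5, 1))
        opus = cluster_opus(spectra_set(mat))
        assert opus.labels == ["OPU01"]

    def test_orthogonal_archetypes_two_opus(self):
        a, b = gauss(600, 5), gauss(1500, 5)
        mat = np.vstack([a, a, b, b])
        opus = cluster_opus(spectra_set(mat), cutoff=0.6)
        assert len(opus.labels) == 2
        assert opus.assignments.iloc[0] != opus.assignments.iloc[2]

    def test_rescaling_invariance(self):
        a, b = gauss(600, 5), gauss(1500, 5)
        mat1 = np.vstack([a, b, a + 0.01 * b])
        mat2 = np.vstack([3 * a, 0.5 * b, 7 * (a + 0.01 * b)])
        o1 = cluster_opus(spectra_set(mat1))
        o2 = cluster_opus(spectra_set(mat2))
        assert (o1.assignments.to_numpy() == o2.assignments.to_numpy()).all()

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(1)
        mat = np.vstack(
            [gauss(500 + 120 * k, 8) + 0.02 * rng.random(len(GRID)) for k in range(6)]
            * 3
        )
        sset = spectra_set(mat)
        n_prev = None
        for cutoff in (0.2, 0.4, 0.6, 0.8):
            n = len(cluster_opus(sset, cutoff=cutoff).labels)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_single_spectrum_warns(self):
        with pytest.warns(UserWarning):
            opus = cluster_opus(spectra_set(gauss(900, 5)))
        assert opus.labels == ["OPU01"]

    def test_average_linkage_matches_bruteforce(self):
        """Merge heights equal an O(n^3) average-linkage re-implementation."""
        rng = np.random.default_rng(3)
        mat = np.abs(rng.normal(0.2, 0.1, (8, 40))) + rng.random((8, 1))
        mat /= np.linalg.norm(mat, axis=1, keepdims=True)
        meta = pd.DataFrame({"sample_id": ["s"] * 8}, index=[f"c{i}" for i in range(8)])
        sset = SpectraSet(np.arange(40.0) * 6 + 400, mat, meta)
        opus = cluster_opus(sset)

        # brute force: cosine distances, average linkage by explicit averaging
        def cosd(u, v):
            return 1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))

        d = {frozenset((i, j)): cosd(mat[i], mat[j]) for i in range(8) for j in range(i)}
        clusters = {i: [i] for i in range(8)}
        heights = []
        while len(clusters) > 1:
            pairs = [(a, b) for a in clusters for b in clusters if a < b]
            def avg(a, b):
                return float(
                    np.mean(
                        [d[frozenset((i, j))] for i in clusters[a] for j in clusters[b]]
                    )
                )
            a, b = min(pairs, key=lambda p: avg(*p))
            heights.append(avg(a, b))
            clusters[a] = clusters[a] + clusters.pop(b)
        assert np.allclose(sorted(heights), sorted(opus.merge_heights), atol=1e-12)


class TestOpuAbundance:
    def _opus_and_meta(self):
        a, b = gauss(600, 5), gauss(1500, 5)
        mat = np.vstack([a, a, b, b])
        meta = pd.DataFrame(
            {"sample_id": ["s0", "s0", "s0", "s0"]}, index=[f"c{i}" for i in range(4)]
        )
        sset = spectra_set(mat, meta)
        return cluster_opus(sset), meta

    def test_even_split(self):
        from paoscope.diversity import shannon

        opus, meta = self._opus_and_meta()
        comp = opu_abundance(opus, meta)
        assert np.allclose(np.sort(comp.loc["s0"].to_numpy()), [0.5, 0.5])
        assert shannon(comp.loc["s0"].to_numpy()) == pytest.approx(np.log(2))

    def test_rows_sum_to_one(self):
        opus, meta = self._opus_and_meta()
        comp = opu_abundance(opus, meta)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_single_opu_zero_diversity(self):
        from paoscope.diversity import shannon

        mat = np.tile(gauss(900, 10), (4, 1))
        meta = pd.DataFrame({"sample_id": ["s0"] * 4}, index=[f"c{i}" for i in range(4)])
        opus = cluster_opus(spectra_set(mat, meta))
        comp = opu_abundance(opus, meta)
        assert shannon(comp.loc["s0"].to_numpy()) == pytest.approx(0.0)


class TestRoundTrip:
    def test_spectra_tsv(self, tmp_path):
        mat = np.vstack([gauss(600, 5), gauss(1500, 5)])
        meta = pd.DataFrame(
            {"sample_id": ["s0", "s1"], "treatment": ["UC", "UW"]},
            index=["c0", "c1"],
        )
        sset = spectra_set(mat, meta)
        sp, mp = tmp_path / "spec.tsv", tmp_path / "meta.tsv"
        sset.to_tsv(sp, mp)
        back = SpectraSet.from_tsv(sp, mp)
        assert np.allclose(back.intensities, sset.intensities)
        assert list(back.meta["treatment"]) == ["UC", "UW"]
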