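"""Frequency estimation, filtering, imputation, dominance, LD, PCA, clusters."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import gxeblup as gx
from gxeblup.genomics import AlleleDepths, FilterThresholds, FrequencyMatrix


def _depths(ref, alt, qual=None):
    ref = np.atleast_2d(ref)
    alt = np.atleast_2d(alt)
    meta = {"id": [f"m{k}" for k in range(ref.shape[1])],
            "chrom": [1] * ref.shape[1],
            "pos": np.arange(1, ref.shape[1] + 1)}
    if qual is not None:
        meta["qual"] = qual
    return AlleleDepths(ref=ref, alt=alt,
                        accessions=[f"a{i}" for i in range(ref.shape[0])],
                        markers=pd.DataFrame(meta))


class TestFrequencies:
    @pytest.mark.parametrize("alt,ref,expected", [
        (9, 1, 10.0 / 12.0),     # pseudo-counts: (9+1)/(9+1+2)
        (0, 0, 0.5),             # empty cell falls back to the prior mean
        (7, 7, 0.5),             # symmetry at equal depths
        (3, 3, 0.5),
    ])
    def test_pseudo_count_formula(self, alt, ref, expected):
        d = _depths([[ref]], [[alt]])
        f = gx.estimate_frequencies(d, min_cell_depth=0)
        assert f.p[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_depth_cell_flagged_missing_by_depth_filter(self):
        d = _depths([[0]], [[0]])
        f = gx.estimate_frequencies(d, min_cell_depth=10)
        assert np.isnan(f.p[0, 0])

    def test_shrinkage_toward_half(self):
        """|p - 0.5| <= |raw ratio - 0.5| whenever depth > 0."""
        rng = np.random.default_rng(3)
        ref = rng.integers(1, 60, size=(6, 40))
        alt = rng.integers(1, 60, size=(6, 40))
        f = gx.estimate_frequencies(_depths(ref, alt), min_cell_depth=0)
        raw = alt / (alt + ref)
        assert np.all(np.abs(f.p - 0.5) <= np.abs(raw - 0.5) + 1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _depths([[-1]], [[2]])


class TestFiltering:
    def test_maf_rule_removes_extreme_frequency_marker(self):
        rng = np.random.default_rng(4)
        n, m = 10, 5
        alt = rng.integers(10, 30, size=(n, m))
        ref = rng.integers(10, 30, size=(n, m))
        alt[:, 2] = 97          # one near-fixed marker
        ref[:, 2] = 3
        d = _depths(ref, alt)
        f = gx.estimate_frequencies(d)
        out, report = gx.filter_markers(d, f, FilterThresholds(
            min_mean_dp=0, max_mean_dp=1e9, min_maf=0.05, max_missing=1.1))
        assert out.n_markers == 4
        assert report.set_index("rule").loc["maf", "n_removed"] == 1

    def test_missing_rate_rule(self):
        """Marker missing in 3/10 accessions is removed at the 20% threshold."""
        ref = np.full((10, 2), 20)
        alt = np.full((10, 2), 20)
        ref[:3, 0] = 0
        alt[:3, 0] = 0          # 30% of cells below min depth -> missing
        d = _depths(ref, alt)
        f = gx.estimate_frequencies(d)
        out, report = gx.filter_markers(d, f, FilterThresholds(
            min_mean_dp=0, max_mean_dp=1e9, min_maf=0.0, max_missing=0.20))
        assert list(out.markers["id"]) == ["m1"]

    def test_noop_thresholds_keep_everything(self):
        rng = np.random.default_rng(5)
        d = _depths(rng.integers(10, 40, (8, 12)), rng.integers(10, 40, (8, 12)))
        f = gx.estimate_frequencies(d)
        noop = FilterThresholds(min_dp=0, min_mean_dp=0, max_mean_dp=np.inf,
                                min_qual=0, min_maf=0, max_missing=1.1)
        out, _ = gx.filter_markers(d, f, noop)
        np.testing.assert_array_equal(out.p, f.p)

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(6)
        alt = rng.integers(0, 60, size=(12, 30))
        ref = rng.integers(0, 60, size=(12, 30))
        d = _depths(ref, alt)
        f = gx.estimate_frequencies(d)
        out1, _ = gx.filter_markers(d, f)
        keep = [list(d.markers["id"]).index(i) for i in out1.markers["id"]]
        d2 = AlleleDepths(ref=ref[:, keep], alt=alt[:, keep],
                          accessions=d.accessions,
                          markers=d.markers.iloc[keep].reset_index(drop=True))
        out2, rep2 = gx.filter_markers(d2, out1)
        assert out2.n_markers == out1.n_markers
        assert rep2.loc[rep2.rule != "kept", "n_removed"].sum() == 0

    def test_quality_rule_uses_vcf_qual_when_present(self):
        ref = np.full((5, 3), 25)
        alt = np.full((5, 3), 25)
        d = _depths(ref, alt, qual=[45.0, 12.0, 88.0])
        f = gx.estimate_frequencies(d)
        out, report = gx.filter_markers(d, f, FilterThresholds(
            min_mean_dp=0, max_mean_dp=1e9, min_maf=0, max_missing=1.1))
        assert list(out.markers["id"]) == ["m0", "m2"]

    def test_all_removed_raises(self):
        d = _depths(np.full((4, 2), 2), np.full((4, 2), 1))
        f = gx.estimate_frequencies(d)
        with pytest.raises(ValueError, match="empty panel"):
            gx.filter_markers(d, f)


class TestImputation:
    def test_missing_cell_gets_marker_mean(self):
        p = np.array([[0.2, 0.6], [0.4, 0.6], [np.nan, 0.6]])
        f = FrequencyMatrix(p=p, accessions=list("abc"),
                            markers=pd.DataFrame({"id": ["m1", "m2"]}))
        out = gx.impute_missing(f)
        assert out.p[2, 0] == pytest.approx(0.3)
        assert not out.missing.any()

    def test_identity_when_complete_and_mean_preservation(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, (6, 8))
        miss = rng.random((6, 8)) < 0.2
        pm = np.where(miss, np.nan, p)
        f = FrequencyMatrix(p=pm, accessions=[f"a{i}" for i in range(6)],
                            markers=pd.DataFrame({"id": [f"m{k}" for k in range(8)]}))
        out = gx.impute_missing(f)
        observed_means = np.nanmean(pm, axis=0)
        np.testing.assert_allclose(out.p.mean(axis=0), observed_means, atol=1e-12)
        # observed cells untouched
        np.testing.assert_array_equal(out.p[~miss], pm[~miss])

    def test_fully_missing_marker_raises(self):
        p = np.array([[np.nan, 0.4], [np.nan, 0.5]])
        f = FrequencyMatrix(p=p, accessions=list("ab"),
                            markers=pd.DataFrame({"id": ["m1", "m2"]}))
        with pytest.raises(ValueError, match="fully missing"):
            gx.impute_missing(f)


class TestDominance:
    def test_heterozygosity_formula_and_symmetric_hand_example(self):
        """p=(0.1, 0.5, 0.9): H=(0.18, 0.50, 0.18); OLS slope 0 by symmetry, so
        codes are H minus its mean."""
        p = np.array([[0.1], [0.5], [0.9]])
        f = FrequencyMatrix(p=p, accessions=list("abc"),
                            markers=pd.DataFrame({"id": ["m1"]}))
        codes = gx.dominance_codes(f)
        h = np.array([0.18, 0.50, 0.18])
        np.testing.assert_allclose(codes[:, 0], h - h.mean(), atol=1e-12)

    def test_residual_orthogonality_per_marker(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, (12, 25))
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(12)],
                            markers=pd.DataFrame({"id": [f"m{k}" for k in range(25)]}))
        codes = gx.dominance_codes(f)
        assert np.abs(codes.mean(axis=0)).max() < 1e-10
        pc = p - p.mean(axis=0)
        assert np.abs((codes * pc).sum(axis=0)).max() < 1e-10

    def test_constant_marker_gives_zero_codes_with_warning(self):
        p = np.column_stack([np.full(5, 0.3), np.linspace(0.2, 0.8, 5)])
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(5)],
                            markers=pd.DataFrame({"id": ["m1", "m2"]}))
        with pytest.warns(UserWarning, match="constant"):
            codes = gx.dominance_codes(f)
        np.testing.assert_allclose(codes[:, 0], 0.0, atol=1e-12)

    def test_dominance_kernel_trace_psd_and_decorrelation(self, small_panel):
        freq = small_panel["freq"]
        GD = gx.dominance_kernel(freq)
        GD.validate()
        GA = gx.additive_kernel(freq)
        # naive 2pq kernel without the decorrelating regression
        H = 2.0 * freq.p * (1.0 - freq.p)
        naive = gx.kernel_from_features(H, freq.accessions, center=True)
        off = ~np.eye(GA.n, dtype=bool)
        r_decor = abs(np.corrcoef(GA.values[off], GD.values[off])[0, 1])
        r_naive = abs(np.corrcoef(GA.values[off], naive.values[off])[0, 1])
        assert r_decor < r_naive


class TestLD:
    def test_duplicated_marker_has_r2_one(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, (20, 2))
        p[:, 1] = p[:, 0]
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(20)],
                            markers=pd.DataFrame({"id": ["m1", "m2"],
                                                  "chrom": [1, 1], "pos": [100, 101]}))
        out = gx.ld_decay(f, max_dist=10)
        assert out["pairs"]["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_markers_hit_the_sampling_floor(self):
        """E[r^2] under independence is ~1/(n-1); check within 2 MC SDs."""
        rng = np.random.default_rng(10)
        n, m = 200, 60
        p = rng.uniform(0.2, 0.8, (n, m))
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(n)],
                            markers=pd.DataFrame({"id": [f"m{k}" for k in range(m)],
                                                  "chrom": [1] * m,
                                                  "pos": np.arange(1, m + 1) * 10}))
        out = gx.ld_decay(f, max_dist=1000)
        r2 = out["pairs"]["r2"]
        floor = 1.0 / (n - 1)
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - floor) < 2 * se + 1e-3

    def test_block_correlated_generator_decays_near_its_length_scale(self):
        depths, truth, _ = gx.simulate_population(
            n_accessions=150, n_markers=300, n_subpops=1, divergence=0.0,
            depth_mean=60, seed=20, n_chromosomes=2, chrom_length=3000,
            ld_decay_length=200.0)
        f = FrequencyMatrix(p=truth.p, accessions=truth.accessions,
                            markers=truth.markers)
        out = gx.ld_decay(f, max_dist=1500, bins=np.arange(0, 1501, 100))
        binned = out["binned"].dropna(subset=["mean"])
        crossing = binned.loc[binned["mean"] < 0.2, "dist_mid"]
        assert len(crossing) > 0
        # r^2 = exp(-2d/L) crosses 0.2 at ~0.8 L; allow generous MC slack
        assert 50 <= crossing.iloc[0] <= 450

    def test_zero_variance_pair_skipped(self):
        p = np.column_stack([np.full(8, 0.4), np.linspace(0.2, 0.8, 8)])
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(8)],
                            markers=pd.DataFrame({"id": ["m1", "m2"],
                                                  "chrom": [1, 1], "pos": [1, 5]}))
        out = gx.ld_decay(f, max_dist=100)
        assert out["n_skipped"] == 1
        assert len(out["pairs"]) == 0


class TestPCA:
    def test_variance_fractions_sum_below_one_and_non_increasing(self, small_panel):
        scores, vf = gx.principal_components(small_panel["freq"], k=5)
        assert vf.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(vf) <= 1e-12)

    def test_reconstruction_error_decreases_in_k(self, small_panel):
        X = small_panel["freq"].centered()
        errs = []
        for k in (1, 3, 6):
            scores, _ = gx.principal_components(small_panel["freq"], k=k)
            # project X onto the score space and measure the residual
            S = scores.to_numpy()
            proj = S @ np.linalg.lstsq(S, X, rcond=None)[0]
            errs.append(np.linalg.norm(X - proj))
        assert errs[0] > errs[1] > errs[2]

    def test_pc1_separates_strong_subpopulations(self):
        depths, truth, subpop = gx.simulate_population(
            n_accessions=60, n_markers=500, n_subpops=2, divergence=0.35,
            depth_mean=60, seed=21)
        f = gx.impute_missing(gx.filter_markers(
            depths, gx.estimate_frequencies(depths))[0])
        scores, _ = gx.principal_components(f, k=2)
        r = np.corrcoef(scores["PC1"], (subpop == 1).astype(float))[0, 1]
        assert abs(r) > 0.9

    def test_k_above_rank_raises(self, small_panel):
        with pytest.raises(ValueError, match="rank|exceeds"):
            gx.principal_components(small_panel["freq"], k=31)


class TestClusters:
    def test_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(0.1, 0.9, (8, 30))
        f = FrequencyMatrix(p=p, accessions=[f"a{i}" for i in range(8)],
                            markers=pd.DataFrame({"id": [f"m{k}" for k in range(30)]}))
        cl = gx.genetic_clusters(f, k=8)
        assert cl.value_counts().max() == 1

    def test_permutation_invariance_up_to_relabeling(self, small_panel):
        f = small_panel["freq"]
        cl = gx.genetic_clusters(f, k=4)
        rng = np.random.default_rng(23)
        perm = rng.permutation(f.n_accessions)
        f2 = FrequencyMatrix(p=f.p[perm], accessions=[f.accessions[i] for i in perm],
                             markers=f.markers)
        cl2 = gx.genetic_clusters(f2, k=4)
        aligned = cl2.reindex(cl.index)
        assert adjusted_rand_score(cl.to_numpy(), aligned.to_numpy()) == pytest.approx(1.0)

    def test_recovers_strong_subpopulations(self):
        depths, truth, subpop = gx.simulate_population(
            n_accessions=66, n_markers=500, n_subpops=3, divergence=0.35,
            depth_mean=60, seed=24)
        f = gx.impute_missing(gx.filter_markers(
            depths, gx.estimate_frequencies(depths))[0])
        cl = gx.genetic_clusters(f, k=3)
        assert adjusted_rand_score(subpop, cl.to_numpy()) >= 0.9

    def test_k_below_two_rejected(self, small_panel):
        with pytest.raises(ValueError):
            gx.genetic_clusters(small_panel["freq"], k=1)
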