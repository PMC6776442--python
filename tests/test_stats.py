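"""Enrichment statistics: normalization, fold estimator, triplet
consistency with shuffle null, NB likelihood-ratio test, thinning power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pesca.errors import ValidationError
from pesca.quant import aggregate_gre, count_umis
from pesca.simulate import ScreenTruth, simulate_screen
from pesca.stats import (
    EnrichmentConfig,
    barcode_consistency,
    expression_enrichment,
    nb_lrt_test,
    normalize_expression,
    screen_folds,
    shuffle_null,
    subsample_power,
)


class TestNormalizeExpression:
    def test_zero_count_maps_to_zero(self):
        X = np.array([[0, 3], [2, 0]])
        out, kept = normalize_expression(X, 10_000)
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0
        assert kept.all()

    def test_matches_formula_elementwise(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(20, 8)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1  # avoid zero-total rows here
        out, kept = normalize_expression(X, 10_000)
        totals = X.sum(axis=1, keepdims=True)
        expected = np.log1p(X / totals * 10_000)
        assert np.allclose(out, expected)

    def test_monotone_within_cell(self):
        X = np.array([[0, 1, 2, 5, 9]], dtype=float)
        out, _ = normalize_expression(X, 10_000)
        assert (np.diff(out[0]) > 0).all()

    def test_zero_total_cells_flagged(self):
        X = np.array([[0, 0], [1, 2]])
        out, kept = normalize_expression(X)
        assert not kept[0] and kept[1]
        assert (out[0] == 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(np.array([[-1, 2]]))


class TestExpressionEnrichment:
    def test_identical_means_give_one(self):
        X = np.array([[2.0], [2.0], [2.0], [2.0]])
        labels = pd.Series(["Sst", "Sst", "Exc", "Exc"])
        fold = expression_enrichment(X, labels, "Sst", 0.01)
        assert fold.iloc[0] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # (0.09 + 0.01) / (0 + 0.01) = 10
        X = np.array([[0.09], [0.09], [0.0], [0.0]])
        labels = pd.Series(["Sst", "Sst", "Exc", "Exc"])
        fold = expression_enrichment(X, labels, "Sst", 0.01)
        assert fold.iloc[0] == pytest.approx(10.0)

    def test_missing_target_rejected(self):
        X = np.zeros((2, 1))
        with pytest.raises(ValidationError):
            expression_enrichment(X, pd.Series(["a", "b"]), "Sst")

    def test_fold_recovery_at_screen_depth(self, full_bset, full_gre_map):
        """A GRE simulated with 8.3-fold true target enrichment is
        recovered within 15% by the pseudocounted estimator (mean over 10
        seeds at 10,000 cells)."""
        truth = ScreenTruth(true_fold={"GRE012": 8.3})
        folds = []
        for seed in range(1, 11):
            scr = simulate_screen(
                truth, 10_000, seed=seed,
                barcode_set=full_bset, gre_map=full_gre_map,
            )
            mat, _ = count_umis(
                scr.reads, scr.barcode_set,
                cell_whitelist=scr.labels["cell_barcode"].tolist(),
            )
            _, gre_folds = screen_folds(
                mat, scr.labels, scr.gre_map, "Sst", EnrichmentConfig()
            )
            folds.append(gre_folds["GRE012"])
        assert np.mean(folds) == pytest.approx(8.3, rel=0.15)


class TestBarcodeConsistency:
    def _map(self, n=30):
        from pesca.barcodes import GreBarcodeMap, design_barcodes, assign_barcodes

        bset = design_barcodes(8, 3, n * 3, seed=2)
        return assign_barcodes([f"G{i}" for i in range(n)], bset, 3, seed=2)

    def test_identical_slot_vectors_r_one(self):
        gmap = self._map(10)
        vals = {}
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        for gi, (g, seqs) in enumerate(gmap.entries.items()):
            for bc in seqs:
                vals[bc] = base[gi]
        out = barcode_consistency(pd.Series(vals), gmap)
        assert np.allclose(out["r"], 1.0)

    def test_negated_vector_r_minus_one(self):
        gmap = self._map(10)
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        vals = {}
        for gi, (g, seqs) in enumerate(gmap.entries.items()):
            vals[seqs[0]] = base[gi]
            vals[seqs[1]] = -base[gi]
            vals[seqs[2]] = base[gi]
        out = barcode_consistency(pd.Series(vals), gmap)
        r01 = out.loc[(out.slot_i == 0) & (out.slot_j == 1), "r"].iloc[0]
        assert r01 == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        gmap = self._map(30)
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(30, 3))
        vals = {}
        for gi, (g, seqs) in enumerate(gmap.entries.items()):
            for si, bc in enumerate(seqs):
                vals[bc] = mat[gi, si]
        out = barcode_consistency(pd.Series(vals), gmap)
        for _, row in out.iterrows():
            x, y = mat[:, int(row.slot_i)], mat[:, int(row.slot_j)]
            r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum())
                * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert row.r == pytest.approx(r_oracle)

    def test_zero_variance_reported_as_nan(self):
        gmap = self._map(5)
        vals = {}
        rng = np.random.default_rng(4)
        for g, seqs in gmap.entries.items():
            vals[seqs[0]] = 1.0  # constant slot
            vals[seqs[1]] = rng.normal()
            vals[seqs[2]] = rng.normal()
        out = barcode_consistency(pd.Series(vals), gmap)
        assert out.loc[(out.slot_i == 0) & (out.slot_j == 1), "r"].isna().all()


@pytest.fixture(scope="module")
def correlated_screen():
    folds = {f"GRE{i:03d}": f for i, f in zip(range(2, 42, 5), range(2, 10))}
    truth = ScreenTruth(n_gres=50, true_fold=folds, seed=6)
    scr = simulate_screen(truth, 1500, seed=6)
    mat, _ = count_umis(
        scr.reads, scr.barcode_set,
        cell_whitelist=scr.labels["cell_barcode"].tolist(),
    )
    bc_folds, _ = screen_folds(mat, scr.labels, scr.gre_map, "Sst")
    return np.log2(bc_folds), scr.gre_map


class TestShuffleNull:
    def test_null_mean_near_zero(self, correlated_screen):
        vals, gmap = correlated_screen
        res = shuffle_null(vals, gmap, n_shuffles=1000, seed=0)
        assert abs(res.mean) < 0.02

    def test_observed_exceeds_null_99th_percentile(self, correlated_screen):
        vals, gmap = correlated_screen
        res = shuffle_null(vals, gmap, n_shuffles=1000, seed=1)
        assert res.observed > np.quantile(res.null_means, 0.99)

    def test_null_sd_matches_independence_scale(self, correlated_screen):
        """Under exchangeability the sd of the mean pairwise r is on the
        1/sqrt(n_GREs - 1) scale (the three pairwise r's are nearly
        uncorrelated, so somewhat below it)."""
        vals, gmap = correlated_screen
        res = shuffle_null(vals, gmap, n_shuffles=1000, seed=2)
        scale = 1.0 / np.sqrt(len(gmap.gre_ids) - 1)
        assert 0.3 * scale < res.sd < 1.5 * scale

    def test_seeded_determinism(self, correlated_screen):
        vals, gmap = correlated_screen
        a = shuffle_null(vals, gmap, n_shuffles=50, seed=3)
        b = shuffle_null(vals, gmap, n_shuffles=50, seed=3)
        assert np.array_equal(a.null_means, b.null_means)


def _nb_loglik_oracle(y, mu, alpha):
    r = 1.0 / alpha
    return sps.nbinom.logpmf(y, r, r / (r + mu)).sum()


def _lrt_oracle(y_target, y_rest):
    """Independent NB LRT by grid likelihood maximization.

    For NB2 with group-saturated means the ML mean estimates are the group
    sample means for any alpha, so profiling reduces to a 1-d grid over
    alpha per model.
    """
    y_t = np.asarray(y_target, float)
    y_r = np.asarray(y_rest, float)
    y_all = np.concatenate([y_t, y_r])
    alphas = np.logspace(-8, 3, 6000)
    mu_t = max(y_t.mean(), 1e-10)
    mu_r = max(y_r.mean(), 1e-10)
    mu_0 = max(y_all.mean(), 1e-10)
    ll_full = max(
        _nb_loglik_oracle(y_t, mu_t, a) + _nb_loglik_oracle(y_r, mu_r, a)
        for a in alphas
    )
    ll_red = max(_nb_loglik_oracle(y_all, mu_0, a) for a in alphas)
    return 2.0 * (ll_full - ll_red)


class TestNbLrt:
    def _run_single(self, y_target, y_rest):
        y = np.array(y_target + y_rest).reshape(-1, 1)
        labels = pd.Series(["Sst"] * len(y_target) + ["Exc"] * len(y_rest))
        cfg = EnrichmentConfig(size_factors="none")
        return nb_lrt_test(y, labels, "Sst", cfg, feature_names=["f"])

    def test_tiny_counts_match_grid_oracle(self):
        """LRT statistic equals an independent direct NB likelihood
        maximization by grid search."""
        table = self._run_single([3, 4, 5], [0, 1, 0])
        oracle = _lrt_oracle([3, 4, 5], [0, 1, 0])
        assert table.loc["f", "lrt_stat"] == pytest.approx(oracle, abs=5e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y_t = rng.negative_binomial(2, 0.3, size=15).tolist()
        y_r = rng.negative_binomial(2, 0.6, size=25).tolist()
        if sum(y_t) + sum(y_r) == 0:
            y_t[0] = 1
        table = self._run_single(y_t, y_r)
        oracle = _lrt_oracle(y_t, y_r)
        assert table.loc["f", "lrt_stat"] == pytest.approx(oracle, abs=2e-2, rel=1e-3)

    def test_matches_statsmodels_loglik(self):
        """Cross-check: maximized likelihoods agree with statsmodels'
        NegativeBinomial ML fit on a moderate instance."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        y = rng.negative_binomial(3, 0.4, size=200)
        group = (np.arange(200) < 40).astype(float)
        table = self._run_single(list(y[:40]), list(y[40:]))
        X_full = sm.add_constant(group)
        llf_full = sm.NegativeBinomial(y, X_full).fit(disp=0).llf
        llf_red = sm.NegativeBinomial(y, np.ones((200, 1))).fit(disp=0).llf
        assert table.loc["f", "lrt_stat"] == pytest.approx(
            2 * (llf_full - llf_red), abs=2e-2
        )

    def test_all_zero_feature_p_one(self):
        table = self._run_single([0, 0, 0], [0, 0, 0, 0])
        assert table.loc["f", "p"] == 1.0

    def test_non_integer_counts_rejected(self):
        X = np.array([[0.5], [1.2]])
        with pytest.raises(ValidationError):
            nb_lrt_test(X, pd.Series(["Sst", "Exc"]), "Sst")

    def test_bh_invariants(self, small_screen):
        mat, _ = count_umis(
            small_screen.reads, small_screen.barcode_set,
            cell_whitelist=small_screen.labels["cell_barcode"].tolist(),
        )
        gre = aggregate_gre(mat, small_screen.gre_map)
        table = nb_lrt_test(gre, small_screen.labels, "Sst")
        t = table.dropna(subset=["p"]).sort_values("p")
        assert (t["q"] >= t["p"] - 1e-12).all()
        assert (np.diff(t["q"].to_numpy()) >= -1e-12).all()

    def test_planted_hit_detected(self, small_screen):
        mat, _ = count_umis(
            small_screen.reads, small_screen.barcode_set,
            cell_whitelist=small_screen.labels["cell_barcode"].tolist(),
        )
        gre = aggregate_gre(mat, small_screen.gre_map)
        table = nb_lrt_test(gre, small_screen.labels, "Sst")
        assert table.loc["GRE003", "q"] < 0.01
        assert table.loc["GRE003", "fold"] > 1

    def test_type_i_error_under_permuted_labels(self, full_bset, full_gre_map):
        """Under randomly permuted labels the NB-LRT p-values are
        approximately uniform: pooled fraction p < 0.05 within
        [0.03, 0.07] over 5 permutations x 287 features."""
        truth = ScreenTruth()  # all folds 1: global null
        scr = simulate_screen(
            truth, 3000, seed=40, barcode_set=full_bset, gre_map=full_gre_map
        )
        mat, _ = count_umis(
            scr.reads, scr.barcode_set,
            cell_whitelist=scr.labels["cell_barcode"].tolist(),
        )
        gre = aggregate_gre(mat, scr.gre_map)
        rng = np.random.default_rng(41)
        fractions = []
        for _ in range(5):
            permuted = scr.labels.copy()
            permuted["cell_type"] = rng.permutation(
                permuted["cell_type"].to_numpy()
            )
            table = nb_lrt_test(gre, permuted, "Sst")
            p = table["p"].dropna()
            fractions.append((p < 0.05).mean())
        assert 0.03 <= np.mean(fractions) <= 0.07


class TestSubsamplePower:
    def test_probability_one_is_identity(self, small_screen):
        mat, _ = count_umis(
            small_screen.reads, small_screen.barcode_set,
            cell_whitelist=small_screen.labels["cell_barcode"].tolist(),
        )
        gre = aggregate_gre(mat, small_screen.gre_map)
        report = subsample_power(
            gre, small_screen.labels, "Sst",
            probabilities=[1.0], replicates=1, seed=0,
        )
        direct = nb_lrt_test(gre, small_screen.labels, "Sst")
        merged = report.set_index("feature")["q"]
        for feat in direct.index:
            assert merged[feat] == pytest.approx(direct.loc[feat, "q"], rel=1e-9)

    def test_invalid_probability_rejected(self, small_screen):
        mat, _ = count_umis(small_screen.reads, small_screen.barcode_set)
        with pytest.raises(ValidationError):
            subsample_power(mat, small_screen.labels, "Sst", probabilities=[0.0])

    def test_detection_rate_non_increasing_with_thinning(self, small_screen):
        """Mean detection of a true hit does not increase as counts are
        thinned more aggressively."""
        mat, _ = count_umis(
            small_screen.reads, small_screen.barcode_set,
            cell_whitelist=small_screen.labels["cell_barcode"].tolist(),
        )
        gre = aggregate_gre(mat, small_screen.gre_map)
        # focus on the planted hit plus two null features
        import scipy.sparse as sp
        from pesca.quant import CellByFeatureMatrix

        from pesca.stats import compute_size_factors

        keep = ["GRE003", "GRE001", "GRE002"]
        idx = [gre.features.index(f) for f in keep]
        sub = CellByFeatureMatrix(
            cells=gre.cells, features=keep, counts=gre.counts[:, idx]
        )
        sf = compute_size_factors(gre.to_dense(), "total")
        report = subsample_power(
            sub, small_screen.labels, "Sst",
            probabilities=[1.0, 0.5, 0.25, 0.125, 0.0625],
            replicates=10, seed=7, size_factors_values=sf,
        )
        hit = report[report.feature == "GRE003"]
        rates = hit.groupby("probability")["detected"].mean()
        rates = rates.sort_index(ascending=False)  # heavier thinning rightward
        assert (np.diff(rates.to_numpy()) <= 1e-12).all()
        assert rates.iloc[0] >= rates.iloc[-1]
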