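import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lpsmono import model, qc, simulate
from lpsmono.errors import ConfigurationError, DataError, ModelError

from conftest import brute_force_bh, clean_spot, scan_from_spots

THRESH = qc.QCThresholds()


def scan_with_nets(nets, dye_of_post_sample="ch2", **scan_kwargs):
    """Array whose spots have the given (net_pre_ch1, net_post_ch2) pairs."""
    rows = []
    for i, (net1, net2) in enumerate(nets):
        rows.append(clean_spot(
            row=i + 1, spot_id=f"SP{i + 1}", gene_id=f"G{i + 1}",
            f1_median=net1 + 50.0, f1_mean=(net1 + 50.0) * 1.01,
            f1_sd=(net1 + 50.0) / 10,
            f2_median=net2 + 50.0, f2_mean=(net2 + 50.0) * 1.01,
            f2_sd=(net2 + 50.0) / 10))
    return scan_from_spots(pd.DataFrame(rows),
                           dye_of_post_sample=dye_of_post_sample, **scan_kwargs)


def build(arrays, annotation=None):
    if annotation is None:
        ids = sorted({s for a in arrays for s in a.spots["spot_id"]})
        annotation = pd.DataFrame({"spot_id": ids,
                                   "gene_id": [i.replace("SP", "G") for i in ids]})
    tables = qc.run_spot_qc(arrays, THRESH)
    return model.build_ratio_matrix(arrays, tables, annotation)


class TestBuildRatioMatrix:
    def test_equal_nets_give_zero_ratio(self):
        matrix = build([scan_with_nets([(300.0, 300.0)])])
        assert matrix.M[0, 0] == pytest.approx(0.0)

    def test_fourfold_net_gives_two(self):
        matrix = build([scan_with_nets([(100.0, 400.0)])])
        assert matrix.M[0, 0] == pytest.approx(2.0)

    def test_dye_swap_orientation_invariance(self):
        """The same physical sample pair yields the same oriented M when
        the dyes are swapped (channels exchanged, orientation flipped)."""
        fwd = scan_with_nets([(100.0, 400.0), (500.0, 250.0)])
        swapped = scan_with_nets([(400.0, 100.0), (250.0, 500.0)],
                                 dye_of_post_sample="ch1")
        np.testing.assert_allclose(build([fwd]).M, build([swapped]).M)

    def test_nonpositive_net_invalidates_cell(self):
        matrix = build([scan_with_nets([(30.0, -10.0)])])
        assert not matrix.valid_mask[0, 0]
        assert np.isnan(matrix.M[0, 0])

    def test_duplicate_spots_averaged(self):
        scan = scan_with_nets([(100.0, 400.0), (100.0, 100.0)])
        annotation = pd.DataFrame({"spot_id": ["SP1", "SP2"],
                                   "gene_id": ["G1", "G1"]})
        matrix = build([scan], annotation)
        assert matrix.M[0, 0] == pytest.approx(1.0)  # mean of 2 and 0
        assert matrix.spot_count[0, 0] == 2

    def test_unannotated_spot_dropped_with_warning(self, caplog):
        scan = scan_with_nets([(100.0, 400.0), (100.0, 200.0)])
        annotation = pd.DataFrame({"spot_id": ["SP1"], "gene_id": ["G1"]})
        with caplog.at_level("WARNING"):
            matrix = build([scan], annotation)
        assert matrix.shape == (1, 1)
        assert any("without annotation" in r.message for r in caplog.records)

    def test_mixed_arms_rejected(self):
        a = scan_with_nets([(100.0, 400.0)])
        b = scan_with_nets([(100.0, 400.0)], arm="saline", array_id="A2")
        with pytest.raises(DataError, match="mix"):
            build([a, b])

    def test_hopeless_array_rejected(self):
        scan = scan_with_nets([(100.0, 400.0)])
        scan.spots["flag"] = -100
        with pytest.raises(DataError, match="rejected"):
            build([scan])


class TestNormalize:
    def _matrix(self, M, A=None):
        M = np.asarray(M, dtype=float)
        A = np.full_like(M, 10.0) if A is None else np.asarray(A, dtype=float)
        valid = np.isfinite(M)
        return model.RatioMatrix(
            gene_ids=np.array([f"G{i}" for i in range(M.shape[0])]),
            array_ids=np.array([f"A{j}" for j in range(M.shape[1])]),
            M=M, A=A, valid_mask=valid, spot_count=valid.astype(int))

    def test_median_centering_is_idempotent(self):
        M = np.array([[-1.0], [0.0], [1.0]])
        out = model.normalize(self._matrix(M), "median")
        np.testing.assert_allclose(out.M, M)

    def test_constant_offset_removed_exactly(self):
        M = np.array([[-1.0], [0.0], [1.0]])
        out = model.normalize(self._matrix(M + 0.3), "median")
        np.testing.assert_allclose(out.M, M)

    def test_loess_removes_intensity_trend(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(8, 14, size=(400, 1))
        M = 0.15 * (A - 11.0) + rng.normal(0, 0.05, size=A.shape)
        out = model.normalize(self._matrix(M, A), "loess")
        slope = np.polyfit(A[:, 0], out.M[:, 0], 1)[0]
        assert abs(slope) < 0.02

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError, match="method"):
            model.normalize(self._matrix(np.zeros((3, 1))), "quantile")


class TestFitGene:
    def test_zero_noise_recovers_mean_exactly(self):
        mu, se, df, sigma, u = model.fit_gene(np.array([1.0, 1.0, 1.0, 1.0]))
        assert mu == pytest.approx(1.0)
        assert se == pytest.approx(0.0)
        assert df == 3

    def test_symmetric_values_give_zero(self):
        mu, *_ = model.fit_gene(np.array([-0.7, 0.7, -0.7, 0.7]))
        assert mu == pytest.approx(0.0)

    def test_too_few_arrays_untestable(self):
        assert np.isnan(model.fit_gene(np.array([1.0, 2.0]))[0])

    def test_replicate_fit_matches_mixedlm(self):
        """Balanced REML fit agrees with statsmodels MixedLM on the same
        random-intercept model."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        reps = [rng.normal(1.2 + rng.normal(0, 0.3), 0.25, size=2)
                for _ in range(8)]
        mu, se, df, *_ = model.fit_gene(None, spot_replicates=reps)
        frame = pd.DataFrame({
            "y": np.concatenate(reps),
            "array": np.repeat(np.arange(8), 2)})
        fit = smf.mixedlm("y ~ 1", frame, groups=frame["array"]).fit(reml=True)
        assert mu == pytest.approx(fit.params["Intercept"], abs=1e-6)
        assert se == pytest.approx(fit.bse["Intercept"], rel=0.05)

    def test_unbalanced_replicate_fit_matches_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(8)
        sizes = [1, 2, 3, 2, 4, 1, 2]
        reps = [rng.normal(0.8 + rng.normal(0, 0.3), 0.25, size=s)
                for s in sizes]
        mu, se, *_ = model.fit_gene(None, spot_replicates=reps)
        frame = pd.DataFrame({
            "y": np.concatenate(reps),
            "array": np.repeat(np.arange(len(sizes)), sizes)})
        fit = smf.mixedlm("y ~ 1", frame, groups=frame["array"]).fit(reml=True)
        assert mu == pytest.approx(fit.params["Intercept"], abs=0.01)
        assert se == pytest.approx(fit.bse["Intercept"], rel=0.1)

    def test_monte_carlo_unbiasedness(self):
        """mu_hat is unbiased for the simulated truth (mu=1.2, tau=0.2,
        sigma=0.3, 10 arrays x 2 spots, 500 replicates)."""
        rng = np.random.default_rng(99)
        mu_true, tau, sigma, a, r, n_rep = 1.2, 0.2, 0.3, 10, 2, 500
        estimates = []
        for _ in range(n_rep):
            u = rng.normal(0, tau, a)
            y = mu_true + np.repeat(u, r) + rng.normal(0, sigma, a * r)
            reps = y.reshape(a, r)
            estimates.append(model.fit_gene(None, spot_replicates=list(reps))[0])
        se_mean = np.sqrt(tau ** 2 / a + sigma ** 2 / (a * r)) / np.sqrt(n_rep)
        assert np.mean(estimates) == pytest.approx(mu_true, abs=3 * se_mean)


class TestModeration:
    def _fits(self, mu, sigma, n=10):
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        return pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(len(mu))],
            "n_valid": n, "mu_hat": mu, "se": sigma / np.sqrt(n),
            "df": float(n - 1), "sigma": sigma,
            "unscaled_sd": 1 / np.sqrt(n)})

    def test_null_point_gene(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0, 0.1, 50)
        mu[0] = 0.0
        res = model.moderate_and_test(self._fits(mu, np.full(50, 0.3)))
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert res.loc[0, "posterior_prob"] < 0.5

    def test_extreme_statistic_limits(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 0.05, 100)
        mu[0] = 8.0  # enormous effect with tiny variance
        sigma = np.full(100, 0.2)
        sigma[0] = 0.01
        res = model.moderate_and_test(self._fits(mu, sigma))
        assert res.loc[0, "p_value"] < 1e-8
        assert res.loc[0, "posterior_prob"] > 0.99

    def test_null_simulation_type_i_error(self):
        """With no spiked genes the moderated test is calibrated:
        the fraction of p-values below 0.05 stays near 0.05."""
        cfg = simulate.SimulationConfig(frac_de=0.0, n_arrays_control=0, seed=1)
        arrays, _, _ = simulate.generate_experiment(cfg)
        tables = qc.run_spot_qc(arrays, THRESH)
        matrix = model.normalize(
            model.build_ratio_matrix(arrays, tables, simulate.make_annotation(cfg)))
        res = model.analyze(matrix)
        frac = (res["p_value"].dropna() < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_too_few_testable_genes_rejected(self):
        fits = self._fits(np.zeros(5), np.full(5, 0.3))
        with pytest.raises(ModelError, match="min_testable"):
            model.moderate_and_test(fits)

    def test_degenerate_zero_variance_floored_not_infinite(self):
        mu = np.concatenate([[0.5], np.random.default_rng(3).normal(0, 0.1, 40)])
        sigma = np.concatenate([[0.0], np.full(40, 0.3)])
        res = model.moderate_and_test(self._fits(mu, sigma))
        assert np.isfinite(res.loc[0, "t_mod"])


class TestBHFdr:
    def test_single_p_identity(self):
        assert model.bh_fdr([0.001])[0] == pytest.approx(0.001)

    def test_equal_spacing_collapses(self):
        np.testing.assert_allclose(model.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(model.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            model.bh_fdr([0.5, 1.5])

    def test_ties_share_q(self):
        q = model.bh_fdr([0.02, 0.02, 0.9])
        assert q[0] == q[1]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=1, max_value=200))
    def test_matches_brute_force_oracle(self, seed, length):
        p = np.random.default_rng(seed).uniform(0, 1, length).round(3)
        np.testing.assert_allclose(model.bh_fdr(p), brute_force_bh(p),
                                   atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(4).uniform(0, 1, 500)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(model.bh_fdr(p), expected, atol=1e-12)

    def test_q_monotone_in_p_rank(self):
        p = np.random.default_rng(5).uniform(0, 1, 300)
        q = model.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestConsistency:
    def test_fraction_counts_fold_in_called_direction(self):
        M = np.array([[1.5, 1.2, 0.5, -0.3, 1.1]])
        valid = np.ones_like(M, dtype=bool)
        matrix = model.RatioMatrix(
            gene_ids=np.array(["G1"]), array_ids=np.array(list("abcde")),
            M=M, A=np.full_like(M, 10.0), valid_mask=valid,
            spot_count=valid.astype(int))
        res = pd.DataFrame({"direction": ["up"]})
        frac = model.consistency_fractions(matrix, res, fold=2.0)
        assert frac[0] == pytest.approx(3 / 5)
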