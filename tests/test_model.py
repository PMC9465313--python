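import numpy as np
import pytest

import splicedelay as sd
from oracles import double_cv_oracle, lasso_qp_oracle, loocv_oracle
from splicedelay.timecourse import Series, TimeGrid
from conftest import make_linear_gene


def random_instance(seed, n=5, p=3, scale=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p)) * scale + rng.uniform(1, 5)
    y = rng.normal(size=n) * scale
    return X, y


class TestLassoSolve:
    def test_full_shrinkage_at_lambda_max(self):
        X, y = random_instance(1)
        lmax = sd.lambda_max(X, y)
        beta, b0 = sd.lasso_solve(X, y, lmax * 1.0001)
        assert np.all(beta == 0.0)
        assert b0 == pytest.approx(y.mean())

    def test_exact_recovery_orthogonal(self):
        # y = 2 * transcript 1 with orthogonal predictors, lam = 0
        X = np.array(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]]
        )
        y = 2.0 * X[:, 0]
        beta, b0 = sd.lasso_solve(X, y, 0.0)
        assert beta == pytest.approx([2.0, 0.0], abs=1e-10)
        assert b0 == pytest.approx(0.0, abs=1e-10)

    def test_matches_qp_oracle_fixed_instance(self):
        X, y = random_instance(42, n=5, p=3)
        beta, b0 = sd.lasso_solve(X, y, 0.1)
        beta_o, b0_o = lasso_qp_oracle(X, y, 0.1)
        assert beta == pytest.approx(beta_o, abs=1e-6)
        assert b0 == pytest.approx(b0_o, abs=1e-6)

    def test_subgradient_optimality(self):
        X, y = random_instance(7, n=6, p=4)
        lam = 0.5
        beta, _ = sd.lasso_solve(X, y, lam)
        N = len(y)
        mx, sdx = X.mean(0), X.std(0)
        Xs = (X - mx) / sdx
        yc = y - y.mean()
        bs = beta * sdx
        grad = 2.0 / N * (Xs.T @ (yc - Xs @ bs))
        for j in range(4):
            if bs[j] != 0:
                assert abs(grad[j] - lam * np.sign(bs[j])) < 1e-8
            else:
                assert abs(grad[j]) <= lam + 1e-8

    def test_constant_y_gives_zero_beta(self):
        X, _ = random_instance(3)
        beta, b0 = sd.lasso_solve(X, np.full(5, 7.0), 0.1)
        assert np.all(beta == 0.0)
        assert b0 == 7.0

    def test_nan_rejected(self):
        X, y = random_instance(2)
        y[0] = np.nan
        with pytest.raises(ValueError):
            sd.lasso_solve(X, y, 0.1)

    def test_scale_behaviour(self):
        # multiplying y by c multiplies the solution of the c-scaled penalty
        X, y = random_instance(9)
        c = 3.7
        lam = 0.2
        b1, i1 = sd.lasso_solve(X, y, lam)
        b2, i2 = sd.lasso_solve(X, c * y, c * lam)
        assert b2 == pytest.approx(c * b1, rel=1e-8, abs=1e-10)
        assert i2 == pytest.approx(c * i1, rel=1e-8, abs=1e-10)


class TestLambdaPath:
    def test_zero_at_top_of_path(self):
        X, y = random_instance(5)
        lams = sd.lambda_path(X, y, 10)
        beta, _ = sd.lasso_solve(X, y, lams[-1])
        assert np.all(beta == 0.0)

    def test_closed_form_single_predictor(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        xs = (x - x.mean()) / x.std()
        expected = 2.0 * abs(np.mean(xs * (y - y.mean())))
        assert sd.lambda_max(x[:, None], y) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing(self):
        X, y = random_instance(6)
        lams = sd.lambda_path(X, y, 25)
        assert np.all(np.diff(lams) > 0)

    def test_zero_variance_design(self):
        X = np.ones((5, 2))
        y = np.arange(5.0)
        assert np.array_equal(sd.lambda_path(X, y, 10), [0.0])


class TestDelayedDesign:
    def setup_method(self):
        self.gene, self.protein, self.beta = make_linear_gene(seed=11)

    def test_zero_delay_equals_aligned(self):
        _, y0 = sd.delayed_design(self.gene, self.protein, 0.0)
        assert y0 == pytest.approx(self.protein.y.values)

    def test_paper_example_targets(self):
        # tau = 0.5 with grid [0,1,2,6,24]: targets interpolated at
        # [0.5, 1.5, 2.5, 6.5, 24.5], the last clamped to the 24 h value
        grid = TimeGrid([0.0, 1.0, 2.0, 6.0, 24.0])
        X = np.arange(5.0)[None, :] + 1.0
        gene = sd.TimeSeriesGene("G", ("G.t1",), X, grid)
        y = np.array([0.0, 10.0, 20.0, 60.0, 240.0])
        protein = sd.ProteinSeries("P", "G", Series(y, grid))
        _, y_shift = sd.delayed_design(gene, protein, 0.5)
        expected = np.interp([0.5, 1.5, 2.5, 6.5, 24.5], grid.times, y)
        assert y_shift == pytest.approx(expected)
        assert y_shift[-1] == 240.0  # clamped

    def test_interpolation_oracle_inside_segment(self):
        tau = 0.7
        t = self.gene.grid.times
        py = self.protein.y
        expected = np.interp(t + tau, py.grid.times, py.values)
        _, y_shift = sd.delayed_design(self.gene, self.protein, tau)
        assert y_shift == pytest.approx(expected, abs=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            sd.delayed_design(self.gene, self.protein, -1.0)


class TestLoocvMse:
    def test_noiseless_single_transcript(self):
        grid = TimeGrid([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        gene = sd.TimeSeriesGene("G", ("G.t1",), x[None, :], grid)
        protein = sd.ProteinSeries("P", "G", Series(3.0 * x, grid))
        assert sd.loocv_mse(gene, protein, 0.0, 1e-9) == pytest.approx(0.0, abs=1e-10)

    def test_matches_nested_loop_oracle(self):
        gene, protein, _ = make_linear_gene(seed=21)
        X_t, y_shift = sd.delayed_design(gene, protein, 1.5)
        for lam in (0.05, 0.7, 4.0):
            assert sd.loocv_mse(gene, protein, 1.5, lam) == pytest.approx(
                loocv_oracle(X_t, y_shift, lam), abs=1e-9
            )

    def test_null_model_at_lambda_max(self):
        gene, protein, _ = make_linear_gene(seed=31)
        X_t, y = sd.delayed_design(gene, protein, 0.0)
        big = 10 * sd.lambda_max(X_t, y)
        N = len(y)
        # each fold predicts the fold mean
        expected = np.mean(
            [
                (y[i] - np.delete(y, i).mean()) ** 2
                for i in range(N)
            ]
        )
        assert sd.loocv_mse(gene, protein, 0.0, big) == pytest.approx(expected, abs=1e-9)

    def test_too_few_points(self):
        grid = TimeGrid([0.0, 1.0])
        gene = sd.TimeSeriesGene("G", ("t",), [[1.0, 2.0]], grid)
        protein = sd.ProteinSeries("P", "G", Series([1.0, 2.0], grid))
        with pytest.raises(ValueError):
            sd.loocv_mse(gene, protein, 0.0, 0.1)


class TestFitProteinModel:
    def test_identity_single_transcript(self):
        grid = TimeGrid([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        gene = sd.TimeSeriesGene("G", ("G.t1",), x[None, :], grid)
        protein = sd.ProteinSeries("P", "G", Series(x.copy(), grid))
        fit = sd.fit_protein_model(gene, protein, [0.0, 1.0, 2.0], n_lams=10, eps=1e-9)
        assert fit.tau == 0.0
        assert fit.beta[0] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_delay_on_synthetic_gene(self, recovery_grid, uniform_delays):
        truth = sd.SyntheticTruth("G1", beta_true=[2.0, -1.0], tau_true=2.0, sigma=0.0)
        gene, protein = sd.simulate_gene(
            truth, recovery_grid, seed=3, protein_sampling="dense"
        )
        fit = sd.fit_protein_model(gene, protein, uniform_delays, n_lams=12)
        assert abs(fit.tau - 2.0) <= 0.5
        assert np.sign(fit.beta[0]) > 0 and np.sign(fit.beta[1]) < 0

    def test_support_bound(self, recovery_grid, uniform_delays):
        dataset, _ = sd.simulate_dataset(
            10, transcript_counts=(4, 5), noise=0.05, grid=recovery_grid, seed=5
        )
        for g, p in dataset:
            fit = sd.fit_protein_model(g, p, uniform_delays, n_lams=10)
            n_points = len(sd.delayed_design(g, p, 0.0)[1])
            assert fit.n_nonzero <= n_points - 1

    def test_selected_pair_minimizes_surface(self):
        gene, protein, _ = make_linear_gene(seed=41)
        delays = [0.0, 1.0, 3.0]
        fit = sd.fit_protein_model(gene, protein, delays, n_lams=8)
        for tau in delays:
            X_t, y_shift = sd.delayed_design(gene, protein, tau)
            for lam in sd.lambda_path(X_t, y_shift, 8):
                assert fit.loocv_mse <= sd.loocv_mse(gene, protein, tau, lam) + 1e-9


class TestDoubleCvPredict:
    def test_noiseless_linear_gene_exact(self, linear_gene):
        gene, protein, _ = linear_gene
        preds = sd.double_cv_predict(gene, protein, [0.0, 1.0, 2.0], n_lams=10, eps=1e-10)
        for q in preds:
            assert q.predicted == pytest.approx(q.observed, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nested_loop_oracle(self, seed):
        gene, protein, _ = make_linear_gene(seed=seed, n_points=7)
        # noise so that the surface has no exact-zero degeneracies
        rng = np.random.default_rng(seed + 100)
        noisy = sd.ProteinSeries(
            protein.protein_id,
            protein.gene_id,
            Series(protein.y.values + rng.normal(0, 0.3, len(protein.y)), protein.y.grid),
        )
        delays = [0.0, 0.8, 2.5]
        preds = sd.double_cv_predict(gene, noisy, delays, n_lams=6)
        oracle = double_cv_oracle(gene, noisy, delays, 6)
        assert len(preds) == len(oracle)
        for q, (i, pred, obs, tau, lam) in zip(preds, oracle):
            assert q.heldout_index == i
            assert q.tau_used == tau
            assert q.lam_used == pytest.approx(lam, rel=1e-12)
            assert q.predicted == pytest.approx(pred, abs=1e-9)
            assert q.observed == obs

    def test_no_information_leak(self):
        gene, protein, _ = make_linear_gene(seed=77, n_points=7)
        delays = [0.0, 1.0]
        preds = sd.double_cv_predict(gene, protein, delays, n_lams=6)
        target = preds[3]
        i = target.heldout_index
        perturbed_vals = protein.y.values.copy()
        perturbed_vals[i] += 1000.0
        perturbed = sd.ProteinSeries(
            protein.protein_id, protein.gene_id, Series(perturbed_vals, protein.y.grid)
        )
        preds2 = sd.double_cv_predict(gene, perturbed, delays, n_lams=6)
        target2 = [q for q in preds2 if q.heldout_index == i][0]
        assert target2.predicted == pytest.approx(target.predicted, abs=1e-9)

    def test_too_few_points(self):
        grid = TimeGrid([0.0, 1.0, 2.0])
        gene = sd.TimeSeriesGene("G", ("t",), [[1.0, 2.0, 3.0]], grid)
        protein = sd.ProteinSeries("P", "G", Series([1.0, 2.0, 3.0], grid))
        with pytest.raises(ValueError):
            sd.double_cv_predict(gene, protein, [0.0, 1.0])


class TestFitDataset:
    def test_skips_unexpressed_gene(self, caplog):
        grid = TimeGrid([0.0, 1.0, 2.0, 4.0, 8.0])
        gene = sd.TimeSeriesGene("G", ("t",), np.zeros((1, 5)), grid)
        protein = sd.ProteinSeries("P", "G", Series(np.arange(5.0), grid))
        fits = sd.fit_dataset([(gene, protein)], [0.0, 1.0], n_lams=5)
        assert fits == []
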