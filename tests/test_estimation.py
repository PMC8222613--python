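import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcmsearch.estimation import (
    GaussianDensity,
    bmr_reduce,
    default_priors,
    free_energy,
    gaussian_kl,
    parameter_probability,
    variational_laplace,
)
from dcmsearch.forward import StimulusDesign, simulate_dataset
from dcmsearch.semantic import TRUE_STRUCTURE_BITS, semantic_benchmark


class TestParameterProbability:
    @pytest.mark.parametrize("mean,sd,expected", [
        (0.0, 1.0, 0.5),
        (1.645, 1.0, 0.95),
        (3.0, 0.0, 1.0),
        (-3.0, 0.0, 1.0),
        (0.0, 0.0, 0.5),
    ])
    def test_reference_values(self, mean, sd, expected):
        assert parameter_probability(mean, sd) == pytest.approx(
            expected, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_monotone_in_signal_to_noise(self, z1, z2):
        lo, hi = sorted([z1, z2])
        assert parameter_probability(lo, 1.0) <= parameter_probability(hi, 1.0)

    def test_vectorized(self):
        p = parameter_probability(np.array([0.0, 1.645]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(p, [0.5, 0.95], atol=5e-4)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            parameter_probability(1.0, -0.5)


class TestFreeEnergy:
    def test_kl_closed_form_unit_shift(self):
        q = GaussianDensity([1.0], [[1.0]])
        p = GaussianDensity([0.0], [[1.0]])
        assert gaussian_kl(q, p) == pytest.approx(0.5)

    def test_zero_complexity_at_prior(self):
        prior = GaussianDensity([0.5, -1.0], np.diag([2.0, 0.3]))
        fe = free_energy(prior, prior, np.zeros(10), lam=0.0)
        assert fe.complexity == pytest.approx(0.0, abs=1e-12)

    def test_extra_shifted_parameter_costs_evidence(self):
        # same residuals; the larger model's posterior shifts one extra
        # parameter away from its prior -> strictly lower Fe
        resid = np.full(20, 0.3)
        prior_small = GaussianDensity([0.0], [[1.0]])
        q_small = GaussianDensity([0.8], [[0.1]])
        prior_big = GaussianDensity([0.0, 0.0], np.eye(2))
        q_big = GaussianDensity([0.8, 0.6], np.diag([0.1, 0.1]))
        fe_small = free_energy(q_small, prior_small, resid, 0.0).total
        fe_big = free_energy(q_big, prior_big, resid, 0.0).total
        assert fe_big < fe_small

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            GaussianDensity([0.0, 0.0], np.array([[1.0, 2.0], [2.0, 1.0]]))


def _conjugate_linear_model(seed=3, T=40, d=4, sigma2=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(T, d))
    beta = np.array([0.8, -0.5, 0.0, 0.3])
    y = X @ beta + rng.normal(0, np.sqrt(sigma2), T)
    m0, S0 = np.zeros(d), np.eye(d) * 2.0
    P = X.T @ X / sigma2 + np.linalg.inv(S0)
    S = np.linalg.inv(P)
    m = S @ (X.T @ y / sigma2)
    return X, y, sigma2, GaussianDensity(m0, S0), GaussianDensity(m, S)


def _analytic_evidence(X, y, sigma2, prior):
    T = len(y)
    Cov = X @ prior.cov @ X.T + sigma2 * np.eye(T)
    r = y - X @ prior.mean
    _, ld = np.linalg.slogdet(Cov)
    return -0.5 * (T * np.log(2 * np.pi) + ld + r @ np.linalg.solve(Cov, r))


class TestBMR:
    def test_identity_reduction_is_exact(self):
        X, y, s2, prior, post = _conjugate_linear_model()
        dF, q = bmr_reduce(post, prior, prior)
        assert abs(dF) < 1e-10
        np.testing.assert_allclose(q.mean, post.mean, atol=1e-12)
        np.testing.assert_allclose(q.cov, post.cov, atol=1e-12)

    def test_matches_analytic_evidence_difference(self):
        X, y, s2, prior, post = _conjugate_linear_model()
        Sr = prior.cov.copy()
        Sr[2, 2] = 1e-8
        Sr[3, 3] = 0.5
        reduced = GaussianDensity(prior.mean, Sr)
        dF, _ = bmr_reduce(post, prior, reduced)
        expected = (_analytic_evidence(X, y, s2, reduced)
                    - _analytic_evidence(X, y, s2, prior))
        assert dF == pytest.approx(expected, abs=1e-6)

    def test_shrinkage_limit_returns_prior_mean(self):
        X, y, s2, prior, post = _conjugate_linear_model()
        Sr = prior.cov.copy()
        Sr[0, 0] = 0.0
        dF, q = bmr_reduce(post, prior,
                           GaussianDensity(prior.mean, np.diag(np.diag(Sr))))
        assert q.mean[0] == pytest.approx(prior.mean[0], abs=1e-6)

    def test_non_nested_prior_rejected(self):
        X, y, s2, prior, post = _conjugate_linear_model()
        Sr = prior.cov.copy()
        Sr[1, 1] *= 3.0  # widened, not shrunk
        with pytest.raises(ValueError, match="nested"):
            bmr_reduce(post, prior, GaussianDensity(prior.mean, Sr))


@pytest.fixture(scope="session")
def vl_fit():
    """One VL fit of the benchmark's true structure (shared across tests)."""
    ds, pars, structure = semantic_benchmark(1)
    return ds, pars, structure, variational_laplace(ds, structure)


class TestVariationalLaplace:
    def test_fe_trace_non_decreasing(self, vl_fit):
        _, _, _, est = vl_fit
        trace = est.fe_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_noise_precision_recovered(self, vl_fit):
        ds, _, _, est = vl_fit
        true_lam = np.log(1.0 / ds.ground_truth["noise_sd"] ** 2)
        assert est.lambda_ == pytest.approx(true_lam, abs=0.3)

    def test_parameter_recovery_single_seed(self, vl_fit):
        ds, pars, _, est = vl_fit
        mats = est.matrices()
        tv, ev = [], []
        for key in est.keys:
            if key[0] == "A" and key[1] != key[2]:
                tv.append(pars.A[key[1], key[2]])
                ev.append(mats["A"][key[1], key[2]])
            elif key[0] == "B":
                tv.append(pars.B[key[1], key[2], key[3]])
                ev.append(mats["B"][key[1], key[2], key[3]])
            elif key[0] == "C":
                tv.append(pars.C[key[1], key[2]])
                ev.append(mats["C"][key[1], key[2]])
        assert np.corrcoef(tv, ev)[0, 1] >= 0.8

    def test_probabilities_consistent_with_posterior(self, vl_fit):
        _, _, _, est = vl_fit
        expected = parameter_probability(est.density.mean, est.density.sd())
        np.testing.assert_allclose(est.probability, expected)

    def test_self_consistency_on_prior_mean_data(self, semantic_spec):
        # noiseless data generated at the prior mean: VL stays at the prior
        structure = semantic_spec.structure(TRUE_STRUCTURE_BITS)
        ds0, _, _ = semantic_benchmark(1, n_scans=50)
        priors = default_priors(structure)
        from dcmsearch.estimation import _Predictor
        from dcmsearch.forward import BOLDDataset, HemodynamicParams

        pred = _Predictor(ds0, structure, priors.keys, HemodynamicParams())
        y0 = pred(priors.density.mean)[0].reshape(50, 4)
        data = BOLDDataset(Y=y0, tr=ds0.tr, design=ds0.design,
                           region_names=ds0.region_names)
        est = variational_laplace(data, structure)
        np.testing.assert_allclose(est.density.mean, priors.density.mean,
                                   atol=0.05)

    def test_deterministic(self):
        ds, _, structure = semantic_benchmark(2, n_scans=50)
        e1 = variational_laplace(ds, structure)
        e2 = variational_laplace(ds, structure)
        assert e1.fe == e2.fe
        np.testing.assert_array_equal(e1.density.mean, e2.density.mean)

    def test_region_count_mismatch_rejected(self, spec9, vl_fit):
        ds = vl_fit[0]
        with pytest.raises(ValueError):
            variational_laplace(ds, spec9.structure("0" * 9))


class TestBMRAgainstDirectVL:
    def test_rank_order_agreement_of_evidence_routes(self, semantic_spec):
        """BMR-from-full and direct VL estimation are different
        approximations of the same evidence; their rankings of nested
        models should agree on most pairs."""
        from dcmsearch.search import BMROracle

        ds, _, _ = semantic_benchmark(3, n_scans=100)
        full = semantic_spec.structure("1" * 16)
        est_full = variational_laplace(ds, full)
        oracle = BMROracle(est_full, default_priors(full), semantic_spec)

        base = "1" * 16
        rng = np.random.default_rng(0)
        candidates = []
        for k in (1, 2, 3, 4, 6, 8):
            bits = list(base)
            for b in rng.choice(16, size=k, replace=False):
                bits[b] = "0"
            bv = "".join(bits)
            if semantic_spec.is_valid_bits(bv):
                candidates.append(bv)
        fe_vl = [variational_laplace(
            ds, semantic_spec.structure(bv)).fe for bv in candidates]
        fe_bmr = [oracle.evaluate(bv).fe for bv in candidates]
        agree = total = 0
        for a in range(len(candidates)):
            for b in range(a + 1, len(candidates)):
                total += 1
                agree += (fe_vl[a] > fe_vl[b]) == (fe_bmr[a] > fe_bmr[b])
        assert agree / total >= 0.8
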