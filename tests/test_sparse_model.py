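import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import ElasticNet as SkElasticNet

from srcstroke import (
    ClassDictionary,
    ElasticNetParams,
    ValidationError,
    classify_batch,
    classify_sample,
    learn_dictionary,
    sparse_encode,
)
from srcstroke.sparse_model import dictionary_objective, enet_objective


def ista_solve(s, D, lam1, lam2, iters=4000):
    """Independent proximal-gradient (ISTA) solver used as an oracle."""
    L = np.linalg.norm(D, 2) ** 2 + lam2
    a = np.zeros(D.shape[1])
    for _ in range(iters):
        g = D.T @ (D @ a - s) + lam2 * a
        u = a - g / L
        a = np.sign(u) * np.maximum(np.abs(u) - lam1 / L, 0.0)
    return a


def soft_threshold_closed_form(s, lam1, lam2):
    """Closed-form elastic net for an orthonormal dictionary."""
    return np.sign(s) * np.maximum(np.abs(s) - lam1, 0.0) / (1.0 + lam2)


def random_problem(rng, m=10, K=12):
    D = rng.standard_normal((m, K))
    D /= np.linalg.norm(D, axis=0)
    return rng.standard_normal(m), D


def kkt_violation(s, D, a, p):
    corr = D.T @ (s - D @ a)
    return float(
        np.max(
            np.where(
                a != 0,
                np.abs(corr - p.lambda1 * np.sign(a) - p.lambda2 * a),
                np.maximum(np.abs(corr) - p.lambda1, 0.0),
            )
        )
    )


STRICT = ElasticNetParams(0.3, 0.1, max_iter=1000, tol=1e-6)


class TestSparseEncode:
    def test_orthonormal_closed_form(self):
        sc = sparse_encode(np.array([1.0, 0.2]), np.eye(2), STRICT)
        np.testing.assert_allclose(sc.coefficients, [0.7 / 1.1, 0.0], atol=1e-9)
        assert sc.nnz == 1

    def test_unregularised_square_system(self, rng):
        D = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        D /= np.linalg.norm(D, axis=0)
        s = rng.standard_normal(4)
        p = ElasticNetParams(0.0, 0.0, max_iter=5000, tol=1e-12)
        sc = sparse_encode(s, D, p)
        np.testing.assert_allclose(sc.coefficients, np.linalg.solve(D, s), atol=1e-6)
        assert sc.objective < 1e-10

    def test_zero_sample_gives_zero_code(self, rng):
        _, D = random_problem(rng)
        sc = sparse_encode(np.zeros(10), D, STRICT)
        assert (sc.coefficients == 0).all()

    def test_objective_sandwich(self, rng):
        s, D = random_problem(rng)
        sc = sparse_encode(s, D, STRICT)
        zero_obj = enet_objective(s, D, np.zeros(12), STRICT)
        lsq = np.linalg.lstsq(D, s, rcond=None)[0]
        lsq_obj = enet_objective(s, D, lsq, STRICT)
        assert sc.objective <= zero_obj + 1e-12
        assert sc.objective <= lsq_obj + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_kkt_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        s, D = random_problem(rng)
        sc = sparse_encode(s, D, STRICT)
        assert kkt_violation(s, D, sc.coefficients, STRICT) < 1e-4
        a_ref = ista_solve(s, D, STRICT.lambda1, STRICT.lambda2)
        assert abs(sc.objective - enet_objective(s, D, a_ref, STRICT)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_elastic_net(self, seed):
        # sklearn minimises (1/2n)||s-Da||^2 + alpha*l1r*||a||_1
        #                    + alpha*(1-l1r)/2*||a||^2
        rng = np.random.default_rng(100 + seed)
        s, D = random_problem(rng)
        m = s.size
        alpha = (STRICT.lambda1 + STRICT.lambda2) / m
        l1r = STRICT.lambda1 / (STRICT.lambda1 + STRICT.lambda2)
        sk = SkElasticNet(alpha=alpha, l1_ratio=l1r, fit_intercept=False,
                          tol=1e-12, max_iter=100000)
        sk.fit(D, s)
        sc = sparse_encode(s, D, STRICT)
        np.testing.assert_allclose(sc.coefficients, sk.coef_, atol=1e-5)

    def test_lambda2_zero_reduces_to_lasso(self, rng):
        s = rng.standard_normal(8)
        p = ElasticNetParams(0.4, 0.0, max_iter=1000, tol=1e-9)
        sc = sparse_encode(s, np.eye(8), p)
        np.testing.assert_allclose(
            sc.coefficients, soft_threshold_closed_form(s, 0.4, 0.0), atol=1e-8
        )

    def test_monotone_sparsity_in_lambda1(self, rng):
        s = rng.standard_normal(12)
        prev_nnz = 12
        for lam1 in [0.0, 0.1, 0.3, 0.6, 1.0]:
            sc = sparse_encode(s, np.eye(12), ElasticNetParams(lam1, 0.05))
            assert sc.nnz <= prev_nnz
            prev_nnz = sc.nnz

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), lam1=st.sampled_from([0.05, 0.3, 0.8]))
    def test_kkt_holds_on_random_problems(self, seed, lam1):
        rng = np.random.default_rng(seed)
        s, D = random_problem(rng)
        p = ElasticNetParams(lam1, 0.1, max_iter=1000, tol=1e-6)
        sc = sparse_encode(s, D, p)
        assert kkt_violation(s, D, sc.coefficients, p) < 1e-4

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            sparse_encode(np.array([np.nan, 0.0]), np.eye(2), STRICT)


class TestLearnDictionary:
    def test_rank_one_data(self):
        u = np.array([3.0, 4.0]) / 5.0
        X = np.tile(u, (20, 1))
        p = ElasticNetParams(0.01, 0.01)
        d = learn_dictionary(X, 1, p, epochs=5, seed=0, mode="batch")
        assert abs(abs(d.atoms[:, 0] @ u) - 1.0) < 1e-6

    def test_batch_objective_monotone(self, rng):
        atoms = rng.standard_normal((20, 5))
        atoms /= np.linalg.norm(atoms, axis=0)
        codes = rng.standard_normal((5, 200)) * (rng.random((5, 200)) < 0.4)
        X = (atoms @ codes + 0.01 * rng.standard_normal((20, 200))).T
        p = ElasticNetParams(0.1, 0.05)
        d = learn_dictionary(X, 8, p, epochs=12, seed=3, mode="batch")
        tr = d.objective_trace
        assert tr is not None and len(tr) == 12
        assert np.all(np.diff(tr) <= 1e-8)

    def test_unit_norm_atoms(self, rng):
        X = rng.standard_normal((50, 6))
        d = learn_dictionary(X, 10, ElasticNetParams(0.1, 0.1), epochs=3, seed=1)
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((80, 6))
        p = ElasticNetParams(0.1, 0.1)
        d1 = learn_dictionary(X, 10, p, epochs=3, seed=42)
        d2 = learn_dictionary(X, 10, p, epochs=3, seed=42)
        assert d1.atoms.tobytes() == d2.atoms.tobytes()

    def test_pads_when_too_few_distinct_samples(self):
        X = np.tile([1.0, 0.0, 0.0], (3, 1))
        with pytest.warns(UserWarning):
            d = learn_dictionary(X, 5, ElasticNetParams(0.1, 0.1), epochs=1, seed=0)
        assert d.K == 5

    def test_invalid_K(self, rng):
        with pytest.raises(ValidationError):
            learn_dictionary(rng.standard_normal((5, 3)), 0, ElasticNetParams())


class TestClassify:
    def _dicts(self, rng):
        Di = rng.standard_normal((6, 4))
        Di /= np.linalg.norm(Di, axis=0)
        Dn = rng.standard_normal((6, 4))
        Dn /= np.linalg.norm(Dn, axis=0)
        return ClassDictionary(Di, "infarct"), ClassDictionary(Dn, "normal")

    def test_exact_atom_match(self, rng):
        Di, Dn = self._dicts(rng)
        p = ElasticNetParams(0.01, 0.001)
        label, res = classify_sample(Di.atoms[:, 2], Di, Dn, p)
        assert label == "infarct"
        assert res["infarct"] < res["normal"]

    def test_orthogonal_sample_ties_to_normal(self):
        Di = ClassDictionary(np.eye(4)[:, :2], "infarct")
        Dn = ClassDictionary(np.eye(4)[:, 2:3], "normal")
        s = np.array([0.0, 0.0, 0.0, 1.0])  # orthogonal to every atom
        label, res = classify_sample(s, Di, Dn, ElasticNetParams(2.0, 0.1))
        assert label == "normal"
        assert res["infarct"] == pytest.approx(res["normal"])

    def test_dimension_mismatch_rejected(self, rng):
        Di, Dn = self._dicts(rng)
        with pytest.raises(ValidationError):
            classify_batch(np.zeros((5, 1)), Di, Dn, ElasticNetParams())

    def test_two_cluster_accuracy(self):
        # 5-sigma class-mean separation; nearest-mean oracle is ~100% here
        rng = np.random.default_rng(5)
        m = 16
        mu1 = rng.standard_normal(m)
        mu1 /= np.linalg.norm(mu1)
        delta = rng.standard_normal(m)
        delta /= np.linalg.norm(delta)
        mu2 = mu1 + 5.0 * delta
        p = ElasticNetParams(0.1, 0.1, max_iter=200, tol=1e-5)
        D1 = learn_dictionary(mu1 + rng.standard_normal((300, m)), 40, p,
                              epochs=5, seed=1, class_label="infarct")
        D2 = learn_dictionary(mu2 + rng.standard_normal((300, m)), 40, p,
                              epochs=5, seed=2, class_label="normal")
        X = np.concatenate([
            mu1 + rng.standard_normal((500, m)),
            mu2 + rng.standard_normal((500, m)),
        ])
        truth = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        labels, _ = classify_batch(X.T, D1, D2, p)
        assert (labels == truth).mean() >= 0.95
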