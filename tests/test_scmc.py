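import numpy as np
import pytest
from scipy.special import expit

from ans_scmc import (
    FilledMatrix,
    PipelineConfig,
    ScmcParams,
    SimilarityMatrix,
    predict,
    scmc_fit,
    scmc_gradients,
    scmc_loss,
    sigmoid_scores,
)


def _sim(n, axis, seed=None, identity=False):
    if identity:
        V = np.eye(n)
    else:
        rng = np.random.default_rng(seed)
        V = rng.random((n, n))
        V = (V + V.T) / 2
    return SimilarityMatrix(V, axis=axis, ids=[f"{axis[0]}{i}" for i in range(n)])


def _problem(nm, nd, r, seed):
    rng = np.random.default_rng(seed)
    AW = rng.random((nm, nd))
    W = rng.random((nm, nd)) + 0.5
    M = rng.normal(size=(nm, r))
    D = rng.normal(size=(nd, r))
    MS = _sim(nm, "microbe", seed + 100)
    DS = _sim(nd, "disease", seed + 200)
    return AW, W, M, D, MS, DS


class TestSigmoid:
    def test_zero_factors_give_half(self):
        P = sigmoid_scores(np.zeros((3, 2)), np.zeros((4, 2)))
        assert np.all(P.values == 0.5)

    def test_unit_inner_product(self):
        P = sigmoid_scores(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert P.values[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_saturation_without_overflow(self):
        M = np.array([[1000.0], [-1000.0]])
        D = np.array([[1.0], [1.0]])
        P = sigmoid_scores(M, D).values
        assert np.isfinite(P).all()
        assert 0 < P[1, 0] < 1e-300  # saturated low but strictly positive
        assert 1 - 1e-12 < P[0, 0] < 1


class TestLoss:
    def test_closed_form_at_origin(self):
        nm, nd, r = 5, 4, 2
        params = ScmcParams(rank=r, lambda_R=0, lambda_alpha=0, lambda_beta=0)
        loss = scmc_loss(
            np.zeros((nm, r)),
            np.zeros((nd, r)),
            np.zeros((nm, nd)),
            np.ones((nm, nd)),
            _sim(nm, "microbe", 1),
            _sim(nd, "disease", 2),
            params,
        )
        assert loss == pytest.approx(nm * nd * np.log(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_trace_form_equals_pairwise_sum(self, seed):
        """tr(M^T (D_S - S) M) == 1/2 sum_ij S_ij ||M_i - M_j||^2."""
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(5, 3))
        S = rng.random((5, 5))
        S = (S + S.T) / 2
        L = np.diag(S.sum(axis=1)) - S
        trace_form = np.trace(M.T @ L @ M)
        brute = 0.5 * sum(
            S[i, j] * np.sum((M[i] - M[j]) ** 2) for i in range(5) for j in range(5)
        )
        assert trace_form == pytest.approx(brute, abs=1e-10)

    def test_identity_similarity_contributes_nothing(self):
        AW, W, M, D, MS, DS = _problem(5, 4, 2, 0)
        base = scmc_loss(M, D, AW, W, MS, DS, ScmcParams(rank=2, lambda_alpha=0))
        with_id = scmc_loss(
            M, D, AW, W, _sim(5, "microbe", identity=True), DS,
            ScmcParams(rank=2, lambda_alpha=0.7),
        )
        assert base == pytest.approx(with_id, abs=1e-12)

    def test_asymmetric_similarity_rejected(self):
        AW, W, M, D, MS, DS = _problem(5, 4, 2, 1)
        bad = SimilarityMatrix(
            np.triu(np.ones((5, 5))), axis="microbe", ids=[f"m{i}" for i in range(5)]
        )
        with pytest.raises(ValueError, match="symmetric"):
            scmc_loss(M, D, AW, W, bad, DS, ScmcParams(rank=2))


class TestGradients:
    @pytest.mark.parametrize("nm,nd,r,seed", [(6, 4, 2, 0), (8, 6, 3, 1)])
    def test_match_central_finite_differences(self, nm, nd, r, seed):
        AW, W, M, D, MS, DS = _problem(nm, nd, r, seed)
        params = ScmcParams(rank=r, lambda_R=0.01, lambda_alpha=0.1, lambda_beta=0.1)
        B_M, B_D = scmc_gradients(M, D, AW, W, MS, DS, params)
        rng = np.random.default_rng(seed + 7)
        h = 1e-6
        for _ in range(20):
            if rng.random() < 0.5:
                i, k = rng.integers(nm), rng.integers(r)
                Mp, Mm = M.copy(), M.copy()
                Mp[i, k] += h
                Mm[i, k] -= h
                fd = (
                    scmc_loss(Mp, D, AW, W, MS, DS, params)
                    - scmc_loss(Mm, D, AW, W, MS, DS, params)
                ) / (2 * h)
                analytic = B_M[i, k]
            else:
                j, k = rng.integers(nd), rng.integers(r)
                Dp, Dm = D.copy(), D.copy()
                Dp[j, k] += h
                Dm[j, k] -= h
                fd = (
                    scmc_loss(M, Dp, AW, W, MS, DS, params)
                    - scmc_loss(M, Dm, AW, W, MS, DS, params)
                ) / (2 * h)
                analytic = B_D[j, k]
            assert abs(fd - analytic) / max(abs(analytic), 1e-8) < 1e-5

    def test_pure_penalty_gradient_is_exact(self):
        AW, _, M, D, MS, DS = _problem(5, 4, 2, 2)
        params = ScmcParams(rank=2, lambda_R=0.3, lambda_alpha=0, lambda_beta=0)
        B_M, B_D = scmc_gradients(M, D, AW, np.zeros_like(AW), MS, DS, params)
        assert np.array_equal(B_M, 2 * 0.3 * M)
        assert np.array_equal(B_D, 2 * 0.3 * D)

    def test_zero_factors_zero_gradient_without_penalties(self):
        AW = np.random.default_rng(3).random((5, 4))
        params = ScmcParams(rank=2, lambda_R=0, lambda_alpha=0, lambda_beta=0)
        B_M, B_D = scmc_gradients(
            np.zeros((5, 2)), np.zeros((4, 2)), AW, np.ones((5, 4)),
            _sim(5, "microbe", 4), _sim(4, "disease", 5), params,
        )
        assert np.all(B_M == 0) and np.all(B_D == 0)


def _filled(nm, nd, seed):
    rng = np.random.default_rng(seed)
    return FilledMatrix(
        rng.random((nm, nd)),
        [f"m{i}" for i in range(nm)],
        [f"d{j}" for j in range(nd)],
    )


class TestFit:
    def test_same_seed_bit_identical(self):
        AW = _filled(8, 6, 0)
        MS, DS = _sim(8, "microbe", 1), _sim(6, "disease", 2)
        params = ScmcParams(rank=3, max_iter=200)
        f1, P1 = scmc_fit(AW, None, MS, DS, params, seed=11)
        f2, P2 = scmc_fit(AW, None, MS, DS, params, seed=11)
        assert np.array_equal(f1.M, f2.M) and np.array_equal(f1.D, f2.D)
        assert np.array_equal(P1.values, P2.values)

    def test_every_update_moves_exactly_epsilon(self):
        AW = _filled(8, 6, 3)
        MS, DS = _sim(8, "microbe", 4), _sim(6, "disease", 5)
        params = ScmcParams(rank=3, epsilon=0.1, tol=1e-300, max_iter=100)
        prev = {}
        steps = []

        def cb(it, M, D, B_M, B_D):
            if "M" in prev:
                steps.append(np.linalg.norm(M - prev["M"]))
                steps.append(np.linalg.norm(D - prev["D"]))
            prev["M"], prev["D"] = M.copy(), D.copy()

        scmc_fit(AW, None, MS, DS, params, seed=6, callback=cb)
        assert len(steps) == 2 * 99
        assert np.allclose(steps, 0.1, atol=1e-10)

    def test_loss_trace_decreases_start_to_end(self):
        for seed in (0, 1, 2):
            AW = _filled(10, 7, seed)
            MS, DS = _sim(10, "microbe", seed + 10), _sim(7, "disease", seed + 20)
            f, _ = scmc_fit(AW, None, MS, DS, ScmcParams(rank=3, max_iter=500), seed=seed)
            assert len(f.loss_trace) == f.iteration
            assert f.loss_trace[-1] <= f.loss_trace[0]

    def test_reduces_to_plain_logistic_mf_without_penalties(self):
        """With all penalties off and uniform weights the fit must equal an
        independent minimal logistic-MF implementation run from the same
        start with the same normalised update rule."""
        AW = _filled(7, 5, 9)
        MS, DS = _sim(7, "microbe", 30), _sim(5, "disease", 31)
        params = ScmcParams(
            rank=2, lambda_R=0, lambda_alpha=0, lambda_beta=0,
            epsilon=0.1, tol=1e-9, max_iter=300,
        )
        rng = np.random.default_rng(12)
        M0 = rng.normal(0, 1 / np.sqrt(2), (7, 2))
        D0 = rng.normal(0, 1 / np.sqrt(2), (5, 2))
        f, P = scmc_fit(AW, None, MS, DS, params, init=(M0, D0))
        # straight-line oracle
        M, D = M0.copy(), D0.copy()
        for _ in range(300):
            R = expit(M @ D.T) - AW.values
            B_M, B_D = R @ D, R.T @ M
            nM, nD = np.linalg.norm(B_M), np.linalg.norm(B_D)
            if nM == 0 or nD == 0:
                break
            prev_nm, prev_nd = np.linalg.norm(M), np.linalg.norm(D)
            M = M - 0.1 * B_M / nM
            D = D - 0.1 * B_D / nD
            if max(
                abs(np.linalg.norm(M) - prev_nm), abs(np.linalg.norm(D) - prev_nd)
            ) < 1e-9:
                break
        assert np.allclose(f.M, M, atol=1e-9)
        assert np.allclose(P.values, expit(M @ D.T), atol=1e-9)

    def test_permuting_microbes_permutes_score_rows(self):
        AW = _filled(6, 4, 13)
        MS, DS = _sim(6, "microbe", 40), _sim(4, "disease", 41)
        rng = np.random.default_rng(14)
        M0 = rng.normal(size=(6, 2))
        D0 = rng.normal(size=(4, 2))
        params = ScmcParams(rank=2, max_iter=150)
        _, P = scmc_fit(AW, None, MS, DS, params, init=(M0, D0))
        perm = np.array([3, 0, 5, 1, 4, 2])
        AWp = FilledMatrix(
            AW.values[perm], tuple(AW.microbe_ids[i] for i in perm), AW.disease_ids
        )
        MSp = SimilarityMatrix(
            MS.values[np.ix_(perm, perm)], "microbe",
            tuple(MS.ids[i] for i in perm),
        )
        _, Pp = scmc_fit(AWp, None, MSp, DS, params, init=(M0[perm], D0))
        assert np.allclose(Pp.values, P.values[perm], atol=1e-12)

    def test_rank_exceeding_dimensions_rejected(self):
        AW = _filled(4, 3, 0)
        with pytest.raises(ValueError, match="rank"):
            scmc_fit(AW, None, _sim(4, "microbe", 1), _sim(3, "disease", 2),
                     ScmcParams(rank=5))


class TestPredict:
    def test_end_to_end_scores_strictly_inside_unit_interval(self, planted):
        A, _ = planted
        sub = A.values[:12, :8]
        from ans_scmc import AssociationMatrix

        # keep every axis populated
        sub = sub.copy()
        for i in np.flatnonzero(sub.sum(axis=1) == 0):
            sub[i, 0] = 1
        for j in np.flatnonzero(sub.sum(axis=0) == 0):
            sub[0, j] = 1
        Asub = AssociationMatrix(
            sub, [f"m{i}" for i in range(12)], [f"d{j}" for j in range(8)]
        )
        P = predict(Asub, PipelineConfig(scmc=ScmcParams(rank=4, max_iter=800)))
        assert np.all(P.values > 0) and np.all(P.values < 1)
        assert P.microbe_ids == Asub.microbe_ids
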