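import numpy as np
import pytest

from dictpair.pdpl import (
    AdmmConfig,
    DictionaryPair,
    PDPLParams,
    TrainedModel,
    TrainingSet,
    classify,
    init_dictionaries,
    load_model,
    objective,
    predict_batch,
    save_model,
    train,
    update_analysis,
    update_codes,
    update_synthesis,
)

from conftest import random_instance


# --- independent oracles -----------------------------------------------------


def codes_oracle(Fk, Dk, Pk, tau):
    """Stacked least squares: min_A ||F - D A||^2 + tau ||P F - A||^2."""
    m = Dk.shape[1]
    top = np.vstack([Dk, np.sqrt(tau) * np.eye(m)])
    rhs = np.vstack([Fk, np.sqrt(tau) * (Pk @ Fk)])
    return np.linalg.lstsq(top, rhs, rcond=None)[0]


def analysis_oracle(Fk, Fbar, Ak, tau, lam, gam):
    """Row-wise stacked least squares:
    min_P tau ||P F - A||^2 + lam ||P Fbar||^2 + gam ||P||^2."""
    p = Fk.shape[0]
    design = np.vstack(
        [np.sqrt(tau) * Fk.T, np.sqrt(lam) * Fbar.T, np.sqrt(gam) * np.eye(p)]
    )
    P = np.empty((Ak.shape[0], p))
    for r in range(Ak.shape[0]):
        target = np.concatenate(
            [np.sqrt(tau) * Ak[r], np.zeros(Fbar.shape[1]), np.zeros(p)]
        )
        P[r] = np.linalg.lstsq(design, target, rcond=None)[0]
    return P


def synthesis_ls_oracle(Fk, Ak):
    """Unconstrained least-squares dictionary F A^T (A A^T)^-1."""
    return np.linalg.lstsq(Ak.T, Fk.T, rcond=None)[0].T


# --- init --------------------------------------------------------------------


class TestInitDictionaries:
    def test_unit_frobenius_norm(self):
        pair = init_dictionaries(p=10, m=4, K=3, seed=0)
        for D, P in zip(pair.D_blocks, pair.P_blocks):
            assert np.linalg.norm(D) == pytest.approx(1.0)
            assert np.linalg.norm(P) == pytest.approx(1.0)

    def test_seed_determinism(self):
        a = init_dictionaries(5, 3, 2, seed=42)
        b = init_dictionaries(5, 3, 2, seed=42)
        for Da, Db in zip(a.D_blocks, b.D_blocks):
            assert np.array_equal(Da, Db)

    def test_different_seeds_differ(self):
        a = init_dictionaries(5, 3, 2, seed=1)
        b = init_dictionaries(5, 3, 2, seed=2)
        assert not np.array_equal(a.D_blocks[0], b.D_blocks[0])

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            init_dictionaries(0, 3, 2, seed=0)


# --- code update -------------------------------------------------------------


class TestUpdateCodes:
    def test_large_tau_limit(self):
        rng = np.random.default_rng(0)
        F, D, P, _ = random_instance(rng)
        A = update_codes(F, D, P, tau=1e8)
        for k in range(F.K):
            target = P[k] @ F.F_blocks[k]
            assert np.linalg.norm(A[k] - target) / np.linalg.norm(target) < 1e-6

    def test_tau_zero_orthonormal(self):
        rng = np.random.default_rng(1)
        F, _, P, _ = random_instance(rng, p=8, m=4)
        D = [np.linalg.qr(rng.standard_normal((8, 4)))[0] for _ in range(F.K)]
        A = update_codes(F, D, P, tau=0.0)
        for k in range(F.K):
            assert np.allclose(A[k], D[k].T @ F.F_blocks[k], atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F, D, P, _ = random_instance(rng, p=8, m=4, n=10)
        A = update_codes(F, D, P, tau=0.05)
        for k in range(F.K):
            oracle = codes_oracle(F.F_blocks[k], D[k], P[k], 0.05)
            assert np.linalg.norm(A[k] - oracle) / np.linalg.norm(oracle) <= 1e-6


# --- analysis update ---------------------------------------------------------


class TestUpdateAnalysis:
    def test_lambda_zero_square_invertible(self):
        rng = np.random.default_rng(2)
        Fk = rng.standard_normal((6, 6)) + 6 * np.eye(6)
        F = TrainingSet([Fk])
        Ak = rng.standard_normal((3, 6))
        P = update_analysis(F, [Ak], tau=1.0, lam=0.0, gam=1e-12)
        assert np.allclose(P[0] @ Fk, Ak, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F, _, _, A = random_instance(rng, p=8, m=4, n=10)
        tau, lam, gam = 0.5, 0.1, 1e-4
        P = update_analysis(F, A, tau, lam, gam)
        for k in range(F.K):
            oracle = analysis_oracle(F.F_blocks[k], F.complement(k), A[k], tau, lam, gam)
            assert np.linalg.norm(P[k] - oracle) / np.linalg.norm(oracle) <= 1e-6

    def test_large_lambda_shrinks_cross_projection(self):
        rng = np.random.default_rng(3)
        F, _, _, A = random_instance(rng, p=6, m=3, n=12)
        norms = []
        for lam in [0.0, 1.0, 100.0, 1e4]:
            P = update_analysis(F, A, tau=1.0, lam=lam, gam=1e-6)
            norms.append(np.linalg.norm(P[0] @ F.complement(0)))
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]


# --- synthesis update (ADMM) -------------------------------------------------


class TestUpdateSynthesis:
    def test_zero_codes_returns_feasible(self):
        rng = np.random.default_rng(4)
        F, D, _, _ = random_instance(rng)
        A = [np.zeros((4, 10)) for _ in range(F.K)]
        out = update_synthesis(F, A, D, AdmmConfig())
        for Dk in out:
            assert (np.linalg.norm(Dk, axis=0) ** 2 <= 1 + 1e-9).all()

    def test_feasible_unconstrained_optimum_recovered(self):
        rng = np.random.default_rng(5)
        _, D_init, _, A = random_instance(rng, p=8, m=4, n=20)
        # scale F so the least-squares dictionary has small column norms
        F_raw = [rng.standard_normal((8, 20)) for _ in range(2)]
        F = TrainingSet([0.05 * Fk for Fk in F_raw])
        out = update_synthesis(F, A, D_init, AdmmConfig(max_inner=500, inner_tol=1e-8))
        for k in range(2):
            D_ls = synthesis_ls_oracle(F.F_blocks[k], A[k])
            assert np.linalg.norm(D_ls, axis=0).max() < 1  # setup sanity
            assert np.abs(out[k] - D_ls).max() <= 1e-4

    def test_single_atom_matches_brute_force(self):
        rng = np.random.default_rng(6)
        Fk = rng.standard_normal((2, 15))
        Ak = rng.standard_normal((1, 15))
        F = TrainingSet([Fk])
        out = update_synthesis(F, [Ak], [rng.standard_normal((2, 1))], AdmmConfig(max_inner=500, inner_tol=1e-8))
        obj = np.linalg.norm(Fk - out[0] @ Ak) ** 2
        # brute-force polar grid over the unit disk:
        # ||F - d a||^2 = ||F||^2 - 2 d.(F a^T) + ||d||^2 ||a||^2
        theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        rad = np.linspace(0, 1, 500)
        dx = np.outer(rad, np.cos(theta)).ravel()
        dy = np.outer(rad, np.sin(theta)).ravel()
        v = (Fk @ Ak.T).ravel()
        grid = (
            np.linalg.norm(Fk) ** 2
            - 2 * (dx * v[0] + dy * v[1])
            + (dx**2 + dy**2) * np.sum(Ak**2)
        )
        assert obj <= grid.min() + 1e-3


# --- objective ---------------------------------------------------------------


class TestObjective:
    def test_hand_computed_instance(self):
        F = TrainingSet([np.array([[1.0], [0.0]]), np.array([[0.0], [2.0]])])
        D = [np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])]
        P = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]
        A = [np.array([[1.0]]), np.array([[1.0]])]
        # k=1: recon 0, code term 0, cross term 0
        # k=2: recon ||[0,1]||^2 = 1; code 0.5*(2-1)^2 = 0.5; cross 0
        assert objective(F, D, P, A, tau=0.5, lam=0.25) == pytest.approx(1.5)

    def test_zero_at_perfect_fit(self):
        rng = np.random.default_rng(7)
        D = [np.linalg.qr(rng.standard_normal((6, 3)))[0] for _ in range(2)]
        A = [rng.standard_normal((3, 5)) for _ in range(2)]
        F = TrainingSet([D[k] @ A[k] for k in range(2)])
        P = [np.zeros((3, 6)) for _ in range(2)]
        A0 = [np.zeros((3, 5)) for _ in range(2)]
        # tau=lam=0: only reconstruction counts; perfect fit gives 0
        assert objective(F, D, P, A, tau=0.0, lam=0.0) == pytest.approx(0.0)
        val = objective(F, D, P, A0, tau=0.0, lam=0.0)
        assert val == pytest.approx(sum(np.linalg.norm(F.F_blocks[k]) ** 2 for k in range(2)))


# --- training ----------------------------------------------------------------


class TestTrain:
    def test_noiseless_subspace_reconstruction(self, small_params):
        from dictpair import SubspaceSpec, make_subspace_dataset
        from dictpair.evaluation import group_by_class

        spec = SubspaceSpec(
            K=3, p=30, r=4, n_per_class_per_subject=20, N_subjects=4,
            subject_shift_scale=0.0, noise_sigma=0.0, class_separation=0.5, seed=11,
        )
        ds = make_subspace_dataset(spec)
        X = np.hstack([s.X for s in ds.subjects])
        y = np.concatenate([s.labels for s in ds.subjects])
        ts = group_by_class(X, y, ds.K)
        model = train(ts, small_params)
        for k, Fk in enumerate(ts.F_blocks):
            D, P = model.pair.D_blocks[k], model.pair.P_blocks[k]
            rel = np.linalg.norm(Fk - D @ (P @ Fk)) / np.linalg.norm(Fk)
            assert rel < 0.05

    def test_determinism(self, small_training_set, small_params):
        a = train(small_training_set, small_params)
        b = train(small_training_set, small_params)
        assert a.energy_trace == b.energy_trace
        for Da, Db in zip(a.pair.D_blocks, b.pair.D_blocks):
            assert np.array_equal(Da, Db)

    def test_energy_descent(self, small_training_set, small_params):
        model = train(small_training_set, small_params)
        tr = model.energy_trace
        allowance = 10 * small_params.admm.inner_tol
        assert all(b <= a + allowance for a, b in zip(tr, tr[1:]))

    def test_atom_feasibility(self, small_training_set, small_params):
        model = train(small_training_set, small_params)
        for D in model.pair.D_blocks:
            assert (np.linalg.norm(D, axis=0) ** 2).max() <= 1 + 1e-9

    def test_null_space_discrimination(self, small_training_set, small_params):
        model = train(small_training_set, small_params)
        K = small_training_set.K
        for k in range(K):
            P = model.pair.P_blocks[k]
            own = np.linalg.norm(P @ small_training_set.F_blocks[k])
            for i in range(K):
                if i != k:
                    cross = np.linalg.norm(P @ small_training_set.F_blocks[i])
                    assert cross / own < 0.2


# --- classification ----------------------------------------------------------


def _toy_model():
    D = [np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])]
    P = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]
    return TrainedModel(DictionaryPair(D, P), PDPLParams(m=1), [], True)


class TestClassify:
    def test_exact_reconstruction_wins(self):
        model = _toy_model()
        label, res = classify(model, np.array([1.0, 0.0]))
        assert label == 1
        assert res[0] == pytest.approx(0.0)
        assert res[1] > 0

    def test_zero_sample_tie_breaks_to_class_one(self):
        label, res = classify(_toy_model(), np.zeros(2))
        assert label == 1
        assert np.allclose(res, 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            classify(_toy_model(), np.zeros(3))

    def test_block_permutation_permutes_labels(self):
        model = _toy_model()
        swapped = TrainedModel(
            DictionaryPair(model.pair.D_blocks[::-1], model.pair.P_blocks[::-1]),
            model.params, [], True,
        )
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        orig = predict_batch(model, X)
        perm = predict_batch(swapped, X)
        assert np.array_equal(perm, 3 - orig)


class TestPredictBatch:
    def test_matches_per_column_classify(self, small_training_set, small_params):
        model = train(small_training_set, small_params)
        X = np.hstack(small_training_set.F_blocks)[:, ::7]
        batch = predict_batch(model, X)
        single = [classify(model, X[:, j])[0] for j in range(X.shape[1])]
        assert np.array_equal(batch, single)

    def test_empty_matrix(self):
        model = _toy_model()
        assert predict_batch(model, np.empty((2, 0))).size == 0

    def test_duplicate_columns_duplicate_labels(self):
        model = _toy_model()
        X = np.array([[1.0, 1.0], [0.2, 0.2]])
        labels = predict_batch(model, X)
        assert labels[0] == labels[1]


# --- serialization -----------------------------------------------------------


class TestSerialization:
    def test_round_trip(self, tmp_path, small_training_set, small_params):
        model = train(small_training_set, small_params)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for Da, Db in zip(model.pair.D_blocks, loaded.pair.D_blocks):
            assert np.allclose(Da, Db)
        assert loaded.params == model.params
        assert loaded.energy_trace == model.energy_trace
        X = np.hstack(small_training_set.F_blocks)[:, :5]
        assert np.array_equal(predict_batch(model, X), predict_batch(loaded, X))

    def test_bad_version_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="format"):
            load_model(path)
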