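import numpy as np
import pytest

from spdalign import geometry as geo
from spdalign import plvq
from spdalign import synthetic as syn
from spdalign.data import SPDDataset
from spdalign.exceptions import InvalidInputError

from conftest import random_spd, random_sym


def make_model(log_protos, labels, sigma2=1.0, omega=None):
    log_protos = np.asarray(log_protos, dtype=float)
    M, n = log_protos.shape[0], log_protos.shape[1]
    if omega is None:
        omega = np.eye(n)
    return plvq.PLVQModel(
        log_protos, np.asarray(labels), omega, sigma2, np.full(M, 1.0 / M), 1
    )


def two_class_separable(seed=0, n_per_class=30, sigma=0.1, sep=2.0, n=3):
    """Diagonal classes separated by ~10x the within-class spread."""
    rng = np.random.default_rng(seed)
    m1 = np.diag([-sep / 2, 0.0, 0.0])
    m2 = np.diag([sep / 2, 0.0, 0.0])
    mats, labels = [], []
    for k, m in enumerate((m1, m2), start=1):
        S = syn.sample_symmetric_gaussian(n, n_per_class, rng, sigma)
        for s in S:
            mats.append(geo.sym_expm(m + s))
            labels.append(k)
    return SPDDataset(np.stack(mats), np.asarray(labels))


class TestDistance:
    def test_zero_at_prototype(self, rng):
        X = random_spd(rng, 3)
        Q = random_spd(rng, 3)
        assert plvq.plvq_distance(X, X, Q) == pytest.approx(0.0, abs=1e-20)

    def test_identity_metric_is_squared_lem(self, rng):
        X, W = random_spd(rng, 3), random_spd(rng, 3)
        assert plvq.plvq_distance(X, W, np.eye(3)) == pytest.approx(
            geo.lem_distance(X, W) ** 2, abs=1e-12
        )

    def test_hand_case(self):
        # logX - logW = diag(1, 2), Q = diag(2, 1) -> Tr[diag(2,1) diag(1,4)] = 6
        W = np.eye(2)
        X = np.diag([np.e, np.e**2])
        Q = np.diag([2.0, 1.0])
        assert plvq.plvq_distance(X, W, Q) == pytest.approx(6.0, abs=1e-12)


class TestPosteriors:
    def test_equidistant_uniform(self):
        protos = np.stack([np.diag([1.0, 0.0]), np.diag([-1.0, 0.0]),
                           np.diag([0.0, 1.0]), np.diag([0.0, -1.0])])
        model = make_model(protos, [1, 2, 3, 4])
        class_probs, _ = plvq.plvq_posteriors(np.eye(2), model)
        assert np.allclose(class_probs, 0.25)

    def test_concentration_at_prototype(self):
        protos = np.stack([np.zeros((2, 2)), np.diag([2.0, 2.0])])
        model = make_model(protos, [1, 2], sigma2=0.01)
        class_probs, _ = plvq.plvq_posteriors(np.eye(2), model)
        assert class_probs[0] >= 0.999

    def test_matches_naive_formula(self, rng):
        protos = np.stack([random_sym(rng, 3, 0.3) for _ in range(4)])
        model = make_model(protos, [1, 1, 2, 2], sigma2=1.5)
        X = geo.sym_expm(random_sym(rng, 3, 0.3))
        log_x = geo.sym_logm(X)
        Q = model.q
        # direct evaluation without log-sum-exp
        num = np.array(
            [
                model.priors[j]
                * np.exp(-np.trace(Q @ (log_x - protos[j]) @ (log_x - protos[j]))
                         / (2 * model.sigma2))
                for j in range(4)
            ]
        )
        expected = np.array([num[:2].sum(), num[2:].sum()]) / num.sum()
        class_probs, proto_probs = plvq.plvq_posteriors(X, model)
        assert np.abs(class_probs - expected).max() <= 1e-12
        assert np.abs(proto_probs - num / num.sum()).max() <= 1e-12

    def test_normalization(self, rng):
        protos = np.stack([random_sym(rng, 3) for _ in range(6)])
        model = make_model(protos, [1, 1, 2, 2, 3, 3], sigma2=0.5)
        for _ in range(5):
            cp, pp = plvq.plvq_posteriors(random_spd(rng, 3), model)
            assert cp.sum() == pytest.approx(1.0, abs=1e-12)
            assert pp.sum() == pytest.approx(1.0, abs=1e-12)


class TestCost:
    def test_zero_at_perfect_posterior(self):
        protos = np.stack([np.diag([5.0, 0.0]), np.diag([-5.0, 0.0])])
        model = make_model(protos, [1, 2], sigma2=0.01)
        ds = SPDDataset(
            np.stack([geo.sym_expm(protos[0]), geo.sym_expm(protos[1])]), [1, 2]
        )
        assert plvq.plvq_cost(model, ds) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_posterior_log4(self):
        protos = np.stack([np.zeros((2, 2))] * 4)
        model = make_model(protos, [1, 2, 3, 4])
        ds = SPDDataset(np.eye(2)[None], [1])
        assert plvq.plvq_cost(model, ds) == pytest.approx(np.log(4.0), abs=1e-12)

    def test_decomposes_over_samples(self, rng):
        protos = np.stack([random_sym(rng, 3, 0.5) for _ in range(4)])
        model = make_model(protos, [1, 1, 2, 2], sigma2=2.0)
        mats = np.stack([random_spd(rng, 3) for _ in range(6)])
        labels = np.array([1, 2, 1, 2, 1, 2])
        ds = SPDDataset(mats, labels)
        total = 0.0
        for X, y in zip(mats, labels):
            cp, _ = plvq.plvq_posteriors(X, model)
            total += -np.log(cp[y - 1])
        assert plvq.plvq_cost(model, ds) == pytest.approx(total, abs=1e-12)

    def test_requires_labels(self, rng):
        model = make_model(np.stack([random_sym(rng, 2)]), [1])
        with pytest.raises(InvalidInputError):
            plvq.plvq_cost(model, SPDDataset(np.eye(2)[None]))


class TestUpdateStep:
    def test_prototype_at_sample_unchanged(self, rng):
        W1 = random_sym(rng, 3, 0.3)
        W2 = random_sym(rng, 3, 0.3) + np.eye(3)
        model = make_model(np.stack([W1, W2]), [1, 2], sigma2=1.0)
        X = geo.sym_expm(W1)
        out = plvq.plvq_update_step(model, X, 1, alpha=0.1)
        # Delta ~ 0 for the matching prototype (up to the logm(expm) round
        # trip): it cannot move beyond floating-point noise
        assert np.abs(out.log_prototypes[0] - W1).max() <= 1e-14

    def test_correct_prototype_moves_toward_sample(self, rng):
        model = make_model(
            np.stack([random_sym(rng, 3, 0.5), random_sym(rng, 3, 0.5)]), [1, 2]
        )
        X = random_spd(rng, 3)
        before = geo.lem_distance(geo.sym_expm(model.log_prototypes[0]), X)
        out = plvq.plvq_update_step(model, X, 1, alpha=0.01)
        after = geo.lem_distance(geo.sym_expm(out.log_prototypes[0]), X)
        assert after < before

    def test_wrong_prototype_moves_away(self, rng):
        model = make_model(
            np.stack([random_sym(rng, 3, 0.5), random_sym(rng, 3, 0.5)]), [1, 2]
        )
        X = random_spd(rng, 3)
        before = geo.lem_distance(geo.sym_expm(model.log_prototypes[1]), X)
        out = plvq.plvq_update_step(model, X, 1, alpha=0.01)
        after = geo.lem_distance(geo.sym_expm(out.log_prototypes[1]), X)
        assert after > before

    def test_invalid_label(self, rng):
        model = make_model(np.stack([random_sym(rng, 2)]), [1])
        with pytest.raises(InvalidInputError):
            plvq.plvq_update_step(model, np.eye(2), 5, alpha=0.1)

    def _fd_instance(self, seed=7):
        rng = np.random.default_rng(seed)
        protos = np.stack([random_sym(rng, 3, 0.4) for _ in range(4)])
        omega = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        omega *= np.sqrt(3 / np.trace(omega @ omega.T))
        model = plvq.PLVQModel(
            protos, np.array([1, 1, 2, 2]), omega, 1.3, np.full(4, 0.25), 2
        )
        log_x = random_sym(rng, 3, 0.4)
        return model, log_x, 1

    def _sample_cost(self, model, log_x, y):
        return plvq._cost_from_logs(model, log_x[None], np.array([y]))

    def test_prototype_gradient_matches_finite_differences(self):
        model, log_x, y = self._fd_instance()
        grad_w, _ = plvq._gradients(
            model.log_prototypes, model.proto_labels, model.omega,
            model.priors, model.sigma2, log_x, y,
        )
        h = 1e-6
        for l in range(4):
            fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(i, 3):
                    for sgn in (1, -1):
                        m = model.copy()
                        m.log_prototypes[l][i, j] += sgn * h
                        m.log_prototypes[l][j, i] = m.log_prototypes[l][i, j]
                        fd[i, j] += sgn * self._sample_cost(m, log_x, y)
                    fd[i, j] /= 2 * h
                    fd[j, i] = fd[i, j]
            # off-diagonal symmetric perturbation moves two entries at once:
            # the fd value is d/dt E(logW + t(Eij+Eji)) = 2 * gradient entry
            analytic = grad_w[l] * (2 - np.eye(3))
            denom = max(np.abs(analytic).max(), 1e-12)
            assert np.abs(analytic - fd).max() / denom <= 1e-4

    def test_omega_gradient_matches_finite_differences(self):
        model, log_x, y = self._fd_instance()
        _, grad_o = plvq._gradients(
            model.log_prototypes, model.proto_labels, model.omega,
            model.priors, model.sigma2, log_x, y,
        )
        h = 1e-6
        fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                for sgn in (1, -1):
                    m = model.copy()
                    m.omega[i, j] += sgn * h
                    fd[i, j] += sgn * self._sample_cost(m, log_x, y)
                fd[i, j] /= 2 * h
        assert np.abs(grad_o - fd).max() / max(np.abs(grad_o).max(), 1e-12) <= 1e-4

    def test_q_stays_psd_over_updates(self, rng):
        ds = two_class_separable(seed=1)
        model = plvq.plvq_fit(
            ds, 2, 1.0, plvq.LearningSchedule(n=3, xi=2, T=5), seed=0
        )
        assert np.linalg.eigvalsh(model.q).min() >= -1e-10
        assert np.trace(model.q) == pytest.approx(3.0)


class TestFit:
    def test_separable_benchmark_perfect_training_accuracy(self):
        ds = two_class_separable(seed=2, sigma=0.1, sep=2.0)
        model = plvq.plvq_fit(
            ds, 1, 1.0, plvq.LearningSchedule(n=3, xi=1, T=50), seed=0
        )
        pred = plvq.plvq_predict(model, ds)
        assert np.mean(pred == ds.labels) == 1.0

    def test_cost_trace_decreases_initially(self):
        ds = two_class_separable(seed=2, sigma=0.1, sep=2.0)
        model = plvq.plvq_fit(
            ds, 1, 1.0, plvq.LearningSchedule(n=3, xi=1, T=12), seed=0
        )
        trace = np.asarray(model.cost_trace[:10])
        assert np.all(np.diff(trace) <= 1e-8)

    def test_zero_rates_keep_initialization(self):
        class ZeroSchedule:
            T, t0 = 3, 1

            def alpha(self, t):
                return 0.0

            def eta(self, t):
                return 0.0

        ds = two_class_separable(seed=3)
        model = plvq.plvq_fit(ds, 1, 1.0, ZeroSchedule(), seed=0)
        init = plvq._init_model(ds, 1, 1.0, np.random.default_rng(0))
        assert np.array_equal(model.log_prototypes, init.log_prototypes)
        assert np.array_equal(model.omega, init.omega)

    def test_too_few_samples_per_class(self):
        ds = two_class_separable(seed=4, n_per_class=2)
        with pytest.raises(InvalidInputError):
            plvq.plvq_fit(ds, 3, 1.0, plvq.LearningSchedule(n=3, xi=3, T=2), seed=0)

    def test_prototype_recovery(self):
        # 1 prototype/class should land near the true class means
        rng = np.random.default_rng(11)
        m1, m2 = np.diag([-1.0, 0.0, 0.0]), np.diag([1.0, 0.0, 0.0])
        mats, labels = [], []
        for k, m in enumerate((m1, m2), 1):
            for s in syn.sample_symmetric_gaussian(3, 100, rng, 0.1):
                mats.append(geo.sym_expm(m + s))
                labels.append(k)
        ds = SPDDataset(np.stack(mats), np.asarray(labels))
        # sigma2 small enough that cross-class responsibilities vanish;
        # with overlapping posteriors the cost optimum sits outside the
        # class means (prototypes repel) and recovery cannot be expected
        model = plvq.plvq_fit(
            ds, 1, 0.25, plvq.LearningSchedule(n=3, xi=1, T=30), seed=0
        )
        for proto, true_m in zip(model.log_prototypes, (m1, m2)):
            assert np.linalg.norm(proto - true_m, "fro") <= 0.2


class TestPredict:
    def test_sample_at_prototype(self, rng):
        protos = np.stack([np.diag([2.0, 0.0]), np.diag([-2.0, 0.0])])
        model = make_model(protos, [1, 2], sigma2=0.01)
        ds = SPDDataset(geo.sym_expm(protos[1])[None])
        assert plvq.plvq_predict(model, ds)[0] == 2

    def test_agrees_with_bruteforce_posterior(self, rng):
        protos = np.stack([random_sym(rng, 3, 0.5) for _ in range(6)])
        model = make_model(protos, [1, 1, 2, 2, 3, 3], sigma2=1.0)
        mats = np.stack([random_spd(rng, 3) for _ in range(100)])
        ds = SPDDataset(mats)
        pred = plvq.plvq_predict(model, ds)
        for i, X in enumerate(mats):
            cp, _ = plvq.plvq_posteriors(X, model)
            assert pred[i] == np.argmax(cp) + 1

    def test_prototype_order_irrelevant(self, rng):
        protos = np.stack([random_sym(rng, 3, 0.5) for _ in range(4)])
        labels = np.array([1, 2, 1, 2])
        model = make_model(protos, labels)
        perm = np.array([2, 0, 3, 1])
        permuted = make_model(protos[perm], labels[perm])
        ds = SPDDataset(np.stack([random_spd(rng, 3) for _ in range(10)]))
        assert np.array_equal(
            plvq.plvq_predict(model, ds), plvq.plvq_predict(permuted, ds)
        )


class TestMDRM:
    def test_sample_at_class_mean(self):
        ds = two_class_separable(seed=5)
        model = plvq.mdrm_fit(ds)
        pred = plvq.mdrm_predict(
            model, SPDDataset(model.class_means[2][None])
        )
        assert pred[0] == 2

    def test_bruteforce_agreement(self, rng):
        ds = two_class_separable(seed=6)
        model = plvq.mdrm_fit(ds)
        test = SPDDataset(np.stack([random_spd(rng, 3) for _ in range(50)]))
        pred = plvq.mdrm_predict(model, test)
        for i, X in enumerate(test.matrices):
            d = {k: geo.lem_distance(m, X) for k, m in model.class_means.items()}
            assert pred[i] == min(sorted(d), key=lambda k: d[k])

    def test_commuting_lem_airm_agree(self):
        rng = np.random.default_rng(7)
        mats = np.stack([np.diag(np.exp(rng.normal(0, 1, 3))) for _ in range(20)])
        labels = (np.arange(20) % 2) + 1
        ds = SPDDataset(mats, labels)
        test = SPDDataset(np.stack([np.diag(np.exp(rng.normal(0, 1, 3))) for _ in range(10)]))
        m_lem = plvq.mdrm_fit(ds, "lem")
        m_airm = plvq.mdrm_fit(ds, "airm")
        assert np.array_equal(
            plvq.mdrm_predict(m_lem, test), plvq.mdrm_predict(m_airm, test)
        )


class TestGridSearch:
    def test_single_point_grid(self):
        ds = two_class_separable(seed=8, n_per_class=15)
        best = plvq.grid_search_cv(ds, (2,), (1.5,), folds=3, seed=0, schedule_T=5)
        assert best[0] == 2 and best[1] == 1.5

    def test_separable_data_perfect_configuration_wins(self):
        ds = two_class_separable(seed=9, n_per_class=15, sigma=0.05, sep=3.0)
        n, s2, score = plvq.grid_search_cv(
            ds, (1, 2), (0.5, 1.0), folds=3, seed=0, schedule_T=10
        )
        assert score == pytest.approx(1.0)
        assert n == 1 and s2 == 0.5  # tie-break to the smallest grid point

    def test_deterministic_under_seed(self):
        ds = two_class_separable(seed=10, n_per_class=15)
        a = plvq.grid_search_cv(ds, (1, 2), (1.0,), folds=3, seed=4, schedule_T=5)
        b = plvq.grid_search_cv(ds, (1, 2), (1.0,), folds=3, seed=4, schedule_T=5)
        assert a == b


class TestScheduleAndSerialization:
    def test_schedule_formulas(self):
        sched = plvq.LearningSchedule(n=8, xi=2, T=100, t0=1)
        assert sched.alpha(100) == pytest.approx((8 * 2 / 100) * 0.01)
        assert sched.eta(100) == pytest.approx((8 * 2 / 10000) * 0.01)
        for t in range(1, 101):
            assert sched.eta(t) < sched.alpha(t)

    def test_model_json_roundtrip(self, rng, tmp_path):
        ds = two_class_separable(seed=12)
        model = plvq.plvq_fit(ds, 1, 1.0, plvq.LearningSchedule(n=3, xi=1, T=3), seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = plvq.PLVQModel.from_json(path)
        assert np.array_equal(model.log_prototypes, back.log_prototypes)
        assert np.array_equal(model.omega, back.omega)
        assert model.sigma2 == back.sigma2
        assert np.array_equal(model.priors, back.priors)
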