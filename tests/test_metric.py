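"""Pair scatters, the CFML eigen solution, and the learned distance."""

import numpy as np
import pytest
from scipy import linalg

from regionbow.metric import (
    MetricModel,
    compute_scatters,
    fit_cfml,
    mahalanobis_distance,
    pairwise_distances,
)
from regionbow.pipeline import within_between_ratio


def _scatter_oracle(features, labels):
    """Explicit pair-loop enumeration of M_S and M_D."""
    sim, dis = [], []
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            d = features[i] - features[j]
            (sim if labels[i] == labels[j] else dis).append(np.outer(d, d))
    return np.mean(sim, axis=0), np.mean(dis, axis=0)


# --- scatters ----------------------------------------------------------------


def test_two_samples_same_label():
    x = np.array([[1.0, 2.0], [3.0, 1.0]])
    with pytest.raises(ValueError, match="dissimilar"):
        compute_scatters(x, np.array([0, 0]))


def test_single_sample_classes_give_no_similar_pairs():
    x = np.eye(3)
    with pytest.raises(ValueError, match="similar"):
        compute_scatters(x, np.array([0, 1, 2]))


def test_three_samples_hand_enumeration():
    x = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
    labels = np.array([0, 0, 1])
    sc = compute_scatters(x, labels)
    v = x[0] - x[1]
    assert np.allclose(sc.m_similar, np.outer(v, v))
    d1, d2 = x[0] - x[2], x[1] - x[2]
    assert np.allclose(sc.m_dissimilar, (np.outer(d1, d1) + np.outer(d2, d2)) / 2)
    assert sc.n_similar == 1 and sc.n_dissimilar == 2


def test_scatters_match_pair_loop_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((12, 5))
    labels = rng.integers(0, 3, 12)
    if len(np.unique(labels)) < 2:  # pragma: no cover - seed-dependent guard
        labels[0] = (labels[0] + 1) % 3
    sc = compute_scatters(x, labels)
    m_s, m_d = _scatter_oracle(x, labels)
    assert np.allclose(sc.m_similar, m_s, atol=1e-10)
    assert np.allclose(sc.m_dissimilar, m_d, atol=1e-10)


def test_duplicating_every_sample_leaves_m_dissimilar_unchanged():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 4))
    labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
    sc = compute_scatters(x, labels)
    sc_dup = compute_scatters(np.vstack([x, x]), np.concatenate([labels, labels]))
    # every cross-class difference appears 4x instead of 1x: the mean is fixed
    assert np.allclose(sc.m_dissimilar, sc_dup.m_dissimilar, atol=1e-10)


# --- CFML fit ----------------------------------------------------------------


def _two_class_toy(rng, n=400, gap=4.0, sd=0.25, dim=2):
    a = rng.standard_normal((n, dim)) * sd
    b = rng.standard_normal((n, dim)) * sd
    a[:, 0] += gap / 2
    b[:, 0] -= gap / 2
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


def test_top_direction_recovers_discriminative_axis():
    x, labels = _two_class_toy(np.random.default_rng(2))
    model = fit_cfml(compute_scatters(x, labels), lam=1e-6, dim_out=2)
    v = model.projection[0] / np.linalg.norm(model.projection[0])
    angle = np.degrees(np.arccos(min(1.0, abs(v[0]))))
    assert angle <= 5.0


def test_constraint_satisfied_to_1e6():
    x, labels = _two_class_toy(np.random.default_rng(3), dim=6)
    sc = compute_scatters(x, labels)
    lam = 1e-6
    model = fit_cfml(sc, lam=lam, dim_out=3)
    b = sc.m_similar + lam * np.eye(6)
    gram = model.projection @ b @ model.projection.T
    assert np.abs(gram - np.eye(3)).max() <= 1e-6


def test_equal_scatters_give_unit_eigenvalues_and_zero_objective():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((5, 5))
    m = a @ a.T + np.eye(5)
    from regionbow.metric import PairScatter

    sc = PairScatter(m_similar=m, m_dissimilar=m, n_similar=1, n_dissimilar=1)
    model = fit_cfml(sc, lam=1e-6, dim_out=2)
    assert np.allclose(model.eigenvalues, 1.0, atol=1e-4)
    obj = np.trace(model.projection @ (m - m) @ model.projection.T)
    assert obj == pytest.approx(0.0, abs=1e-10)


def test_eigen_solution_matches_dense_brute_force():
    rng = np.random.default_rng(5)
    for dim in (5, 12, 20):
        x = rng.standard_normal((30, dim))
        labels = rng.integers(0, 3, 30)
        sc = compute_scatters(x, labels)
        lam = 1e-6
        model = fit_cfml(sc, lam=lam, dim_out=dim)
        b_inv_a = np.linalg.solve(sc.m_similar + lam * np.eye(dim), sc.m_dissimilar)
        brute = np.sort(np.linalg.eigvals(b_inv_a).real)[::-1]
        assert np.allclose(np.sort(model.eigenvalues)[::-1], brute, atol=1e-8)


def test_solution_beats_random_constraint_satisfying_projections():
    rng = np.random.default_rng(6)
    x = rng.standard_normal((40, 8))
    labels = rng.integers(0, 2, 40)
    sc = compute_scatters(x, labels)
    lam = 1e-3
    d = 2
    model = fit_cfml(sc, lam=lam, dim_out=d)
    diff = sc.m_similar - sc.m_dissimilar
    best = np.trace(model.projection @ diff @ model.projection.T)
    b = sc.m_similar + lam * np.eye(8)
    chol = np.linalg.cholesky(b)
    for _ in range(100):
        # random L with L B L^T = I: orthonormal rows in the B-metric
        q, _ = np.linalg.qr(rng.standard_normal((8, d)))
        l_rand = np.linalg.solve(chol.T, q).T
        assert np.allclose(l_rand @ b @ l_rand.T, np.eye(d), atol=1e-8)
        assert best <= np.trace(l_rand @ diff @ l_rand.T) + 1e-10


def test_dim_out_validation_and_reduction():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((20, 4))
    labels = rng.integers(0, 2, 20)
    sc = compute_scatters(x, labels)
    with pytest.raises(ValueError):
        fit_cfml(sc, dim_out=0)
    with pytest.raises(ValueError):
        fit_cfml(sc, lam=0.0)
    with pytest.warns(UserWarning, match="projection rows"):
        model = fit_cfml(sc, dim_out=10)
    assert model.dim_out == 4


def test_fit_is_deterministic():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((30, 6))
    labels = rng.integers(0, 3, 30)
    sc = compute_scatters(x, labels)
    a = fit_cfml(sc, dim_out=2)
    b = fit_cfml(sc, dim_out=2)
    assert np.array_equal(a.projection, b.projection)


# --- distance ----------------------------------------------------------------


def test_distance_basics():
    rng = np.random.default_rng(9)
    l = rng.standard_normal((2, 5))
    model = MetricModel(projection=l, lam=1e-6)
    x = rng.standard_normal(5)
    y = rng.standard_normal(5)
    assert mahalanobis_distance(model, x, x) == 0.0
    assert mahalanobis_distance(model, x, y) == mahalanobis_distance(model, y, x)
    # dense matrix-form oracle
    oracle = (x - y) @ l.T @ l @ (x - y)
    assert mahalanobis_distance(model, x, y) == pytest.approx(oracle)


def test_identity_projection_is_squared_euclidean():
    model = MetricModel(projection=np.eye(4), lam=1e-6)
    x, y = np.arange(4.0), np.ones(4)
    assert mahalanobis_distance(model, x, y) == pytest.approx(((x - y) ** 2).sum())


def test_dimension_mismatch_raises():
    model = MetricModel(projection=np.eye(3), lam=1e-6)
    with pytest.raises(ValueError):
        mahalanobis_distance(model, np.zeros(3), np.zeros(4))


def test_root_distance_triangle_inequality():
    rng = np.random.default_rng(10)
    model = MetricModel(projection=rng.standard_normal((3, 6)), lam=1e-6)
    for _ in range(200):
        a, b, c = rng.standard_normal((3, 6))
        dab = np.sqrt(mahalanobis_distance(model, a, b))
        dbc = np.sqrt(mahalanobis_distance(model, b, c))
        dac = np.sqrt(mahalanobis_distance(model, a, c))
        assert dac <= dab + dbc + 1e-12


def test_pairwise_matches_scalar_distance():
    rng = np.random.default_rng(11)
    model = MetricModel(projection=rng.standard_normal((2, 5)), lam=1e-6)
    q = rng.standard_normal(5)
    data = rng.standard_normal((10, 5))
    d = pairwise_distances(model, q, data)
    for i in range(10):
        assert d[i] == pytest.approx(mahalanobis_distance(model, q, data[i]))


def test_learned_metric_tightens_classes_vs_euclidean():
    """On separable 3-class features the within/between ratio drops."""
    rng = np.random.default_rng(12)
    means = np.zeros((3, 10))
    means[0, 0], means[1, 1], means[2, 2] = 3.0, 3.0, 3.0
    x = np.vstack([rng.standard_normal((20, 10)) * 0.5 + means[c] for c in range(3)])
    labels = np.repeat(np.arange(3), 20)
    model = fit_cfml(compute_scatters(x, labels), lam=1e-6, dim_out=2)
    assert within_between_ratio(x, labels, model) < within_between_ratio(x, labels)
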