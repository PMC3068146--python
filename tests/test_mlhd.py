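"""MLHD discriminant: closed-form oracles, CV estimators, degenerate inputs."""

import numpy as np
import pytest

from tissuesig import CVConfig, fit_mlhd, inner_cv_accuracy, outer_accuracy, predict_mlhd
from tissuesig.datasets import SyntheticConfig, generate_paired
from tissuesig.mlhd import FitError

from conftest import make_dataset


def brute_force_discriminant(x_train, y_train, x_test, priors_mode="empirical"):
    """Independent evaluator: explicit inverse, explicit per-class loops."""
    classes = sorted(set(y_train.tolist()))
    n, p = x_train.shape
    mus, cov = [], np.zeros((p, p))
    for c in classes:
        xc = x_train[y_train == c]
        mu = xc.mean(axis=0)
        mus.append(mu)
        for row in xc:
            d = (row - mu).reshape(-1, 1)
            cov += d @ d.T
    cov /= n - len(classes)
    inv = np.linalg.inv(cov)
    out = []
    for x in x_test:
        scores = []
        for c, mu in zip(classes, mus):
            prior = (y_train == c).mean() if priors_mode == "empirical" else 1 / len(classes)
            scores.append(x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(prior))
        out.append(classes[int(np.argmax(scores))])
    return np.array(out)


def test_predictions_match_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n, p = int(rng.integers(8, 21)), int(rng.integers(1, 5))
        x = rng.standard_normal((n, p))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=n // 2, replace=False)] = 1
        ds = make_dataset(x, y)
        model = fit_mlhd(ds, "gleason", range(p))
        pred, scores = predict_mlhd(model, x)
        assert scores.shape == (n, 2)
        expected = brute_force_discriminant(x, y, x)
        assert np.array_equal(pred, expected)


def test_univariate_boundary_at_class_mean_midpoint():
    """Classes at means 1 and 5 with equal pooled variance split at 3."""
    x = np.array([[0.0], [0.0], [2.0], [2.0], [4.0], [4.0], [6.0], [6.0]])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    model = fit_mlhd(make_dataset(x, y), "gleason", [0])
    pred, _ = predict_mlhd(model, np.array([[2.9], [3.1]]))
    assert list(pred) == [0, 1]


def test_identical_classes_tie_resolved_to_lowest_class():
    x = np.tile(np.array([[1.0, 2.0], [3.0, 1.0]]), (2, 1))
    y = np.array([0, 0, 1, 1])
    model = fit_mlhd(make_dataset(x, y), "gleason", [0, 1])
    assert np.allclose(model.class_means[0], model.class_means[1])
    pred, scores = predict_mlhd(model, x)
    assert np.allclose(scores[:, 0], scores[:, 1])
    assert (pred == 0).all()


def test_point_at_class_mean_and_separable_resubstitution():
    rng = np.random.default_rng(3)
    x = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(6, 0.2, (10, 2))])
    y = np.repeat([0, 1], 10)
    model = fit_mlhd(make_dataset(x, y), "gleason", [0, 1], priors="equal")
    pred, _ = predict_mlhd(model, model.class_means)
    assert list(pred) == [0, 1]
    pred, _ = predict_mlhd(model, x)
    assert (pred == y).all()


def test_fit_and_predict_errors():
    x = np.arange(12, dtype=float).reshape(6, 2)
    ds = make_dataset(x, [0, 0, 0, 0, 0, 1])
    with pytest.raises(FitError, match="fewer than 2"):
        fit_mlhd(ds, "gleason", [0, 1])
    ds2 = make_dataset(x, [0, 0, 0, 1, 1, 1])
    with pytest.raises(FitError, match="duplicate"):
        fit_mlhd(ds2, "gleason", [0, 0])
    model = fit_mlhd(ds2, "gleason", [0, 1])
    with pytest.raises(ValueError, match="columns"):
        predict_mlhd(model, np.zeros((2, 3)))


def test_priors_shift_decision():
    x = np.array([[0.0], [2.0], [4.0], [6.0], [4.5], [5.5]])
    y = np.array([0, 0, 0, 0, 1, 1])
    at = np.array([[3.4]])  # left of the equal-prior boundary (mean midpoint 4)
    eq = fit_mlhd(make_dataset(x, y), "gleason", [0], priors="equal")
    emp = fit_mlhd(make_dataset(x, y), "gleason", [0], priors="empirical")
    assert np.isclose(eq.priors, [0.5, 0.5]).all()
    assert np.isclose(emp.priors, [4 / 6, 2 / 6]).all()
    assert predict_mlhd(emp, at)[0][0] == 0
    # scores differ exactly by the log prior ratio
    _, s_eq = predict_mlhd(eq, at)
    _, s_emp = predict_mlhd(emp, at)
    gap = (s_emp - s_eq)[0]
    assert np.allclose(gap, np.log([4 / 6, 2 / 6]) - np.log(0.5))


def test_ridge_handles_singular_covariance():
    """p > n and duplicated columns: ridge escalation keeps the fit usable."""
    rng = np.random.default_rng(5)
    base = rng.standard_normal((8, 2))
    x = np.hstack([base, base, base, base, base])  # rank 2, p = 10
    y = np.repeat([0, 1], 4)
    x[y == 1] += 2.0
    model = fit_mlhd(make_dataset(x, y), "gleason", range(10))
    assert model.ridge > 0
    pred, _ = predict_mlhd(model, x)
    assert (pred == y).mean() == 1.0


def test_inner_cv_matches_manual_leave_one_out():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((12, 3))
    y = np.tile([0, 1], 6)
    x[y == 1] += 1.0
    ds = make_dataset(x, y)
    acc = inner_cv_accuracy(ds, "gleason", [0, 1, 2], CVConfig(inner_k=12, seed=0))
    hits = []
    for i in range(12):
        tr = np.setdiff1d(np.arange(12), [i])
        pred = brute_force_discriminant(x[tr], y[tr], x[[i]])
        hits.append(pred[0] == y[i])
    assert acc == pytest.approx(np.mean(hits))


def test_inner_cv_null_and_signal_levels():
    rng = np.random.default_rng(1)
    cv = CVConfig(inner_k=5, seed=4)
    y = np.tile([0, 1], 50)
    null_accs = [
        inner_cv_accuracy(
            make_dataset(rng.standard_normal((100, 4)), y), "gleason", range(4), cv
        )
        for _ in range(5)
    ]
    # label-independent data: accuracy hovers around chance for most draws
    assert sum(0.35 <= a <= 0.65 for a in null_accs) >= 4
    assert 0.4 <= np.mean(null_accs) <= 0.6

    x2 = rng.standard_normal((60, 5))
    y2 = np.tile([0, 1], 30)
    x2[y2 == 1] += 3.0  # strongly separable planted signal
    assert inner_cv_accuracy(make_dataset(x2, y2), "gleason", range(5), cv) >= 0.95


def test_outer_accuracy_null_and_signal_levels():
    rng = np.random.default_rng(2)
    cv = CVConfig(outer_splits=40, seed=8)
    x = rng.standard_normal((90, 4))
    y = np.tile([0, 1], 45)
    mean, per_split = outer_accuracy(make_dataset(x, y), "gleason", range(4), cv)
    assert len(per_split) == 40
    se = per_split.std(ddof=1) / np.sqrt(40)
    assert abs(mean - 0.5) <= max(3 * se, 0.1)

    x2 = rng.standard_normal((60, 5))
    y2 = np.tile([0, 1], 30)
    x2[y2 == 1] += 3.0
    mean2, _ = outer_accuracy(make_dataset(x2, y2), "gleason", range(5), cv)
    assert mean2 >= 0.9

    single = CVConfig(outer_splits=1, seed=8)
    a, _ = outer_accuracy(make_dataset(x2, y2), "gleason", range(5), single)
    b, _ = outer_accuracy(make_dataset(x2, y2), "gleason", range(5), single)
    assert a == b


def test_accuracy_invariant_to_gene_order(small_paired):
    normal, _ = small_paired
    cv = CVConfig(seed=3)
    genes = [4, 0, 2, 1]
    a = inner_cv_accuracy(normal, "gleason", genes, cv)
    b = inner_cv_accuracy(normal, "gleason", list(reversed(genes)), cv)
    assert a == b
    ma, _ = outer_accuracy(normal, "gleason", genes, cv)
    mb, _ = outer_accuracy(normal, "gleason", list(reversed(genes)), cv)
    assert ma == mb
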