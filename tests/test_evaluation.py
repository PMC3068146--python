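"""Specificity swap test and PCA gene-contribution analysis."""

import numpy as np
import pytest
from scipy import stats

from tissuesig import (
    CVConfig,
    GAConfig,
    SelectorConfig,
    SyntheticConfig,
    ga_mlhd_selector,
    generate_paired,
    pca_contributions,
    specificity_test,
)
from tissuesig.datasets import PairingError

from conftest import make_dataset

FAST_SELECTOR = SelectorConfig(
    ga=GAConfig(population_size=20, generations=8, n_runs=6), max_size=8
)


def _paired(seed, signal_tissue="normal", effect=2.0, n_genes=200):
    cfg = SyntheticConfig(
        n_patients=40, n_genes=n_genes, n_informative=6, effect_size=effect,
        signal_tissue=signal_tissue, seed=seed, endpoints=("gleason",),
    )
    return generate_paired(cfg)


def test_identical_tissue_control_gives_equal_accuracies():
    """With the tumour data replaced by the normal data, Step 2 == Step 1."""
    normal, _ = _paired(3)
    mirror = normal.subset_samples(range(normal.n_samples))
    mirror.tissue = "tumour"
    res = specificity_test(
        normal, mirror, "gleason", selector=ga_mlhd_selector(FAST_SELECTOR),
        n_repeats=2, seed=0,
    )
    assert np.array_equal(res.same_tissue_accuracies, res.cross_tissue_accuracies)


def test_tissue_specific_signal_collapses_across_tissues():
    normal, tumour = _paired(5, signal_tissue="normal")
    res = specificity_test(
        normal, tumour, "gleason", selector=ga_mlhd_selector(FAST_SELECTOR),
        n_repeats=3, seed=1,
    )
    assert res.same_tissue_accuracy >= 0.8
    assert 0.25 <= res.cross_tissue_accuracy <= 0.7
    assert res.n_repeats == 3 and len(res.signatures) == 3


def test_shared_signal_survives_the_swap():
    normal, tumour = _paired(7, signal_tissue="both")
    res = specificity_test(
        normal, tumour, "gleason", selector=ga_mlhd_selector(FAST_SELECTOR),
        n_repeats=2, seed=2,
    )
    assert res.cross_tissue_accuracy >= 0.85


def test_swap_symmetric_between_tissues():
    """Signature tissue and probe tissue play symmetric roles."""
    as_normal, as_tumour = [], []
    for seed in range(6):
        n1, t1 = _paired(50 + seed, signal_tissue="normal", n_genes=120)
        r1 = specificity_test(
            n1, t1, "gleason", signature_tissue="normal",
            selector=ga_mlhd_selector(FAST_SELECTOR), n_repeats=1, seed=seed,
        )
        as_normal.append(r1.same_tissue_accuracy)
        n2, t2 = _paired(80 + seed, signal_tissue="tumour", n_genes=120)
        r2 = specificity_test(
            n2, t2, "gleason", signature_tissue="tumour",
            selector=ga_mlhd_selector(FAST_SELECTOR), n_repeats=1, seed=seed,
        )
        as_tumour.append(r2.same_tissue_accuracy)
    assert stats.ttest_ind(as_normal, as_tumour).pvalue > 0.01


def test_unpaired_datasets_rejected():
    normal, _ = _paired(9)
    other, _ = _paired(10)
    stranger = other.subset_samples(range(other.n_samples))
    stranger.tissue = "tumour"
    stranger.patient_id = [f"Q{i}" for i in range(stranger.n_samples)]
    with pytest.raises(PairingError):
        specificity_test(normal, stranger, "gleason", n_repeats=1)


# ---------------------------------------------------------------------------
# PCA loadings
# ---------------------------------------------------------------------------


def test_two_correlated_genes_rank_one():
    rng = np.random.default_rng(0)
    g = rng.standard_normal(30)
    x = np.column_stack([g, 2.0 * g])
    ds = make_dataset(x, np.tile([0, 1], 15))
    profiles, scores = pca_contributions(ds, [0, 1], n_components=2)
    assert profiles[0].explained_variance_fraction == pytest.approx(1.0)
    v = np.abs(profiles[0].loadings)
    assert not np.allclose(v, [1 / np.sqrt(2), 1 / np.sqrt(2)])  # unequal scales
    # equal-scale version: loadings exactly 1/sqrt(2) each
    ds2 = make_dataset(np.column_stack([g, g]), np.tile([0, 1], 15))
    p2, _ = pca_contributions(ds2, [0, 1], n_components=1)
    assert np.allclose(np.abs(p2[0].loadings), 1 / np.sqrt(2))
    assert p2[0].explained_variance_fraction == pytest.approx(1.0)


def test_loadings_match_eigendecomposition():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((25, 6)) @ rng.standard_normal((6, 6))
    ds = make_dataset(x, np.tile([0, 1], 13)[:25])
    profiles, scores = pca_contributions(ds, range(6), n_components=4)
    cov = np.cov(x, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for k, prof in enumerate(profiles):
        assert np.allclose(np.abs(prof.loadings), np.abs(evecs[:, k]), atol=1e-8)
        assert prof.explained_variance_fraction == pytest.approx(
            evals[k] / evals.sum(), abs=1e-8
        )
        assert prof.loadings[np.argmax(np.abs(prof.loadings))] > 0  # sign convention
    # variance fractions sum to <= 1
    total = sum(p.explained_variance_fraction for p in profiles)
    assert total <= 1 + 1e-9


def test_planted_shift_dominates_separating_component():
    rng = np.random.default_rng(2)
    y = np.tile([0, 1], 20)
    x = rng.standard_normal((40, 6))
    x[y == 1, :4] += 3.0  # four signature genes carry the class shift
    ds = make_dataset(x, y)
    profiles, scores = pca_contributions(ds, range(6), n_components=2)
    sep = max(
        profiles,
        key=lambda p: abs(
            scores[y == 1, p.component_index - 1].mean()
            - scores[y == 0, p.component_index - 1].mean()
        ),
    )
    assert all(abs(l) > 0.3 for l in sep.loadings[:4])
    assert set(sep.highlighted) >= {"G000", "G001", "G002", "G003"}


def test_constant_genes_dropped_with_warning():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((15, 4))
    x[:, 1] = 7.0
    ds = make_dataset(x, np.tile([0, 1], 8)[:15])
    with pytest.warns(UserWarning, match="constant"):
        profiles, _ = pca_contributions(ds, range(4), n_components=2)
    assert profiles[0].genes == ["G000", "G002", "G003"]
    x2 = np.column_stack([x[:, 1], x[:, 1]])
    ds2 = make_dataset(x2, np.tile([0, 1], 8)[:15])
    with pytest.warns(UserWarning), pytest.raises(ValueError):
        pca_contributions(ds2, range(2), n_components=1)


def test_scores_invariant_to_gene_order_up_to_sign():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((20, 5))
    ds = make_dataset(x, np.tile([0, 1], 10))
    _, s1 = pca_contributions(ds, [0, 1, 2, 3, 4], n_components=3)
    _, s2 = pca_contributions(ds, [4, 2, 0, 3, 1], n_components=3)
    for k in range(3):
        assert np.allclose(s1[:, k], s2[:, k], atol=1e-8) or np.allclose(
            s1[:, k], -s2[:, k], atol=1e-8
        )
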