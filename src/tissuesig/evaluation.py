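"""Tissue specificity of gene signatures, and per-gene PCA contributions.

The swap test asks whether a signature selected in one tissue compartment
carries class information in the other.  Step 1 selects a signature on the
signature tissue's training patients (2/3 of patients) and records its test
accuracy there; Step 2 restricts the *other* tissue's data to the same
genes, retrains the discriminant on that tissue's training patients and
records its test accuracy.  A tissue-specific signature keeps its Step 1
accuracy but falls to chance (~50%) in Step 2.  Patients are co-assigned
to train or test in both tissues, so no patient seen in training is ever
tested in either compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .datasets import ExpressionDataset, check_paired
from .ga import GAConfig, evolve
from .mlhd import CVConfig, fit_mlhd, predict_mlhd
from .summary import best_per_run_frequency, forward_select_representative, gene_frequency

Selector = Callable[[ExpressionDataset, str, int], list[int]]


@dataclass(frozen=True)
class SelectorConfig:
    """How Step 1 picks a signature from the training data.

    The GA runs ``ga.n_runs`` independent searches; genes are then ranked
    either by their frequency across each run's best chromosome
    (``ranking="best_per_run"``, the default — replication across
    independent searches is what separates informative genes from
    run-specific passengers) or by inclusion frequency in the top
    ``top_fraction`` of all evaluated models (``ranking="top_fraction"``).
    The signature is the top ``max_size`` ranked genes, or the outcome of
    greedy forward selection down the ranking when ``forward_select``.
    """

    ga: GAConfig = GAConfig(n_runs=20)
    cv: CVConfig = CVConfig()
    ranking: str = "best_per_run"
    top_fraction: float = 0.01
    max_size: int = 10
    forward_select: bool = False


def ga_mlhd_selector(cfg: SelectorConfig = SelectorConfig()) -> Selector:
    """Build a Step 1 signature selector around the GA-MLHD engine."""
    if cfg.ranking not in ("best_per_run", "top_fraction"):
        raise ValueError("ranking must be 'best_per_run' or 'top_fraction'")

    def select(train_ds: ExpressionDataset, endpoint: str, seed: int) -> list[int]:
        from dataclasses import replace

        ga_cfg = replace(cfg.ga, seed=seed)
        cv = replace(cfg.cv, seed=seed)
        pop = evolve(train_ds, endpoint, ga_cfg, cv)
        if cfg.ranking == "best_per_run":
            ranked = best_per_run_frequency(pop)["gene"].tolist()
        else:
            ranked = gene_frequency(pop, cfg.top_fraction)["gene"].tolist()
        if cfg.forward_select:
            model = forward_select_representative(
                ranked, train_ds, endpoint, cv, max_size=cfg.max_size
            )
            return [train_ds.gene_ids.index(g) for g in model.genes]
        return [int(g) for g in ranked[: cfg.max_size]]

    return select


@dataclass
class SpecificityResult:
    """Same-tissue vs cross-tissue accuracies of a signature, over repeats."""

    endpoint: str
    signature_tissue: str
    n_repeats: int
    same_tissue_accuracies: np.ndarray
    cross_tissue_accuracies: np.ndarray
    signatures: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.same_tissue_accuracies) != self.n_repeats:
            raise ValueError("per-repeat accuracy count mismatch")
        if len(self.cross_tissue_accuracies) != self.n_repeats:
            raise ValueError("per-repeat accuracy count mismatch")

    @property
    def same_tissue_accuracy(self) -> float:
        return float(np.mean(self.same_tissue_accuracies))

    @property
    def cross_tissue_accuracy(self) -> float:
        return float(np.mean(self.cross_tissue_accuracies))


def _patient_split(
    ds: ExpressionDataset, endpoint: str, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Stratified 2/3-1/3 split of *patients* by endpoint label."""
    patients = sorted(set(ds.patient_id))
    pos = {p: i for i, p in enumerate(ds.patient_id)}
    y = np.array([ds.endpoint(endpoint)[pos[p]] for p in patients])
    splitter = StratifiedShuffleSplit(1, train_size=train_fraction, random_state=seed)
    tr, te = next(splitter.split(np.zeros(len(patients)), y))
    return [patients[i] for i in tr], [patients[i] for i in te]


def _by_patients(ds: ExpressionDataset, patients: list[str]) -> ExpressionDataset:
    want = set(patients)
    idx = [i for i, p in enumerate(ds.patient_id) if p in want]
    return ds.subset_samples(idx)


def _train_test_accuracy(
    train: ExpressionDataset, test: ExpressionDataset, endpoint: str, genes: list[int]
) -> float:
    model = fit_mlhd(train, endpoint, genes)
    pred, _ = predict_mlhd(model, test.matrix[:, genes])
    return float(np.mean(pred == test.endpoint(endpoint)))


def specificity_test(
    normal_ds: ExpressionDataset,
    tumour_ds: ExpressionDataset,
    endpoint: str,
    signature_tissue: str = "normal",
    selector: Selector | None = None,
    n_repeats: int = 10,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SpecificityResult:
    """Run the two-step tissue-specificity swap test.

    Step 1: on each repeat's training patients of ``signature_tissue``,
    ``selector`` picks a gene signature; the discriminant trained on those
    samples is scored on the held-out patients of the same tissue.
    Step 2: the other tissue's data, restricted to the Step 1 genes, is
    used to retrain and score a discriminant on the *same* patient split.
    """
    check_paired(normal_ds, tumour_ds)
    by_tissue = {normal_ds.tissue: normal_ds, tumour_ds.tissue: tumour_ds}
    if signature_tissue not in by_tissue:
        raise ValueError(f"signature_tissue {signature_tissue!r} not present")
    sig_ds = by_tissue[signature_tissue]
    other_ds = tumour_ds if sig_ds is normal_ds else normal_ds
    if selector is None:
        selector = ga_mlhd_selector()

    same, cross, signatures = [], [], []
    for rep in range(n_repeats):
        rep_seed = int(np.random.default_rng((seed, rep)).integers(2**31 - 1))
        train_p, test_p = _patient_split(sig_ds, endpoint, train_fraction, rep_seed)
        sig_train, sig_test = _by_patients(sig_ds, train_p), _by_patients(sig_ds, test_p)
        genes = selector(sig_train, endpoint, rep_seed)
        same.append(_train_test_accuracy(sig_train, sig_test, endpoint, genes))
        other_train, other_test = _by_patients(other_ds, train_p), _by_patients(other_ds, test_p)
        cross.append(_train_test_accuracy(other_train, other_test, endpoint, genes))
        signatures.append([sig_ds.gene_ids[g] for g in genes])
    return SpecificityResult(
        endpoint=endpoint,
        signature_tissue=signature_tissue,
        n_repeats=n_repeats,
        same_tissue_accuracies=np.array(same),
        cross_tissue_accuracies=np.array(cross),
        signatures=signatures,
    )


@dataclass
class LoadingProfile:
    """Unit-norm loadings of one principal component over the signature genes."""

    component_index: int
    genes: list[str]
    loadings: np.ndarray
    explained_variance_fraction: float
    threshold: float = 0.3

    @property
    def highlighted(self) -> list[str]:
        return [g for g, l in zip(self.genes, self.loadings) if abs(l) > self.threshold]


def pca_contributions(
    ds: ExpressionDataset,
    genes,
    n_components: int = 2,
    threshold: float = 0.3,
) -> tuple[list[LoadingProfile], np.ndarray]:
    """PCA of the dataset restricted to a gene signature.

    Columns are centred (per-gene mean 0) but not scaled; loadings are the
    unit-norm right singular vectors, with the sign convention that the
    largest-|loading| entry of each component is positive.  Genes with
    |loading| above ``threshold`` (default 0.3) are flagged as the main
    contributors to that component.  Returns the loading profiles and the
    per-sample component scores.
    """
    gene_idx = list(genes)
    if len(gene_idx) < 2:
        raise ValueError("need at least 2 genes for PCA")
    x = ds.matrix[:, gene_idx]
    ids = [ds.gene_ids[g] for g in gene_idx]
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant genes from PCA: {dropped}")
        x = x[:, keep]
        ids = [g for g, k in zip(ids, keep) if k]
        if x.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant genes remain")
    n, p = x.shape
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}]")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    profiles = []
    scores = np.empty((n, n_components))
    for k in range(n_components):
        v = vt[k]
        if v[np.argmax(np.abs(v))] < 0:  # deterministic sign convention
            v = -v
        profiles.append(
            LoadingProfile(
                component_index=k + 1,
                genes=list(ids),
                loadings=v.copy(),
                explained_variance_fraction=float(frac[k]),
                threshold=threshold,
            )
        )
        scores[:, k] = xc @ v
    return profiles, scores
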