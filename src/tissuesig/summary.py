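"""Distilling model populations into representative models.

Both selection engines emit a population of near-optimal gene subsets.
The summary stage ranks genes by their inclusion frequency within the most
predictive slice of the population (default: top 1% by fitness, boundary
ties included), then forward-selects a single representative model from
that ranking.  A hypergeometric overlap test compares top-gene lists
between methods or datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datasets import ExpressionDataset
from .ga import ModelPopulation
from .mlhd import CVConfig, inner_cv_accuracy, outer_accuracy


@dataclass
class RepresentativeModel:
    """A single summary gene subset with its estimated accuracy."""

    genes: list[str]
    method: str
    endpoint: str
    tissue: str
    accuracy: float
    size: int
    inner_accuracy: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size != len(self.genes):
            raise ValueError("size must equal len(genes)")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")


@dataclass
class OverlapTest:
    """Overlap between two top-k gene lists drawn from a common universe."""

    list_a: list[str]
    list_b: list[str]
    universe_size: int
    overlap: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(len(self.list_a), len(self.list_b)):
            raise ValueError("overlap exceeds the shorter list")
        if max(len(self.list_a), len(self.list_b)) > self.universe_size:
            raise ValueError("universe smaller than a list")


def gene_frequency(pop: ModelPopulation, top_fraction: float = 0.01) -> pd.DataFrame:
    """Per-gene inclusion frequency within the top fitness slice.

    The slice holds the ``ceil(top_fraction * len(pop))`` fittest records,
    extended to include all records tied with the boundary fitness.
    Returns a DataFrame (gene, frequency, rank) sorted by descending
    frequency, ties broken by gene index.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    records = pop.sorted_by_fitness().records
    if not records:
        raise ValueError("empty model population")
    n_top = max(1, int(np.ceil(top_fraction * len(records))))
    boundary = records[n_top - 1].fitness
    top = [r for r in records if r.fitness >= boundary]
    counts: dict[int, int] = {}
    for r in top:
        for g in r.chromosome.genes:
            counts[g] = counts.get(g, 0) + 1
    df = pd.DataFrame(
        {"gene": list(counts), "frequency": [counts[g] / len(top) for g in counts]}
    )
    df = df.sort_values(["frequency", "gene"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def best_per_run_frequency(pop: ModelPopulation) -> pd.DataFrame:
    """Per-gene frequency across each run's single best chromosome.

    Genes that recur in the winners of *independent* GA runs replicate
    across searches, which separates genuinely informative genes from the
    run-specific passengers that ride along in any one converged
    population.  Ties within a run resolve to the earliest generation,
    then to the lexicographically smallest gene tuple.  Returns (gene,
    frequency, rank) with frequency = runs containing the gene / n_runs.
    """
    if not pop.records:
        raise ValueError("empty model population")
    best: dict[int, object] = {}
    for r in pop.records:
        cur = best.get(r.run)
        key = (-r.fitness, r.generation, r.chromosome.genes)
        if cur is None or key < (-cur.fitness, cur.generation, cur.chromosome.genes):
            best[r.run] = r
    counts: dict[int, int] = {}
    for r in best.values():
        for g in r.chromosome.genes:
            counts[g] = counts.get(g, 0) + 1
    df = pd.DataFrame(
        {"gene": list(counts), "frequency": [counts[g] / len(best) for g in counts]}
    )
    df = df.sort_values(["frequency", "gene"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def forward_select_representative(
    ranked_genes,
    ds: ExpressionDataset,
    endpoint: str,
    cv: CVConfig,
    max_size: int = 15,
    tolerance: float = 0.001,
    patience: int = 5,
    method: str = "GA-MLHD",
    priors: str = "empirical",
) -> RepresentativeModel:
    """Greedy forward selection down a ranked gene list.

    The top-ranked gene seeds the model; each subsequent candidate is kept
    only if it improves the inner-CV accuracy by more than ``tolerance``.
    Selection stops at ``max_size`` genes or once ``patience`` consecutive
    candidates fail to improve.  The reported accuracy is the outer
    repeated-split estimate; the inner estimate is kept alongside.
    """
    ranked = list(dict.fromkeys(int(g) for g in ranked_genes))  # dedupe, keep order
    if not ranked:
        raise ValueError("ranked gene list is empty")
    current = [ranked[0]]
    best = inner_cv_accuracy(ds, endpoint, current, cv, priors)
    fails = 0
    for g in ranked[1:]:
        if len(current) >= max_size or fails >= patience:
            break
        acc = inner_cv_accuracy(ds, endpoint, current + [g], cv, priors)
        if acc > best + tolerance:
            current.append(g)
            best = acc
            fails = 0
        else:
            fails += 1
    outer_mean, _ = outer_accuracy(ds, endpoint, current, cv, priors)
    return RepresentativeModel(
        genes=[ds.gene_ids[g] for g in current],
        method=method,
        endpoint=endpoint,
        tissue=ds.tissue,
        accuracy=outer_mean,
        size=len(current),
        inner_accuracy=best,
    )


def make_overlap_test(list_a, list_b, universe_size: int) -> OverlapTest:
    """Build an OverlapTest with the observed overlap and its p-value filled in."""
    a, b = list(list_a), list(list_b)
    test = OverlapTest(a, b, universe_size, overlap=len(set(a) & set(b)))
    test.p_value = overlap_significance(test)
    return test


def overlap_significance(test: OverlapTest) -> float:
    """Right-tail hypergeometric probability of >= the observed overlap.

    Under independence, the overlap of two random lists of sizes |A| and
    |B| from a universe of size U is Hypergeometric(U, |A|, |B|); the
    returned value is P(overlap >= observed), equal to 1 when the observed
    overlap is 0.
    """
    u, na, nb = test.universe_size, len(test.list_a), len(test.list_b)
    if test.overlap > min(na, nb):
        raise ValueError("overlap exceeds the shorter list")
    return float(hypergeom.sf(test.overlap - 1, u, na, nb))
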