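"""Enrichment and group-comparison statistics for selected gene sets.

Contains the network Score (right-tail hypergeometric enrichment of focus
genes in a candidate pathway, reported as -log10 p; scores above 5
correspond to p < 1e-5), a right-tailed Fisher exact test for canonical
pathways (alpha = 0.01), a one-way ANOVA for multi-group comparisons,
and the univariate F-ranking baseline the multivariate selectors are
compared against.  Gene sets are read from plain GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import f as f_dist
from scipy.stats import fisher_exact, ttest_ind
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

SCORE_THRESHOLD = 5.0  # score > 5  <=>  p_right < 1e-5


@dataclass
class ScoredPathway:
    """Hypergeometric enrichment problem for one pathway.

    Of ``N`` genes in the genomic network, ``G`` are focus genes; the
    pathway holds ``s`` genes of which ``f`` are focus genes.  ``p_right``
    is P(X >= f) for X ~ Hypergeometric(N, G, s); ``score`` = -log10 p.
    """

    N: int
    G: int
    s: int
    f: int
    p_right: float
    score: float

    def __post_init__(self) -> None:
        if self.f > min(self.G, self.s):
            raise ValueError(f"f={self.f} exceeds min(G={self.G}, s={self.s})")
        if self.G > self.N or self.s > self.N:
            raise ValueError("G and s cannot exceed N")
        if self.p_right > 0 and abs(self.score + np.log10(self.p_right)) > 1e-9:
            raise ValueError("score must equal -log10(p_right)")

    @property
    def passes(self) -> bool:
        return self.score > SCORE_THRESHOLD


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def network_score(N: int, G: int, s: int, f: int) -> ScoredPathway:
    """Right-tail hypergeometric enrichment score of a gene set.

    p_right = sum_{i=f}^{min(G,s)}  C(G,i) C(N-G, s-i) / C(N,s),
    evaluated in log space so that very small tails (large N) keep full
    relative precision; score = -log10(p_right).
    """
    for name, v in (("N", N), ("G", G), ("s", s)):
        if v < 1:
            raise ValueError(f"{name} must be a positive integer")
    if f < 0:
        raise ValueError("f must be non-negative")
    if G > N or s > N:
        raise ValueError(f"G={G} and s={s} must not exceed N={N}")
    if f > min(G, s):
        raise ValueError(f"f={f} exceeds min(G={G}, s={s})")
    lo = max(f, s - (N - G))
    hi = min(G, s)
    if lo > hi:
        logp = 0.0  # support below f is the whole distribution
    else:
        i = np.arange(lo, hi + 1)
        terms = _log_comb(G, i) + _log_comb(N - G, s - i) - _log_comb(N, s)
        logp = min(float(logsumexp(terms)), 0.0)
    p = float(np.exp(logp))
    score = float(-logp / np.log(10.0))
    return ScoredPathway(N=N, G=G, s=s, f=f, p_right=p, score=score)


def fisher_pathway_test(table, alpha: float = 0.01) -> tuple[float, bool]:
    """Right-tailed Fisher exact test on a 2x2 contingency table.

    Returns (p, significant at ``alpha``).  Row 1 is the pathway, column 1
    the focus genes, so the right tail asks for enrichment of focus genes
    in the pathway.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table cells must be non-negative integers")
    _, p = fisher_exact(t, alternative="greater")
    return float(p), bool(p < alpha)


@dataclass
class GroupComparison:
    """One-way ANOVA result for a single gene across sample groups."""

    gene: str
    group_means: dict[str, float]
    f_statistic: float
    p_value: float


def anova_by_group(values, group_labels, gene: str = "") -> GroupComparison:
    """Classic one-way fixed-effects ANOVA across labelled groups."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = {}
    for g in pd.unique(group_labels):
        v = values[group_labels == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        groups[g] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    n = len(values)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
        p = float(f_dist.sf(f_stat, df1, df2))
    return GroupComparison(
        gene=gene,
        group_means={str(g): float(v.mean()) for g, v in groups.items()},
        f_statistic=float(f_stat),
        p_value=max(p, np.finfo(float).tiny),
    )


def anova_table(ds: ExpressionDataset, group_labels, genes=None) -> pd.DataFrame:
    """One-way ANOVA per gene, with Benjamini-Hochberg FDR alongside raw p."""
    gene_idx = range(ds.n_genes) if genes is None else list(genes)
    rows = []
    for g in gene_idx:
        cmp = anova_by_group(ds.matrix[:, g], group_labels, gene=ds.gene_ids[g])
        rows.append({"gene": cmp.gene, "F": cmp.f_statistic, "p": cmp.p_value})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def univariate_rank(ds: ExpressionDataset, endpoint: str) -> pd.DataFrame:
    """Rank genes by the two-class F ratio, with t-test p-values alongside.

    The univariate baseline: for a binary endpoint the one-way F statistic
    equals the squared pooled t statistic, so this ranking is the t-test
    ranking.  Constant genes get F = 0 and rank last; ties break by gene id.
    """
    y = ds.endpoint(endpoint)
    if len(np.unique(y)) != 2:
        raise ValueError(f"endpoint {endpoint!r} is not binary")
    x0, x1 = ds.matrix[y == 0], ds.matrix[y == 1]
    n0, n1 = len(x0), len(x1)
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    ss = ((x0 - m0) ** 2).sum(axis=0) + ((x1 - m1) ** 2).sum(axis=0)
    grand = ds.matrix.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(ss > 0, ss_between / (ss / (n0 + n1 - 2)), 0.0)
        p_f = np.where(ss > 0, f_dist.sf(f_stat, 1, n0 + n1 - 2), 1.0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
        t_p = ttest_ind(x0, x1, axis=0).pvalue
    t_p = np.where(np.isnan(t_p), 1.0, t_p)
    df = pd.DataFrame(
        {"gene": ds.gene_ids, "index": range(ds.n_genes), "F": f_stat, "p": p_f, "t_p": t_p}
    )
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["F", "gene"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = (desc, genes)
    return sets


def score_gene_sets(
    focus_genes, gene_sets: dict[str, tuple[str, list[str]]], universe_size: int
) -> pd.DataFrame:
    """Network Score for each gene set against a list of focus genes."""
    focus = set(focus_genes)
    rows = []
    for name, (_, members) in gene_sets.items():
        s = len(set(members))
        f = len(focus & set(members))
        sp = network_score(N=universe_size, G=len(focus), s=s, f=f)
        rows.append(
            {
                "set": name,
                "N": sp.N,
                "G": sp.G,
                "s": sp.s,
                "f": sp.f,
                "p": sp.p_right,
                "score": sp.score,
                "pass_score_gt_5": sp.passes,
            }
        )
    return pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
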