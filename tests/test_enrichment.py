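"""Network score, Fisher test, one-way ANOVA and the univariate baseline."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tissuesig import (
    SyntheticConfig,
    anova_by_group,
    fisher_pathway_test,
    generate_paired,
    network_score,
    read_gmt,
    score_gene_sets,
    univariate_rank,
)
from tissuesig.enrichment import anova_table

from conftest import make_dataset


def exact_tail(N, G, s, f):
    """Big-integer enumeration of the right-tail hypergeometric probability."""
    total = Fraction(0)
    for i in range(f, min(G, s) + 1):
        if s - i <= N - G:
            total += Fraction(comb(G, i) * comb(N - G, s - i), comb(N, s))
    return total


def test_network_score_trivial_and_exact():
    sp = network_score(N=100, G=10, s=8, f=0)
    assert sp.p_right == 1.0 and sp.score == 0.0

    sp = network_score(N=20, G=5, s=5, f=3)
    assert sp.p_right == pytest.approx(float(exact_tail(20, 5, 5, 3)), rel=1e-12)
    assert sp.score == pytest.approx(-np.log10(float(exact_tail(20, 5, 5, 3))), abs=1e-9)


def test_network_score_matches_enumeration_up_to_N_60():
    rng = np.random.default_rng(0)
    for _ in range(200):
        N = int(rng.integers(2, 61))
        G = int(rng.integers(1, N + 1))
        s = int(rng.integers(1, N + 1))
        f = int(rng.integers(0, min(G, s) + 1))
        sp = network_score(N, G, s, f)
        assert sp.p_right == pytest.approx(float(exact_tail(N, G, s, f)), rel=1e-9)


def test_network_score_input_validation():
    with pytest.raises(ValueError):
        network_score(N=10, G=4, s=4, f=5)
    with pytest.raises(ValueError):
        network_score(N=10, G=11, s=4, f=2)
    with pytest.raises(ValueError):
        network_score(N=10, G=4, s=11, f=2)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    N=st.integers(5, 50),
    data=st.data(),
)
def test_network_score_monotone_in_focus_count(N, data):
    G = data.draw(st.integers(1, N))
    s = data.draw(st.integers(1, N))
    f = data.draw(st.integers(0, min(G, s) - 1)) if min(G, s) > 0 else 0
    a = network_score(N, G, s, f)
    b = network_score(N, G, s, f + 1)
    assert b.p_right <= a.p_right + 1e-15
    assert b.score >= a.score - 1e-9


def test_score_threshold_matches_p_threshold():
    """Score > 5 is exactly the p < 1e-5 filter."""
    rng = np.random.default_rng(1)
    seen_pass = seen_fail = 0
    for _ in range(300):
        N = int(rng.integers(20, 200))
        G = int(rng.integers(1, N // 2))
        s = int(rng.integers(1, N // 2))
        f = int(rng.integers(0, min(G, s) + 1))
        sp = network_score(N, G, s, f)
        assert sp.passes == (sp.p_right < 1e-5)
        seen_pass += sp.passes
        seen_fail += not sp.passes
    assert seen_pass and seen_fail  # both sides of the boundary exercised


def test_network_score_agrees_with_fisher_right_tail():
    """The same hypergeometric tail through two independent routes."""
    for N, G, s, f in [(40, 8, 10, 3), (60, 12, 6, 2), (25, 5, 5, 5), (30, 10, 3, 0)]:
        sp = network_score(N, G, s, f)
        table = np.array([[f, s - f], [G - f, N - G - s + f]])
        p_fisher, _ = fisher_pathway_test(table)
        assert sp.p_right == pytest.approx(p_fisher, abs=1e-9)


def test_fisher_trivial_and_exact_cases():
    p, sig = fisher_pathway_test([[0, 5], [7, 11]])
    assert p == 1.0 and not sig

    p, _ = fisher_pathway_test([[10, 0], [0, 10]])
    assert p == pytest.approx(1 / comb(20, 10), rel=1e-12)

    p, _ = fisher_pathway_test([[0, 0], [3, 4]])
    assert p == 1.0

    with pytest.raises(ValueError):
        fisher_pathway_test([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_pathway_test([[0.5, 2], [3, 4]])


def test_anova_f_equals_squared_t_for_two_groups():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(30)
    groups = np.repeat(["a", "b"], 15)
    res = anova_by_group(x, groups, gene="g")
    t = stats.ttest_ind(x[:15], x[15:]).statistic
    assert res.f_statistic == pytest.approx(t**2, abs=1e-9)
    assert set(res.group_means) == {"a", "b"}


def test_anova_power_and_errors():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(40)
    groups = np.repeat(["a", "b", "c", "d"], 10)
    x[groups == "c"] += 5.0
    assert anova_by_group(x, groups).p_value < 1e-6

    with pytest.raises(ValueError, match="'d'"):
        anova_by_group(x[:31], groups[:31])


def test_anova_null_p_values_uniform():
    rng = np.random.default_rng(4)
    pvals = [
        anova_by_group(rng.standard_normal(24), np.repeat(["a", "b", "c"], 8)).p_value
        for _ in range(800)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_anova_table_shape(small_paired):
    normal, _ = small_paired
    groups = np.where(normal.endpoint("gleason") == 1, "high", "low")
    df = anova_table(normal, groups, genes=range(10))
    assert list(df.columns) == ["gene", "F", "p", "fdr"]
    assert (df["fdr"] >= df["p"] - 1e-12).all()


def test_univariate_rank_recovers_planted_and_matches_t_ordering():
    cfg = SyntheticConfig(
        n_patients=50, n_genes=100, n_informative=5, effect_size=3.0,
        signal_tissue="normal", seed=19, endpoints=("gleason",),
    )
    normal, _ = generate_paired(cfg)
    df = univariate_rank(normal, "gleason")
    top5 = set(df.head(5)["gene"])
    assert top5 == set(normal.informative["gleason"])

    # F ordering equals squared-t ordering
    y = normal.endpoint("gleason")
    t = stats.ttest_ind(normal.matrix[y == 0], normal.matrix[y == 1], axis=0).statistic
    t2 = {g: v**2 for g, v in zip(normal.gene_ids, t)}
    f_by_gene = dict(zip(df["gene"], df["F"]))
    for g in normal.gene_ids:
        assert f_by_gene[g] == pytest.approx(t2[g], rel=1e-9)

    # permuted labels destroy the enrichment of planted ranks
    rng = np.random.default_rng(7)
    shuffled = normal.subset_samples(rng.permutation(normal.n_samples))
    shuffled.labels["gleason"] = normal.labels["gleason"].copy()
    df_null = univariate_rank(shuffled, "gleason")
    ranks = df_null.set_index("gene")["rank"]
    mean_rank = np.mean([ranks[g] for g in normal.informative["gleason"]])
    assert abs(mean_rank - 50.5) < 35


def test_univariate_rank_constant_gene_last():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((20, 4))
    x[:, 3] = 2.0
    ds = make_dataset(x, np.tile([0, 1], 10))
    df = univariate_rank(ds, "gleason")
    last = df.iloc[-1]
    assert last["gene"] == "G003" and last["F"] == 0.0


def test_gmt_roundtrip_and_scoring(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "pathway_a\tfirst set\tg1\tg2\tg3\n"
        "pathway_b\tsecond set\tg4\tg5\n"
    )
    sets = read_gmt(path)
    assert sets["pathway_a"] == ("first set", ["g1", "g2", "g3"])

    df = score_gene_sets(["g1", "g2", "g9"], sets, universe_size=50)
    row = df.set_index("set").loc["pathway_a"]
    assert row["f"] == 2 and row["G"] == 3 and row["s"] == 3
    assert row["p"] == pytest.approx(float(exact_tail(50, 3, 3, 2)), rel=1e-9)

    bad = tmp_path / "bad.gmt"
    bad.write_text("only_name\tdesc\n")
    with pytest.raises(ValueError, match="bad.gmt:1"):
        read_gmt(bad)
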