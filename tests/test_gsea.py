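"""Signal2Noise ranking, weighted running sum, permutation GSEA, ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicross.datatypes import InputError
from omicross.gsea import (enrichment_score, ora_enrich, read_gmt, run_gsea,
                           signal_to_noise, write_gmt)


def _df(rows, genes, n1=3, n2=3):
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    return pd.DataFrame(rows, index=genes, columns=cols)


def _groups(n1=3, n2=3):
    idx = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    return pd.Series(["g1"] * n1 + ["g2"] * n2, index=idx)


# ---------------------------------------------------------------- s2n

def test_s2n_sigma_floor_hand_example():
    # group1 constant 2, group2 constant 0: sigma -> 0.4 and 0.2, s2n = 3.333
    df = _df([[2, 2, 2, 0, 0, 0]], ["g"])
    s = signal_to_noise(df, _groups())
    assert s.iloc[0] == pytest.approx(2 / 0.6)


def test_s2n_identical_groups_zero():
    df = _df([[1, 2, 3, 1, 2, 3]], ["g"])
    assert signal_to_noise(df, _groups()).iloc[0] == pytest.approx(0.0)


def test_s2n_antisymmetric_under_group_swap():
    rng = np.random.default_rng(0)
    df = _df(rng.uniform(0, 5, size=(20, 6)), [f"g{i}" for i in range(20)])
    g = _groups()
    s1 = signal_to_noise(df, g, group1="g1")
    s2 = signal_to_noise(df, g, group1="g2")
    np.testing.assert_allclose(s1.sort_index(), -s2.sort_index(), atol=1e-12)


def test_s2n_requires_three_per_group():
    df = _df([[1, 2, 3, 4, 5]], ["g"], n1=2, n2=3)
    with pytest.raises(InputError):
        signal_to_noise(df, _groups(2, 3))


def test_s2n_sorted_descending_with_id_tiebreak():
    df = _df([[2, 2, 2, 0, 0, 0], [2, 2, 2, 0, 0, 0], [0, 0, 0, 2, 2, 2]],
             ["zz", "aa", "bb"])
    s = signal_to_noise(df, _groups())
    assert list(s.index) == ["aa", "zz", "bb"]


# ---------------------------------------------------------------- ES

def _ranked():
    return pd.Series([3.0, 2.0, 1.0, 0.5], index=["g1", "g2", "g3", "g4"])


def test_es_hand_walk_top_set():
    es, running = enrichment_score(_ranked(), {"g1", "g2"})
    np.testing.assert_allclose(running, [0.6, 1.0, 0.5, 0.0])
    assert es == pytest.approx(1.0)


def test_es_hand_walk_bottom_set():
    es, running = enrichment_score(_ranked(), {"g3", "g4"})
    np.testing.assert_allclose(running, [-0.5, -1.0, -1 / 3, 0.0], atol=1e-12)
    assert es == pytest.approx(-1.0)


def test_es_all_genes_no_misses():
    es, running = enrichment_score(_ranked(), {"g1", "g2", "g3", "g4"})
    assert es == pytest.approx(1.0)
    assert running[-1] == pytest.approx(1.0)


def test_es_empty_intersection_rejected():
    with pytest.raises(InputError):
        enrichment_score(_ranked(), {"nope"})


def test_es_bounded_in_unit_interval():
    rng = np.random.default_rng(1)
    scores = pd.Series(np.sort(rng.normal(size=50))[::-1],
                       index=[f"g{i}" for i in range(50)])
    for _ in range(20):
        size = rng.integers(1, 30)
        gs = set(rng.choice(scores.index, size=size, replace=False))
        es, _ = enrichment_score(scores, gs)
        assert -1.0 <= es <= 1.0


# ---------------------------------------------------------------- run_gsea

def _planted_expression(seed=0, n_genes=120, n_per=10):
    rng = np.random.default_rng(seed)
    vals = rng.normal(5, 1, size=(n_genes, 2 * n_per))
    vals[:20, :n_per] += 2.0  # first 20 genes respond in group 1
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    df = pd.DataFrame(vals, index=genes, columns=cols)
    groups = pd.Series(["g1"] * n_per + ["g2"] * n_per, index=cols)
    return df, groups, set(genes[:20])


def test_planted_set_is_significant():
    df, groups, planted = _planted_expression()
    rng = np.random.default_rng(5)
    sets = {"planted": sorted(planted)}
    for i in range(10):
        sets[f"rand{i}"] = list(rng.choice(df.index, size=20, replace=False))
    res = run_gsea(df, groups, sets, n_perm=500, seed=2)
    assert res.loc["planted", "q"] < 0.05
    assert res.loc["planted", "NES"] == res["NES"].max()


def test_gsea_rankings_stable_across_seeds():
    """Permutation q-values are seed-stable on a graded positive-control run."""
    df, groups, planted = _planted_expression(seed=3)
    planted = sorted(planted)
    background = [g for g in df.index if g not in set(planted)]
    rng = np.random.default_rng(7)
    sets = {}
    for i in range(0, 21, 2):  # sets carrying 0..20 planted genes
        fill = list(rng.choice(background, size=20 - i, replace=False))
        sets[f"s{i:02d}"] = planted[:i] + fill
    r1 = run_gsea(df, groups, sets, n_perm=300, seed=11)
    r2 = run_gsea(df, groups, sets, n_perm=300, seed=22)
    from scipy.stats import spearmanr
    rho = spearmanr(r1["q"].sort_index(), r2["q"].sort_index()).statistic
    assert rho > 0.9


def test_zero_permutations_emit_es_only():
    df, groups, planted = _planted_expression()
    res = run_gsea(df, groups, {"planted": sorted(planted)}, n_perm=0, seed=0)
    assert np.isfinite(res["ES"]).all()
    assert res[["NES", "p", "q"]].isna().all().all()


def test_size_filter_and_empty_error():
    df, groups, planted = _planted_expression()
    sets = {"tiny": list(planted)[:3]}
    with pytest.raises(InputError):
        run_gsea(df, groups, sets, n_perm=10, min_size=15)


def test_gmt_round_trip(tmp_path):
    sets = {"setA": ["g1", "g2", "g3"], "setB": ["g9", "g2"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets


# ---------------------------------------------------------------- ORA

def test_ora_hand_hypergeometric():
    universe = [f"g{i}" for i in range(100)]
    gene_set = universe[:10]
    query = universe[:5] + universe[50:55]  # overlap 5
    res = ora_enrich(query, universe, {"s": gene_set})
    assert res["overlap"].iloc[0] == 5
    # sum_{k>=5} C(10,k) C(90,10-k) / C(100,10), by direct enumeration
    assert res["p"].iloc[0] == pytest.approx(6.7163e-4, rel=1e-3)


def test_ora_no_enrichment_when_universe_equals_set():
    genes = ["a", "b", "c"]
    res = ora_enrich(genes, genes, {"s": genes})
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_ora_zero_overlap_p_one():
    universe = [f"g{i}" for i in range(30)]
    res = ora_enrich(universe[:5], universe, {"s": universe[20:]})
    assert res["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_ora_guards():
    with pytest.raises(InputError):
        ora_enrich([], ["a"], {"s": ["a"]})
    with pytest.raises(InputError):
        ora_enrich(["x"], ["a"], {"s": ["a"]})


@settings(max_examples=50, deadline=None)
@given(st.integers(5, 30), st.integers(1, 10), st.integers(1, 10), st.integers(0, 99))
def test_ora_matches_bruteforce_tail(n_universe, n_set, n_query, seed):
    from math import comb
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(n_universe)]
    n_set = min(n_set, n_universe)
    n_query = min(n_query, n_universe)
    gene_set = list(rng.choice(universe, size=n_set, replace=False))
    query = list(rng.choice(universe, size=n_query, replace=False))
    res = ora_enrich(query, universe, {"s": gene_set})
    k_obs = res["overlap"].iloc[0]
    brute = sum(comb(n_set, k) * comb(n_universe - n_set, n_query - k)
                for k in range(k_obs, min(n_set, n_query) + 1)
                if n_query - k <= n_universe - n_set) / comb(n_universe, n_query)
    assert res["p"].iloc[0] == pytest.approx(brute, rel=1e-9)
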