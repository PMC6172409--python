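"""Pairwise correlation, co-expression filter, triplet rule, DB validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from omicross.crosstalk import (export_network, filter_coexpressed,
                                infer_triplets, pairwise_correlation,
                                read_edge_list, to_edge_list, validate_triplets)
from omicross.datatypes import ExpressionMatrix, InputError
from omicross.simulate import (DB_COLUMNS, SimConfig, generate_dataset,
                               generate_target_db)


def _layer(vals, layer, prefix):
    arr = np.asarray(vals, float)
    genes = [f"{prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), layer)


# ---------------------------------------------------------------- correlation

def test_gene_with_itself_r_one_p_zero():
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 50, size=(1, 10))
    a = _layer(vals, "mRNA", "mrna:g")
    b = _layer(vals, "lncRNA", "lnc:g")
    ct = pairwise_correlation(b, a)
    assert ct["r"].iloc[0] == pytest.approx(1.0)
    assert ct["p"].iloc[0] == 0.0


def test_correlation_p_value_matches_scipy():
    rng = np.random.default_rng(1)
    a = _layer(rng.uniform(0, 50, size=(4, 25)), "lncRNA", "lnc:g")
    b = _layer(rng.uniform(0, 50, size=(5, 25)), "mRNA", "mrna:g")
    ct = pairwise_correlation(a, b)
    from scipy.stats import pearsonr
    la, lb = a.log2p1(), b.log2p1()
    for row in ct.itertuples():
        r, p = pearsonr(la.loc[row.gene_a], lb.loc[row.gene_b])
        assert row.r == pytest.approx(r, abs=1e-12)
        assert row.p == pytest.approx(p, abs=1e-12)


def test_r_point_four_at_n_25_crosses_threshold():
    # analytic: r=0.4, n=25 -> t=2.093, df=23, two-sided p=0.04757
    from scipy import stats
    t = 0.4 * np.sqrt(23) / np.sqrt(1 - 0.16)
    p = 2 * stats.t.sf(t, 23)
    assert p == pytest.approx(0.047568, abs=1e-5)
    assert p < 0.05


def test_zero_variance_gene_skipped():
    rng = np.random.default_rng(2)
    vals = rng.uniform(1, 9, size=(3, 10))
    vals[1] = 4.0
    a = _layer(vals, "lncRNA", "lnc:g")
    b = _layer(rng.uniform(1, 9, size=(2, 10)), "mRNA", "mrna:g")
    ct = pairwise_correlation(a, b)
    assert "lnc:g1" not in set(ct["gene_a"])
    assert len(ct) == 4


def test_too_few_samples_rejected():
    a = _layer([[1, 2, 3]], "lncRNA", "lnc:g")
    b = _layer([[1, 2, 3]], "mRNA", "mrna:g")
    with pytest.raises(InputError):
        pairwise_correlation(a, b)


# ---------------------------------------------------------------- filter

def test_filter_boundaries():
    ct = pd.DataFrame({
        "gene_a": list("abc"), "gene_b": list("xyz"),
        "r": [0.4, 0.39, 0.9], "p": [0.01, 0.001, 0.06], "n": 25,
    })
    kept = filter_coexpressed(ct)
    assert list(kept["gene_a"]) == ["a"]  # r=0.4 inclusive; others fail r or p


def test_filter_negative_r_passes_on_magnitude():
    ct = pd.DataFrame({"gene_a": ["a"], "gene_b": ["x"], "r": [-0.5],
                       "p": [0.01], "n": 25})
    assert len(filter_coexpressed(ct)) == 1


def test_raising_r_min_never_adds_pairs():
    rng = np.random.default_rng(3)
    ct = pd.DataFrame({"gene_a": "a", "gene_b": [f"x{i}" for i in range(100)],
                       "r": rng.uniform(-1, 1, 100), "p": rng.uniform(0, 0.1, 100),
                       "n": 25})
    prev = None
    for r_min in (0.2, 0.4, 0.6, 0.8):
        cur = set(filter_coexpressed(ct, r_min=r_min)["gene_b"])
        if prev is not None:
            assert cur <= prev
        prev = cur


# ---------------------------------------------------------------- triplets

def _pairs(rows, cols=("gene_a", "gene_b")):
    df = pd.DataFrame(rows, columns=list(cols))
    df["r"] = 0.5
    df["p"] = 0.01
    return df


def test_simple_triplet_inferred():
    net = infer_triplets(_pairs([("L1", "M1")]), _pairs([("u1", "L1")]),
                         _pairs([("u1", "M1")]))
    assert len(net) == 1
    row = net.iloc[0]
    assert (row["mirna"], row["lncrna"], row["mrna"]) == ("u1", "L1", "M1")


def test_missing_edge_blocks_triplet():
    net = infer_triplets(_pairs([("L1", "M1")]), _pairs([("u1", "L1")]),
                         _pairs([], cols=("gene_a", "gene_b")))
    assert len(net) == 0


def test_triplets_match_bruteforce_triple_loop():
    rng = np.random.default_rng(4)
    mirs = [f"u{i}" for i in range(8)]
    lncs = [f"L{i}" for i in range(10)]
    mrnas = [f"M{i}" for i in range(10)]
    lm = _pairs([(l, m) for l in lncs for m in mrnas if rng.random() < 0.3])
    ul = _pairs([(u, l) for u in mirs for l in lncs if rng.random() < 0.3])
    um = _pairs([(u, m) for u in mirs for m in mrnas if rng.random() < 0.3])
    net = infer_triplets(lm, ul, um)
    got = {(r.mirna, r.lncrna, r.mrna) for r in net.itertuples()}
    lm_set = set(map(tuple, lm[["gene_a", "gene_b"]].to_numpy()))
    ul_set = set(map(tuple, ul[["gene_a", "gene_b"]].to_numpy()))
    um_set = set(map(tuple, um[["gene_a", "gene_b"]].to_numpy()))
    expected = {(u, l, m) for u, l, m in itertools.product(mirs, lncs, mrnas)
                if (l, m) in lm_set and (u, l) in ul_set and (u, m) in um_set}
    assert got == expected


# ---------------------------------------------------------------- validation

def _net_one(mir="mir:u1", lnc="lnc:L1", mrna="mrna:M1"):
    return pd.DataFrame([{
        "mirna": mir, "lncrna": lnc, "mrna": mrna,
        "r_lnc_mrna": 0.5, "p_lnc_mrna": 0.01,
        "r_mir_lnc": -0.5, "p_mir_lnc": 0.01,
        "r_mir_mrna": -0.5, "p_mir_mrna": 0.01,
    }])


def _evidence(rows):
    df = pd.DataFrame(rows)
    for c in DB_COLUMNS:
        if c not in df:
            df[c] = 0
    return df[["mirna", "target", *DB_COLUMNS]]


def test_validation_rules_pass_and_fail():
    net = _net_one()
    ev = _evidence([
        {"mirna": "mir:u1", "target": "mrna:M1", "db_mirwalk": 1, "db_miranda": 1,
         "db_mirdb": 1, "db_rna22": 1},  # 4 of 6
        {"mirna": "mir:u1", "target": "lnc:L1", "db_targetscan": 1},  # 1 of 3
    ])
    out = validate_triplets(net, ev)
    assert bool(out["validated"].iloc[0])

    ev2 = _evidence([
        {"mirna": "mir:u1", "target": "mrna:M1", "db_mirwalk": 1, "db_miranda": 1,
         "db_mirdb": 1},  # only 3 of 6
        {"mirna": "mir:u1", "target": "lnc:L1", "db_targetscan": 1},
    ])
    assert not validate_triplets(net, ev2)["validated"].iloc[0]


def test_lncrna_support_counts_designated_columns_only():
    net = _net_one()
    ev = _evidence([
        {"mirna": "mir:u1", "target": "mrna:M1", "db_mirwalk": 1, "db_miranda": 1,
         "db_mirdb": 1, "db_rna22": 1},
        # lncRNA edge supported only in non-designated columns
        {"mirna": "mir:u1", "target": "lnc:L1", "db_mirdb": 1, "db_rna22": 1,
         "db_mirnamap": 1},
    ])
    out = validate_triplets(net, ev)
    assert out["lnc_db_support"].iloc[0] == 0
    assert not out["validated"].iloc[0]


def test_absent_evidence_rows_count_zero():
    out = validate_triplets(_net_one(), _evidence(
        [{"mirna": "mir:zz", "target": "mrna:zz"}]))
    assert out["mrna_db_support"].iloc[0] == 0
    assert not out["validated"].iloc[0]


def test_malformed_evidence_rejected():
    with pytest.raises(InputError):
        validate_triplets(_net_one(), pd.DataFrame({"mirna": [], "target": []}))


def test_end_to_end_truth_recovery():
    """Planted triplets recovered exactly with synthetic evidence."""
    cfg = SimConfig(n_tumor=200, n_normal=10, n_mrna=40, n_mirna=20, n_lncrna=40,
                    n_triplets=8, triplet_r=0.7, subtype_shift=0.0,
                    de_fraction=0.0, seed=17)
    layers, annot, truth = generate_dataset(cfg)
    tumors = annot.index[annot.group == "tumor"]
    pools = {k: m.subset_samples(tumors) for k, m in layers.items()}
    pairs = {}
    for key, (la, lb) in {"lnc_mrna": ("lncRNA", "mRNA"),
                          "mir_lnc": ("miRNA", "lncRNA"),
                          "mir_mrna": ("miRNA", "mRNA")}.items():
        pairs[key] = filter_coexpressed(pairwise_correlation(pools[la], pools[lb]))
    net = infer_triplets(pairs["lnc_mrna"], pairs["mir_lnc"], pairs["mir_mrna"])
    ev = generate_target_db(truth, decoy_fraction=1.0, seed=17)
    net = validate_triplets(net, ev)
    got = {(r.mirna, r.lncrna, r.mrna) for r in net[net["validated"]].itertuples()}
    planted = {(t["mirna"], t["lncrna"], t["mrna"]) for t in truth.triplets}
    assert got == planted


# ---------------------------------------------------------------- export

def test_single_triplet_writes_three_edges(tmp_path):
    net = _net_one()
    net["validated"] = True
    edges = export_network(net, tmp_path / "edges.tsv")
    assert len(edges) == 3
    assert set(edges["edge_type"]) == {"lncRNA-mRNA", "miRNA-lncRNA", "miRNA-mRNA"}
    sif = (tmp_path / "edges.sif").read_text().splitlines()
    assert len(sif) == 3


def test_empty_network_header_only(tmp_path):
    net = _net_one().iloc[:0]
    net["validated"] = pd.Series(dtype=bool)
    export_network(net, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("source\t")


def test_export_round_trip_bytes_identical(tmp_path):
    net = _net_one()
    net["validated"] = True
    export_network(net, tmp_path / "a.tsv")
    edges = read_edge_list(tmp_path / "a.tsv")
    edges.to_csv(tmp_path / "b.tsv", sep="\t", index=False, float_format="%.10g")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
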