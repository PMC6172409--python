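"""Generator contracts: determinism, planted effects, survival and evidence."""

import numpy as np
import pandas as pd
import pytest

from omicross.datatypes import InputError
from omicross.simulate import (SimConfig, generate_dataset, generate_survival,
                               generate_target_db, DB_COLUMNS, LNC_DB_COLUMNS)


def _log2(m, samples):
    return np.log2(m.values[samples] + 1.0)


def test_identical_seed_gives_bit_identical_output():
    cfg = SimConfig(n_tumor=30, n_normal=8, n_mrna=60, n_mirna=25, n_lncrna=60,
                    n_triplets=4, seed=7)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    for layer in a[0]:
        pd.testing.assert_frame_equal(a[0][layer].values, b[0][layer].values)
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[2].to_json_dict() == b[2].to_json_dict()


def test_different_seed_changes_values():
    base = dict(n_tumor=30, n_normal=8, n_mrna=60, n_mirna=25, n_lncrna=60, n_triplets=4)
    a, _, _ = generate_dataset(SimConfig(seed=1, **base))
    b, _, _ = generate_dataset(SimConfig(seed=2, **base))
    assert not np.allclose(a["mRNA"].values, b["mRNA"].values)


def test_zero_subtype_shift_means_no_subtype_difference():
    cfg = SimConfig(n_tumor=200, n_normal=5, n_mrna=80, n_mirna=20, n_lncrna=80,
                    subtype_shift=0.0, de_fraction=0.0, n_triplets=0, seed=3)
    layers, annot, truth = generate_dataset(cfg)
    tumors = annot.index[annot.group == "tumor"]
    lg = _log2(layers["mRNA"], tumors)
    s1 = truth.subtype_labels[truth.subtype_labels == 1].index
    s2 = truth.subtype_labels[truth.subtype_labels == 2].index
    diff = lg[s1].mean(axis=1) - lg[s2].mean(axis=1)
    # zero in expectation: mean difference small relative to noise/sqrt(n)
    assert np.abs(diff.mean()) < 0.1
    assert np.abs(diff).max() < 5 * cfg.noise_sd * np.sqrt(2 / 100)


def test_subtype_shift_recovers_labels_perfectly():
    cfg = SimConfig(n_tumor=100, n_normal=5, n_mrna=200, n_mirna=50, n_lncrna=200,
                    k_true=2, subtype_shift=3.0, noise_sd=0.5, n_triplets=0, seed=11)
    layers, annot, truth = generate_dataset(cfg)
    from sklearn.metrics import adjusted_rand_score
    from omicross.consensus import hclust_cut, pearson_distance
    from omicross.preprocess import cluster_input
    tumors = annot.index[annot.group == "tumor"]
    d = pearson_distance(cluster_input(layers["mRNA"].subset_samples(tumors)))
    labels = hclust_cut(d, "complete", 2)
    assert adjusted_rand_score(truth.subtype_labels, labels) == 1.0


def test_triplet_pairwise_correlation_calibrated():
    cfg = SimConfig(n_tumor=1000, n_normal=5, n_mrna=40, n_mirna=20, n_lncrna=40,
                    n_triplets=8, triplet_r=0.7, de_fraction=0.0,
                    subtype_shift=0.0, seed=13)
    layers, annot, truth = generate_dataset(cfg)
    tumors = annot.index[annot.group == "tumor"]
    lg = {k: _log2(m, tumors) for k, m in layers.items()}
    for t in truth.triplets:
        r_ml = np.corrcoef(lg["miRNA"].loc[t["mirna"]], lg["lncRNA"].loc[t["lncrna"]])[0, 1]
        r_mm = np.corrcoef(lg["miRNA"].loc[t["mirna"]], lg["mRNA"].loc[t["mrna"]])[0, 1]
        r_lm = np.corrcoef(lg["lncRNA"].loc[t["lncrna"]], lg["mRNA"].loc[t["mrna"]])[0, 1]
        assert r_ml == pytest.approx(0.7 * t["sign_mir_lnc"], abs=0.05)
        assert r_mm == pytest.approx(0.7 * t["sign_mir_mrna"], abs=0.05)
        assert r_lm == pytest.approx(0.7 * t["sign_lnc_mrna"], abs=0.05)


def test_truth_ids_exist_in_matrices():
    cfg = SimConfig(n_tumor=30, n_normal=8, n_mrna=60, n_mirna=25, n_lncrna=60,
                    n_triplets=4, seed=5)
    layers, _, truth = generate_dataset(cfg)
    all_genes = set()
    for m in layers.values():
        all_genes |= set(m.genes)
    assert set(truth.de_genes) <= all_genes
    for t in truth.triplets:
        assert {t["mirna"], t["lncrna"], t["mrna"]} <= all_genes
        assert t["mirna"].startswith("mir:")
        assert t["lncrna"].startswith("lnc:")
        assert t["mrna"].startswith("mrna:")
    assert set(truth.prognostic_genes) <= all_genes


def test_ari_monotone_in_subtype_shift():
    """Stronger planted separation never hurts clustering recovery (10 seeds)."""
    from sklearn.metrics import adjusted_rand_score
    from omicross.consensus import hclust_cut, pearson_distance
    from omicross.preprocess import cluster_input

    shifts = (0.5, 1.5, 3.0)
    means = []
    for shift in shifts:
        aris = []
        for seed in range(10):
            cfg = SimConfig(n_tumor=60, n_normal=5, n_mrna=150, n_mirna=40,
                            n_lncrna=40, subtype_shift=shift, n_triplets=0, seed=seed)
            layers, annot, truth = generate_dataset(cfg)
            tumors = annot.index[annot.group == "tumor"]
            d = pearson_distance(cluster_input(layers["mRNA"].subset_samples(tumors)))
            aris.append(adjusted_rand_score(truth.subtype_labels, hclust_cut(d, "complete", 2)))
        means.append(np.mean(aris))
    assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9


def test_sizing_error_when_triplets_exceed_layer():
    with pytest.raises(InputError):
        generate_dataset(SimConfig(n_mirna=3, n_triplets=10))


@pytest.mark.parametrize("bad", [
    dict(de_fraction=1.5), dict(censor_rate=-0.1), dict(triplet_r=1.0),
    dict(noise_sd=0.0), dict(n_tumor=0),
])
def test_config_invariants_rejected(bad):
    with pytest.raises(InputError):
        SimConfig(**bad)


# ---------------------------------------------------------------- survival

def test_survival_no_censoring_all_events():
    cfg = SimConfig(censor_rate=0.0, seed=1)
    labels = pd.Series([1] * 50 + [2] * 50)
    surv = generate_survival(labels, cfg)
    assert (surv["event"] == 1).all()
    assert (surv["time"] > 0).all()


def test_survival_censor_rate_approximate():
    cfg = SimConfig(censor_rate=0.3, seed=2)
    surv = generate_survival(pd.Series([1] * 2000), cfg)
    assert 1 - surv["event"].mean() == pytest.approx(0.3, abs=0.03)


def test_survival_hazard_ratio_shortens_times():
    cfg = SimConfig(hazard_ratio=3.0, censor_rate=0.0, seed=3)
    surv = generate_survival(pd.Series([1] * 3000 + [2] * 3000), cfg)
    m1 = surv["time"][:3000].mean()
    m2 = surv["time"][3000:].mean()
    assert m1 / m2 == pytest.approx(3.0, rel=0.15)


def test_survival_rejects_bad_hazard_and_empty_labels():
    cfg = SimConfig(seed=1)
    cfg.hazard_ratio = -1.0
    with pytest.raises(InputError):
        generate_survival(pd.Series([1, 2]), cfg)
    with pytest.raises(InputError):
        generate_survival(pd.Series([], dtype=int), SimConfig(seed=1))


# ---------------------------------------------------------------- evidence

def test_target_db_supports_planted_edges():
    cfg = SimConfig(n_tumor=20, n_normal=5, n_mrna=60, n_mirna=25, n_lncrna=60,
                    n_triplets=6, seed=9)
    _, _, truth = generate_dataset(cfg)
    ev = generate_target_db(truth, decoy_fraction=1.0, seed=9)
    idx = ev.set_index(["mirna", "target"])
    planted = set()
    for t in truth.triplets:
        mrna_row = idx.loc[(t["mirna"], t["mrna"])]
        assert mrna_row[list(DB_COLUMNS)].sum() >= 4
        lnc_row = idx.loc[(t["mirna"], t["lncrna"])]
        assert lnc_row[list(LNC_DB_COLUMNS)].sum() >= 1
        planted |= {(t["mirna"], t["mrna"]), (t["mirna"], t["lncrna"])}
    decoys = ev[[tuple(x) not in planted for x in ev[["mirna", "target"]].to_numpy()]]
    assert len(decoys) > 0
    for _, row in decoys.iterrows():
        if row["target"].startswith("mrna:"):
            assert row[list(DB_COLUMNS)].sum() <= 3
        else:
            assert row[list(LNC_DB_COLUMNS)].sum() == 0
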