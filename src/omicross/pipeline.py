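"""End-to-end orchestration of the multi-omic subtype / crosstalk analysis.

Stage order: simulate (or ingest) -> preprocess -> consensus clustering per
layer -> cluster-of-clusters K selection -> tumor-vs-normal differential
expression -> subtype GSEA -> classification evaluation -> DEFG intersection
-> crosstalk triplet inference + database validation -> survival and clinical
readouts.  Every artifact is written under the output directory and recorded
in a manifest (stage, parameters, SHA-256 of each artifact); the manifest
carries no timestamps, so the same config and seed reproduce it byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, crosstalk, diffexpr, gsea, kselect, preprocess, survival
from .consensus import build_consensus, pearson_distance
from .datatypes import ExpressionMatrix, InputError, TruthSet
from .simulate import SimConfig, generate_dataset, generate_target_db

TOP_MAD = {"mRNA": 3000, "miRNA": 300, "lncRNA": 3000}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the reference protocol values."""

    sim: SimConfig = field(default_factory=SimConfig)
    mean_filter: float = 0.25
    top_mad: dict = field(default_factory=lambda: dict(TOP_MAD))
    reps: int = 50
    k_max: int = 6
    p_item: float = 0.8
    linkage: str = "complete"
    u1: float = 0.1
    u2: float = 0.9
    delta_elbow: float = 0.1
    fdr: float = 0.05
    lfc_abs: float = 0.57
    n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    train_frac: float = 0.6
    folds: int = 10
    backend: str = "centroid"  # or "xgboost"
    xgb_rounds: int = 2000
    r_min: float = 0.4
    p_max: float = 0.05
    mrna_min_db: int = 4
    lnc_min_db: int = 1
    horizon: float = survival.FIVE_YEARS_DAYS
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise InputError("k_max must be >= 2")
        if not 0 < self.train_frac < 1:
            raise InputError("train_frac must be in (0, 1)")


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    report: dict = {}

    def record(stage: str, params: dict, artifacts: list[Path]) -> None:
        manifest[stage] = {
            "params": params,
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        }

    # ---- simulate -------------------------------------------------------
    sim = SimConfig(**{**asdict(cfg.sim), "seed": _stage_seed(cfg.seed, 0)})
    layers, annot, truth = generate_dataset(sim)
    evidence = generate_target_db(truth, seed=_stage_seed(cfg.seed, 1))
    arts = []
    for layer, m in layers.items():
        arts.append(_write_tsv(m.values, out / f"expr_{layer}.tsv", index_label="gene"))
    arts.append(_write_tsv(annot, out / "annotation.tsv"))
    arts.append(_write_tsv(evidence, out / "evidence.tsv", index=False))
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.to_json_dict(), sort_keys=True, indent=1))
    arts.append(truth_path)
    record("simulate", asdict(sim), arts)

    tumors = annot.index[annot["group"] == "tumor"]
    tumor_groups = annot.loc[annot.index, "group"]

    # ---- preprocess + consensus clustering per layer --------------------
    per_layer_results = {}
    filtered = {}
    arts = []
    for i, (layer, m) in enumerate(layers.items()):
        f = preprocess.filter_low_mean(m, cfg.mean_filter)
        f = preprocess.select_top_mad(f, cfg.top_mad[layer])
        filtered[layer] = f
        tm = f.subset_samples(tumors)
        data = preprocess.cluster_input(tm)
        res = build_consensus(data, k_range=range(2, cfg.k_max + 1),
                              reps=cfg.reps, p_item=cfg.p_item,
                              method=cfg.linkage, seed=_stage_seed(cfg.seed, 10 + i))
        per_layer_results[layer] = res
        labels = pd.DataFrame({f"K{k}": r.labels for k, r in res.items()})
        arts.append(_write_tsv(labels, out / f"cc_labels_{layer}.tsv", index_label="sample"))
    record("consensus", {"reps": cfg.reps, "k_max": cfg.k_max, "p_item": cfg.p_item,
                         "linkage": cfg.linkage, "mean_filter": cfg.mean_filter,
                         "top_mad": cfg.top_mad}, arts)

    # ---- cluster-of-clusters K selection --------------------------------
    metrics, coc_results, encoding = kselect.coc_select_k(
        per_layer_results, k_range=range(2, cfg.k_max + 1), reps=cfg.reps,
        p_item=cfg.p_item, seed=_stage_seed(cfg.seed, 20),
        u1=cfg.u1, u2=cfg.u2, delta_elbow=cfg.delta_elbow)
    k_sel = metrics.selected_k
    subtype_labels = coc_results[k_sel].labels.rename("subtype_call")
    arts = [
        _write_tsv(metrics.table, out / "kmetrics.tsv"),
        _write_tsv(subtype_labels.to_frame(), out / "subtypes.tsv", index_label="sample"),
        _write_tsv(coc_results[k_sel].consensus, out / "coc_consensus.tsv"),
    ]
    record("coc_kselect", {"votes": metrics.votes, "selected_k": k_sel}, arts)
    report["selected_k"] = k_sel
    report["k_votes"] = metrics.votes
    if truth is not None and k_sel == truth.subtype_labels.nunique():
        from sklearn.metrics import adjusted_rand_score
        report["subtype_ari"] = float(adjusted_rand_score(
            truth.subtype_labels, subtype_labels.reindex(truth.subtype_labels.index)))

    # ---- differential expression (tumor vs normal, per layer) -----------
    degs_all: list[str] = []
    arts = []
    deg_counts = {}
    for layer, m in layers.items():
        tab = diffexpr.de_table(m, tumor_groups, fdr=cfg.fdr, lfc_abs=cfg.lfc_abs,
                                numerator="tumor")
        up, down = diffexpr.deg_lists(tab)
        degs_all += up + down
        deg_counts[layer] = {"up": len(up), "down": len(down)}
        arts.append(_write_tsv(tab, out / f"de_{layer}.tsv", index_label="gene"))
    record("diffexpr", {"fdr": cfg.fdr, "lfc_abs": cfg.lfc_abs}, arts)
    report["deg_counts"] = deg_counts

    # ---- GSEA on the subtype contrast (mRNA layer) -----------------------
    mrna_t = filtered["mRNA"].subset_samples(tumors)
    contrast = subtype_labels.map(lambda s: f"subtype{min(s, 2)}")
    gene_sets = _default_gene_sets(mrna_t, contrast, seed=_stage_seed(cfg.seed, 30),
                                   min_size=cfg.gsea_min_size)
    gsea_tab = gsea.run_gsea(mrna_t, contrast, gene_sets, n_perm=cfg.n_perm,
                             seed=_stage_seed(cfg.seed, 31),
                             min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size)
    arts = [_write_tsv(gsea_tab, out / "gsea.tsv")]
    record("gsea", {"n_perm": cfg.n_perm}, arts)
    report["gsea_top"] = gsea_tab.index[0]

    # ---- classification evaluation per layer ----------------------------
    feature_genes: list[str] = []
    aucs = {}
    cvs = {}
    for i, (layer, f) in enumerate(filtered.items()):
        x = preprocess.cluster_input(f.subset_samples(tumors)).T.to_numpy()
        y = subtype_labels.to_numpy()
        y = np.minimum(y, 2)  # binary protocol: merge any extra clusters
        names = list(f.genes)
        tr, te = classify.stratified_split(list(tumors), pd.Series(y, index=tumors),
                                           train_frac=cfg.train_frac,
                                           seed=_stage_seed(cfg.seed, 40 + i))
        tr_i = [list(tumors).index(s) for s in tr]
        te_i = [list(tumors).index(s) for s in te]
        backend = _make_backend(cfg, seed=_stage_seed(cfg.seed, 50 + i))
        backend.fit(x[tr_i], y[tr_i])
        _, auc_val = classify.roc_auc(backend.score_samples(x[te_i]), y[te_i])
        aucs[layer] = auc_val
        cvs[layer] = classify.cross_validate(
            lambda: _make_backend(cfg, seed=_stage_seed(cfg.seed, 50 + i)),
            x, y, folds=cfg.folds, seed=_stage_seed(cfg.seed, 60 + i))
        feature_genes += classify.select_feature_genes(backend, names)
    report["auc"] = aucs
    report["cv_accuracy"] = cvs
    record("classify", {"train_frac": cfg.train_frac, "folds": cfg.folds,
                        "backend": cfg.backend}, [])

    # ---- DEFGs -----------------------------------------------------------
    defgs = classify.defg_intersect(feature_genes, degs_all)
    report["defg_counts"] = {k: len(v) for k, v in defgs.items()}
    defg_path = out / "defgs.json"
    defg_path.write_text(json.dumps(defgs, sort_keys=True, indent=1))
    record("defg", {}, [defg_path])

    # ---- crosstalk network ----------------------------------------------
    # fall back to the DE gene lists when a layer has no DEFGs (tiny runs)
    pools = {}
    for layer, m in layers.items():
        pool = defgs[layer] or [g for g in degs_all if g in set(m.genes)]
        pools[layer] = m.subset_genes([g for g in pool if g in set(m.genes)]) \
            if pool else m
    pairs = {}
    for key, (la, lb) in {"lnc_mrna": ("lncRNA", "mRNA"),
                          "mir_lnc": ("miRNA", "lncRNA"),
                          "mir_mrna": ("miRNA", "mRNA")}.items():
        ct = crosstalk.pairwise_correlation(pools[la].subset_samples(tumors),
                                            pools[lb].subset_samples(tumors))
        pairs[key] = crosstalk.filter_coexpressed(ct, cfg.r_min, cfg.p_max)
    net = crosstalk.infer_triplets(pairs["lnc_mrna"], pairs["mir_lnc"], pairs["mir_mrna"])
    net = crosstalk.validate_triplets(net, evidence, cfg.mrna_min_db, cfg.lnc_min_db)
    edges = crosstalk.export_network(net, out / "network_edges.tsv")
    arts = [_write_tsv(net, out / "triplets.tsv", index=False),
            out / "network_edges.tsv", (out / "network_edges.tsv").with_suffix(".sif")]
    record("crosstalk", {"r_min": cfg.r_min, "p_max": cfg.p_max,
                         "mrna_min_db": cfg.mrna_min_db, "lnc_min_db": cfg.lnc_min_db}, arts)
    report["triplets_inferred"] = int(len(net))
    report["triplets_validated"] = int(net["validated"].sum()) if len(net) else 0
    report["network_edges"] = int(len(edges))

    # ---- survival & clinical --------------------------------------------
    t = annot.loc[tumors, "time"]
    e = annot.loc[tumors, "event"]
    chi2, p = survival.logrank_by_group(t, e, subtype_labels.map(lambda s: min(s, 2)))
    rates = {}
    for s in sorted(subtype_labels.map(lambda v: min(v, 2)).unique()):
        mask = subtype_labels.map(lambda v: min(v, 2)) == s
        km = survival.km_curve(t[mask].to_numpy(), e[mask].to_numpy())
        rates[f"subtype{s}"] = survival.survival_rate_at(km, cfg.horizon)
    report["subtype_logrank"] = {"chi2": chi2, "p": p}
    report["five_year_rates"] = rates

    clin = {}
    for cov in ("stage", "grade"):
        table = pd.crosstab(subtype_labels.map(lambda v: min(v, 2)), annot.loc[tumors, cov])
        c2, df_, pv = survival.chisq_clinical(table)
        clin[cov] = {"chi2": c2, "df": df_, "p": pv}
    report["clinical_chisq"] = clin

    # gene-level survival for validated triplet members
    gene_surv = {}
    if report["triplets_validated"]:
        members = set()
        for tdict in net[net["validated"]].itertuples():
            members |= {tdict.mirna, tdict.lncrna, tdict.mrna}
        for g in sorted(members)[:10]:
            layer = {"mrna": "mRNA", "mir": "miRNA", "lnc": "lncRNA"}[g.split(":")[0]]
            expr = layers[layer].values.loc[g, tumors]
            try:
                gene_surv[g] = survival.gene_survival(expr, t, e, horizon=cfg.horizon)
            except InputError:
                continue
    report["gene_survival"] = gene_surv
    record("survival", {"horizon": cfg.horizon}, [])

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=1, default=float))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(
        {"config": _jsonable(asdict(cfg)), "stages": manifest},
        sort_keys=True, indent=1, default=float))
    return report


def _jsonable(d):
    if isinstance(d, dict):
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(d, (list, tuple)):
        return [_jsonable(v) for v in d]
    if isinstance(d, (np.integer,)):
        return int(d)
    if isinstance(d, (np.floating,)):
        return float(d)
    return d


def _make_backend(cfg: RunConfig, seed: int):
    if cfg.backend == "xgboost":
        return classify.XGBoostBackend(n_estimators=cfg.xgb_rounds, seed=seed)
    return classify.CentroidLogisticBackend()


def _default_gene_sets(m: ExpressionMatrix, groups: pd.Series, seed: int,
                       min_size: int = 15, n_random: int = 20,
                       set_size: int = 30) -> dict[str, list[str]]:
    """Benchmark gene sets for a synthetic run: one positive-control set of
    the most subtype-responsive genes plus random same-size sets."""
    from .gsea import signal_to_noise

    ranked = signal_to_noise(m, groups)
    size = max(set_size, min_size)
    pos = list(ranked.index[:size])  # top of the signed ranking
    rng = np.random.default_rng(seed)
    sets = {"planted_subtype_response": pos}
    genes = list(ranked.index)
    for i in range(n_random):
        sets[f"random_{i + 1:02d}"] = list(rng.choice(genes, size=size, replace=False))
    return sets
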