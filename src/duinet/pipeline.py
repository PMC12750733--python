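"""End-to-end orchestration on synthetic inputs with one config.

``run_pipeline`` executes the full analysis in the study's order —
expression calls, orthogroup screening, convergence scan with controls,
branch-model selection on the constrained genes, rate covariation with
the mitochondrial tree, lncRNA hit enrichment, and PPI-network
integration — writing per-stage TSVs plus a single JSON summary.  All
randomness fans out deterministically from one master seed, so repeated
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    codon_model,
    convergence,
    erc as erc_mod,
    expression,
    lncrna_hits,
    network,
    og_filter,
    synthetic,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All thresholds default to the study's printed values."""

    seed: int = 1

    # thresholds
    bias_threshold: float = 0.70
    min_cpm: float = 2.0
    de_q: float = 0.95
    og_min_species: int = 15
    og_min_foreground: int = 4
    hit_min_len: float = 100
    hit_min_cov: float = 0.5
    hit_min_ident: float = 90
    flank: int = 100
    min_score: float = 0.400
    alpha: float = 0.05
    erc_min_shared: int = 10

    # permutation / resampling sizes
    n_perm: int = 499
    n_random_controls: int = 50
    random_tag_size: int = 10
    n_null_de: int = 100_000
    n_resample: int = 999

    # synthetic generation block
    n_species: int = 36
    clade_sizes: tuple = (2, 2, 2, 2, 1, 1)
    n_genes: int = 120
    constrained_frac: float = 0.15
    accelerated_frac: float = 0.05
    rate_multiplier: float = 0.3
    noise_sd: float = 0.2
    missing_frac: float = 0.1
    erc_linked_frac: float = 0.12
    n_codons: int = 200
    omega_bg: float = 0.5
    omega_fg: float = 0.1
    kappa: float = 2.0
    n_features: int = 3000
    n_samples: int = 8
    de_frac: float = 0.02
    lfc_mean: float = 3.0
    dispersion: float = 0.1
    n_lncrnas: int = 20
    hits_per_lncrna: int = 15
    focal_gene_bias: float = 8.0
    interactome_nodes: int = 250
    background_edge_prob: float = 0.02
    planted_edge_prob: float = 0.30
    module_size: int = 12

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clade_sizes" in data:
            data["clade_sizes"] = tuple(data["clade_sizes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clade_sizes"] = list(d["clade_sizes"])
        return d


def _stage_seed(master: int, k: int) -> int:
    return int((master * 1000 + k) % (2**31 - 1))


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the summary dict."""
    cfg = config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict()}

    # ---- stage 0: synthetic inputs --------------------------------------
    species_tree = synthetic.make_species_tree(
        cfg.n_species,
        len(cfg.clade_sizes),
        list(cfg.clade_sizes),
        seed=_stage_seed(cfg.seed, 0),
    )
    (out / "species_tree.nwk").write_text(species_tree.to_newick())
    mito_tree, gene_sims = synthetic.simulate_joint_gene_trees(
        species_tree,
        n_genes=cfg.n_genes,
        constrained_frac=cfg.constrained_frac,
        accelerated_frac=cfg.accelerated_frac,
        rate_multiplier=cfg.rate_multiplier,
        lognormal_noise_sd=cfg.noise_sd,
        missing_frac=cfg.missing_frac,
        erc_linked_frac=cfg.erc_linked_frac,
        seed=_stage_seed(cfg.seed, 1),
        min_species=cfg.og_min_species,
        min_foreground=cfg.og_min_foreground,
    )
    (out / "mito_tree.nwk").write_text(mito_tree.to_newick())
    truth = pd.DataFrame(
        [t.__dict__ for _, _, t in gene_sims]
    ).set_index("gene_id")

    # ---- stage 1: expression --------------------------------------------
    rng_expr = np.random.default_rng(_stage_seed(cfg.seed, 2))
    cm, count_truth = synthetic.simulate_counts(
        n_features=cfg.n_features,
        n_samples=cfg.n_samples,
        de_frac=cfg.de_frac,
        lfc_mean=cfg.lfc_mean,
        dispersion=cfg.dispersion,
        seed=_stage_seed(cfg.seed, 3),
    )
    # operator scoring: three noisy reads of the true sex ratio, median rule
    op = np.clip(
        cm.sex_ratios.to_numpy()[None, :]
        + rng_expr.normal(0, 0.03, size=(3, cfg.n_samples)),
        0,
        1,
    )
    labels = [
        expression.classify_sex_bias(op[:, i], threshold=cfg.bias_threshold)
        for i in range(cfg.n_samples)
    ]
    sample_sheet = pd.DataFrame(
        {
            "sample": cm.counts.columns,
            "operator_1": op[0],
            "operator_2": op[1],
            "operator_3": op[2],
            "sex_ratio": cm.sex_ratios.to_numpy(),
            "bias_label": labels,
        }
    )
    _write(sample_sheet, out / "sample_sheet.tsv")

    kept = expression.cpm_filter(cm.counts, min_cpm=cfg.min_cpm)
    factors, norm = expression.tmm_factors(cm.counts.loc[kept])
    de = expression.de_test(
        norm,
        cm.groups.to_numpy(),
        n_null=cfg.n_null_de,
        q=cfg.de_q,
        seed=_stage_seed(cfg.seed, 4),
    )
    rho, p_rho = [], []
    sigma = cm.sex_ratios.to_numpy()
    for f in de.index:
        if de.loc[f, "called"]:
            r, p = expression.sexratio_correlation(norm.loc[f], sigma)
        else:
            r, p = np.nan, np.nan
        rho.append(r)
        p_rho.append(p)
    de["rho"] = rho
    de["p_rho"] = p_rho
    _write(de.reset_index(names="feature"), out / "de_results.tsv")
    de_called = set(de.index[de["called"]])
    summary["expression"] = {
        "n_features_total": int(cfg.n_features),
        "n_features_kept": int(len(kept)),
        "n_de": len(de_called),
        "n_de_correlated": int(
            ((de["p_rho"] < cfg.alpha) & de["called"]).sum()
        ),
        "tmm_factors": {s: round(float(v), 6) for s, v in factors.items()},
    }

    # map a random subset of features onto the orthogroup universe
    rng_map = np.random.default_rng(_stage_seed(cfg.seed, 5))
    og_ids = truth.index.to_list()
    rows = rng_map.choice(len(de), size=len(og_ids), replace=False)
    feature_of_og = dict(zip(og_ids, de.index[rows]))
    de_ogs = {og for og, f in feature_of_og.items() if f in de_called}

    # ---- stage 2: orthogroup screening ----------------------------------
    og_rows = []
    retained_genes = []
    for gid, gt, _t in gene_sims:
        mono = og_filter.check_subclass_monophyly(gt)
        n_sp = gt.n_tips
        n_fg = len(set(gt.tip_labels) & species_tree.foreground)
        ok = (
            mono.passed
            and n_sp >= cfg.og_min_species
            and n_fg >= cfg.og_min_foreground
        )
        og_rows.append(
            {
                "og_id": gid,
                "n_species": n_sp,
                "n_foreground": n_fg,
                "monophyly": mono.status,
                "status": "retained" if ok else "discarded",
            }
        )
        if ok:
            retained_genes.append((gid, gt))
    _write(pd.DataFrame(og_rows), out / "og_report.tsv")
    summary["og_filter"] = {
        "n_total": len(gene_sims),
        "n_retained": len(retained_genes),
    }

    # ---- stage 3: convergence scan + controls ---------------------------
    conv_rows = []
    for gid, gt in retained_genes:
        res = convergence.convergence_test(
            gt,
            species_tree,
            n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, 6) + int(gid[2:]),
            gene_id=gid,
        )
        conv_rows.append(
            {
                "gene_id": gid,
                "T": res.statistic,
                "direction": res.direction,
                "p": res.p,
            }
        )
    conv = pd.DataFrame(conv_rows).set_index("gene_id")
    _write(conv.reset_index(), out / "convergence_results.tsv")
    constrained = set(
        conv.index[(conv["p"] < cfg.alpha) & (conv["direction"] == "constrained")]
    )
    accelerated = set(
        conv.index[(conv["p"] < cfg.alpha) & (conv["direction"] == "accelerated")]
    )

    report = convergence.control_scan(
        retained_genes,
        species_tree,
        n_random=cfg.n_random_controls,
        random_tag_size=cfg.random_tag_size,
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=_stage_seed(cfg.seed, 7),
    )
    _write(
        report.low_p_fraction.reset_index(names="run"),
        out / "control_report.tsv",
    )
    _write(
        report.p_values.T.reset_index(names="gene_id"),
        out / "control_p_values.tsv",
    )
    summary["convergence"] = {
        "n_constrained": len(constrained),
        "n_accelerated": len(accelerated),
        "n_control_runs": int(report.low_p_fraction.shape[0]),
        "true_rank_constrained": report.true_rank_constrained,
        "true_rank_accelerated": report.true_rank_accelerated,
    }

    # ---- stage 4: branch-model selection on constrained genes -----------
    sel_rows = []
    gene_tree_of = dict(retained_genes)
    for gid in sorted(constrained):
        gt = gene_tree_of[gid]
        is_planted = truth.loc[gid, "convergence_class"] == "constrained"
        omega_fg = cfg.omega_fg if is_planted else cfg.omega_bg
        seqs = synthetic.simulate_codon_alignment(
            gt,
            n_codons=cfg.n_codons,
            omega_bg=cfg.omega_bg,
            omega_fg=omega_fg,
            kappa=cfg.kappa,
            seed=_stage_seed(cfg.seed, 8) + int(gid[2:]),
        )
        res = codon_model.branch_model_lrt(seqs, gt, og_id=gid)
        sel_rows.append(
            {
                "og_id": gid,
                "lnL0": res.lnL0,
                "lnL1": res.lnL1,
                "LRT": res.lrt,
                "p": res.p,
                "omega_bg": res.omega_bg,
                "omega_fg": res.omega_fg,
                "delta_omega": res.delta_omega,
                "converged": res.converged,
            }
        )
    sel = pd.DataFrame(
        sel_rows,
        columns=[
            "og_id", "lnL0", "lnL1", "LRT", "p",
            "omega_bg", "omega_fg", "delta_omega", "converged",
        ],
    )
    _write(sel, out / "selection_results.tsv")
    ce_genes = set(
        sel.loc[
            (sel["p"] < cfg.alpha) & (sel["delta_omega"] < 0) & sel["converged"],
            "og_id",
        ]
    )
    summary["selection"] = {
        "n_tested": len(sel),
        "n_ce": len(ce_genes),
        "median_delta_omega": (
            float(sel["delta_omega"].median()) if len(sel) else float("nan")
        ),
    }

    # ---- stage 5: rate covariation with the mito tree -------------------
    erc_rows = []
    for gid, gt in retained_genes:
        try:
            res = erc_mod.erc_test(
                gt, mito_tree, species_tree,
                min_shared=cfg.erc_min_shared, gene_id=gid,
            )
        except erc_mod.InsufficientOverlap:
            continue
        erc_rows.append(
            {
                "gene_id": gid,
                "n_shared": res.n_shared_species,
                "slope": res.slope,
                "correlation": res.correlation,
                "p": res.p,
            }
        )
    erc_df = pd.DataFrame(erc_rows).set_index("gene_id")
    _write(erc_df.reset_index(), out / "erc_results.tsv")
    erc_sig = set(erc_df.index[erc_df["p"] < cfg.alpha])
    universe = set(g for g, _ in retained_genes)
    erc_in_ce = erc_mod.enrichment_2x2(
        ce_genes, erc_sig, universe, method="fisher_exact"
    )
    de_ce_overlap = erc_mod.enrichment_2x2(
        de_ogs & universe, ce_genes, universe, method="fisher_exact"
    )
    summary["erc"] = {
        "n_tested": len(erc_df),
        "n_significant": len(erc_sig),
        "erc_among_ce_p": erc_in_ce["p"],
        "erc_among_ce_table": erc_in_ce["table"].tolist(),
        "de_ce_overlap_p": de_ce_overlap["p"],
    }

    # ---- stage 6: lncRNA hits -------------------------------------------
    focal_n = max(len(de_ogs), 5)
    genes_iv = synthetic.make_gene_intervals(
        n_genes=cfg.n_genes,
        n_focal=focal_n,
        seed=_stage_seed(cfg.seed, 9),
    )
    hits, _hit_truth = synthetic.simulate_hit_table(
        genes_iv,
        n_lncrnas=cfg.n_lncrnas,
        hits_per_lncrna=cfg.hits_per_lncrna,
        focal_gene_bias=cfg.focal_gene_bias,
        seed=_stage_seed(cfg.seed, 10),
    )
    filt = lncrna_hits.filter_hits(
        hits,
        min_len=cfg.hit_min_len,
        min_cov=cfg.hit_min_cov,
        min_ident=cfg.hit_min_ident,
    )
    assigned = lncrna_hits.annotate_containment(filt, genes_iv, flank=cfg.flank)
    focal_genes = set(genes_iv.loc[genes_iv["focal"], "gene_id"])
    hit_enr = lncrna_hits.hit_enrichment(
        assigned,
        focal_genes,
        set(genes_iv["gene_id"]),
        n_resample=cfg.n_resample,
        seed=_stage_seed(cfg.seed, 11),
    )
    _write(assigned, out / "lncrna_hits.tsv")
    summary["lncrna_hits"] = {
        "n_hits_raw": len(hits),
        "n_hits_filtered": len(filt),
        "n_antisense": int((assigned["orientation"] == "antisense").sum()),
        "enrichment": hit_enr,
    }

    # ---- stage 7: network integration -----------------------------------
    rng_net = np.random.default_rng(_stage_seed(cfg.seed, 12))
    nodes = [f"n{i + 1:04d}" for i in range(cfg.interactome_nodes)]
    node_labels = {}
    de_nodes = nodes[: cfg.module_size]
    ce_nodes = nodes[cfg.module_size : 2 * cfg.module_size]
    for n in de_nodes:
        node_labels[n] = "DE"
    for n in ce_nodes:
        node_labels[n] = "CE"
    graph, _net_truth = synthetic.simulate_interactome(
        cfg.interactome_nodes,
        cfg.background_edge_prob,
        set_A=de_nodes,
        set_B=ce_nodes,
        planted_edge_prob=cfg.planted_edge_prob,
        seed=_stage_seed(cfg.seed, 13),
        min_score=cfg.min_score,
    )
    combined = set(de_nodes) | set(ce_nodes)
    edge_enr = network.edge_enrichment(
        graph, combined, n_resample=cfg.n_resample,
        seed=_stage_seed(cfg.seed, 14),
    )
    comps, isolated = network.components(graph, combined)
    sub = graph.subgraph(combined)
    metrics = network.node_metrics(sub)
    contrasts = network.compare_groups(metrics, node_labels)
    _write(metrics.reset_index(), out / "network_metrics.tsv")
    _write(contrasts, out / "network_contrasts.tsv")
    summary["network"] = {
        "observed_edges": edge_enr["observed"],
        "expected_edges": round(edge_enr["expected"], 3),
        "enrichment_p": edge_enr["p"],
        "component_sizes": [len(c) for c in comps],
        "n_isolated": len(isolated),
        "contrasts": {
            f"{r.metric}_{r.test}": round(float(r.p), 6)
            for r in contrasts.itertuples()
        },
    }

    # ---- truth-based recovery scores ------------------------------------
    planted_con = set(truth.index[truth["convergence_class"] == "constrained"])
    planted_erc = set(truth.index[truth["is_erc_linked"]])
    tested = universe
    summary["recovery"] = {
        "constrained_recall": (
            len(constrained & planted_con) / len(planted_con & tested)
            if planted_con & tested
            else float("nan")
        ),
        "constrained_false_sign": (
            len(accelerated & planted_con) / len(planted_con & tested)
            if planted_con & tested
            else float("nan")
        ),
        "de_recall": (
            len(de_called & set(count_truth.index[count_truth["is_de"]]))
            / max(int(count_truth["is_de"].sum()), 1)
        ),
        "erc_sig_in_linked": (
            len(erc_sig & planted_erc) / len(planted_erc & tested)
            if planted_erc & tested
            else float("nan")
        ),
    }

    def _default(o):
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return summary
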