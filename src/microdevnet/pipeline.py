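"""End-to-end orchestration: simulate -> DE -> enrichment -> separation -> network.

One YAML-serializable config drives the whole run; a master seed fans out
into named child streams (``[master, stage_offset]``) so any stage can be
rerun in isolation and reproduce its outputs bit-identically. All tables
are TSV with headers; metadata and the run summary are JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import STAGES, CountMatrix, make_design
from . import expression, enrichment, separation, funcnet
from .genesets import GeneSetCollection
from .simulate import (
    EvidenceCollection,
    SimulationConfig,
    config_from_dict,
    generate_counts,
    generate_evidence,
    generate_gene_sets,
    generate_known_interactions,
)

# child-seed offsets per stage
SEED_SIMULATE, SEED_SEPARATION, SEED_NETWORK = 10, 20, 30


@dataclass
class PipelineConfig:
    """All pipeline parameters with the study-scale defaults."""

    seed: int = 0
    n_genes: int = 10_000
    n_replicates: int = 4
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    focal_stage: str = "brain_rudiment"
    reference_stages: tuple[str, ...] = ("yolk_sac", "neonate", "adult")
    n_perm: int = 1000
    subsample_genes: int = 5000
    subsample_reps: int = 100
    n_go_like: int = 50
    size_min: int = 10
    size_max: int = 500
    go_fdr: float = 0.01
    tf_fdr: float = 0.1
    vst_prior_count: float = 1.0
    # network stage
    n_network_genes: int = 200
    n_evidence_datasets: int = 10
    within_module_signal: float = 0.8
    evidence_noise_sd: float = 0.5
    known_coverage: float = 0.8
    n_negatives_per_positive: float = 19.0
    n_bins: int = 5
    smoothing_alpha: float = 1.0
    min_fold_over_prior: float = 5.0
    top_k: int = 25
    max_steps: int = 2
    cpm_high_cut: float = 50.0
    cpm_low_cut: float = 10.0
    n_cv_folds: int = 5
    seed_gene: str | None = None  # default: first gene of the first module
    query_tfs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.focal_stage not in STAGES:
            raise ValueError(f"unknown focal stage {self.focal_stage!r}")
        for st in self.reference_stages:
            if st not in STAGES:
                raise ValueError(f"unknown reference stage {st!r}")
        if not (0 < self.go_fdr < 1 and 0 < self.tf_fdr < 1):
            raise ValueError("FDR cutoffs must lie in (0, 1)")
        if self.min_fold_over_prior <= 0 or self.top_k < 1 or self.max_steps < 1:
            raise ValueError("network thresholds out of domain")

    def sim_config(self) -> SimulationConfig:
        return config_from_dict(self.simulation) if self.simulation else SimulationConfig()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("reference_stages", "query_tfs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in dependency order; returns the summary dict.

    Artifacts land under ``outdir`` with deterministic names; the summary
    JSON records each statistic with its producing stage and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    # --- simulate ---------------------------------------------------------
    design = make_design(config.n_replicates)
    counts, truth = generate_counts(
        config.n_genes, design, config.sim_config(), seed=[config.seed, SEED_SIMULATE]
    )
    counts.to_tsv(out / "counts.tsv", out / "design.tsv")
    sets = generate_gene_sets(
        truth,
        config.n_go_like,
        size_range=(5, min(600, config.n_genes)),
        seed=[config.seed, SEED_SIMULATE],
        universe=counts.genes,
    )
    sets.to_gmt(out / "gene_sets.gmt")
    summary["simulate"] = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "n_samples": len(design),
        "n_de_planted": {st: len(d) for st, d in truth.de_genes_by_stage.items()},
    }

    # --- differential expression -----------------------------------------
    de_by_stage = expression.de_all_stages(counts)
    for stage, de in de_by_stage.items():
        de.to_csv(out / f"de_{stage}.tsv", sep="\t", index=False)
    summary["de"] = {
        "stage": "expression_core",
        "n_significant": {
            st: int((de["fdr"] < config.tf_fdr).sum()) for st, de in de_by_stage.items()
        },
    }

    # --- enrichment -------------------------------------------------------
    go = sets.subset("go_like")
    regulons = sets.subset("tf_regulon")
    focal_de = de_by_stage[config.focal_stage]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        go_res = enrichment.page_enrich(
            focal_de, go, size_min=config.size_min, size_max=config.size_max
        )
    go_res.to_csv(out / "enrichment_go.tsv", sep="\t", index=False)
    heat = enrichment.tf_z_heatmap(de_by_stage, regulons)
    heat.to_csv(out / "tf_z_heatmap.tsv", sep="\t")
    frac, frac_agg = enrichment.tf_target_fraction(
        de_by_stage, regulons, fdr_cut=config.tf_fdr
    )
    frac.to_csv(out / "tf_target_fraction.tsv", sep="\t", index=False)
    frac_agg.to_csv(out / "tf_target_fraction_aggregate.tsv", sep="\t", index=False)
    summary["enrichment"] = {
        "stage": "enrichment",
        "n_go_tested": int(len(go_res)),
        "n_go_significant": int((go_res["fdr"] <= config.go_fdr).sum()) if len(go_res) else 0,
        "top_go_set": str(go_res["set_name"].iloc[0]) if len(go_res) else None,
        "tf_fraction_aggregate": {
            str(r["stage"]): (None if pd.isna(r["fraction"]) else round(float(r["fraction"]), 6))
            for _, r in frac_agg.iterrows()
        },
    }

    # --- separation -------------------------------------------------------
    expr = expression.vst(counts, prior_count=config.vst_prior_count)
    mds = separation.classical_mds(separation.euclidean_distances(expr), k=3)
    mds.coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t")
    perm_results = {}
    for i, ref in enumerate(config.reference_stages):
        res = separation.permutation_test(
            expr,
            config.focal_stage,
            ref,
            n_perm=config.n_perm,
            seed=[config.seed, SEED_SEPARATION, i],
        )
        perm_results[ref] = {
            "observed": res.observed,
            "b": res.b,
            "n_perm": res.n_perm,
            "pvalue": res.pvalue,
            "seed": config.seed,
        }
    pd.DataFrame(
        [{"reference_stage": k, **v} for k, v in perm_results.items()]
    ).to_csv(out / "permutation_tests.tsv", sep="\t", index=False)

    sig_res = separation.signature_test(
        expr,
        truth.signature_genes,
        config.focal_stage,
        config.reference_stages[0],
        n_perm=config.n_perm,
        seed=[config.seed, SEED_SEPARATION, 100],
    )
    scores, evr = separation.signature_pca(expr, truth.signature_genes, k=2)
    scores.to_csv(out / "signature_pca.tsv", sep="\t")
    summary["separation"] = {
        "stage": "separation",
        "permutation_pvalues": {k: v["pvalue"] for k, v in perm_results.items()},
        "signature_test_pvalue": sig_res.pvalue,
        "signature_pca_explained": [round(float(x), 6) for x in evr],
        "mds_negative_eigenvalue_mass": round(mds.negative_eigenvalue_mass, 9),
    }
    if config.subsample_reps > 0:
        pvals, med = separation.subsample_robustness(
            expr,
            config.focal_stage,
            config.reference_stages[0],
            n_genes=min(config.subsample_genes, config.n_genes),
            n_reps=config.subsample_reps,
            n_perm=config.n_perm,
            seed=config.seed + SEED_SEPARATION,
        )
        pd.DataFrame({"replicate": range(len(pvals)), "pvalue": pvals}).to_csv(
            out / "subsample_pvalues.tsv", sep="\t", index=False
        )
        summary["separation"]["subsample_median_pvalue"] = med

    # --- functional network ----------------------------------------------
    net_genes = counts.genes[: config.n_network_genes]
    net_truth = _network_truth(truth, net_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evidence = generate_evidence(
            net_truth,
            config.n_evidence_datasets,
            within_module_signal=config.within_module_signal,
            noise_sd=config.evidence_noise_sd,
            seed=[config.seed, SEED_NETWORK],
        )
        evidence.to_tsv(out / "evidence")
        known = generate_known_interactions(
            net_truth, coverage=config.known_coverage, seed=[config.seed, SEED_NETWORK]
        )
        c = expression.cpm(counts)
        rud = c.values.loc[:, (c.design["stage"] == "brain_rudiment").to_numpy()]
        adu = c.values.loc[:, (c.design["stage"] == "adult").to_numpy()]
        from .datatypes import ExpressionMatrix

        ctx = funcnet.context_genes(
            ExpressionMatrix(rud, "cpm"),
            ExpressionMatrix(adu, "cpm"),
            high_cut=config.cpm_high_cut,
            low_cut=config.cpm_low_cut,
            comparative_sets=(set(net_genes),),
        )
        gold = funcnet.build_gold_standard(
            ctx,
            known,
            pair_universe={
                funcnet.canonical_pair(a, b)
                for df in evidence.datasets.values()
                for a, b in zip(df["gene_a"], df["gene_b"])
            },
            n_negatives_per_positive=config.n_negatives_per_positive,
            seed=[config.seed, SEED_NETWORK],
        )
        gold.to_tsv(out / "gold_standard.tsv")
        binned = funcnet.bin_evidence(evidence, n_bins=config.n_bins)
        model = funcnet.train_nb(gold, binned, smoothing_alpha=config.smoothing_alpha)
        model.to_json(out / "nb_model.json")
        net = funcnet.score_pairs(model, binned)
        net.to_tsv(out / "network_edges.tsv")
        strong = funcnet.threshold_network(net, config.min_fold_over_prior)
        strong.to_tsv(out / "network_edges_strong.tsv")
        cv = funcnet.cross_validate(
            gold,
            evidence,
            n_folds=config.n_cv_folds,
            seed=config.seed + SEED_NETWORK,
            n_bins=config.n_bins,
            smoothing_alpha=config.smoothing_alpha,
        )
    seed_gene = config.seed_gene or next(iter(net_truth.modules.values()))[0]
    neighbors = funcnet.top_neighbors(net, seed_gene, k=config.top_k)
    tf_query = list(config.query_tfs) or neighbors[: min(2, len(neighbors))]
    links = funcnet.link_tfs(strong, neighbors, tf_query, max_steps=config.max_steps)
    try:
        recap = funcnet.de_recapitulation(neighbors, focal_de, fdr_cut=config.tf_fdr)
    except ValueError:
        recap = {"pvalue": None, "overlap": None}
    _write_json(
        out / "network_query.json",
        {
            "seed_gene": seed_gene,
            "top_neighbors": neighbors,
            "tf_links": {
                tf: {"present": v["present"], "links": {g: p for g, p in v["links"].items()}}
                for tf, v in links.items()
            },
        },
    )
    summary["network"] = {
        "stage": "funcnet",
        "seed": config.seed,
        "n_edges": int(len(net)),
        "n_edges_strong": int(len(strong)),
        "cv_auc": round(cv["auc"], 6),
        "cv_average_precision": round(cv["average_precision"], 6),
        "seed_gene": seed_gene,
        "n_top_neighbors": len(neighbors),
        "n_tfs_linked": sum(1 for v in links.values() if v["links"]),
        "de_recapitulation_pvalue": recap["pvalue"],
        "de_recapitulation_overlap": recap["overlap"],
    }

    _write_json(out / "summary.json", summary)
    return summary


def _network_truth(truth, net_genes):
    """Restrict the planted module graph to the network gene subset."""
    from .simulate import SimulationTruth

    keep = set(net_genes)
    modules = {
        m: [g for g in genes if g in keep] for m, genes in truth.modules.items()
    }
    modules = {m: gs for m, gs in modules.items() if len(gs) >= 3}
    return SimulationTruth(
        de_genes_by_stage=truth.de_genes_by_stage,
        signature_genes=[g for g in truth.signature_genes if g in keep],
        regulons=truth.regulons,
        modules=modules,
        dispersion=truth.dispersion,
        library_size_range=truth.library_size_range,
    )


def make_report(run_dir) -> str:
    """Deterministic human-readable report from a completed run directory.

    Incomplete runs yield a partial report with missing-section markers;
    every number is read back from summary.json so the two cannot diverge.
    """
    run = Path(run_dir)
    summary_path = run / "summary.json"
    lines = ["# microdevnet run report", ""]
    if not summary_path.exists():
        lines.append("[MISSING] summary.json not found; run incomplete.")
        report = "\n".join(lines) + "\n"
        (run / "report.md").write_text(report)
        return report
    s = json.loads(summary_path.read_text())

    lines += ["## Differential expression", ""]
    if "de" in s:
        for st, n in sorted(s["de"]["n_significant"].items()):
            lines.append(f"- {st}: {n} genes significant")
    else:
        lines.append("[MISSING] differential expression section")
    lines += ["", "## Enrichment", ""]
    if "enrichment" in s:
        e = s["enrichment"]
        if e["n_go_tested"] == 0:
            lines.append("- no sets passed the size filter")
        else:
            lines.append(f"- {e['n_go_tested']} GO-like sets tested, "
                         f"{e['n_go_significant']} significant; top set: {e['top_go_set']}")
        for st, f in sorted((e.get("tf_fraction_aggregate") or {}).items()):
            lines.append(f"- TF-target DE fraction, {st}: {f}")
    else:
        lines.append("[MISSING] enrichment section")
    lines += ["", "## Separation", ""]
    if "separation" in s:
        for ref, p in sorted(s["separation"]["permutation_pvalues"].items()):
            lines.append(f"- permutation p vs {ref}: {p}")
        lines.append(f"- signature test p: {s['separation']['signature_test_pvalue']}")
        if "subsample_median_pvalue" in s["separation"]:
            lines.append(
                f"- subsample median p: {s['separation']['subsample_median_pvalue']}"
            )
    else:
        lines.append("[MISSING] separation section")
    lines += ["", "## Functional network", ""]
    if "network" in s:
        n = s["network"]
        lines.append(f"- edges: {n['n_edges']} ({n['n_edges_strong']} strong)")
        lines.append(f"- cross-validated AUC: {n['cv_auc']}")
        lines.append(
            f"- seed gene {n['seed_gene']}: {n['n_top_neighbors']} top neighbors, "
            f"{n['n_tfs_linked']} TFs linked"
        )
        lines.append(f"- DE recapitulation p: {n['de_recapitulation_pvalue']}")
    else:
        lines.append("[MISSING] network section")
    report = "\n".join(lines) + "\n"
    (run / "report.md").write_text(report)
    return report
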