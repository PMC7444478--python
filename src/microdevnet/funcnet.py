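"""Tissue-context functional gene network by naive-Bayes evidence integration.

A gold standard of gene pairs is built from expression context rules
(highly expressed in brain-rudiment microglia, CPM > 50, and low in adult,
CPM < 10, optionally extended by comparative marker sets) crossed with a
known-interaction list. Per-dataset gene-pair evidence is discretized into
quantile bins (with a reserved missing-evidence bin) and a naive Bayes
classifier turns prior odds into per-pair posterior odds:

    posterior_odds(pair) = prior_odds * prod_d P(bin_d | linked) / P(bin_d | unlinked)

Edges at >= 5-fold over prior form the displayed network; queries return a
seed gene's top-25 neighborhood and the genes linking it to transcription
factors within two steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import ExpressionMatrix
from .simulate import EvidenceCollection, _rng

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


def context_genes(
    rudiment_expr: ExpressionMatrix,
    adult_expr: ExpressionMatrix,
    high_cut: float = 50.0,
    low_cut: float = 10.0,
    comparative_sets: tuple = (),
) -> set[str]:
    """Brain-rudiment context genes by strict CPM rules plus comparative sets.

    {g : mean rudiment CPM > high_cut and mean adult CPM < low_cut} union
    any supplied marker sets (e.g. microglia-vs-other-cell-type lists).
    """
    if rudiment_expr.transform != "cpm" or adult_expr.transform != "cpm":
        raise ValueError("context rules are defined on CPM matrices")
    shared = [g for g in rudiment_expr.genes if g in set(adult_expr.genes)]
    r_mean = rudiment_expr.values.loc[shared].mean(axis=1)
    a_mean = adult_expr.values.loc[shared].mean(axis=1)
    core = set(r_mean.index[(r_mean > high_cut) & (a_mean < low_cut)])
    for s in comparative_sets:
        core |= set(s)
    return core


@dataclass
class GoldStandard:
    positives: set[Pair]
    negatives: set[Pair]
    context_genes: set[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positive and negative pairs overlap")
        for a, b in self.positives:
            if a not in self.context_genes or b not in self.context_genes:
                raise ValueError(f"positive pair ({a}, {b}) outside context genes")

    def to_tsv(self, path) -> None:
        rows = [(a, b, 1) for a, b in sorted(self.positives)] + [
            (a, b, 0) for a, b in sorted(self.negatives)
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]).to_csv(
            path, sep="\t", index=False
        )


def build_gold_standard(
    context: set[str],
    known_pairs,
    pair_universe,
    n_negatives_per_positive: float = 19.0,
    seed: int = 0,
) -> GoldStandard:
    """Positives: known pairs inside the context. Negatives: sampled pairs
    that are either not known interactions or have a member outside context.
    """
    known = {canonical_pair(*p) for p in known_pairs}
    universe = {canonical_pair(*p) for p in pair_universe}
    positives = {p for p in known if p[0] in context and p[1] in context}
    if not positives:
        raise ValueError(
            f"no positive pairs: {len(known)} known pairs, "
            f"{len(context)} context genes, {len(universe)} universe pairs"
        )
    candidates = sorted(
        p for p in universe if (p not in known) or (p[0] not in context or p[1] not in context)
    )
    candidates = [p for p in candidates if p not in positives]
    if not candidates:
        raise ValueError("no negative candidates in the pair universe")
    n_neg = int(round(n_negatives_per_positive * len(positives)))
    rng = _rng(seed, 5)
    if n_neg >= len(candidates):
        warnings.warn(
            f"only {len(candidates)} negative candidates for requested {n_neg}",
            stacklevel=2,
        )
        negatives = set(candidates)
    else:
        idx = rng.choice(len(candidates), size=n_neg, replace=False)
        negatives = {candidates[i] for i in idx}
    return GoldStandard(positives=positives, negatives=negatives, context_genes=set(context))


@dataclass
class BinnedEvidence:
    """Quantile-discretized evidence; bin index n_bins is the missing bin."""

    n_bins: int
    bin_edges: dict[str, np.ndarray]  # dataset -> interior edges
    assignments: dict[str, dict[Pair, int]]  # dataset -> pair -> bin

    @property
    def missing_bin(self) -> int:
        return self.n_bins

    def bin_of(self, dataset: str, pair: Pair) -> int:
        return self.assignments[dataset].get(pair, self.missing_bin)

    def pair_universe(self) -> set[Pair]:
        out: set[Pair] = set()
        for a in self.assignments.values():
            out.update(a)
        return out


def bin_evidence(evidence: EvidenceCollection, n_bins: int = 5) -> BinnedEvidence:
    """Quantile-bin each dataset's scores; absent pairs map to the missing bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges: dict[str, np.ndarray] = {}
    assignments: dict[str, dict[Pair, int]] = {}
    for name, df in evidence.datasets.items():
        scores = df["score"].to_numpy(dtype=float)
        if np.ptp(scores) == 0:
            warnings.warn(f"dataset {name!r} has constant scores: single usable bin",
                          stacklevel=2)
        # rank-based quantile bins: occupancies balanced to within 1 for
        # tie-free scores (interpolated quantile edges do not guarantee this)
        n = len(scores)
        order = np.argsort(scores, kind="stable")
        bins = np.empty(n, dtype=int)
        bins[order] = np.arange(n) * n_bins // n
        srt = scores[order]
        cuts = np.arange(1, n_bins) * n / n_bins
        e = np.array([srt[min(int(np.ceil(c)) - 1, n - 1)] for c in cuts])
        edges[name] = e
        assignments[name] = {
            canonical_pair(a, b): int(k)
            for a, b, k in zip(df["gene_a"], df["gene_b"], bins)
        }
    return BinnedEvidence(n_bins=n_bins, bin_edges=edges, assignments=assignments)


@dataclass
class NaiveBayesModel:
    prior_odds: float
    n_bins: int
    p_pos: dict[str, np.ndarray]  # dataset -> P(bin | linked), length n_bins+1
    p_neg: dict[str, np.ndarray]
    bin_edges: dict[str, np.ndarray]
    smoothing_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_odds <= 0:
            raise ValueError("prior_odds must be positive")
        for tab in (self.p_pos, self.p_neg):
            for name, row in tab.items():
                row = np.asarray(row, dtype=float)
                if not np.isclose(row.sum(), 1.0):
                    raise ValueError(f"conditional table for {name!r} does not sum to 1")
                if (row <= 0).any():
                    raise ValueError(f"zero probability in table for {name!r} after smoothing")

    def log_likelihood_ratio(self, dataset: str, bin_idx: int) -> float:
        return float(np.log(self.p_pos[dataset][bin_idx]) - np.log(self.p_neg[dataset][bin_idx]))

    def to_json(self, path) -> None:
        obj = {
            "prior_odds": self.prior_odds,
            "n_bins": self.n_bins,
            "smoothing_alpha": self.smoothing_alpha,
            "p_pos": {k: list(v) for k, v in self.p_pos.items()},
            "p_neg": {k: list(v) for k, v in self.p_neg.items()},
            "bin_edges": {k: list(map(float, v)) for k, v in self.bin_edges.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "NaiveBayesModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            prior_odds=obj["prior_odds"],
            n_bins=obj["n_bins"],
            smoothing_alpha=obj["smoothing_alpha"],
            p_pos={k: np.array(v) for k, v in obj["p_pos"].items()},
            p_neg={k: np.array(v) for k, v in obj["p_neg"].items()},
            bin_edges={k: np.array(v) for k, v in obj["bin_edges"].items()},
        )


def train_nb(
    gold: GoldStandard, binned: BinnedEvidence, smoothing_alpha: float = 1.0
) -> NaiveBayesModel:
    """Count-based conditional tables with additive (Laplace) smoothing.

    prior_odds is the constructed positive:negative ratio. Datasets covering
    no gold pair (all gold pairs in the missing bin) are dropped with a
    warning.
    """
    if not gold.positives or not gold.negatives:
        raise ValueError("both gold-standard classes must be nonempty")
    if smoothing_alpha <= 0:
        raise ValueError("smoothing_alpha must be positive")
    n_cells = binned.n_bins + 1
    p_pos: dict[str, np.ndarray] = {}
    p_neg: dict[str, np.ndarray] = {}
    edges: dict[str, np.ndarray] = {}
    for name in binned.assignments:
        cp = np.zeros(n_cells)
        cn = np.zeros(n_cells)
        for pair in gold.positives:
            cp[binned.bin_of(name, pair)] += 1
        for pair in gold.negatives:
            cn[binned.bin_of(name, pair)] += 1
        if cp[: binned.n_bins].sum() + cn[: binned.n_bins].sum() == 0:
            warnings.warn(f"dataset {name!r} covers no gold pair; dropped", stacklevel=2)
            continue
        p_pos[name] = (cp + smoothing_alpha) / (cp.sum() + smoothing_alpha * n_cells)
        p_neg[name] = (cn + smoothing_alpha) / (cn.sum() + smoothing_alpha * n_cells)
        edges[name] = binned.bin_edges[name]
    return NaiveBayesModel(
        prior_odds=len(gold.positives) / len(gold.negatives),
        n_bins=binned.n_bins,
        p_pos=p_pos,
        p_neg=p_neg,
        bin_edges=edges,
        smoothing_alpha=smoothing_alpha,
    )


@dataclass
class FunctionalNetwork:
    """Gene-pair posterior-odds edges over a stated prior."""

    edges: pd.DataFrame  # gene_a, gene_b, posterior_odds, fold_over_prior
    prior_odds: float

    def __post_init__(self) -> None:
        po = self.edges["posterior_odds"].to_numpy(dtype=float)
        if len(po) and (not np.isfinite(po).all() or (po <= 0).any()):
            raise ValueError("posterior odds must be finite and positive")
        bad = self.edges["gene_a"] >= self.edges["gene_b"]
        if bad.any():
            raise ValueError("edges must be stored with gene_a < gene_b")

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, po in self.edges[["gene_a", "gene_b", "posterior_odds"]].itertuples(
            index=False
        ):
            g.add_edge(a, b, posterior_odds=float(po))
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, prior_odds: float) -> "FunctionalNetwork":
        return cls(pd.read_csv(path, sep="\t"), prior_odds)


def score_pairs(
    model: NaiveBayesModel, binned: BinnedEvidence, pairs=None
) -> FunctionalNetwork:
    """Posterior odds for every pair (default: the binned pair universe).

    Pairs with all-missing evidence are scored through the missing-bin
    likelihood ratios, not skipped.
    """
    if pairs is None:
        pairs = sorted(binned.pair_universe())
    else:
        pairs = sorted(canonical_pair(*p) for p in pairs)
    log_prior = np.log(model.prior_odds)
    rows = []
    for pair in pairs:
        llr = sum(
            model.log_likelihood_ratio(name, binned.bin_of(name, pair))
            for name in model.p_pos
        )
        po = float(np.exp(log_prior + llr))
        rows.append((pair[0], pair[1], po, float(np.exp(llr))))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "posterior_odds", "fold_over_prior"])
    return FunctionalNetwork(edges=edges, prior_odds=model.prior_odds)


def threshold_network(net: FunctionalNetwork, min_fold_over_prior: float = 5.0) -> FunctionalNetwork:
    """Keep edges at >= the fold-over-prior cutoff (inclusive)."""
    if min_fold_over_prior <= 0:
        raise ValueError("min_fold_over_prior must be positive")
    keep = net.edges["fold_over_prior"] >= min_fold_over_prior
    return FunctionalNetwork(net.edges.loc[keep].reset_index(drop=True), net.prior_odds)


def top_neighbors(net: FunctionalNetwork, seed_gene: str, k: int = 25) -> list[str]:
    """The k genes with the highest posterior-odds edges to the seed.

    Ties break lexicographically; fewer than k are returned when the seed
    has fewer partners.
    """
    e = net.edges
    touching = e[(e["gene_a"] == seed_gene) | (e["gene_b"] == seed_gene)]
    if seed_gene not in net.genes():
        raise ValueError(f"seed gene {seed_gene!r} not in the pair universe")
    partners = np.where(
        touching["gene_a"] == seed_gene, touching["gene_b"], touching["gene_a"]
    )
    df = pd.DataFrame({"partner": partners, "odds": touching["posterior_odds"].to_numpy()})
    df = df.sort_values(["odds", "partner"], ascending=[False, True], kind="stable")
    return list(df["partner"].head(k))


def link_tfs(
    net_thresholded: FunctionalNetwork,
    neighborhood,
    tfs,
    max_steps: int = 2,
) -> dict[str, dict]:
    """Neighborhood genes reaching each TF within max_steps thresholded edges.

    Returns per TF: ``{"present": bool, "links": {gene: shortest path}}``
    where each path runs from the neighborhood gene to the TF. TFs absent
    from the network are reported unreachable, not an error.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    g = net_thresholded.to_graph()
    hood = [x for x in neighborhood]
    out: dict[str, dict] = {}
    for tf in tfs:
        if tf not in g:
            out[tf] = {"present": False, "links": {}}
            continue
        paths = nx.single_source_shortest_path(g, tf, cutoff=max_steps)
        links = {
            gene: list(reversed(paths[gene]))
            for gene in hood
            if gene in paths and gene != tf
        }
        out[tf] = {"present": True, "links": links}
    return out


def cross_validate(
    gold: GoldStandard,
    evidence: EvidenceCollection,
    n_folds: int = 5,
    seed: int = 0,
    n_bins: int = 5,
    smoothing_alpha: float = 1.0,
) -> dict:
    """Stratified pair-level cross-validation of the classifier.

    Bin edges are computed once on all observed scores (unsupervised); each
    fold retrains the conditional tables on its training pairs only and
    scores the held-out pairs. Reports pooled ROC AUC and average precision.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    binned = bin_evidence(evidence, n_bins=n_bins)
    pairs = sorted(gold.positives) + sorted(gold.negatives)
    labels = np.array([1] * len(gold.positives) + [0] * len(gold.negatives))
    for attempt in range(2):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) + attempt)
        folds = list(skf.split(np.zeros(len(pairs)), labels))
        ok = all(
            labels[tr].min() == 0 and labels[tr].max() == 1 and len(te) > 0
            for tr, te in folds
        )
        if ok:
            break
    else:
        raise ValueError("could not form folds with both classes present")
    scores = np.empty(len(pairs))
    for tr, te in folds:
        tr_set = {pairs[i] for i in tr}
        fold_gold = GoldStandard(
            positives=gold.positives & tr_set,
            negatives=gold.negatives & tr_set,
            context_genes=gold.context_genes,
        )
        model = train_nb(fold_gold, binned, smoothing_alpha=smoothing_alpha)
        log_prior = np.log(model.prior_odds)
        for i in te:
            llr = sum(
                model.log_likelihood_ratio(name, binned.bin_of(name, pairs[i]))
                for name in model.p_pos
            )
            scores[i] = log_prior + llr
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "average_precision": float(average_precision_score(labels, scores)),
        "n_positives": int(labels.sum()),
        "n_negatives": int(len(labels) - labels.sum()),
        "n_folds": n_folds,
        "seed": int(seed),
    }


def de_recapitulation(
    neighbors, de: pd.DataFrame, fdr_cut: float = 0.1
) -> dict:
    """Hypergeometric enrichment of DE genes among a network neighborhood.

    One-sided tail probability of >= the observed overlap between the
    neighbor list and genes at fdr < fdr_cut, with the tested genes as the
    universe. Neighbors outside the tested universe are reported and dropped.
    """
    neighbors = list(dict.fromkeys(neighbors))
    if not neighbors:
        raise ValueError("neighbor list is empty")
    universe = set(de["gene"])
    dropped = [g for g in neighbors if g not in universe]
    kept = [g for g in neighbors if g in universe]
    if not kept:
        raise ValueError("no neighbor overlaps the tested universe")
    de_genes = set(de.loc[de["fdr"] < fdr_cut, "gene"])
    overlap = len(de_genes & set(kept))
    M, K, n = len(universe), len(de_genes), len(kept)
    pvalue = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    return {
        "pvalue": pvalue,
        "overlap": overlap,
        "n_neighbors_tested": n,
        "n_de": K,
        "universe": M,
        "dropped": dropped,
    }


def map_orthologs(net: FunctionalNetwork, ortholog_map: pd.DataFrame) -> tuple[FunctionalNetwork, int]:
    """Rename edges through a two-column (source/target) ortholog table.

    The map must be injective in both columns; edges with an unmapped
    endpoint are dropped and counted. Returns (mapped network, n_dropped).
    """
    for col in ("source", "target"):
        dup = ortholog_map[col][ortholog_map[col].duplicated()]
        if len(dup):
            rows = ortholog_map[ortholog_map[col].isin(set(dup))]
            raise ValueError(f"ortholog map not injective in {col!r}:\n{rows}")
    mapping = dict(zip(ortholog_map["source"], ortholog_map["target"]))
    rows = []
    dropped = 0
    for a, b, po, fop in net.edges.itertuples(index=False):
        if a in mapping and b in mapping:
            na, nb = canonical_pair(mapping[a], mapping[b])
            rows.append((na, nb, po, fop))
        else:
            dropped += 1
    edges = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "posterior_odds", "fold_over_prior"]
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    return FunctionalNetwork(edges=edges, prior_odds=net.prior_odds), dropped
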