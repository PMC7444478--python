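"""Synthetic data with planted ground truth for every pipeline input.

The generator emulates the study design end to end: negative-binomial
gene x sample counts over 4 stages x 2 genotypes with stage-specific planted
genotype effects, GO-like gene sets and TF regulons, a microglia identity
signature, a planted functional-module graph with per-dataset gene-pair
evidence scores, a known-interaction list, and an ortholog table.

All generators are pure functions of (config, seed). Child streams are
derived as ``np.random.default_rng([seed, stream_index])`` so individual
stages can be rerun in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import STAGES, GENOTYPES, CountMatrix, validate_design
from .genesets import GeneSetCollection


def _rng(seed, stream: int) -> np.random.Generator:
    """Child generator for (seed, stream); seed may be an int or an int sequence."""
    if np.isscalar(seed):
        key = [int(seed), stream]
    else:
        key = [int(s) for s in seed] + [stream]
    return np.random.default_rng(key)


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic study.

    Defaults mirror the study analog: a common NB dispersion of 0.1,
    library sizes of 1-2 million reads, and a |log2FC| = 2 genotype effect
    planted on 10% of genes in the brain rudiment stage only.
    """

    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    de_stages: tuple[str, ...] = ("brain_rudiment",)
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    baseline_sigma: float = 1.5  # log-sd of relative gene abundances
    stage_effect_fraction: float = 0.3
    stage_effect_sd: float = 1.0  # log2 units, per affected gene per stage
    n_signature: int = 239
    signature_de_fraction: float = 0.5
    n_tfs: int = 18
    regulon_size_range: tuple[int, int] = (20, 100)
    n_perturbed_tfs: int = 3
    regulon_de_fraction: float = 0.6
    module_size: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        for st in self.de_stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage in de_stages: {st!r}")


@dataclass
class SimulationTruth:
    """Planted ground truth recoverable without re-simulation."""

    de_genes_by_stage: dict[str, dict[str, float]]  # stage -> gene -> signed log2FC
    signature_genes: list[str]
    regulons: dict[str, set[str]]
    modules: dict[str, list[str]]  # module name -> genes; partitions the universe
    dispersion: float
    library_size_range: tuple[int, int]
    perturbed_tf_stage: dict[str, str] = field(default_factory=dict)

    @property
    def module_of(self) -> dict[str, str]:
        return {g: m for m, genes in self.modules.items() for g in genes}

    def within_module_pairs(self) -> list[tuple[str, str]]:
        pairs: list[tuple[str, str]] = []
        for genes in self.modules.values():
            pairs.extend(itertools.combinations(sorted(genes), 2))
        return pairs


def sample_nb(mu, dispersion: float, rng: np.random.Generator):
    """Draw NB counts with variance mu + dispersion * mu^2 (gamma-Poisson).

    dispersion = 0 is the Poisson limit.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def _gene_names(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_counts(
    n_genes: int,
    design: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate NB counts with planted stage and genotype structure.

    Per-gene baselines are log-normal relative abundances; a subset of genes
    carries stage effects; planted DE genes of each configured stage carry a
    signed genotype (KI vs WT) log2 effect applied to KI samples of that
    stage only. Library sizes are drawn log-uniformly within the configured
    range and enter through the NB mean.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    config = config or SimulationConfig()
    design = validate_design(design, require_full=True)
    genes = _gene_names(n_genes)
    rng = _rng(seed, 0)

    w = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_genes)
    w /= w.sum()

    lo, hi = config.library_size_range
    n_samples = len(design)
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    # stage effects: log2 shifts for a random subset of genes, per stage
    stage_eff = np.zeros((n_genes, len(STAGES)))
    n_aff = int(round(config.stage_effect_fraction * n_genes))
    if n_aff and config.stage_effect_sd > 0:
        aff = rng.choice(n_genes, size=n_aff, replace=False)
        stage_eff[aff, :] = rng.normal(0.0, config.stage_effect_sd, size=(n_aff, len(STAGES)))

    # planted genotype effects, stage-specific
    geno_eff = np.zeros((n_genes, len(STAGES)))
    de_by_stage: dict[str, dict[str, float]] = {st: {} for st in STAGES}
    n_de = int(round(config.de_fraction * n_genes))
    for st in config.de_stages:
        if n_de == 0 or config.de_log2fc == 0:
            continue
        si = STAGES.index(st)
        idx = rng.choice(n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        geno_eff[idx, si] = signs * config.de_log2fc
        de_by_stage[st] = {genes[i]: float(signs[k] * config.de_log2fc) for k, i in enumerate(idx)}

    stage_idx = np.array([STAGES.index(st) for st in design["stage"]])
    is_ki = (design["genotype"] == "KI").to_numpy()
    log2_shift = stage_eff[:, stage_idx] + geno_eff[:, stage_idx] * is_ki[None, :]
    mu = libs[None, :] * w[:, None] * np.exp2(log2_shift)
    counts = sample_nb(mu, config.dispersion, rng)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=list(design["sample_id"])), design
    )

    truth = SimulationTruth(
        de_genes_by_stage=de_by_stage,
        signature_genes=_pick_signature(genes, de_by_stage, config, rng),
        regulons={},
        modules=_make_modules(genes, config.module_size, rng),
        dispersion=config.dispersion,
        library_size_range=tuple(config.library_size_range),
    )
    truth.regulons, truth.perturbed_tf_stage = _make_regulons(genes, de_by_stage, config, rng)
    return cm, truth


def _pick_signature(genes, de_by_stage, config: SimulationConfig, rng) -> list[str]:
    n_sig = min(config.n_signature, len(genes))
    de_pool = sorted(set().union(*(set(d) for d in de_by_stage.values())) if de_by_stage else set())
    n_from_de = min(int(round(config.signature_de_fraction * n_sig)), len(de_pool))
    sig = list(rng.choice(de_pool, size=n_from_de, replace=False)) if n_from_de else []
    rest = [g for g in genes if g not in set(sig)]
    sig += list(rng.choice(rest, size=n_sig - len(sig), replace=False))
    return sorted(sig)


def _make_modules(genes, module_size: int, rng) -> dict[str, list[str]]:
    order = list(rng.permutation(genes))
    modules: dict[str, list[str]] = {}
    for i in range(0, len(order), module_size):
        modules[f"M{i // module_size + 1:03d}"] = sorted(order[i : i + module_size])
    return modules


def _make_regulons(genes, de_by_stage, config: SimulationConfig, rng):
    regulons: dict[str, set[str]] = {}
    perturbed: dict[str, str] = {}
    de_stages = [st for st in STAGES if de_by_stage.get(st)]
    lo, hi = config.regulon_size_range
    hi = min(hi, len(genes))
    for t in range(1, config.n_tfs + 1):
        name = f"TF{t:02d}"
        size = int(rng.integers(lo, hi + 1))
        if t <= config.n_perturbed_tfs and de_stages:
            st = de_stages[(t - 1) % len(de_stages)]
            # a perturbed TF moves its targets coherently: draw from one
            # effect direction so the regulon carries a net signed shift
            sign = 1.0 if rng.random() < 0.5 else -1.0
            de_pool = sorted(g for g, e in de_by_stage[st].items() if e * sign > 0)
            n_from_de = min(int(round(config.regulon_de_fraction * size)), len(de_pool))
            members = list(rng.choice(de_pool, size=n_from_de, replace=False))
            rest = [g for g in genes if g not in set(members)]
            members += list(rng.choice(rest, size=size - len(members), replace=False))
            perturbed[name] = st
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        regulons[name] = set(members)
    return regulons, perturbed


def generate_gene_sets(
    truth: SimulationTruth,
    n_go_like: int,
    size_range: tuple[int, int] = (5, 600),
    seed: int = 0,
    universe: list[str] | None = None,
) -> GeneSetCollection:
    """GO-like sets (random plus effect-enriched), TF regulons, and the signature.

    When the universe is large enough, boundary sets of size below 10 and
    above 500 are always included so the downstream 10-500 size filter is
    exercised.
    """
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range is inverted")
    if universe is None:
        universe = sorted({g for m in truth.modules.values() for g in m})
    if not (2 <= lo and hi <= len(universe)):
        raise ValueError("size_range outside [2, n_genes]")
    rng = _rng(seed, 1)
    sets: dict[str, set[str]] = {}
    categories: dict[str, str] = {}

    for i in range(1, n_go_like + 1):
        size = int(rng.integers(lo, hi + 1))
        sets[f"GO{i:04d}"] = set(rng.choice(universe, size=size, replace=False))
    # effect-enriched GO-like sets, one per stage carrying planted DE genes
    for st, d in truth.de_genes_by_stage.items():
        if not d:
            continue
        de_pool = sorted(d)
        size = min(100, max(10, len(de_pool)))
        n_de = min(int(round(0.7 * size)), len(de_pool))
        members = set(rng.choice(de_pool, size=n_de, replace=False))
        rest = [g for g in universe if g not in members]
        members |= set(rng.choice(rest, size=size - len(members), replace=False))
        sets[f"GO_enriched_{st}"] = members
    if n_go_like > 0 and len(universe) > 501 + 5:
        sets["GO_boundary_small"] = set(rng.choice(universe, size=9, replace=False))
        sets["GO_boundary_large"] = set(rng.choice(universe, size=501, replace=False))
    for name in sets:
        categories[name] = "go_like"

    for tf, members in truth.regulons.items():
        sets[tf] = set(members)
        categories[tf] = "tf_regulon"
    if truth.signature_genes:
        sets["microglia_identity"] = set(truth.signature_genes)
        categories["microglia_identity"] = "signature"
    return GeneSetCollection(sets=sets, categories=categories)


@dataclass
class EvidenceCollection:
    """Per-dataset gene-pair scores; pairs stored with gene_a < gene_b."""

    datasets: dict[str, pd.DataFrame]  # columns gene_a, gene_b, score

    def names(self) -> list[str]:
        return list(self.datasets)

    def to_tsv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.datasets.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, paths) -> "EvidenceCollection":
        from pathlib import Path

        datasets = {}
        for p in paths:
            p = Path(p)
            datasets[p.stem] = pd.read_csv(p, sep="\t")
        return cls(datasets)


def generate_evidence(
    truth: SimulationTruth,
    n_datasets: int,
    within_module_signal: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
    between_per_within: float = 4.0,
) -> EvidenceCollection:
    """Gene-pair evidence with a planted within-module mean shift.

    Every within-module pair is included (these carry the gold standard);
    between-module pairs are sampled at ``between_per_within`` times the
    within-pair count to keep the pair universe at desk scale. Scores are
    ``within_module_signal * 1{within} + N(0, noise_sd)`` per dataset.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not (0 < within_module_signal <= 1):
        raise ValueError("within_module_signal must be in (0, 1]")
    rng = _rng(seed, 2)
    within = truth.within_module_pairs()
    genes = sorted({g for m in truth.modules.values() for g in m})
    module_of = truth.module_of
    n_between = int(round(between_per_within * len(within)))
    between: set[tuple[str, str]] = set()
    max_tries = 50 * max(n_between, 1)
    tries = 0
    while len(between) < n_between and tries < max_tries:
        a, b = rng.choice(genes, size=2, replace=False)
        tries += 1
        if module_of[a] == module_of[b]:
            continue
        between.add((a, b) if a < b else (b, a))
    pairs = within + sorted(between)
    is_within = np.array([1.0] * len(within) + [0.0] * len(between))
    datasets = {}
    for d in range(1, n_datasets + 1):
        scores = within_module_signal * is_within + rng.normal(0.0, noise_sd, size=len(pairs))
        df = pd.DataFrame(
            {
                "gene_a": [p[0] for p in pairs],
                "gene_b": [p[1] for p in pairs],
                "score": scores,
            }
        ).sort_values(["gene_a", "gene_b"], ignore_index=True)
        datasets[f"dataset{d:03d}"] = df
    return EvidenceCollection(datasets)


def generate_known_interactions(
    truth: SimulationTruth, coverage: float = 1.0, seed: int = 0
) -> list[tuple[str, str]]:
    """A random ``coverage`` fraction of within-module pairs (known interactions)."""
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    rng = _rng(seed, 3)
    within = truth.within_module_pairs()
    k = int(round(coverage * len(within)))
    idx = rng.choice(len(within), size=k, replace=False)
    return [within[i] for i in sorted(idx)]


def generate_ortholog_map(
    gene_universe_a,
    gene_universe_b,
    mapped_fraction: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Injective partial map (columns source/target) covering a fraction of A."""
    a = list(gene_universe_a)
    b = list(gene_universe_b)
    if not a or not b:
        raise ValueError("gene universes must be nonempty")
    if not (0 < mapped_fraction <= 1):
        raise ValueError("mapped_fraction must be in (0, 1]")
    k = int(round(mapped_fraction * len(a)))
    if k > len(b):
        raise ValueError("target universe too small for requested coverage")
    rng = _rng(seed, 4)
    src = rng.choice(a, size=k, replace=False)
    tgt = rng.choice(b, size=k, replace=False)
    return pd.DataFrame({"source": src, "target": tgt}).sort_values(
        "source", ignore_index=True
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("de_stages",):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    for key in ("library_size_range", "regulon_size_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
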