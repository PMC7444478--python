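"""Parametric gene-set enrichment (PAGE) and TF-target statistics.

PAGE scores a gene set of size m against a per-gene score vector by
z = (Sm - mu) * sqrt(m) / delta, with Sm the member mean, mu the global
mean, and delta the global population standard deviation; the p-value is
two-sided normal. The per-gene score fed to enrichment is by default the
signed DE significance, sign(log2fc) * -log10(pvalue).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import STAGES
from .expression import bh_fdr
from .genesets import GeneSetCollection

P_FLOOR = 1e-300  # guards -log10 against exact zeros


class ZeroOverlapError(ValueError):
    """A gene set has no member in the scored universe: untestable, not z=0."""


def de_score_vector(de: pd.DataFrame, method: str = "signed_logp") -> pd.Series:
    """Per-gene enrichment score from a DE table.

    ``signed_logp`` (default): sign(log2fc) * -log10(pvalue);
    ``log2fc``: the fold change itself.
    """
    if method == "signed_logp":
        vals = np.sign(de["log2fc"]) * -np.log10(np.maximum(de["pvalue"], P_FLOOR))
    elif method == "log2fc":
        vals = de["log2fc"].astype(float)
    else:
        raise ValueError(f"unknown score method {method!r}")
    return pd.Series(vals.to_numpy(), index=de["gene"].to_numpy())


def page_zscore(scores: pd.Series, members) -> tuple[float, float]:
    """PAGE z and two-sided normal p for one gene set.

    Raises ZeroOverlapError when no member is scored; requires a
    non-degenerate global score distribution.
    """
    x = scores.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 scored genes")
    mu = x.mean()
    delta = x.std(ddof=0)  # population sd: PAGE's original formulation
    if delta == 0:
        raise ValueError("global score standard deviation is zero")
    idx = scores.index.isin(set(members))
    m = int(idx.sum())
    if m == 0:
        raise ZeroOverlapError("gene set has no overlap with scored genes")
    sm = x[idx].mean()
    z = (sm - mu) * np.sqrt(m) / delta
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def page_enrich(
    de: pd.DataFrame,
    sets: GeneSetCollection,
    size_min: int = 10,
    size_max: int = 500,
    score_method: str = "signed_logp",
) -> pd.DataFrame:
    """PAGE over a collection with the 10-500 size filter and BH FDR.

    Set size is counted after intersection with the scored universe (untested
    genes cannot contribute to the member mean). Results sorted by rank_score
    = sign(z) * -log10(p), descending.
    """
    scores = de_score_vector(de, score_method)
    if len(scores) < size_min:
        raise ValueError("DE table covers fewer genes than size_min")
    universe = set(scores.index)
    rows = []
    for name in sorted(sets.sets):
        m = len(sets.sets[name] & universe)
        if not (size_min <= m <= size_max):
            continue
        z, p = page_zscore(scores, sets.sets[name])
        rows.append({"set_name": name, "z": z, "pvalue": p, "m": m})
    if not rows:
        warnings.warn("no gene sets passed the size filter", stacklevel=2)
        return pd.DataFrame(columns=["set_name", "z", "pvalue", "fdr", "rank_score", "m"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out["rank_score"] = np.sign(out["z"]) * -np.log10(np.maximum(out["pvalue"], P_FLOOR))
    out = out.sort_values("rank_score", ascending=False, ignore_index=True)
    return out[["set_name", "z", "pvalue", "fdr", "rank_score", "m"]]


def tf_target_fraction(
    de_by_stage: dict[str, pd.DataFrame],
    regulons: GeneSetCollection,
    fdr_cut: float = 0.1,
    aggregate_tfs: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of each TF's tested targets differentially expressed per stage.

    Returns (per-TF table, aggregate table). The aggregate pools the target
    union of ``aggregate_tfs`` (default: all TFs in the collection) per
    stage. Regulons with zero tested targets in a stage are reported with a
    missing fraction.
    """
    if not (0 < fdr_cut < 1):
        raise ValueError("fdr_cut must be in (0, 1)")
    rows = []
    for stage, de in de_by_stage.items():
        tested = de.set_index("gene")["fdr"]
        for tf in sorted(regulons.sets):
            targets = regulons.sets[tf] & set(tested.index)
            n_t = len(targets)
            n_de = int((tested.loc[sorted(targets)] < fdr_cut).sum()) if n_t else 0
            rows.append(
                {
                    "tf": tf,
                    "stage": stage,
                    "n_targets": n_t,
                    "n_de": n_de,
                    "fraction": (n_de / n_t) if n_t else np.nan,
                }
            )
    per_tf = pd.DataFrame(rows)
    agg_tfs = sorted(regulons.sets) if aggregate_tfs is None else list(aggregate_tfs)
    agg_rows = []
    for stage, de in de_by_stage.items():
        tested = de.set_index("gene")["fdr"]
        pooled = set().union(*(regulons.sets[tf] for tf in agg_tfs if tf in regulons.sets))
        pooled &= set(tested.index)
        n_t = len(pooled)
        n_de = int((tested.loc[sorted(pooled)] < fdr_cut).sum()) if n_t else 0
        agg_rows.append(
            {
                "stage": stage,
                "n_targets": n_t,
                "n_de": n_de,
                "fraction": (n_de / n_t) if n_t else np.nan,
            }
        )
    return per_tf, pd.DataFrame(agg_rows)


def tf_z_heatmap(
    de_by_stage: dict[str, pd.DataFrame],
    regulons: GeneSetCollection,
    score_method: str = "signed_logp",
) -> pd.DataFrame:
    """TF x stage matrix of PAGE z-scores of each regulon per stage.

    Rows are TFs in sorted order, columns stages in developmental order;
    untestable cells (no scored targets) are NaN, never zero.
    """
    tfs = sorted(regulons.sets)
    stages = [s for s in STAGES if s in de_by_stage] + [
        s for s in de_by_stage if s not in STAGES
    ]
    mat = pd.DataFrame(np.nan, index=tfs, columns=stages)
    for stage in stages:
        scores = de_score_vector(de_by_stage[stage], score_method)
        for tf in tfs:
            try:
                z, _ = page_zscore(scores, regulons.sets[tf])
            except ZeroOverlapError:
                continue
            mat.loc[tf, stage] = z
    return mat
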