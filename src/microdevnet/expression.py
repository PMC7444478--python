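"""Normalization, variance stabilization, and NB differential expression.

Differential expression for one stage's KI-vs-WT contrast uses a
common-dispersion negative-binomial exact test: library sizes are equalized
by scaling to the geometric-mean depth, a single dispersion is estimated by
a pooled moment estimator, and each gene's p-value is the two-sided
conditional probability of the KI group sum given the total (Robinson-Smyth
style). FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .datatypes import STAGES, CountMatrix, ExpressionMatrix


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / sample total x 1e6."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    values = counts.counts / totals * 1e6
    return ExpressionMatrix(values, "cpm", counts.design)


def vst(counts: CountMatrix, prior_count: float = 1.0) -> ExpressionMatrix:
    """Variance-stabilizing transform log2(CPM + prior_count).

    De-trends the mean-variance dependence of NB counts well enough for
    distance-based sample comparison; monotone in counts within a sample.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    c = cpm(counts)
    return ExpressionMatrix(np.log2(c.values + prior_count), "vst", counts.design)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method."""
    vals = [ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control]
    if not np.isfinite(vals).all():
        raise ValueError("Ct values must be finite")
    dd = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-dd))


def filter_low_counts(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM > min_cpm in at least min_samples samples."""
    c = cpm(counts)
    keep = (c.values > min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(counts.counts.loc[keep], counts.design)


def equalize_library_sizes(counts: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Equalize sequencing depth to the geometric-mean level; round to integers.

    Per-sample depth is estimated by median-of-ratios size factors
    (normalized to geometric mean 1) rather than raw totals: totals are
    confounded by highly expressed differential genes (composition bias),
    which would shift every null gene and break FDR control. Matrices too
    small to support the median (few all-positive genes) fall back to
    total-count scaling. Returns (pseudo-counts, geometric-mean total);
    rounding keeps the exact test's integer domain and is negligible at
    sequencing-scale depths.
    """
    X = counts.to_numpy(dtype=float)
    libs = X.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("all samples must have positive totals")
    pos = (X > 0).all(axis=1)
    if pos.sum() >= 50:
        ref = np.exp(np.log(X[pos]).mean(axis=1))
        sf = np.median(X[pos] / ref[:, None], axis=0)
    else:
        sf = libs.copy()
    sf = sf / np.exp(np.mean(np.log(sf)))
    common = float(np.exp(np.mean(np.log(libs))))
    pseudo = np.rint(X / sf[None, :]).astype(np.int64)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


def estimate_common_dispersion(counts: pd.DataFrame, groups, n_iter: int = 3) -> float:
    """Pooled moment estimator of the common NB dispersion phi.

    Within each replicate group, (sample variance - mean) / mean^2 is a
    per-gene moment estimate of phi. Per-gene estimates are combined by a
    weighted mean with weights df * (mu / (1 + phi * mu))^2 — the inverse
    large-sample variance of the per-gene ratio — refined over a few
    iterations. The cap at 1/phi^2 for abundant genes keeps any single gene
    from dominating the pool (a plain ratio of sums is driven by the most
    abundant genes and is far noisier). Clipped at zero.
    """
    groups = np.asarray(groups)
    X = counts.to_numpy(dtype=float)
    cells = []  # (phi_hat, mean, df) per gene x group
    for g in np.unique(groups):
        sub = X[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        cells.append(((v[ok] - m[ok]) / m[ok] ** 2, m[ok], np.full(ok.sum(), n - 1.0)))
    if not cells:
        return 0.0
    phi_g = np.concatenate([c[0] for c in cells])
    m = np.concatenate([c[1] for c in cells])
    df = np.concatenate([c[2] for c in cells])
    phi = 0.1  # starting value only; washed out by the iterations
    for _ in range(n_iter):
        w = df * (m / (1.0 + phi * m)) ** 2
        phi = max(float(np.sum(w * phi_g) / np.sum(w)), 0.0)
    return phi


def _exact_nb_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional NB exact p for the group-2 sum given the total.

    Sums the conditional probabilities of all splits no more probable than
    the observed one. phi = 0 reduces to the conditional binomial.
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi < 1e-10:
        logp = stats.binom.logpmf(k, t, n2 / (n1 + n2))
    else:
        mu = t / (n1 + n2)  # per-library mean under the null
        r1, r2 = n1 / phi, n2 / phi
        logp = stats.nbinom.logpmf(t - k, r1, r1 / (r1 + n1 * mu)) + stats.nbinom.logpmf(
            k, r2, r2 / (r2 + n2 * mu)
        )
        logp = logp - logsumexp(logp)
    p = np.exp(logp)
    p_obs = p[y2]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def nb_exact_test(
    counts: CountMatrix,
    stage: str,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    dispersion: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """KI-vs-WT differential expression for one stage.

    Returns a DataFrame with columns gene/log2fc/pvalue/fdr/stage; log2fc is
    KI over WT from equalized group means with a prior count. ``dispersion``
    overrides the pooled moment estimate (0 forces the Poisson/binomial
    limit).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    sub = counts.subset_stage(stage)
    geno = sub.design["genotype"].to_numpy()
    n_wt, n_ki = int((geno == "WT").sum()), int((geno == "KI").sum())
    if n_wt < 2 or n_ki < 2:
        raise ValueError(
            f"stage {stage!r} needs >=2 replicates per genotype (WT={n_wt}, KI={n_ki})"
        )
    if min_cpm is not None:
        sub = filter_low_counts(sub, min_cpm=min_cpm, min_samples=min_samples)
    pseudo, _ = equalize_library_sizes(sub.counts)
    phi = estimate_common_dispersion(pseudo, geno) if dispersion is None else float(dispersion)

    wt = pseudo.loc[:, geno == "WT"].to_numpy()
    ki = pseudo.loc[:, geno == "KI"].to_numpy()
    y1 = wt.sum(axis=1)
    y2 = ki.sum(axis=1)
    pvals = np.array(
        [_exact_nb_pvalue(int(a), int(b), n_wt, n_ki, phi) for a, b in zip(y1, y2)]
    )
    log2fc = np.log2((y2 / n_ki + prior_count) / (y1 / n_wt + prior_count))
    return pd.DataFrame(
        {
            "gene": pseudo.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "stage": stage,
        }
    ).reset_index(drop=True)


def de_all_stages(counts: CountMatrix, **kwargs) -> dict[str, pd.DataFrame]:
    """nb_exact_test for every stage present with both genotypes replicated."""
    out = {}
    for stage in STAGES:
        d = counts.design
        sub = d[d["stage"] == stage]
        if ((sub["genotype"] == "WT").sum() >= 2) and ((sub["genotype"] == "KI").sum() >= 2):
            out[stage] = nb_exact_test(counts, stage, **kwargs)
    return out
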