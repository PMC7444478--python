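"""Sample-separation analysis: MDS, a distance contrast, and permutation tests.

The contrast statistic compares how far apart the two genotypes sit in a
focal developmental stage versus a reference stage: the mean over all
cross-genotype sample pairs of the Euclidean distance (on the
variance-stabilized matrix), focal minus reference. Its null distribution
comes from permuting each gene's expression values independently across all
samples; p-values follow the Phipson-Smyth (b+1)/(m+1) rule and can never
be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA

from .datatypes import ExpressionMatrix


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class PermutationTestResult:
    observed: float
    n_perm: int
    b: int  # permutation statistics >= observed
    pvalue: float
    seed: int

    def __post_init__(self) -> None:
        expected = (self.b + 1) / (self.n_perm + 1)
        if abs(self.pvalue - expected) > 1e-12:
            raise ValueError("pvalue must equal (b+1)/(n_perm+1)")
        lo = 1.0 / (self.n_perm + 1)
        if not (lo - 1e-12 <= self.pvalue <= 1.0 + 1e-12):
            raise ValueError("pvalue outside its attainable range")


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    negative_eigenvalue_mass: float  # |sum of negatives| / sum of positives


def euclidean_distances(expr: ExpressionMatrix) -> DistanceMatrix:
    """All-pairs Euclidean distances between samples (columns)."""
    X = expr.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("expression values must be finite")
    return DistanceMatrix(expr.samples, squareform(pdist(X.T)))


def classical_mds(dmat: DistanceMatrix, k: int = 3, tol: float = 1e-9) -> MDSResult:
    """Classical (Torgerson) MDS via the double-centered Gram eigendecomposition.

    Coordinates come from the top-k nonnegative eigenvalues; for a Euclidean
    input the full-rank embedding reproduces the distances. Negative
    eigenvalues beyond tolerance flag non-Euclidean input; the nonnegative
    part is still returned.
    """
    n = len(dmat.samples)
    if k > n - 1:
        raise ValueError("k must be <= number of samples - 1")
    D2 = dmat.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(evals.max(initial=0.0), 1.0)
    pos = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(pos)[None, :]
    neg = evals[evals < -tol * scale]
    neg_mass = float(abs(neg.sum()) / max(evals[evals > 0].sum(), 1e-300)) if len(neg) else 0.0
    cols = [f"MDS{i + 1}" for i in range(k)]
    return MDSResult(pd.DataFrame(coords, index=dmat.samples, columns=cols), evals, neg_mass)


def _stage_columns(design: pd.DataFrame, stage: str, genotype: str) -> np.ndarray:
    mask = (design["stage"] == stage) & (design["genotype"] == genotype)
    return np.flatnonzero(mask.to_numpy())


def _mean_cross_genotype_distance(X: np.ndarray, wt_cols, ki_cols) -> float:
    d = cdist(X[:, wt_cols].T, X[:, ki_cols].T)
    return float(d.mean())


def separation_statistic(
    expr: ExpressionMatrix, focal_stage: str, reference_stage: str
) -> float:
    """meanDist(WT, KI | focal) - meanDist(WT, KI | reference)."""
    if expr.design is None:
        raise ValueError("expression matrix carries no design")
    X = expr.values.to_numpy(dtype=float)
    cols = {}
    for stage in (focal_stage, reference_stage):
        for gt in ("WT", "KI"):
            idx = _stage_columns(expr.design, stage, gt)
            if len(idx) == 0:
                raise ValueError(f"stage {stage!r} has no {gt} samples")
            cols[(stage, gt)] = idx
    return _mean_cross_genotype_distance(
        X, cols[(focal_stage, "WT")], cols[(focal_stage, "KI")]
    ) - _mean_cross_genotype_distance(
        X, cols[(reference_stage, "WT")], cols[(reference_stage, "KI")]
    )


def permutation_test(
    expr: ExpressionMatrix,
    focal_stage: str,
    reference_stage: str,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "all_samples",
) -> PermutationTestResult:
    """Gene-wise permutation null for the separation statistic.

    Each permutation independently shuffles every gene's values across
    samples — across all samples by default, destroying both stage and
    genotype structure while preserving each gene's marginal; mode
    ``within_stage`` shuffles within each stage block instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("all_samples", "within_stage"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    observed = separation_statistic(expr, focal_stage, reference_stage)
    X = expr.values.to_numpy(dtype=float)
    design = expr.design
    cols = {
        (st, gt): _stage_columns(design, st, gt)
        for st in (focal_stage, reference_stage)
        for gt in ("WT", "KI")
    }
    stage_blocks = [
        np.flatnonzero((design["stage"] == st).to_numpy())
        for st in design["stage"].unique()
    ]
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if mode == "all_samples":
            Xp = rng.permuted(X, axis=1)
        else:
            Xp = X.copy()
            for block in stage_blocks:
                Xp[:, block] = rng.permuted(X[:, block], axis=1)
        stat = _mean_cross_genotype_distance(
            Xp, cols[(focal_stage, "WT")], cols[(focal_stage, "KI")]
        ) - _mean_cross_genotype_distance(
            Xp, cols[(reference_stage, "WT")], cols[(reference_stage, "KI")]
        )
        if stat >= observed:
            b += 1
    seed_int = int(seed) if np.isscalar(seed) else int(np.asarray(seed).ravel()[0])
    return PermutationTestResult(
        observed=observed, n_perm=n_perm, b=b, pvalue=(b + 1) / (n_perm + 1), seed=seed_int
    )


def subsample_robustness(
    expr: ExpressionMatrix,
    focal_stage: str,
    reference_stage: str,
    n_genes: int = 5000,
    n_reps: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Permutation test on repeated random gene subsets.

    Guards against a handful of genes driving the separation. Each replicate
    draws a uniform subset of ``n_genes`` genes with its own child stream
    (``[seed, rep]`` for the draw, ``[seed, rep, 1]`` for the permutations)
    and reruns the test. Returns (p-values, their median).
    """
    genes = expr.genes
    if n_genes > len(genes):
        raise ValueError("n_genes exceeds the available gene count")
    pvals = []
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), rep])
        idx = rng.choice(len(genes), size=n_genes, replace=False)
        sub = ExpressionMatrix(expr.values.iloc[np.sort(idx)], expr.transform, expr.design)
        res = permutation_test(
            sub, focal_stage, reference_stage, n_perm=n_perm, seed=[int(seed), rep, 1]
        )
        pvals.append(res.pvalue)
    return pvals, float(np.median(pvals))


def signature_test(
    expr: ExpressionMatrix,
    signature,
    focal_stage: str,
    reference_stage: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test restricted to signature genes (no subsampling)."""
    sig = set(signature)
    keep = [g for g in expr.genes if g in sig]
    if not keep:
        raise ValueError("signature has no overlap with expressed genes")
    sub = ExpressionMatrix(expr.values.loc[keep], expr.transform, expr.design)
    return permutation_test(sub, focal_stage, reference_stage, n_perm=n_perm, seed=seed)


def signature_pca(
    expr: ExpressionMatrix, signature, k: int = 2, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples on the signature-restricted matrix.

    Returns (sample x k score table, explained-variance fractions).
    """
    sig = set(signature)
    keep = [g for g in expr.genes if g in sig]
    if len(keep) < k:
        raise ValueError("signature overlap smaller than requested components")
    X = expr.values.loc[keep].to_numpy(dtype=float).T  # samples x genes
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k_eff = min(k, X.shape[0] - 1, X.shape[1])
    if k_eff < k:
        raise ValueError(f"k={k} exceeds the matrix rank bound {k_eff}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=expr.samples, columns=cols),
        pca.explained_variance_ratio_,
    )
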