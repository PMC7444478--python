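"""Core containers shared across the pipeline.

The experimental design is four developmental stages (yolk sac and brain
rudiment at E9.5, neonate, adult) crossed with two genotypes (wild type and
the Psen1 knock-in), with replicate microglia samples in every cell.
Counts live in a gene x sample integer matrix aligned to that design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("yolk_sac", "brain_rudiment", "neonate", "adult")
GENOTYPES: tuple[str, ...] = ("WT", "KI")

DESIGN_COLUMNS = ("sample_id", "stage", "genotype", "replicate")


def make_design(n_replicates: int = 4, stages=STAGES, genotypes=GENOTYPES) -> pd.DataFrame:
    """Full-factorial sample design with `n_replicates` per (stage, genotype) cell."""
    rows = [
        {
            "sample_id": f"{st}_{gt}_r{r}",
            "stage": st,
            "genotype": gt,
            "replicate": r,
        }
        for st in stages
        for gt in genotypes
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def validate_design(design: pd.DataFrame, require_full: bool = False) -> pd.DataFrame:
    """Validate a sample design table.

    Checks unique sample ids, enum-valued stage/genotype columns (errors name
    the offending sample), positive integer replicates, and >=2 replicates per
    observed (stage, genotype) cell. With ``require_full`` every stage x
    genotype cell must be present.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")
    design = design.loc[:, list(DESIGN_COLUMNS)].reset_index(drop=True)
    dup = design["sample_id"][design["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
    for _, row in design.iterrows():
        if row["stage"] not in STAGES:
            raise ValueError(
                f"sample {row['sample_id']!r} has invalid stage {row['stage']!r}; "
                f"expected one of {STAGES}"
            )
        if row["genotype"] not in GENOTYPES:
            raise ValueError(
                f"sample {row['sample_id']!r} has invalid genotype {row['genotype']!r}; "
                f"expected one of {GENOTYPES}"
            )
        if int(row["replicate"]) < 1:
            raise ValueError(f"sample {row['sample_id']!r} has non-positive replicate")
    counts = design.groupby(["stage", "genotype"]).size()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"(stage, genotype) cells with <2 replicates: {list(bad.index)}")
    if require_full:
        want = {(st, gt) for st in STAGES for gt in GENOTYPES}
        have = set(map(tuple, design[["stage", "genotype"]].itertuples(index=False)))
        if want - have:
            raise ValueError(f"design missing (stage, genotype) cells: {sorted(want - have)}")
    return design


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with its aligned sample design."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count matrix columns do not match design sample_ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_stage(self, stage: str) -> "CountMatrix":
        keep = self.design["stage"] == stage
        d = self.design.loc[keep].reset_index(drop=True)
        return CountMatrix(self.counts.loc[:, list(d["sample_id"])], d)

    def to_tsv(self, counts_path, design_path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        self.design.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t")
        counts = counts.set_index("gene")
        counts.index.name = None
        design = pd.read_csv(design_path, sep="\t")
        return cls(counts, design)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix after a named transform (cpm/log_cpm/vst)."""

    values: pd.DataFrame
    transform: str
    design: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.transform not in ("cpm", "log_cpm", "vst"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.design is not None:
            self.design = validate_design(self.design)
            if list(self.values.columns) != list(self.design["sample_id"]):
                raise ValueError("expression columns do not match design sample_ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.transform, self.design)
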