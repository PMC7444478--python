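import numpy as np
import pandas as pd
import pytest

import microdevnet as md


@pytest.fixture(scope="session")
def design3():
    return md.make_design(3)


@pytest.fixture(scope="session")
def small_sim(design3):
    """500-gene simulation with the default planted brain-rudiment effect."""
    return md.generate_counts(500, design3, md.SimulationConfig(), seed=42)


@pytest.fixture(scope="session")
def null_sim(design3):
    """No planted genotype or stage effects: fully exchangeable samples."""
    cfg = md.SimulationConfig(de_fraction=0.0, stage_effect_sd=0.0)
    return md.generate_counts(400, design3, cfg, seed=7)


@pytest.fixture(scope="session")
def module_truth():
    """Hand-built module partition over 120 genes for network tests."""
    genes = [f"N{i:03d}" for i in range(1, 121)]
    modules = {f"M{m:02d}": genes[m * 15 : (m + 1) * 15] for m in range(8)}
    return md.SimulationTruth(
        de_genes_by_stage={},
        signature_genes=[],
        regulons={},
        modules=modules,
        dispersion=0.1,
        library_size_range=(1, 2),
    )


def two_group_counts(wt_rows, ki_rows, stage="brain_rudiment"):
    """CountMatrix with one stage, 2 WT + 2 KI samples, genes as given rows.

    Rows are dicts gene -> (wt1, wt2, ki1, ki2).
    """
    design = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "stage": [stage] * 4,
            "genotype": ["WT", "WT", "KI", "KI"],
            "replicate": [1, 2, 1, 2],
        }
    )
    data = {g: list(v) for g, v in {**wt_rows, **ki_rows}.items()}
    counts = pd.DataFrame.from_dict(data, orient="index", columns=design["sample_id"])
    return md.CountMatrix(counts, design)
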