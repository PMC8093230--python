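import numpy as np
import pandas as pd
import pytest

import peaflow as pf


@pytest.fixture(scope="session")
def small_config() -> pf.SimConfig:
    return pf.SimConfig(
        n_subjects=12, n_t2d_subjects=8, n_proteins=24, n_variants=60, seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> pf.SimStudy:
    return pf.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_npx(small_study) -> pf.NPXMatrix:
    return pf.counts_to_npx(small_study.counts, design=small_study.design)


def truth_wide(truth: pf.SimTruth) -> pd.DataFrame:
    """True log2 abundances reindexed by sample id."""
    x = truth.log_abundance.copy()
    x.index = pf.simulate.sample_id(
        x.index.get_level_values(0), x.index.get_level_values(1)
    )
    return x


def make_count_matrix(counts: np.ndarray, ext: np.ndarray, plate_ids=None, **extra):
    """Small CountMatrix from a samples x assays array and extension counts."""
    n_s, n_a = counts.shape
    sample_ids = [f"S{i}" for i in range(n_s)]
    plate_ids = plate_ids or ["PL1"] * n_s
    rows = []
    for i, s in enumerate(sample_ids):
        for j in range(n_a):
            rows.append(
                {
                    "sample_id": s,
                    "assay_id": f"A{j}",
                    "panel": 1,
                    "plate_id": plate_ids[i],
                    "batch_id": "B1",
                    "well_type": extra.get("well_type", "sample"),
                    "count": counts[i, j],
                }
            )
    controls = []
    for i, s in enumerate(sample_ids):
        for name, val in (
            ("extension", ext[i]),
            ("incubation", extra.get("incubation", ext)[i]),
            ("amplification", ext[i]),
        ):
            controls.append(
                {
                    "sample_id": s,
                    "plate_id": plate_ids[i],
                    "batch_id": "B1",
                    "control": name,
                    "count": val,
                }
            )
    return pf.CountMatrix(counts=pd.DataFrame(rows), controls=pd.DataFrame(controls))
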