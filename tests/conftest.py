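"""Shared fixtures: small synthetic studies generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tmabatch.datamodel import BiomarkerTable, CovariateTable
from tmabatch.synthdata import StudyDesign, generate_study


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Model-fitting chatter (convergence notes etc.) is asserted explicitly
    where it matters; silence it elsewhere."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_study():
    """6 batches x ~40 tumors, 2 markers, additive batch shifts."""
    design = StudyDesign(
        n_batches=6,
        tumors_per_batch=(38, 44),
        n_markers=2,
        batch_shift_sd=0.7,
        gleason_effect=0.2,
        stage_effect=0.1,
        seed=11,
    )
    return generate_study(design)


@pytest.fixture(scope="session")
def null_study():
    """No batch effects at all (shifts 0, scales 1)."""
    design = StudyDesign(
        n_batches=5, tumors_per_batch=(40, 40), n_markers=2, batch_shift_sd=0.0, seed=21
    )
    return generate_study(design)


def make_biomarker(values_by_batch, marker="m") -> BiomarkerTable:
    """Tiny one-marker table from {batch: [values]}."""
    rows = []
    for batch, values in values_by_batch.items():
        for i, v in enumerate(values):
            rows.append((f"{batch}-t{i}", "c1", batch, marker, float(v)))
    return BiomarkerTable(
        pd.DataFrame(rows, columns=["tumor_id", "core_id", "batch_id", "marker_id", "value"])
    )


def make_covariates(bm: BiomarkerTable, rng=None, **overrides) -> CovariateTable:
    """Covariate table matching a biomarker table's tumors (cycled levels)."""
    from tmabatch.datamodel import GLEASON_LEVELS, STAGE_LEVELS

    rng = rng or np.random.default_rng(0)
    tumors = bm.df.drop_duplicates("tumor_id")[["tumor_id", "batch_id"]]
    n = len(tumors)
    df = pd.DataFrame(
        {
            "tumor_id": tumors["tumor_id"].to_numpy(),
            "batch_id": tumors["batch_id"].to_numpy(),
            "gleason_group": [GLEASON_LEVELS[i % 5] for i in range(n)],
            "stage_category": [STAGE_LEVELS[i % 4] for i in range(n)],
            "diagnosis_year": 1990 + (np.arange(n) % 10),
            "event": rng.integers(0, 2, n),
            "follow_up_time": rng.uniform(1, 20, n),
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return CovariateTable(df)
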