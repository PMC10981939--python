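"""Shared fixtures: one moderately sized simulated study reused across tests."""

import numpy as np
import pandas as pd
import pytest

from mesosieve import (
    NoiseConfig,
    generate_annotations,
    generate_proteome,
    generate_sequence_features,
    normalize_q95,
    simulate_filtration_scenario,
)
from mesosieve.quant import merge_quant_tables

STUDY_SEED = 7


@pytest.fixture(scope="session")
def truth():
    """Default 4000-species ground truth."""
    return generate_proteome(4000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def features(truth):
    return generate_sequence_features(truth, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def annotations(truth, features):
    return generate_annotations(truth, features, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(truth):
    """Noisy default filtration + dilution study, normalized, with the merged table."""
    scenario = simulate_filtration_scenario(truth, noise=NoiseConfig(seed=STUDY_SEED))
    tables = [normalize_q95(t) for t in scenario.tables]
    return {"tables": tables, "merged": merge_quant_tables(tables)}


def single_condensate(d0=100.0, d_mono=5.0, c_ratio=2.0, phi_core=0.0, lam=1.0):
    """One-row condensate ground-truth table for targeted elution tests."""
    return pd.DataFrame(
        {
            "class": ["condensate"],
            "d0": [d0],
            "d_mono": [d_mono],
            "c_ratio": [c_ratio],
            "phi_core": [phi_core],
            "lam": [lam],
            "abundance": [1.0],
        },
        index=pd.Index(["C0"], name="species_id"),
    )


def species_row(cls, d0, d_mono=None, **kw):
    """One-row ground-truth table of an arbitrary class."""
    return pd.DataFrame(
        {
            "class": [cls],
            "d0": [d0],
            "d_mono": [d_mono if d_mono is not None else (d0 if cls == "free" else 5.0)],
            "c_ratio": [kw.get("c_ratio", np.nan)],
            "phi_core": [kw.get("phi_core", np.nan)],
            "lam": [kw.get("lam", 0.0)],
            "abundance": [1.0],
        },
        index=pd.Index([kw.get("sid", "S0")], name="species_id"),
    )
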