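import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import metadiv as md


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration synthetic study, shared across tests."""
    return md.simulate(md.SimConfig(seed=2024))


@pytest.fixture(scope="session")
def small_sim():
    """A small planted study for fast recovery checks."""
    cfg = md.SimConfig(n_metabolites=60, n_reactions=40, seed=7)
    return md.simulate(cfg)


@pytest.fixture()
def balanced_samples():
    """Balanced 3-species design: 3 individuals x 2 replicates each."""
    rows = []
    for sp, tag in zip(md.SPECIES, "HCR"):
        for i in range(3):
            for r in (1, 2):
                rows.append({"measurement_id": f"{tag}{i}_r{r}",
                             "species": sp, "individual": f"{tag}{i}",
                             "replicate": r, "batch": f"batch{r}",
                             "sex": "unknown"})
    return pd.DataFrame(rows).set_index("measurement_id")


def make_measurements(values_by_individual, n_rep=2, noise=0.0, rng=None):
    """Expand per-individual values into replicate measurements."""
    rng = np.random.default_rng(rng)
    y, rows = [], []
    for (ind, sp, val) in values_by_individual:
        for r in range(1, n_rep + 1):
            rows.append({"measurement_id": f"{ind}_r{r}", "species": sp,
                         "individual": ind, "replicate": r,
                         "batch": f"batch{r}", "sex": "unknown"})
            y.append(val + (rng.normal(0, noise) if noise else 0.0))
    return np.array(y), pd.DataFrame(rows).set_index("measurement_id")
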