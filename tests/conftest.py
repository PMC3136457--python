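import numpy as np
import pandas as pd
import pytest

from crosscomp.compendium import LogratioCompendium
from crosscomp import simulate as sim


@pytest.fixture
def tiny_compendium() -> LogratioCompendium:
    """Hand-built 6-gene x 6-contrast compendium with missing values."""
    values = pd.DataFrame(
        {
            "E1_c1": [1.0, 1.0, 1.0, -1.0, 0.0, np.nan],
            "E1_c2": [2.0, 2.0, 2.0, -2.0, 0.0, 1.0],
            "E1_c3": [0.5, np.nan, 0.4, -0.5, 0.0, 1.0],
            "E2_c1": [-1.0, -1.0, -1.2, 1.0, 0.0, np.nan],
            "E2_c2": [0.1, -0.1, 0.0, 0.0, 0.0, 2.0],
            "E2_c3": [np.nan, np.nan, np.nan, np.nan, 0.0, 2.0],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    meta = pd.DataFrame(
        {
            "experiment_id": ["E1"] * 3 + ["E2"] * 3,
            "platform_id": ["P1"] * 3 + ["P2"] * 3,
        },
        index=values.columns,
    )
    return LogratioCompendium(values, meta, name="tiny")


@pytest.fixture(scope="session")
def recovery_study():
    """Planted 30-gene regulon compendium (seeded) for recovery checks."""
    return sim.regulon_recovery_study(seed=11)


@pytest.fixture(scope="session")
def meta_study():
    """Heterogeneous 8-experiment compendium (seeded) for the meta contrast."""
    return sim.meta_comparison_study(seed=11)


@pytest.fixture(scope="session")
def homogenized():
    """Raw multi-platform study (seeded) run through the full pipeline."""
    from crosscomp.ingest import build_compendium_from_raw

    study = sim.homogenization_study(seed=11)
    compendium, build_log = build_compendium_from_raw(
        study.hybridizations,
        study.contrast_definitions,
        study.probe_annotations,
        study.gene_index,
    )
    return study, compendium, build_log
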