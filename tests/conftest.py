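import numpy as np
import pandas as pd
import pytest

from sncmirror import CohortConfig, ExpressionExperiment, simulate_cohort


def make_experiment(intensities, detected=None, design=None, probe_meta=None):
    """Hand-build a small ExpressionExperiment from plain structures."""
    intensities = pd.DataFrame(intensities)
    if detected is None:
        detected = intensities.notna()
    else:
        detected = pd.DataFrame(detected, index=intensities.index, columns=intensities.columns)
    if design is None:
        design = pd.DataFrame(
            {
                "patient": list(intensities.columns),
                "phase": "control",
                "sex": "F",
                "treatment": "none",
            },
            index=intensities.columns,
        )
    if probe_meta is None:
        probe_meta = pd.DataFrame(
            {"kind": "miRNA", "human": True}, index=intensities.index
        )
    return ExpressionExperiment(
        intensities=intensities, detected=detected, design=design, probe_meta=probe_meta
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """13 all-female pairs + 13 controls, strong planted effects, low noise."""
    cfg = CohortConfig(
        n_patients=13,
        n_controls=13,
        n_probes=300,
        sex_ratio=1.0,
        n_de_relapse_f=10,
        n_de_remission_f=10,
        n_de_remission_m=0,
        n_mirror=8,
        effect_log2=2.0,
        noise_sd=0.3,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
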