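"""Shared fixtures: small synthetic experiments generated at test time."""

import numpy as np
import pandas as pd
import pytest

from dualstress import simulate


@pytest.fixture(scope="session")
def small_design():
    return simulate.ArrayDesignSpec(
        n_probes=60, n_duplicated=5,
        control_classes=(("spike", 2), ("blank", 2), ("buffer", 1),
                         ("polyA", 1), ("negative", 1)),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design):
    return simulate.generate_array_experiment(small_design, simulate.EffectSpec())


@pytest.fixture(scope="session")
def clean_experiment():
    """No missing spots, no duplicates/controls: every probe fully observed."""
    design = simulate.ArrayDesignSpec(
        n_probes=40, n_duplicated=0, control_classes=(), seed=321
    )
    effects = simulate.EffectSpec(frac_differential=0.2, missing_rate=0.0)
    return simulate.generate_array_experiment(design, effects)


@pytest.fixture(scope="session")
def metab_experiment():
    return simulate.generate_metabolite_experiment(
        simulate.MetabDesignSpec(seed=77)
    )


@pytest.fixture()
def toy_sheet():
    rows = []
    for run in (1, 2):
        for trt in ("Psyr", "Spod"):
            for h in (1, 6, 24):
                for rep in (1, 2):
                    rows.append((f"r{run}_{trt}_{h}h_rep{rep}", run, trt, h, rep))
    return pd.DataFrame(
        rows, columns=["array_id", "run", "treatment", "time_h", "replicate"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
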