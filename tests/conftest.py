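import numpy as np
import pandas as pd
import pytest

from cpa.datamodel import ClinotypeMatrix
from cpa.preprocess import apply_normalization, fit_normalization, temporal_split
from cpa.synthetic import GeneratorConfig, LatentModel, generate_cohort


def toy_matrix(values: dict, low: float = -1.0, high: float = 1.0) -> ClinotypeMatrix:
    """Build a small ClinotypeMatrix from {patient: {clinotype: value}} with a
    shared (low, high) reference range."""
    df = pd.DataFrame(values, dtype=float).T
    return ClinotypeMatrix(
        df,
        pd.DataFrame(low, index=df.index, columns=df.columns),
        pd.DataFrame(high, index=df.index, columns=df.columns),
    )


@pytest.fixture(scope="session")
def linear_cohort():
    """Noiseless linear cohort: two clinotypes are exact linear functions of
    the others, masked only on those targets so predictors stay observed."""
    from cpa.synthetic import inject_missingness

    clins = [f"C{i:02d}" for i in range(8)]
    # coefficient vectors near unit norm keep the targets' variance near 1,
    # so all three annotation classes are well populated
    coefs = {"C05": {"C00": 0.7, "C01": -0.5, "C02": 0.3}, "C06": {"C03": 0.8, "C04": 0.6}}
    latent = LatentModel(coefficients=coefs, noise_sd={"C05": 0.0, "C06": 0.0})
    config = GeneratorConfig(
        n_patients=1200, clinotypes=clins, latent=latent, missing_rate=0.0, seed=3
    )
    matrix, patients, diagnoses, truth = generate_cohort(config)
    masked, removed = inject_missingness(
        matrix, 0.08, "mcar", seed=11, columns=["C05", "C06"]
    )
    return {
        "config": config,
        "coefs": coefs,
        "matrix": masked,
        "patients": patients,
        "removed": removed,
    }


@pytest.fixture(scope="session")
def linear_cohort_split(linear_cohort):
    split = temporal_split(linear_cohort["matrix"], "2013-06-30")
    params = fit_normalization(split.train)
    return {
        **linear_cohort,
        "params": params,
        "train": apply_normalization(split.train, params),
        "test": apply_normalization(split.test, params),
    }
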