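import pandas as pd
import pytest

from icufluid import (
    BaselineTable,
    FeatureSchema,
    HazardCoefs,
    PhenotypeSpec,
    TrajectorySpec,
    default_phenotypes,
    default_trajectory,
    default_units,
    generate_cohort,
    impute,
    scale_numeric,
)


@pytest.fixture
def tiny_table():
    """Six patients, two numeric + one categorical feature, no missing."""
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(6)],
            "x1": [0.0, 0.1, 0.2, 1.0, 1.1, 1.2],
            "x2": [0.0, 0.2, 0.1, 0.9, 1.0, 1.1],
            "colour": ["red", "red", "blue", "blue", "blue", "blue"],
        }
    )
    schema = FeatureSchema(
        numeric={"x1": "", "x2": ""}, categorical={"colour": ("blue", "red")}
    )
    return BaselineTable(df, schema)


@pytest.fixture(scope="session")
def small_cohort():
    """Default four-phenotype cohort at n=2000 (shared, read-only)."""
    return generate_cohort(
        default_phenotypes(), default_trajectory(), n=2000, seed=42, units=default_units()
    )


@pytest.fixture(scope="session")
def scaled_small_cohort(small_cohort):
    baseline, persondays = small_cohort
    complete, _ = impute(baseline)
    scaled, _ = scale_numeric(complete, "minmax01")
    return scaled, persondays


def single_phenotype_dgp(
    intercept=-6.0,
    theta_covar=0.25,
    theta_fluid=0.0,
    theta_fluid2=0.0,
    theta_day=0.0,
    **traj_kwargs,
):
    """A one-phenotype generator whose law the g-formula model family nests."""
    spec = PhenotypeSpec(
        label="only",
        prevalence=1.0,
        numeric_means={"sofa": 5.0},
        numeric_sds={"sofa": 1.5},
        categorical_probs={},
        hazard_coefs=HazardCoefs(
            intercept,
            theta_covar=theta_covar,
            theta_fluid=theta_fluid,
            theta_fluid2=theta_fluid2,
            theta_day=theta_day,
        ),
    )
    return [spec], TrajectorySpec(**traj_kwargs)


@pytest.fixture(scope="session")
def true_labels(small_cohort):
    baseline, _ = small_cohort
    return baseline.df.set_index("patient_id")["true_phenotype"]
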