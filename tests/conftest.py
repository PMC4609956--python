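import numpy as np
import pandas as pd
import pytest

from coage import (
    AnalysisConfig,
    CohortSpec,
    DonorTable,
    ExpressionMatrix,
    TissueSampleMap,
    TissueSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def strong_cohort():
    """Single-tissue cohort with strong planted age effects (t ~ 8 per gene)."""
    spec = CohortSpec(
        n_donors=100,
        n_genes=300,
        tissues=[TissueSpec("heart", 90, frac_aging_genes=0.1, fixed_effect_size=0.06)],
        deviation_sd=0.0,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Single-tissue cohort with no planted effects."""
    spec = CohortSpec(
        n_donors=80,
        n_genes=400,
        tissues=[TissueSpec("lung", 70, frac_aging_genes=0.0)],
        deviation_sd=0.0,
        seed=13,
    )
    return generate_cohort(spec)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 5-gene x 4-sample dataset with full metadata."""
    genes = [f"g{i}" for i in range(5)]
    samples = ["s1", "s2", "s3", "s4"]
    rng = np.random.default_rng(0)
    expr = ExpressionMatrix(
        "heart", pd.DataFrame(rng.normal(size=(5, 4)), index=genes, columns=samples)
    )
    donors = DonorTable(
        pd.DataFrame(
            {
                "age": [25, 40, 55, 70],
                "sex": ["male", "female", "male", "female"],
                "geno_pc1": [0.1, -0.2, 0.0, 0.3],
                "geno_pc2": [0.0, 0.1, -0.1, 0.2],
                "geno_pc3": [0.2, 0.0, 0.1, -0.3],
            },
            index=pd.Index(["d1", "d2", "d3", "d4"], name="donor_id"),
        )
    )
    smap = TissueSampleMap(
        pd.DataFrame(
            {"donor_id": ["d1", "d2", "d3", "d4"], "tissue": ["heart"] * 4},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return expr, donors, smap
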