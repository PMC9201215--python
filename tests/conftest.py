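import numpy as np
import pandas as pd
import pytest

from episcan import (
    GenotypeMatrix,
    SampleTable,
    SnpInfo,
    simulate,
    study_template,
)


@pytest.fixture(scope="session")
def template_cohort():
    """One deterministic null cohort under the study design template."""
    cfg = study_template(seed=42)
    return simulate(cfg)


@pytest.fixture
def tiny_cohort():
    """Hand-built 6-subject, 3-SNP cohort with known genotypes."""
    snps = [
        SnpInfo("rs1", "SFTPA1", "C", "T"),
        SnpInfo("rs2", "SFTPA1", "C", "G"),
        SnpInfo("rs3", "SFTPB", "A", "C"),
    ]
    dosages = np.array(
        [
            [0, 1, 2],
            [1, 1, 1],
            [2, 0, 0],
            [1, 2, 1],
            [0, 0, -1],
            [2, 1, 2],
        ],
        dtype=np.int8,
    )
    subjects = [f"S{i}" for i in range(1, 7)]
    G = GenotypeMatrix(snps=snps, subjects=subjects, dosages=dosages)
    samples = SampleTable(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "status": ["case", "case", "case", "control", "control", "control"],
                "sex": ["male", "male", "female", "male", "female", "male"],
                "smoking": [
                    "smoker",
                    "nonsmoker",
                    "smoker",
                    "smoker",
                    "nonsmoker",
                    "nonsmoker",
                ],
            }
        )
    )
    return G, samples
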