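import numpy as np
import pandas as pd
import pytest

from gutsig import synthetic
from gutsig.composition import SampleTaxaMatrix


def make_matrix(values, groups, subjects=None, species=None):
    """Small hand-built sample-taxa matrix (rows are re-closed)."""
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    n, d = values.shape
    samples = [f"s{i}" for i in range(n)]
    if subjects is None:
        subjects = [f"subj{i}" for i in range(n)]
    if species is None:
        species = [f"sp{j:03d}" for j in range(d)]
    abundance = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"),
                             columns=species)
    metadata = pd.DataFrame(
        {"subject_id": subjects, "group": groups},
        index=abundance.index,
    )
    return SampleTaxaMatrix(abundance, metadata)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort with one planted twofold-elevated species."""
    spec = synthetic.CohortSpec(
        groups=[
            synthetic.GroupSpec("case", 25, (0.5, 0.3, 0.2, 0.0, 0.0)),
            synthetic.GroupSpec("ctrl", 25, (0.5, 0.3, 0.2, 0.0, 0.0)),
        ],
        D=20,
        sparsity=0.1,
        da_spec=[("sp000", "case", 2.0)],
        seed=11,
    )
    matrix, metadata, truth = synthetic.generate_cohort(spec)
    return matrix, truth
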