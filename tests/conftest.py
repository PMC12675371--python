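import numpy as np
import pandas as pd
import pytest

from netsurv.cohort import Cohort, ExpressionMatrix
from netsurv.simulate import SimConfig, generate_cohort


def build_cohort(values, genes=None, samples=None, patients=None,
                 time=None, event=None, timepoint="recurrent", normalized=False):
    """Assemble a Cohort directly from arrays (samples already co-ordered)."""
    values = np.atleast_2d(np.asarray(values, float))
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = list(samples) if samples is not None else [f"s{i:02d}" for i in range(n_samples)]
    patients = list(patients) if patients is not None else [f"p{i:02d}" for i in range(n_samples)]
    time = np.asarray(time, float) if time is not None else np.arange(1.0, n_samples + 1)
    event = np.asarray(event, int) if event is not None else np.ones(n_samples, int)
    expr = ExpressionMatrix(gene_ids=pd.Index(genes), sample_ids=pd.Index(samples),
                            values=values, normalized=normalized)
    clinical = pd.DataFrame(
        {"sample_id": samples, "patient_id": patients, "time": time,
         "event": event, "timepoint": timepoint}
    )
    return Cohort(expression=expr, clinical=clinical)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort reused by read-only tests (60 patients)."""
    config = SimConfig(n_patients=60, n_samples=66, n_genes=80, n_prognostic=2,
                       block_size=12)
    cohort, truth = generate_cohort(config, seed=11)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
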