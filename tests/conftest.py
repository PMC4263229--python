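import numpy as np
import pytest

from cormotif import (
    MultiStudySet,
    SimulationSpec,
    StudyDataset,
    TStatMatrix,
    moderate,
    simulate_model_based,
)


def make_tstat(t, df=6.0, scale=2.0):
    """TStatMatrix from a raw array with shared df/scale across studies."""
    t = np.atleast_2d(np.asarray(t, dtype=float))
    g, d = t.shape
    return TStatMatrix(
        t=t,
        df=np.full(d, float(df)),
        scale_alt=np.full(d, float(scale)),
        gene_ids=[f"g{i}" for i in range(g)],
        study_ids=[f"s{j}" for j in range(d)],
    )


def make_study(values, n_case, n_control, study_id="s1", gene_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return StudyDataset(
        study_id=study_id,
        values=values,
        gene_ids=gene_ids,
        group_labels=["case"] * n_case + ["control"] * n_control,
        n_case=n_case,
        n_control=n_control,
    )


SMALL_SPEC = SimulationSpec(
    patterns=[(1, 1, 0), (0, 1, 1), (0, 0, 0)],
    counts=[60, 60, 480],
    seed=5,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small three-study simulated dataset shared across unit tests."""
    return simulate_model_based(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_tstat(small_sim):
    """Moderated t-statistics of the small dataset (true w supplied)."""
    return moderate(small_sim.data, w=SMALL_SPEC.w_true)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
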