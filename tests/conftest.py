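import numpy as np
import pandas as pd
import pytest

from protometa.data import FeatureMatrix, QualityMatrix, SampleAnnotation
from protometa.network import from_edges
from protometa.simulate import SimulationParams, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240705)


@pytest.fixture
def small_matrix():
    """4 features x 4 samples with two missing entries, raw scale."""
    values = pd.DataFrame(
        [
            [8.0, 4.0, 2.0, 1.0],
            [2.0, np.nan, 2.0, 2.0],
            [1.0, 1.0, np.nan, 4.0],
            [16.0, 16.0, 16.0, 16.0],
        ],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return FeatureMatrix(values=values, is_log=False, feature_kind="protein")


@pytest.fixture
def chain5():
    """Linear 5-metabolite chain M1 -> E1 -> M2 -> E2 -> M3 -> E3 -> M4 -> E4 -> M5."""
    mets = [f"M{i}" for i in range(1, 6)]
    enzymes = [f"E{i}" for i in range(1, 5)]
    kinds = {m: "metabolite" for m in mets} | {e: "enzyme" for e in enzymes}
    edges = []
    for i, e in enumerate(enzymes):
        rid = f"R{i + 1}"
        edges.append((mets[i], e, rid))
        edges.append((e, mets[i + 1], rid))
    return from_edges(edges, kinds, reverse={f"R{i}": False for i in range(1, 5)})


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired cohort with planted effects, shared across tests."""
    params = SimulationParams(
        n_proteins=250, n_metabolites=40, n_hallmark_sets=5, hallmark_set_size=15, seed=99
    )
    return params, simulate_cohort(params)


def make_annotation(sample_ids, conditions, methods, subjects=None):
    subjects = subjects or [f"S{i}" for i in range(len(sample_ids))]
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": subjects,
                "condition": conditions,
                "method": methods,
                "matrix_type": "fresh-frozen",
            }
        )
    )
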