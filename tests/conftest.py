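import numpy as np
import pandas as pd
import pytest

from ferroscore import CohortAnnotations, ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 2 samples, log2 scale."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def five_gene_expr() -> ExpressionMatrix:
    """The canonical 5-gene single-sample walk fixture: g1..g5 = 5,4,3,2,1."""
    return ExpressionMatrix(
        ["g1", "g2", "g3", "g4", "g5"],
        ["s1"],
        np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]),
    )


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("top2", "top two genes", frozenset({"g1", "g2"})),
            GeneSet("bottom2", "bottom two genes", frozenset({"g4", "g5"})),
        ]
    )


def make_annotations(times, events, groups=None, ids=None) -> CohortAnnotations:
    n = len(times)
    ids = ids or [f"p{i}" for i in range(n)]
    groups = groups if groups is not None else ["all"] * n
    return CohortAnnotations(
        pd.DataFrame(
            {"group": list(groups), "time": list(times), "event": list(events)},
            index=pd.Index(ids, name="sample_id"),
        )
    )


@pytest.fixture
def six_subject_ann() -> CohortAnnotations:
    """Six subjects, two groups, mixed censoring — hand-checkable."""
    return make_annotations(
        times=[2.0, 4.0, 5.0, 3.0, 6.0, 8.0],
        events=[1, 1, 0, 1, 1, 0],
        groups=["a", "a", "a", "b", "b", "b"],
    )
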