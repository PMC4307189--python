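import numpy as np
import pandas as pd
import pytest

from xtalknet.expression_io import ExpressionMatrix
from xtalknet.network_builder import RelationshipNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240135)


def make_network(g, edges, condition=None, gene_ids=None):
    """Small adjacency helper used across test modules."""
    adj = np.zeros((g, g), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return RelationshipNetwork(
        gene_ids or [f"G{k}" for k in range(g)], adj, condition=condition
    )


def make_expr(values, gene_ids=None, sample_ids=None, sample_info=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    data = pd.DataFrame(
        values,
        index=gene_ids or [f"G{k}" for k in range(g)],
        columns=sample_ids or [f"S{k}" for k in range(n)],
    )
    return ExpressionMatrix(data, sample_info)


@pytest.fixture
def dosed_expr_pair():
    """Tiny paired parental/resistant matrices with dose and replicate labels.

    One replicate (index 1) per condition, doses 0 / 0.1 / 1.0; values chosen
    by hand so fold-change screens have known answers (see the tests).
    """

    def build(p_values, r_values, gene_ids):
        cols_p = ["P_d0", "P_d01", "P_d1"]
        cols_r = ["R_d0", "R_d01", "R_d1"]
        info_p = pd.DataFrame(
            {"condition": "parental", "dose": [0.0, 0.1, 1.0], "replicate": 1},
            index=pd.Index(cols_p, name="sample_id"),
        )
        info_r = pd.DataFrame(
            {"condition": "resistant", "dose": [0.0, 0.1, 1.0], "replicate": 1},
            index=pd.Index(cols_r, name="sample_id"),
        )
        par = make_expr(p_values, gene_ids, cols_p, info_p)
        res = make_expr(r_values, gene_ids, cols_r, info_r)
        return par, res

    return build
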