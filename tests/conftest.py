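import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonal_surveil.io_formats import ExpressionMatrix, GeneSet, Rearrangement


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    """Random 50-gene x 30-cell raw count matrix."""
    counts = rng.poisson(3.0, size=(30, 50))
    return ExpressionMatrix(
        genes=[f"G{i:03d}" for i in range(50)],
        cells=[f"c{i:03d}" for i in range(30)],
        counts=sp.csr_matrix(counts),
        layer="raw",
    )


def make_lognorm(values, genes=None, cells=None):
    """Wrap a dense array as a log-normalized ExpressionMatrix (test helper)."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return ExpressionMatrix(
        genes=genes or [f"g{i}" for i in range(n_genes)],
        cells=cells or [f"c{i}" for i in range(n_cells)],
        counts=sp.csr_matrix(values),
        layer="lognorm",
    )


def make_rearrangement(
    cell_id="cell1",
    v_call="VH1-26",
    j_call="JH1",
    c_call="IGHM",
    cdr3_aa="CARDYW",
    v_seq=None,
    germ=None,
    sample_id=None,
):
    germ = germ if germ is not None else "ACGT" * 10
    v_seq = v_seq if v_seq is not None else germ
    return Rearrangement(
        cell_id=cell_id, v_call=v_call, j_call=j_call, c_call=c_call,
        cdr3_aa=cdr3_aa, v_seq_aligned=v_seq, germline_v_aligned=germ,
        sample_id=sample_id,
    )


@pytest.fixture
def two_group_annotation():
    return pd.DataFrame(
        {
            "cell_id": ["u_cell", "t_cell"],
            "sample_id": ["U1", "T1"],
            "group": ["untreated", "treated"],
        }
    )
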