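import numpy as np
import pandas as pd
import pytest

from hepatlas import GeneSet, LabeledExpression, ScSimConfig, simulate_sc
from hepatlas.qc_markers import de_stats


def make_expression(counts, gene_ids=None, subtype=None, stage="healthy",
                    mito=0.0, n_detected=None):
    """Hand-built LabeledExpression for boundary fixtures."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    subtype = subtype if subtype is not None else ["a"] * n_cells
    mito = np.broadcast_to(np.asarray(mito, float), n_cells)
    if n_detected is None:
        n_detected = (counts > 0).sum(axis=0)
    meta = pd.DataFrame(
        {
            "stage": stage,
            "subtype": subtype,
            "mito_fraction": mito,
            "n_detected_genes": np.asarray(n_detected),
        },
        index=[f"c{i}" for i in range(n_cells)],
    )
    return LabeledExpression(counts=counts, gene_ids=pd.Index(gene_ids),
                             cell_meta=meta)


@pytest.fixture(scope="session")
def sc_config():
    return ScSimConfig(n_types=4, cells_per_type=200, n_genes=1000,
                       markers_per_type=10, marker_log2fc=3.0, seed=0)


@pytest.fixture(scope="session")
def sc_expr(sc_config):
    return simulate_sc(sc_config)


@pytest.fixture(scope="session")
def sc_de_table(sc_expr):
    return de_stats(sc_expr)


@pytest.fixture(scope="session")
def immune_panel():
    rng = np.random.default_rng(123)
    return [
        GeneSet(f"immune_{j}",
                [f"g{i:05d}" for i in rng.choice(np.arange(100, 2000), 30,
                                                 replace=False)])
        for j in range(3)
    ]


@pytest.fixture(scope="session")
def signature_genes():
    return tuple(f"g{i:05d}" for i in range(40))
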