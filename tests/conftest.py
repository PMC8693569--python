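import numpy as np
import pandas as pd
import pytest

import seqdash


@pytest.fixture
def toy_expr():
    """5 genes x 3 samples with annotations, one symbol containing a comma."""
    counts = pd.DataFrame(
        np.arange(15, dtype=float).reshape(5, 3) + 1.0,
        index=[f"g{i}" for i in range(1, 6)],
        columns=["s1", "s2", "s3"],
    )
    sample_table = pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3"], "group": ["A", "A", "B"]}
    )
    gene_table = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 6)],
            "symbol": ["Alpha", "Beta, like", "Gamma", "Delta", "Eps"],
        }
    )
    return seqdash.attach_tables(
        seqdash.ExpressionData(counts=counts), sample_table, gene_table
    )


@pytest.fixture
def toy_de(toy_expr):
    """DE table aligned with toy_expr: 2 annotation + 4 stat columns."""
    lc = seqdash.log_cpm(toy_expr)
    table = pd.DataFrame(
        {
            "gene_id": toy_expr.gene_ids,
            "symbol": list(toy_expr.gene_table["symbol"]),
            "logfc": [1.0, -2.0, 0.5, 3.0, 0.0],
            "ave_expr": lc.mean(axis=1).to_numpy(),
            "p_value": [0.01, 0.04, 0.03, 0.20, 1.0],
            "adj_p": [0.04, 0.05333, 0.05333, 0.20, 1.0],
        }
    )
    return seqdash.DEResult(table)


@pytest.fixture(scope="session")
def sim_data():
    """One simulated dataset shared across tests (seed fixed)."""
    return seqdash.simulate_counts(seed=7)


@pytest.fixture(scope="session")
def sim_de(sim_data):
    expr, _ = sim_data
    return seqdash.fixture_de_test(expr, "group", ("A", "B"))
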