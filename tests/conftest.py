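import numpy as np
import pandas as pd
import pytest

from stemreo import SyntheticConfig, simulate_bulk_cohorts, simulate_single_cell


def rankwise_monotone(expr: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Apply an independent strictly increasing transform to each column.

    Values are replaced by a*(rank+1)**g + c of their within-column rank,
    with parameters drawn per column: strictly increasing and exactly
    order-preserving in floating point (input columns must be tie-free).
    """
    out = {}
    for col in expr.columns:
        v = expr[col].to_numpy()
        assert len(np.unique(v)) == len(v), "rankwise_monotone requires tie-free columns"
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        ranks[order] = np.arange(len(v))
        a = rng.uniform(0.5, 3.0)
        g = rng.uniform(0.8, 2.0)
        c = rng.uniform(0.0, 10.0)
        out[col] = a * (ranks + 1.0) ** g + c
    res = pd.DataFrame(out, index=expr.index)
    res.columns.name = expr.columns.name
    return res


@pytest.fixture(scope="session")
def sc_data():
    """Single-cell fixture: 100 cells, 50 of 200 genes tied to stemness."""
    cfg = SyntheticConfig(n_genes=200, n_cells=100, n_stem_genes=50,
                          stem_effect=2.0, sigma=0.5, n_planted_pairs=20, seed=1)
    expr, profile, truth = simulate_single_cell(cfg)
    return expr, profile, truth


@pytest.fixture(scope="session")
def bulk_small():
    """Two small bulk cohorts with planted pairs and subtype hazards."""
    cfg = SyntheticConfig(n_genes=120, n_samples_per_cohort=80, n_stem_genes=20,
                          n_planted_pairs=15, delta=1.5, sigma=0.5,
                          hazard_ratio=2.5, seed=7)
    exprs, records, truth = simulate_bulk_cohorts(cfg)
    return cfg, exprs, records, truth
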