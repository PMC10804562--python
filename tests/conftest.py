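import numpy as np
import pandas as pd
import pytest

from lmdhet import SimConfig, quantify_cohort, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients, 200 proteins — fast cohort for unit tests."""
    cfg = SimConfig(n_patients=3, n_proteins=200, seed=11)
    truth, psms, designs, annot = simulate_cohort(cfg)
    return cfg, truth, psms, designs, annot


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (9 patients, 2000 proteins), quantified once."""
    cfg = SimConfig(seed=1)
    truth, psms, designs, annot = simulate_cohort(cfg)
    res = quantify_cohort(psms, designs, annotation=annot)
    return cfg, truth, annot, res.matrix


@pytest.fixture
def toy_annot():
    """2 patients x (2 ET + 2 ES) annotation."""
    rows = []
    for p in ("PA", "PB"):
        for ct in ("ET", "ES"):
            for lv in (1, 2):
                rows.append({"sample_id": f"{p}_{ct}_L{lv}", "patient": p,
                             "collection_type": ct, "level": lv})
    return pd.DataFrame(rows)


def random_missing_matrix(rng, n_rows, n_cols, frac_missing):
    """Random matrix with planted missingness (used by imputation tests)."""
    X = rng.normal(0, 1, size=(n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < frac_missing
    X[mask] = np.nan
    idx = [f"P{i:03d}" for i in range(n_rows)]
    cols = [f"S{j:02d}" for j in range(n_cols)]
    return pd.DataFrame(X, index=idx, columns=cols)
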