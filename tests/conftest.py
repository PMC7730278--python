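import numpy as np
import pandas as pd
import pytest

import invresist as ir


@pytest.fixture(scope="session")
def noiseless_cfg():
    return ir.SimConfig(seed=101, plate_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_counts():
    """Moderate planted-truth count simulation shared across tests."""
    cfg = ir.SimConfig(seed=202, n_genes=2000, effect_log2fc=3.0,
                       dispersion=0.05)
    counts, samples, truth = ir.simulate_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_well_data(rng, concs, slopes, noise=3.0, tau=0.0, n_plates=3,
                   n_wells=4, intercept=95.0):
    """Well-level linear dose-response data for two (or more) lines."""
    rows = []
    for line, beta in slopes.items():
        for plate in range(1, n_plates + 1):
            b = beta + (rng.normal(0, tau) if tau > 0 else 0.0)
            c = np.repeat(np.asarray(concs, dtype=float), n_wells)
            v = intercept + b * c + rng.normal(0, noise, c.size)
            rows.append(pd.DataFrame({
                "cell_line": line, "plate": plate, "conc": c, "viability": v,
            }))
    return pd.concat(rows, ignore_index=True)
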