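import numpy as np
import pytest

from phytoedm import (
    CommunityTable,
    MonthlyTimeSeries,
    NoiseModelParams,
    TaxonRecord,
    simulate_noise_model,
)


def series(values, start=(2000, 1), **kw):
    return MonthlyTimeSeries(start, np.asarray(values, dtype=float), **kw)


def seasonal_sine(n_months=240, phase=0.0, amplitude=1.0, start=(2000, 1)):
    t = np.arange(n_months)
    return MonthlyTimeSeries(
        start, amplitude * np.sin(2 * np.pi * t / 12 + phase) + amplitude
    )


def tiny_table(n_taxa=6, n_months=72, seed=0, start=(2000, 1)):
    """Small seasonal community with lognormal noise for fast experiments."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_months)
    taxa = []
    groups = ["diatom", "dinoflagellate", "coccolithophore", "phytoflagellate"]
    for i in range(n_taxa):
        base = 100.0 * (i + 1) * (np.sin(2 * np.pi * t / 12 + rng.uniform(0, 6)) + 1.2)
        vals = base * np.exp(0.3 * rng.standard_normal(n_months))
        taxa.append(
            TaxonRecord(
                taxon_id=f"tx{i:02d}",
                functional_group=groups[i % len(groups)],
                cell_radius=float(2 + 4 * i),
                series=MonthlyTimeSeries(start, vals),
            )
        )
    return CommunityTable(taxa)


@pytest.fixture
def sine_series():
    return seasonal_sine()


@pytest.fixture
def small_table():
    return tiny_table()


@pytest.fixture(scope="session")
def noise_free_table():
    """100-species noise-free seasonal community (shared across tests)."""
    return simulate_noise_model(NoiseModelParams(gamma_obs=0.0), rng_seed=7)
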