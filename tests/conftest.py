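import pandas as pd
import pytest

from fim_riskweight import SyntheticConfig, crude_rates, generate, quintile_classify


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic draw (100 countries x 11 years, 3 missing units)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_matrices(default_sim):
    """Rate and risk-level matrices of the full-size draw."""
    table, _ = default_sim
    rates = crude_rates(table, unit="country-year")
    return rates, quintile_classify(rates)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast draw for tests that only need structure."""
    cfg = SyntheticConfig(n_countries=25, years=(2006, 2008), missing_rows=2, seed=3)
    return cfg, *generate(cfg)


@pytest.fixture()
def toy_levels():
    """Hand-built level matrix: X1 tracks the outcome, X2 is scrambled."""
    lcm = [1, 2, 3, 4, 5] * 4
    return pd.DataFrame(
        {
            "X1": lcm,
            "X2": [3, 1, 5, 2, 4, 4, 2, 1, 5, 3, 2, 5, 4, 1, 3, 1, 3, 2, 5, 4],
            "LCM": lcm,
        }
    )
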