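import warnings

import pytest

import cndc


@pytest.fixture(scope="session")
def table2():
    """The packaged treatment-mean fixture (80 rows)."""
    return cndc.load_table2_fixture()


@pytest.fixture(scope="session")
def synth_default():
    """One default synthetic trial with its ground truth (seed 1)."""
    return cndc.simulate_experiment(cndc.SyntheticConfig(seed=1))


@pytest.fixture()
def quiet():
    """Suppress the package's diagnostic warnings inside a test."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", cndc.CndcWarning)
        yield


def make_observations(rows, **common):
    """Build PlotObservation list from (n_rate, ldm, pnc[, extra]) tuples."""
    defaults = dict(variety="v1", season="early", stage="TS", year=2000)
    defaults.update(common)
    out = []
    for row in rows:
        n_rate, ldm, pnc = row[0], row[1], row[2]
        extra = row[3] if len(row) > 3 else {}
        out.append(cndc.PlotObservation(
            n_rate=n_rate, ldm=ldm, pnc=pnc, **{**defaults, **extra}))
    return out
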