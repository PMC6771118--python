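import numpy as np
import pytest

import bestqspr as bq


@pytest.fixture(scope="session")
def reference_cohort():
    return bq.load_reference_cohort()


@pytest.fixture(scope="session")
def reference_energies():
    return bq.load_reference_energies()


@pytest.fixture(scope="session")
def reference_dataset():
    return bq.load_reference_qspr()


@pytest.fixture(scope="session")
def reference_fit(reference_dataset):
    """The validated reference regression (outlier removal at defaults)."""
    return bq.fit_with_outlier_removal(reference_dataset)


@pytest.fixture(scope="session")
def ring_structure(tmp_path_factory):
    """Synthetic pentamer fixture: (ChannelModel, truth dict)."""
    from bestqspr.structure import load_structure

    path = tmp_path_factory.mktemp("structure") / "ring.pdb"
    _, truth = bq.make_fixture_structure(5, seed=0, path=path)
    model = load_structure(path, membrane_band=truth["membrane_band"])
    return model, truth


def brute_force_loo(x, y):
    """Independent LOO oracle: n explicit drop-one polyfits."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.empty(len(x))
    for i in range(len(x)):
        mask = np.ones(len(x), bool)
        mask[i] = False
        slope, intercept = np.polyfit(x[mask], y[mask], 1)
        out[i] = y[i] - (slope * x[i] + intercept)
    return out
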