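import numpy as np
import pytest

from taguchi_biocat import datasets, snr
from taguchi_biocat.design import build_l9


@pytest.fixture(scope="session")
def study():
    """Bundled esterification L9 study: (array, run sheet with conversions)."""
    return datasets.babassu_study()


@pytest.fixture(scope="session")
def study_snr(study):
    """Per-run S/N records of the bundled study conversions."""
    _, sheet = study
    return snr.compute_snr(snr.ResponseSet.from_single(sheet["conversion"].to_numpy()))


@pytest.fixture(scope="session")
def l9():
    return build_l9(["Temperature", "Time", "Molar ratio", "Biocatalyst"])


def brute_force_level_mean(cells, values, factor_idx, level):
    """Oracle: mean response over rows where a factor sits at a level."""
    mask = cells[:, factor_idx] == level
    return float(np.asarray(values)[mask].mean())
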