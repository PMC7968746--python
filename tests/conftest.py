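import numpy as np
import pytest

import fpinfer as fp


@pytest.fixture(scope="session")
def two_path_model() -> fp.FPModel:
    """Well-separated two-path mixture: T-bar=(10, 80) ms, CV=(0.5, 0.2),
    p=(0.6, 0.4)  ->  L=(4, 25), tau=(2.5, 3.2), x2=2/3."""
    return fp.FPModel(tau=[2.5, 3.2], L=[4.0, 25.0], x=[2.0 / 3.0])


@pytest.fixture(scope="session")
def two_path_sample(two_path_model) -> np.ndarray:
    """N=2e4 quantized draws (dt=0.1 ms) from the two-path generator."""
    return fp.generate_dataset(two_path_model, 20_000, 0.1, seed=42)


@pytest.fixture(scope="session")
def two_path_fit(two_path_sample) -> tuple[fp.BinnedData, fp.FitResult]:
    data = fp.bin_isi(two_path_sample, 0.1)
    fit = fp.fit_mle(data, 2, config=fp.FitConfig(seed=7))
    return data, fit


@pytest.fixture(scope="session")
def tiny_exponentialish_data() -> fp.BinnedData:
    """Five quantized events from a single Gamma path; small enough that the
    evidence integral can be brute-forced on a dense 2-D grid."""
    times = fp.generate_dataset(fp.FPModel(tau=[5.0], L=[2.0]), 5, 0.5, seed=3)
    return fp.bin_isi(times, 0.5)
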