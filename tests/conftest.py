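import numpy as np
import pandas as pd
import pytest

from gridbind.io_cv import BiasSpec, WindowConfig
from gridbind.reweight import BiasedSampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


def make_sample_set(values_by_window, cv_names, temperature=300.0):
    """Build a BiasedSampleSet from {window_id: (n, n_cvs) array}."""
    frames = []
    origin = []
    window_ids = list(values_by_window)
    for i, wid in enumerate(window_ids):
        arr = np.atleast_2d(np.asarray(values_by_window[wid], dtype=float))
        frames.append(pd.DataFrame(arr, columns=cv_names))
        origin.append(np.full(len(arr), i))
    return BiasedSampleSet(
        cv_values=pd.concat(frames, ignore_index=True),
        window_of_origin=np.concatenate(origin).astype(np.intp),
        window_ids=window_ids,
        temperature=temperature,
    )


def gaussian_umbrella_samples(kappa, centers, k_bias, n, seed, temperature=300.0):
    """Exact draws from each biased Gaussian e^{-beta(kappa x^2/2 + k(x-c)^2/2)}."""
    rt = 1.987204e-3 * temperature
    rng = np.random.default_rng(seed)
    data = {}
    for i, c in enumerate(centers):
        prec = (kappa + k_bias) / rt
        mean = k_bias * c / (kappa + k_bias)
        data[f"w{i}"] = rng.normal(mean, 1.0 / np.sqrt(prec), size=(n, 1))
    samples = make_sample_set(data, ["x"], temperature)
    config = WindowConfig(
        windows=[
            (f"w{i}", [BiasSpec(cv="x", center=float(c), force_constant=k_bias)])
            for i, c in enumerate(centers)
        ],
        temperature=temperature,
    )
    return samples, config
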