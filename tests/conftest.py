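import numpy as np
import pytest

import csbn


@pytest.fixture(scope="session")
def builtin_calibration() -> csbn.MassCalibration:
    """Sigmoid calibration fitted once to the builtin 12-marker table."""
    return csbn.fit_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def gaussian_mixture_profiles(
    seed: int,
    n_proteins: int,
    n_slices: int = 64,
    n_peaks_max: int = 3,
    amp_decades: tuple[float, float] = (3.0, 5.0),
    sigma_range: tuple[float, float] = (1.5, 6.0),
    floor_rel: float = 1e-3,
) -> csbn.ProfileSet:
    """Multi-peak truth profiles for quantification recovery experiments."""
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_slices + 1, dtype=float)
    prof = np.zeros((n_proteins, n_slices))
    for i in range(n_proteins):
        for _ in range(int(rng.integers(1, n_peaks_max + 1))):
            mu = rng.uniform(10, n_slices - 10)
            sg = rng.uniform(*sigma_range)
            amp = 10.0 ** rng.uniform(*amp_decades)
            prof[i] += amp * np.exp(-0.5 * ((x - mu) / sg) ** 2)
    prof += floor_rel * prof.max(axis=1, keepdims=True)
    return csbn.ProfileSet([f"P{i:03d}" for i in range(n_proteins)], prof)


def sliding_average(profile: np.ndarray, half_window: int = 2) -> np.ndarray:
    """5-slice window-integrated profile: the quantifier's estimand."""
    out = np.empty_like(profile, dtype=float)
    for j in range(profile.size):
        lo, hi = max(0, j - half_window), min(profile.size, j + half_window + 1)
        out[j] = profile[lo:hi].mean()
    return out
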