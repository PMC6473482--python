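import numpy as np
import pytest

import ramancell as rc


@pytest.fixture(scope="session")
def two_class_full():
    """Default calibrated SW480/SW620 dataset (163 + 167 cells, seed 0)."""
    cfg = rc.GeneratorConfig(
        profiles=rc.default_profiles(classes=["SW480", "SW620"]), seed=0)
    ds = rc.generate_study_dataset(cfg)
    return ds, rc.RamanPreprocessor().process(ds)


@pytest.fixture(scope="session")
def five_class_full():
    """Default calibrated five-class study dataset (680 cells, seed 0)."""
    cfg = rc.GeneratorConfig(seed=0)
    ds = rc.generate_study_dataset(cfg)
    return ds, rc.RamanPreprocessor().process(ds)


@pytest.fixture(scope="session")
def two_class_small():
    """Small SW480/SW620 dataset for cheap unit tests (30 + 30, seed 11)."""
    cfg = rc.GeneratorConfig(
        profiles=rc.default_profiles(classes=["SW480", "SW620"]),
        cells_per_class={"SW480": 30, "SW620": 30}, seed=11)
    ds = rc.generate_study_dataset(cfg)
    return ds, rc.RamanPreprocessor().process(ds)


@pytest.fixture(scope="session")
def three_class_small():
    """Staged adenocarcinoma trio SW480/HT29/SW620 (24 each, seed 5)."""
    cfg = rc.GeneratorConfig(
        profiles=rc.default_profiles(classes=["SW480", "HT29", "SW620"]),
        cells_per_class={"SW480": 24, "HT29": 24, "SW620": 24}, seed=5)
    ds = rc.generate_study_dataset(cfg)
    return ds, rc.RamanPreprocessor().process(ds)


@pytest.fixture()
def quiet_instrument():
    """Noise-free, spike-free, flat-baseline instrument."""
    return rc.InstrumentModel(noise_sd=0.0, cosmic_rate=0.0,
                              baseline_coeffs=(0.0,), quartz_amplitude=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
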