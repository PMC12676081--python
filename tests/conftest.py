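import numpy as np
import pytest

from paleoflim import flim as fl
from paleoflim import scenes as sc


@pytest.fixture(scope="session")
def irf():
    return fl.default_irf()


@pytest.fixture(scope="session")
def acq():
    """Default TCSPC timing: 50 ns window, 1024 bins."""
    return sc.default_acquisition()


@pytest.fixture(scope="session")
def acq_fast():
    """Coarser timing for tests where sub-bin lifetime accuracy is not at stake."""
    return sc.FLIMAcquisition(period_ns=50.0, n_bins=256)


@pytest.fixture(scope="session")
def default_scene_run(irf):
    """One seeded default-scene simulation + full-cube analysis, shared.

    Returns (spec, label, cube, truth, fit_table, maps); generated once per
    session because the cube and the per-pixel unmixing dominate runtime.
    """
    spec = sc.default_scene(seed=7)
    label = sc.generate_structure_masks(spec)
    cube, truth = sc.generate_flim_cube(label, irf=irf, seed=7)
    table, maps = fl.fit_cube(cube, irf, k=3)
    return spec, label, cube, truth, table, maps


def pooled_histogram(cube, label, class_name):
    sel = label == sc.CLASS_IDS[class_name]
    return cube.counts[:, sel].sum(axis=1)


@pytest.fixture(scope="session")
def noiseless_carbon_fit():
    """Noiseless 514 nm arbuscule spectrum through the full Raman pipeline."""
    from paleoflim import raman as rm

    spec = sc.generate_raman_spectrum(sc.arbuscule_material(), 514.0, noise="none")
    ref = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
    corrected = rm.baseline_correct(spec, reference=ref)
    return rm.fit_bands(corrected)
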