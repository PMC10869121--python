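import numpy as np
import pytest

from burnhsi.montecarlo import MCConfig
from burnhsi.spectra import load_extinction_library, unmixing_grid
from burnhsi.synthetic import default_scenario


@pytest.fixture(scope="session")
def library():
    return load_extinction_library()


@pytest.fixture(scope="session")
def grid14():
    return unmixing_grid()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def small_calibration():
    """Tiny, fast Monte Carlo calibration for plumbing tests (not precision)."""
    from burnhsi.forward_model import build_calibration_dataset
    spec = {"cm": [0.0, 5.0], "chbo": [0.0, 10.0, 30.0], "chbr": [0.0, 15.0],
            "cmethb": [0.0, 10.0]}
    return build_calibration_dataset(grid_spec=spec,
                                     config=MCConfig(n_photons=2000, seed=99),
                                     tiers=((60.0, 1, 0.0), (4.0, 4, 2.0), (1.3, 8, 20.0)))


@pytest.fixture(scope="session")
def surrogate_dataset(library):
    """Noiseless calibration dataset from the linear Beer-Lambert surrogate."""
    import itertools
    from burnhsi.forward_model import CalibrationDataset
    from burnhsi.synthetic import surrogate_absorbance
    from burnhsi.unmixing import fit_absorbance_spectrum

    axes = {"cm": [0.0, 5.0, 10.0], "chbo": [0.0, 10.0, 25.0],
            "chbr": [0.0, 10.0, 25.0], "cmethb": [0.0, 8.0, 20.0]}
    pts = np.array(list(itertools.product(*axes.values())))
    a = surrogate_absorbance(pts, library)
    rd = 10.0 ** (-a)
    coeffs = np.array([fit_absorbance_spectrum(-np.log10(r), library).as_array()
                       for r in rd])
    return CalibrationDataset(axes={k: list(map(float, v)) for k, v in axes.items()},
                              grid=library.grid, truth=pts, reflectance=rd,
                              coefficients=coeffs,
                              r_squared=np.ones(len(pts)),
                              excluded=np.zeros(len(pts), dtype=bool),
                              provenance={"method": "surrogate", "seed": 0})


@pytest.fixture(scope="session")
def linear_surrogate_formulas(surrogate_dataset):
    """Degree-1 empirical formulas fitted on noiseless surrogate spectra.

    The Beer-Lambert surrogate forward model is exactly linear in the
    extinction spectra, so a linear formula set inverts it exactly; this gives
    the pipeline an exact reference inversion for plumbing and end-to-end
    tests that do not probe the Monte Carlo calibration itself.
    """
    from burnhsi.forward_model import fit_empirical_formulas
    return fit_empirical_formulas(surrogate_dataset, degree=1, n_augment=0,
                                  max_total_hb=1e9)
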