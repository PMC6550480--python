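import numpy as np
import pytest

from aqpflux import (FilmGeometry, monomer_curve, solve_steady_state,
                     sweep_capping, voxelize)

# sweep grid covering the analysis point 0.64 densely at desk cost
SWEEP_FRACTIONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10)) + (0.64,)


@pytest.fixture(scope="session")
def study_geometry():
    """The study film: 1 nm pores at 28% areal coverage, 5x5 supercell."""
    return FilmGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """2x2-pore supercell with a thin film, for fast solver tests."""
    return FilmGeometry(film_thickness=4.0, reservoir_depth=0.5,
                        n_pores_y=2, n_pores_z=2)


@pytest.fixture(scope="session")
def open_solution(study_geometry):
    dom = voxelize(study_geometry, None, 0.25)
    return dom, solve_steady_state(dom)


@pytest.fixture(scope="session")
def capping_curve(study_geometry):
    """Pore-capping De(f) sweep on the study geometry (12 solves)."""
    return sweep_capping(study_geometry, SWEEP_FRACTIONS, seed=1)


@pytest.fixture(scope="session")
def aggregate_curve(study_geometry):
    return sweep_capping(study_geometry, SWEEP_FRACTIONS,
                         mode="aggregate_disk", seed=1)


@pytest.fixture(scope="session")
def monomer_curve_matched(study_geometry, aggregate_curve):
    """Monomer curve evaluated on the aggregate curve's fraction grid."""
    return monomer_curve(study_geometry, aggregate_curve.fractions)
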