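"""Shared fixtures: calibrated landscapes and one converged metadynamics run.

The expensive well-tempered metadynamics run under the full study conditions
(hill height 1.0 kcal/mol, widths 0.1 Å, bias factor 10, pace 200 steps,
2000 hills) is session-scoped so the convergence, hill-decay and
free-energy-recovery checks all share a single simulation.
"""

import numpy as np
import pytest
from hypothesis import settings

from glypath import fel as fl
from glypath import sampling as sp
from glypath import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def conf_landscape() -> syn.PotentialSpec:
    """Default two-basin conformational landscape on the pucker disk."""
    return syn.make_conformational_landscape()


@pytest.fixture(scope="session")
def reaction_landscape() -> syn.PotentialSpec:
    """Default desk-scale three-CV reaction landscape."""
    return syn.make_reaction_landscape()


@pytest.fixture(scope="session")
def double_well_1d() -> syn.PotentialSpec:
    """1-D double well with a 3.0 kcal/mol barrier and 0.5 kcal/mol offset."""
    return syn.make_double_well_1d()


@pytest.fixture(scope="session")
def converged_conf_run(conf_landscape):
    """Full conformational metadynamics protocol (2000 hills, pace 200)."""
    langevin = sp.LangevinParams(seed=20260919)
    metad = sp.MetadParams(height=1.0, widths=(0.1, 0.1), pace=200,
                           bias_factor=10.0, max_hills=2000)
    hills, traj = sp.run_wt_metadynamics(conf_landscape, langevin, metad,
                                         conf_landscape.truth.minima[1])
    return hills, traj


@pytest.fixture(scope="session")
def converged_1d_run(double_well_1d):
    """Long, well-converged 1-D metadynamics run (fine hills, 3000 deposits)."""
    langevin = sp.LangevinParams(seed=13)
    metad = sp.MetadParams(height=0.3, widths=(0.05,), pace=100,
                           bias_factor=10.0, max_hills=3000)
    return sp.run_wt_metadynamics(double_well_1d, langevin, metad,
                                  double_well_1d.truth.minima[1])


@pytest.fixture(scope="session")
def reaction_grid(reaction_landscape) -> fl.FELGrid:
    """Analytic reaction FEL on the default 41-point grid."""
    return fl.grid_from_potential(reaction_landscape, n=41)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
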