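"""Shared fixtures: simulated spheroids and analyzed stacks.

Heavy simulated objects are session-scoped so the suite renders each
condition once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spherotox as st
from spherotox.pipeline import RunConfig, analyze_stack


@pytest.fixture(scope="session")
def default_config():
    return st.SyntheticConfig(n_cells=1000, seed=1)


@pytest.fixture(scope="session")
def control_truth(default_config):
    return st.generate_spheroid_truth(default_config, dose_uM=0.0)


@pytest.fixture(scope="session")
def control_stack(control_truth, default_config):
    return st.render_stack(control_truth, default_config, well_id="ctrl")


@pytest.fixture(scope="session")
def analyzed_control(control_stack):
    """(nuclei3d, cyto3d, region) for the untreated 1,000-cell spheroid."""
    return analyze_stack(control_stack, RunConfig())


@pytest.fixture(scope="session")
def table1():
    return st.load_table_fixtures("T1")


@pytest.fixture(scope="session")
def table2():
    return st.load_table_fixtures("T2")


def make_plane_object(label, z, x_um, y_um, area_um2=50.0, compartment="nucleus"):
    """Minimal PlaneObject for linker tests (no pixel mask needed)."""
    from spherotox.seg2d import PlaneObject

    n = max(1, int(round(area_um2)))
    coords = np.zeros((n, 2), dtype=int)
    return PlaneObject(
        label=label, z_index=z, coords=coords, area_um2=area_um2,
        centroid_um=(x_um, y_um), compartment=compartment,
    )


def synthetic_truth_from_cells(cells_df, config, radius=110.0, fov=300.0,
                               dose_uM=0.0):
    """Hand-built GroundTruth (synthetic stand-in for generator output)
    so optics tests can place cells at exact coordinates."""
    return st.GroundTruth(
        cells=cells_df,
        spheroid_center_um=(fov / 2, fov / 2, radius),
        spheroid_radius_um=radius,
        fov_xy_um=fov,
        dose_uM=dose_uM,
        dead_fraction_expected=0.0,
        seed=config.seed,
        config=config,
        effect=st.EffectParams(),
    )


def cell_row(x, y, z, I_DAPI=100.0, I_FITC=0.0, I_TexasRed=0.0,
             r_nuc=5.0, r_cell=8.8, state="live"):
    return {
        "cell_id": 0, "x_um": x, "y_um": y, "z_um": z,
        "nucleus_radius_um": r_nuc, "cell_radius_um": r_cell,
        "state": state, "detached": False,
        "caspase_positive": False, "mito_intact": True,
        "I_DAPI": I_DAPI, "I_FITC": I_FITC, "I_TexasRed": I_TexasRed,
    }
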