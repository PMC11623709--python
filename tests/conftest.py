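import numpy as np
import pytest

import impelo


@pytest.fixture(scope="session")
def model():
    return impelo.default_beam_model()


@pytest.fixture(scope="session")
def calibration():
    return impelo.default_calibration()


@pytest.fixture(scope="session")
def water_small():
    """10 cm water cube at 2 mm."""
    return impelo.make_water_phantom(100.0, 2.0)


@pytest.fixture(scope="session")
def abdomen_setup():
    """Shared three-beam synthetic case with assembled influence matrix."""
    return impelo.build_setup("abdomen", seed=1)


@pytest.fixture(scope="session")
def brain_setup():
    return impelo.build_setup("brain", seed=1)


@pytest.fixture(scope="session")
def water_single_spot(water_small, calibration, model):
    """One central spot of a mid-range layer in uniform water, no cutoff."""
    ph = water_small
    cx = ph.axis_coords(0)[ph.shape[0] // 2]   # a voxel-center coordinate
    cz = ph.axis_coords(2)[ph.shape[2] // 2]
    iso = np.array([cx, ph.upper_corner[1], cz])  # beam entry face
    geom = impelo.BeamGeometry(gantry_angle_deg=0.0, iso=iso,
                               sad_x=model.sad_x, sad_y=model.sad_y)
    li = 4  # 80 MeV, r80 ~ 51 mm, fits inside the 10 cm cube
    spot = impelo.Spot(beam=0, energy_index=li,
                       energy_mev=model.layers[li].nominal_energy,
                       x=0.0, y=0.0, weight=1.0)
    idx, vals = impelo.spot_dose(ph, calibration, spot, geom, model, cutoff=0.0)
    dose = np.zeros(ph.n_voxels)
    dose[idx] = vals
    return ph, geom, model.layers[li], spot, dose.reshape(ph.shape)
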