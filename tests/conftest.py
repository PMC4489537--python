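import pytest

import eiphase as ei


@pytest.fixture(scope="session")
def pet():
    return ei.get_material("PET")


@pytest.fixture(scope="session")
def peek():
    return ei.get_material("PEEK")


@pytest.fixture(scope="session")
def water():
    return ei.get_material("water")


@pytest.fixture(scope="session")
def wire_geometry():
    """Synchrotron wire-scan geometry: 27 keV, z = 3.85 m, 20 µm scan steps,
    46 µm detector pixels."""
    return ei.BeamGeometry(energy_keV=27.0, z_od=3.85, step_y_um=20.0, step_x_um=46.0)


@pytest.fixture(scope="session")
def slit_curve():
    """Illumination curve of the 20 µm / 250 µm slit pair, no source blur."""
    return ei.AnalyticCurve(a1_um=20.0, a2_um=250.0, sigma_src_um=0.0)


@pytest.fixture(scope="session")
def wp50(slit_curve):
    """50% illumination on the rising (lower-edge) branch."""
    return ei.working_point(slit_curve, 0.5, "lower")
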