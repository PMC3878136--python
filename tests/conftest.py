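"""Shared fixtures: published cell parameters and cached synthetic structures."""

import pytest

from packmotif import CrystalStructure, UnitCell
from packmotif.synthetic import MotifSpec, build_crystal

# Published unit cells of the five 4-substituted methylidene oxindoles
# (C2/c, C2/c, P-1, P-1, P21/c), with formula weight, Z and the printed
# volume / density they must reproduce.
TABLE1 = {
    "3a": {"cell": UnitCell(19.623, 4.0710, 32.979, 90, 101.698, 90),
           "fw": 318.17, "formula": "C15H12BrNO2", "z": 8, "n_ops": 8,
           "volume": 2579.8, "density": 1.638},
    "3b": {"cell": UnitCell(19.6553, 4.0406, 32.653, 90, 101.378, 90),
           "fw": 273.71, "formula": "C15H12ClNO2", "z": 8, "n_ops": 8,
           "volume": 2542.3, "density": 1.430},
    "3c": {"cell": UnitCell(4.1302, 12.9513, 13.0829, 62.708, 86.495, 86.546),
           "fw": 251.27, "formula": "C16H13NO2", "z": 2, "n_ops": 2,
           "volume": 620.35, "density": 1.345},
    "3d": {"cell": UnitCell(8.1168, 9.2556, 9.3927, 62.290, 80.933, 72.180),
           "fw": 235.27, "formula": "C16H13NO", "z": 2, "n_ops": 2,
           "volume": 594.64, "density": 1.314},
    "3e": {"cell": UnitCell(9.9484, 7.9134, 16.013, 90, 104.340, 90),
           "fw": 266.25, "formula": "C15H10N2O3", "z": 4, "n_ops": 4,
           "volume": 1221.4, "density": 1.448},
}


@pytest.fixture(scope="session")
def table1():
    return TABLE1


@pytest.fixture(scope="session")
def dimer_structure():
    """Noise-free inversion-dimer crystal (P-1)."""
    contents, _ = build_crystal(MotifSpec("inversion_dimer", seed=11))
    return CrystalStructure(contents)


@pytest.fixture(scope="session")
def hydrate_structure():
    contents, truth = build_crystal(MotifSpec("hydrate_channel", seed=11))
    return CrystalStructure(contents), truth


@pytest.fixture(scope="session")
def stack_structure():
    contents, _ = build_crystal(MotifSpec("translation_stack", seed=11))
    return CrystalStructure(contents)
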