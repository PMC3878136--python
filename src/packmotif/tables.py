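"""Element data used throughout the pipeline.

Three fixed tables, each keyed by element symbol:

* ``ATOMIC_WEIGHT`` -- IUPAC conventional standard atomic weights (g/mol).
* ``COVALENT_RADIUS`` -- single-bond covalent radii (Angstrom), Cordero et al. values;
  used for bond perception.
* ``VDW_RADIUS`` -- van der Waals radii (Angstrom), Bondi values; used for close-contact
  and cluster-shell criteria.

The tables cover the elements that occur in small-molecule organic crystals plus the
common halogen/chalcogen substituents.  Lookups go through :func:`atomic_weight`,
:func:`covalent_radius` and :func:`vdw_radius`, which raise :class:`UnknownElementError`
for symbols outside the tables.
"""

from __future__ import annotations

__all__ = [
    "ATOMIC_WEIGHT",
    "COVALENT_RADIUS",
    "VDW_RADIUS",
    "UnknownElementError",
    "atomic_weight",
    "covalent_radius",
    "vdw_radius",
    "normalize_element",
]

AVOGADRO = 6.02214076e23  # 1/mol
# 1 g/mol per A^3  ->  g/cm^3 : 1 / (N_A * 1e-24)
AMU_PER_A3_TO_G_PER_CM3 = 1.0 / (AVOGADRO * 1e-24)


class UnknownElementError(KeyError):
    """Raised when an element symbol has no tabulated value."""


ATOMIC_WEIGHT = {
    "H": 1.008, "D": 2.014, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.904,
}

# Cordero et al. single-bond covalent radii; C is the sp3 value.
COVALENT_RADIUS = {
    "H": 0.31, "D": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "K": 2.03, "Ca": 1.76,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32,
    "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}

# Bondi van der Waals radii.
VDW_RADIUS = {
    "H": 1.20, "D": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "K": 2.75, "Ca": 2.31,
    "Mn": 2.05, "Fe": 2.05, "Co": 2.00, "Ni": 1.63, "Cu": 1.40,
    "Zn": 1.39, "Se": 1.90, "Br": 1.85, "I": 1.98,
}


def normalize_element(symbol: str) -> str:
    """Canonical capitalization of an element symbol (``"BR"`` -> ``"Br"``)."""
    s = symbol.strip()
    if not s:
        raise UnknownElementError(symbol)
    return s[0].upper() + s[1:].lower()


def _lookup(table: dict, symbol: str, what: str) -> float:
    key = normalize_element(symbol)
    try:
        return table[key]
    except KeyError:
        raise UnknownElementError(f"no tabulated {what} for element {symbol!r}") from None


def atomic_weight(symbol: str) -> float:
    return _lookup(ATOMIC_WEIGHT, symbol, "atomic weight")


def covalent_radius(symbol: str) -> float:
    return _lookup(COVALENT_RADIUS, symbol, "covalent radius")


def vdw_radius(symbol: str) -> float:
    return _lookup(VDW_RADIUS, symbol, "van der Waals radius")
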