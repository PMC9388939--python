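"""Photon interaction data for phantom and detector materials.

Each :class:`Material` carries a mass attenuation coefficient table
(mu/rho, cm^2/g) and a mass energy-absorption coefficient table
(muen/rho, cm^2/g) on a shared 25-point energy grid spanning
0.01-7 MeV, together with a bulk density and a mean Z/A (electrons per
atomic mass unit, used to split off the incoherent-scattering part of
the cross-section during transport).

The water, air and cortical-bone tables are package-internal surrogate
compilations patterned after the standard reference (XCOM-style)
photon-interaction data.  Soft tissue, brain, lung and thyroid reuse
the water shape rescaled so that their 6 MeV muen/rho equals the
measured-coefficient values used by the TLD reduction chain (0.0179
cm^2/g for soft-tissue-like organs, 0.0194 cm^2/g for thyroid).  The
tungsten-alloy entry is a coarse surrogate for collimator attenuation
studies; beam collimation itself is modelled parametrically by the
transport module, not by transporting photons through tungsten.

Lookups interpolate log-log between grid points and refuse to
extrapolate outside the tabulated range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "EnergyOutOfRangeError",
    "coefficient_at",
    "MATERIALS",
    "get_material",
]


class EnergyOutOfRangeError(ValueError):
    """Raised when a coefficient is requested outside the tabulated range."""


# Shared energy grid, MeV.
_E_GRID = np.array(
    [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10,
     0.15, 0.20, 0.30, 0.40, 0.50, 0.60, 0.80, 1.00, 1.25, 1.50,
     2.00, 3.00, 4.00, 5.00, 6.00, 7.00]
)

_WATER_MU = np.array(
    [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707,
     0.1505, 0.1370, 0.1186, 0.1061, 0.09687, 0.08956, 0.07865, 0.07072,
     0.06323, 0.05754, 0.04942, 0.03969, 0.03403, 0.03031, 0.02770, 0.02583]
)
_WATER_MUEN = np.array(
    [4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223, 0.03190, 0.02597,
     0.02546, 0.02764, 0.02967, 0.03192, 0.03279, 0.03299, 0.03284, 0.03206,
     0.03103, 0.02965, 0.02833, 0.02608, 0.02281, 0.02066, 0.01915, 0.01806,
     0.01723]
)

_AIR_MU = np.array(
    [5.120, 1.614, 0.7779, 0.3538, 0.2485, 0.2080, 0.1875, 0.1662, 0.1541,
     0.1356, 0.1233, 0.1067, 0.09549, 0.08712, 0.08055, 0.07074, 0.06358,
     0.05687, 0.05175, 0.04447, 0.03581, 0.03079, 0.02751, 0.02522, 0.02345]
)
_AIR_MUEN = np.array(
    [4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098, 0.03041, 0.02407,
     0.02325, 0.02496, 0.02672, 0.02872, 0.02949, 0.02966, 0.02953, 0.02882,
     0.02789, 0.02666, 0.02547, 0.02345, 0.02057, 0.01870, 0.01740, 0.01647,
     0.01579]
)

_BONE_MU = np.array(
    [28.51, 9.032, 4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855,
     0.1480, 0.1309, 0.1113, 0.09908, 0.09022, 0.08332, 0.07308, 0.06566,
     0.05871, 0.05346, 0.04607, 0.03745, 0.03257, 0.02946, 0.02734, 0.02582]
)
_BONE_MUEN = np.array(
    [26.80, 8.388, 3.601, 1.070, 0.4507, 0.2336, 0.1400, 0.06896, 0.04585,
     0.03183, 0.03003, 0.03032, 0.03069, 0.03073, 0.03052, 0.02973, 0.02875,
     0.02745, 0.02623, 0.02421, 0.02137, 0.01964, 0.01853, 0.01782, 0.01737]
)

# Tungsten alloy (MLC/jaw material).  Non-monotone structure around the
# K edge (69.5 keV) is physical.
_W_MU = np.array(
    [96.91, 120.4, 65.73, 22.73, 10.67, 5.949, 3.713, 7.810, 4.438,
     1.581, 0.7844, 0.3238, 0.1925, 0.1378, 0.1093, 0.08066, 0.06618,
     0.05577, 0.05000, 0.04433, 0.04075, 0.04038, 0.04103, 0.04210, 0.04334]
)
_W_MUEN = np.array(
    [91.0, 100.0, 55.0, 18.5, 8.40, 4.50, 2.71, 3.76, 2.31,
     0.832, 0.4302, 0.1838, 0.1080, 0.07587, 0.05879, 0.04200, 0.03385,
     0.02905, 0.02684, 0.02545, 0.02618, 0.02768, 0.02937, 0.03095, 0.03238]
)

# Soft-tissue-like organs: water shape scaled so muen/rho(6 MeV) = 0.0179.
_TISSUE_MUEN = _WATER_MUEN * (0.0179 / 0.01806)
_TISSUE_MU = _WATER_MU * 0.992
# Thyroid: muen/rho(6 MeV) pinned to 0.0194 (iodine content raises the
# high-energy absorption relative to generic soft tissue).
_THYROID_MUEN = _WATER_MUEN * (0.0194 / 0.01806)
_THYROID_MU = _WATER_MU * 1.05


def _as_table(energies: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.column_stack([energies, values]).astype(float)


@dataclass(frozen=True)
class Material:
    """A named bulk material with photon coefficient tables.

    ``mu_table`` and ``muen_table`` are (N, 2) arrays of
    (energy MeV, coefficient cm^2/g) rows with strictly increasing
    energies covering at least [0.01, 7.0] MeV.
    """

    name: str
    density: float  # g/cm^3
    z_over_a: float  # mean Z/A
    mu_table: np.ndarray = field(repr=False)
    muen_table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for label, tab in (("mu", self.mu_table), ("muen", self.muen_table)):
            tab = np.asarray(tab, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2:
                raise ValueError(f"{self.name}: {label} table must be (N, 2)")
            e = tab[:, 0]
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"{self.name}: {label} energies must be strictly increasing")
            if e[0] > 0.01 or e[-1] < 7.0:
                raise ValueError(f"{self.name}: {label} table must cover [0.01, 7.0] MeV")
            if not np.all(tab[:, 1] > 0):
                raise ValueError(f"{self.name}: {label} coefficients must be positive")
        if self.density < 0:
            raise ValueError(f"{self.name}: density must be non-negative")
        # When the two tables share a grid, energy absorption can never
        # exceed total attenuation.
        mu, muen = np.asarray(self.mu_table), np.asarray(self.muen_table)
        if mu.shape == muen.shape and np.allclose(mu[:, 0], muen[:, 0]):
            if np.any(muen[:, 1] > mu[:, 1] * (1 + 1e-12)):
                raise ValueError(f"{self.name}: muen/rho exceeds mu/rho")

    def mu(self, energy):
        """Mass attenuation coefficient, cm^2/g."""
        return coefficient_at(self, energy, "mu")

    def muen(self, energy):
        """Mass energy-absorption coefficient, cm^2/g."""
        return coefficient_at(self, energy, "muen")


def coefficient_at(material: Material, energy, which: str = "mu"):
    """Interpolate a photon coefficient at ``energy`` (MeV), log-log.

    ``which`` selects the table: ``"mu"`` (mass attenuation) or
    ``"muen"`` (mass energy absorption).  Energies outside the
    tabulated range raise :class:`EnergyOutOfRangeError`; the tables
    are never extrapolated.
    """
    if which == "mu":
        tab = np.asarray(material.mu_table, dtype=float)
    elif which == "muen":
        tab = np.asarray(material.muen_table, dtype=float)
    else:
        raise ValueError(f"unknown coefficient kind {which!r}")
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if np.any(e < tab[0, 0]) or np.any(e > tab[-1, 0]):
        raise EnergyOutOfRangeError(
            f"{material.name}: energy outside tabulated range "
            f"[{tab[0, 0]}, {tab[-1, 0]}] MeV"
        )
    out = np.exp(np.interp(np.log(e), np.log(tab[:, 0]), np.log(tab[:, 1])))
    return float(out[0]) if scalar else out


def _make(name, density, z_over_a, mu, muen) -> Material:
    return Material(name, density, z_over_a, _as_table(_E_GRID, mu), _as_table(_E_GRID, muen))


MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        _make("air", 1.2048e-3, 0.49919, _AIR_MU, _AIR_MUEN),
        _make("water", 0.998, 0.55509, _WATER_MU, _WATER_MUEN),
        _make("soft_tissue", 1.06, 0.55000, _TISSUE_MU, _TISSUE_MUEN),
        _make("brain", 1.04, 0.55400, _TISSUE_MU, _TISSUE_MUEN),
        _make("bone", 1.85, 0.51478, _BONE_MU, _BONE_MUEN),
        _make("lung", 0.26, 0.55000, _TISSUE_MU, _TISSUE_MUEN),
        _make("thyroid", 1.05, 0.55000, _THYROID_MU, _THYROID_MUEN),
        _make("tungsten_alloy", 17.0, 0.40250, _W_MU, _W_MUEN),
        # True vacuum for transport edge cases: zero density, so zero
        # linear attenuation regardless of the (water) table shape.
        _make("vacuum", 0.0, 0.55509, _WATER_MU, _WATER_MUEN),
    ]
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; packaged materials: {sorted(MATERIALS)}"
        ) from None
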