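"""Materials and photon interaction coefficients.

A :class:`Material` is a named elemental mixture with a bulk density.  Photon
interaction coefficients (photoelectric, incoherent/Compton, and mass
energy-absorption) are obtained from embedded per-element tables on an
energy grid spanning 0.01-0.8 MeV, combined with the standard mixture rule

    (mu/rho)_mix = sum_i w_i (mu/rho)_i

and interpolated log-log between grid energies.  Coherent (Rayleigh)
scattering is omitted throughout; at the 0.662 MeV source energy of the
Cs-137 decay chain its effect on air kerma is small.

The default material library (air, soil, brick, wood, mineral-wool
insulation, glass, concrete, asphalt, water) uses representative Northern
European building compositions; the asphalt mixture is the 15-element
street composition used in the neighbourhood scenario.  All compositions
and densities are overridable through the scenario configuration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "CompositionError",
    "EnergyRangeError",
    "CoefficientTable",
    "Material",
    "build_material",
    "linear_attenuation",
    "energy_absorption",
    "material_library",
    "SOURCE_ENERGY_MEV",
]

SOURCE_ENERGY_MEV = 0.662  # Ba-137m line following Cs-137 beta decay

_COMPOSITION_TOL = 1e-3


class CompositionError(ValueError):
    """Raised when elemental mass fractions do not form a valid mixture."""


class EnergyRangeError(ValueError):
    """Raised when an energy lies outside the embedded coefficient grid."""


def _load_element_table() -> dict[str, dict[str, np.ndarray]]:
    ref = resources.files("suburbdose.data") / "element_coefficients.csv"
    table: dict[str, dict[str, list[float]]] = {}
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            rec = table.setdefault(
                row["element"],
                {"energy": [], "photoelectric": [], "incoherent": [], "mu_en": []},
            )
            rec["energy"].append(float(row["energy_mev"]))
            rec["photoelectric"].append(float(row["photoelectric"]))
            rec["incoherent"].append(float(row["incoherent"]))
            rec["mu_en"].append(float(row["mu_en"]))
    return {
        sym: {k: np.asarray(v) for k, v in rec.items()} for sym, rec in table.items()
    }


_ELEMENT_TABLE = _load_element_table()


@dataclass(frozen=True)
class CoefficientTable:
    """Per-material coefficients on the embedded energy grid, cm^2/g.

    ``total`` is photoelectric + incoherent (coherent scattering omitted);
    evaluation between grid points is log-log linear.
    """

    energy: np.ndarray
    photoelectric: np.ndarray
    incoherent: np.ndarray
    mu_en: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.incoherent

    def _interp(self, column: np.ndarray, energy_mev) -> np.ndarray | float:
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < self.energy[0]) or np.any(e > self.energy[-1]):
            raise EnergyRangeError(
                f"energy {energy_mev} MeV outside table range "
                f"[{self.energy[0]}, {self.energy[-1]}]"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy), np.log(column))
        )
        return float(out) if np.isscalar(energy_mev) else out

    def mass_attenuation(self, energy_mev) -> np.ndarray | float:
        return self._interp(self.total, energy_mev)

    def mass_energy_absorption(self, energy_mev) -> np.ndarray | float:
        return self._interp(self.mu_en, energy_mev)

    def photoelectric_fraction(self, energy_mev) -> np.ndarray | float:
        tau = self._interp(self.photoelectric, energy_mev)
        return tau / self._interp(self.total, energy_mev)


def _validate_composition(composition: Mapping[str, float]) -> dict[str, float]:
    if not composition:
        raise CompositionError("empty composition")
    for sym, w in composition.items():
        if sym not in _ELEMENT_TABLE:
            raise CompositionError(f"element {sym!r} not in embedded tables")
        if not 0.0 <= w <= 1.0:
            raise CompositionError(f"mass fraction for {sym} is {w}, outside [0, 1]")
    total = sum(composition.values())
    if abs(total - 1.0) > _COMPOSITION_TOL:
        raise CompositionError(
            f"mass fractions sum to {total:.6f}, outside 1 +/- {_COMPOSITION_TOL}"
        )
    return dict(composition)


@dataclass(frozen=True)
class Material:
    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(repr=False)
    table: CoefficientTable = field(repr=False, compare=False)

    def linear_attenuation(self, energy_mev) -> np.ndarray | float:
        """mu in 1/cm: density-weighted mixture attenuation."""
        return self.density * self.table.mass_attenuation(energy_mev)

    def mean_free_path(self, energy_mev) -> float:
        return 1.0 / float(self.linear_attenuation(energy_mev))


def build_material(
    name: str, composition: Mapping[str, float], density: float
) -> Material:
    """Create a material from elemental mass fractions and density (g/cm^3)."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    comp = _validate_composition(composition)
    # renormalise the (already validated) fractions so mixtures like the
    # 15-element asphalt, whose printed fractions sum to 0.9999, are exact
    norm = sum(comp.values())
    grid = next(iter(_ELEMENT_TABLE.values()))["energy"]
    photo = np.zeros_like(grid)
    incoh = np.zeros_like(grid)
    muen = np.zeros_like(grid)
    for sym, w in comp.items():
        rec = _ELEMENT_TABLE[sym]
        photo += w / norm * rec["photoelectric"]
        incoh += w / norm * rec["incoherent"]
        muen += w / norm * rec["mu_en"]
    table = CoefficientTable(grid.copy(), photo, incoh, muen)
    return Material(name=name, density=density, composition=comp, table=table)


def linear_attenuation(material: Material, energy_mev) -> np.ndarray | float:
    """Linear attenuation coefficient mu, 1/cm."""
    return material.linear_attenuation(energy_mev)


def energy_absorption(material: Material, energy_mev) -> np.ndarray | float:
    """Mass energy-absorption coefficient mu_en/rho, cm^2/g."""
    return material.table.mass_energy_absorption(energy_mev)


# --- default library ------------------------------------------------------

ASPHALT_COMPOSITION = {
    "H": 0.1340, "C": 0.1101, "N": 0.0005, "O": 0.4982, "Na": 0.0088,
    "Mg": 0.0155, "Al": 0.0328, "Si": 0.1431, "S": 0.0015, "K": 0.0076,
    "Ca": 0.0366, "Ti": 0.0012, "Mn": 0.0001, "Fe": 0.0098, "Pb": 0.0001,
}

_DEFAULT_LIBRARY: dict[str, tuple[float, dict[str, float]]] = {
    "air": (1.205e-3, {"N": 0.7552, "O": 0.2318, "Ar": 0.0129, "C": 0.0001}),
    "water": (1.0, {"H": 0.1119, "O": 0.8881}),
    "soil": (1.6, {"O": 0.49, "Si": 0.33, "Al": 0.07, "Fe": 0.05,
                   "Ca": 0.03, "K": 0.02, "Mg": 0.01}),
    "brick": (1.8, {"O": 0.50, "Si": 0.29, "Al": 0.10, "Fe": 0.05,
                    "Ca": 0.04, "K": 0.02}),
    "wood": (0.5, {"C": 0.50, "O": 0.43, "H": 0.06, "N": 0.01}),
    "insulation": (0.1, {"O": 0.47, "Si": 0.25, "Ca": 0.10, "Al": 0.08,
                         "Mg": 0.05, "Fe": 0.03, "Na": 0.02}),
    "glass": (2.5, {"O": 0.46, "Si": 0.336, "Na": 0.10, "Ca": 0.08,
                    "Al": 0.01, "Mg": 0.014}),
    "concrete": (2.3, {"H": 0.01, "C": 0.001, "O": 0.529, "Na": 0.016,
                       "Mg": 0.002, "Al": 0.034, "Si": 0.337, "K": 0.013,
                       "Ca": 0.044, "Fe": 0.014}),
    "asphalt": (2.5784, ASPHALT_COMPOSITION),
}


def material_library(
    overrides: Mapping[str, tuple[float, Mapping[str, float]]] | None = None,
) -> dict[str, Material]:
    """Build the default material library, optionally overriding entries.

    ``overrides`` maps material name to (density, composition).
    """
    lib = {}
    merged = dict(_DEFAULT_LIBRARY)
    if overrides:
        merged.update({k: (d, dict(c)) for k, (d, c) in overrides.items()})
    for name, (density, comp) in merged.items():
        lib[name] = build_material(name, comp, density)
    return lib
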