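"""Nernst equilibrium potentials and perturbation-energy relations.

Cells spend energy to hold large transmembrane ion gradients (K+ ~150 mM
inside vs ~4 mM outside, etc.).  The equilibrium (Nernst) potential of an
ion balances its diffusive force:

    E = (R·T)/(z·F) · ln(c_out / c_in)

A change in the extracellular concentration changes the energy needed to
maintain the gradient by ΔE = (RT/zF)·ln(c_ex2/c_ex1); this potential
change is what the reservoir's perturbation amplitude δq emulates.  For
the potassium-driven immune workflow the encoding is simply
δq = [K+]in − [K+]ex (optionally rescaled into simulation units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

R_GAS = 8.314          # J/(mol K)
FARADAY = 96485.0      # C/mol
T_21C = 294.15         # K
T_37C = 310.15         # K
K_IN_DEFAULT = 150.0   # mM, typical intracellular potassium


class DomainError(ValueError):
    """Concentration outside the Nernst equation's domain."""


@dataclass(frozen=True)
class IonSpecies:
    """One ion row: signed valence and intra/extracellular concentrations (mM)."""

    name: str
    z: int
    c_in: float
    c_out: float

    def __post_init__(self):
        if self.z == 0:
            raise DomainError(f"{self.name}: valence must be nonzero")


@dataclass(frozen=True)
class FilamentSpec:
    """Effective ohmic filament bundle: conductivity (S/m), cross-section
    (m^2) and length (m)."""

    sigma: float
    area: float
    length: float

    def __post_init__(self):
        if min(self.sigma, self.area, self.length) <= 0:
            raise DomainError("filament sigma, area and length must be positive")


def load_ion_table() -> pd.DataFrame:
    """The packaged table of typical cellular ion concentrations."""
    with resources.files("cellreservoir.data").joinpath("ion_table.csv").open() as fh:
        return pd.read_csv(fh)


def ion_species() -> list[IonSpecies]:
    df = load_ion_table()
    return [
        IonSpecies(r.ion, int(r.z), float(r.c_in_mM), float(r.c_out_mM))
        for r in df.itertuples()
    ]


def nernst_potential(ion: IonSpecies, T: float = T_37C) -> float:
    """Equilibrium potential in volts: E = (RT/zF) ln(c_out/c_in)."""
    if ion.c_in <= 0 or ion.c_out <= 0:
        raise DomainError(
            f"{ion.name}: Nernst potential undefined for non-positive concentration"
        )
    return R_GAS * T / (ion.z * FARADAY) * math.log(ion.c_out / ion.c_in)


def nernst_table(temperatures: tuple[float, ...] = (T_21C, T_37C)) -> pd.DataFrame:
    """Equilibrium potentials (mV) for every packaged ion at each temperature.

    Ions with a zero concentration (organic anions trapped inside the
    cell) get NaN, mirroring the dash in the reference table.
    """
    rows = []
    for ion in ion_species():
        row = {"ion": ion.name, "z": ion.z, "c_in_mM": ion.c_in, "c_out_mM": ion.c_out}
        for T in temperatures:
            key = f"E_mV_at_{T - 273.15:.0f}C"
            try:
                row[key] = nernst_potential(ion, T) * 1e3
            except DomainError:
                row[key] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def delta_energy(c_ex1: float, c_ex2: float, z: int = 1, T: float = T_37C) -> float:
    """Equilibrium-potential change (volts) when the extracellular
    concentration moves from c_ex1 to c_ex2: ΔE = (RT/zF) ln(c_ex2/c_ex1).

    Antisymmetric in the two concentrations (the relation holds in the
    reverse case with opposite sign) and additive along chains.
    """
    if c_ex1 <= 0 or c_ex2 <= 0:
        raise DomainError("concentrations must be positive")
    if z == 0:
        raise DomainError("valence must be nonzero")
    return R_GAS * T / (z * FARADAY) * math.log(c_ex2 / c_ex1)


def perturbation_from_K(k_in: float = K_IN_DEFAULT, k_ex: float = 0.0) -> float:
    """Charge-amplitude encoding of a potassium perturbation: [K+]in − [K+]ex.

    Unitless; a configuration multiplier (default 1/k_in so the maximal
    perturbation maps to unit charge) rescales it before driving sources.
    """
    return k_in - k_ex


def filament_conductance(spec: FilamentSpec) -> float:
    """Bundle conductance in siemens: G = σ·A/l.

    For a 10 μm bundle of 1 μm^2 cross-section and conductivities of
    0.1–100 S/m this spans 1e-8 to 1e-5 S.
    """
    return spec.sigma * spec.area / spec.length


def k_sequence_to_charges(
    k_ex_values: np.ndarray, k_in: float = K_IN_DEFAULT, scale: float | None = None
) -> np.ndarray:
    """Map an ascending [K+]ex sweep to source-charge amplitudes."""
    k_ex_values = np.asarray(k_ex_values, dtype=float)
    if scale is None:
        scale = 1.0 / k_in
    return scale * (k_in - k_ex_values)
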