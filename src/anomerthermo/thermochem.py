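"""Rigid-rotor/harmonic-oscillator (RRHO) ideal-gas thermochemistry.

Given a geometry and its real harmonic frequencies, computes the zero-point
vibrational energy, thermal enthalpy, entropy components and the standard
Gibbs energy G° = H − T·S. Translation uses the Sackur–Tetrode equation,
rotation the classical rigid rotor (symmetry number 1 by default — the
species studied here are asymmetric), vibration the quantum harmonic
oscillator. No frequency scaling factor is applied. The standard state is
the 1 atm ideal gas for both the "vacuum" and "aqueous" phase tags; no
solution standard-state correction is applied.

Units: energies in kcal/mol, entropies in cal/(mol·K), frequencies in cm⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem_core import Geometry
from .constants import (
    AMU_TO_KG,
    ATM_TO_PA,
    AVOGADRO,
    BOLTZMANN_J_K,
    CAL_TO_J,
    HC_J_CM,
    KB_KCAL_PER_MOL_K,
    PLANCK_J_S,
    thermal_energy_kT,
)
from .errors import NotAMinimumError

__all__ = ["ThermoConditions", "ThermoBreakdown", "zpe", "rrho_thermo", "thermal_energy_kT"]

#: gas constant in cal/(mol·K)
R_CAL = BOLTZMANN_J_K * AVOGADRO / CAL_TO_J
#: gas constant in kcal/(mol·K)
R_KCAL = R_CAL / 1000.0

_LINEAR_MOMENT_TOL = 1e-8  # amu·Å², below this a principal moment counts as zero


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature (K) and pressure (atm); defaults are STP-like 298.15 K, 1 atm."""

    temperature: float = 298.15
    pressure_atm: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.pressure_atm <= 0:
            raise ValueError("pressure must be positive")


@dataclass(frozen=True)
class ThermoBreakdown:
    """RRHO thermochemistry summary for one structure.

    ``gibbs`` satisfies G° = H − T·S (with S converted from cal to kcal)
    to numerical identity. ``enthalpy`` includes the electronic energy,
    ZPE, thermal corrections and the pV (=RT) term.
    """

    zpe: float  # kcal/mol
    thermal_enthalpy_correction: float  # H − E_elec − ZPE, kcal/mol
    entropy_translational: float  # cal/(mol·K)
    entropy_rotational: float
    entropy_vibrational: float
    enthalpy: float  # kcal/mol
    entropy: float  # cal/(mol·K)
    gibbs: float  # kcal/mol
    electronic_energy: float  # kcal/mol
    conditions: ThermoConditions

    @property
    def e_plus_zpe(self) -> float:
        return self.electronic_energy + self.zpe


def zpe(frequencies) -> float:
    """Zero-point vibrational energy ½·Σ h·c·ν̃ᵢ in kcal/mol.

    All frequencies must be real and positive; imaginary modes must be
    rejected upstream. An empty list gives 0 (e.g. a single atom).
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return 0.0
    if np.any(freqs <= 0):
        raise NotAMinimumError(
            "non-positive frequency encountered; structure is not a vetted minimum"
        )
    joule_per_molecule = 0.5 * HC_J_CM * float(np.sum(freqs))
    return joule_per_molecule * AVOGADRO / (CAL_TO_J * 1000.0)


def _principal_moments(geom: Geometry) -> np.ndarray:
    """Principal moments of inertia in amu·Å², ascending."""
    m = geom.masses()
    com = (m[:, None] * geom.coords).sum(axis=0) / m.sum()
    r = geom.coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    Ixx = np.sum(m * (y**2 + z**2))
    Iyy = np.sum(m * (x**2 + z**2))
    Izz = np.sum(m * (x**2 + y**2))
    Ixy = -np.sum(m * x * y)
    Ixz = -np.sum(m * x * z)
    Iyz = -np.sum(m * y * z)
    tensor = np.array([[Ixx, Ixy, Ixz], [Ixy, Iyy, Iyz], [Ixz, Iyz, Izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def n_rigid_modes(geom: Geometry) -> int:
    """Number of zero-frequency rigid modes: 3 (atom), 5 (linear), 6 (nonlinear)."""
    if geom.n_atoms == 1:
        return 3
    moments = _principal_moments(geom)
    return 5 if moments[0] < _LINEAR_MOMENT_TOL * max(moments[-1], 1.0) else 6


def _translational(mass_amu: float, cond: ThermoConditions) -> tuple[float, float]:
    """(S_trans in cal/mol·K, H_trans in kcal/mol) by Sackur–Tetrode / ideal gas."""
    T = cond.temperature
    m_kg = mass_amu * AMU_TO_KG
    p_pa = cond.pressure_atm * ATM_TO_PA
    q_trans = (2.0 * math.pi * m_kg * BOLTZMANN_J_K * T / PLANCK_J_S**2) ** 1.5 * (
        BOLTZMANN_J_K * T / p_pa
    )
    s = R_CAL * (math.log(q_trans) + 2.5)
    h = 2.5 * R_KCAL * T  # 3/2 RT kinetic + RT pV term
    return s, h


def _rotational(geom: Geometry, cond: ThermoConditions, symmetry_number: int) -> tuple[float, float]:
    """(S_rot in cal/mol·K, U_rot in kcal/mol) for the classical rigid rotor."""
    if geom.n_atoms == 1:
        return 0.0, 0.0
    T = cond.temperature
    moments = _principal_moments(geom) * AMU_TO_KG * 1e-20  # kg·m²
    if moments[0] < _LINEAR_MOMENT_TOL * max(moments[-1], 1e-30):
        # linear top
        I = moments[-1]
        q_rot = 8.0 * math.pi**2 * I * BOLTZMANN_J_K * T / (symmetry_number * PLANCK_J_S**2)
        return R_CAL * (math.log(q_rot) + 1.0), R_KCAL * T
    pref = 8.0 * math.pi**2 * BOLTZMANN_J_K * T / PLANCK_J_S**2
    q_rot = (math.sqrt(math.pi) / symmetry_number) * pref**1.5 * math.sqrt(
        float(np.prod(moments))
    )
    return R_CAL * (math.log(q_rot) + 1.5), 1.5 * R_KCAL * T


def _vibrational(freqs: np.ndarray, T: float) -> tuple[float, float]:
    """(S_vib in cal/mol·K, U_vib_thermal in kcal/mol) — thermal part, ZPE excluded."""
    if freqs.size == 0:
        return 0.0, 0.0
    theta = HC_J_CM * freqs / BOLTZMANN_J_K  # vibrational temperatures, K
    x = theta / T
    expm = np.expm1(x)
    s = R_CAL * float(np.sum(x / expm - np.log1p(-np.exp(-x))))
    u = R_KCAL * T * float(np.sum(x / expm))
    return s, u


def vibrational_heat_capacity(frequencies, temperature: float) -> float:
    """Harmonic-oscillator Cv in cal/(mol·K); per mode it approaches R at high T."""
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return 0.0
    x = HC_J_CM * freqs / (BOLTZMANN_J_K * temperature)
    return R_CAL * float(np.sum(x**2 * np.exp(x) / np.expm1(x) ** 2))


def rrho_thermo(
    geom: Geometry,
    frequencies,
    conditions: ThermoConditions = ThermoConditions(),
    electronic_energy: float = 0.0,
    symmetry_number: int = 1,
) -> ThermoBreakdown:
    """Full RRHO breakdown for a vetted minimum.

    *frequencies* are the real harmonic wavenumbers in cm⁻¹ (rigid modes
    already removed). A single atom must come with an empty frequency list.
    """
    if geom.n_atoms == 0:
        raise ValueError("empty geometry")
    freqs = np.asarray(list(frequencies), dtype=float)
    if geom.n_atoms == 1 and freqs.size > 0:
        raise ValueError("a single atom cannot carry vibrational frequencies")
    expected = 3 * geom.n_atoms - n_rigid_modes(geom)
    if freqs.size > expected:
        raise ValueError(
            f"{freqs.size} frequencies for {geom.n_atoms} atoms (at most {expected} internal modes)"
        )
    zpe_val = zpe(freqs) if freqs.size else 0.0

    T = conditions.temperature
    s_trans, h_trans = _translational(float(geom.masses().sum()), conditions)
    s_rot, u_rot = _rotational(geom, conditions, symmetry_number)
    s_vib, u_vib = _vibrational(freqs, T)

    thermal_corr = h_trans + u_rot + u_vib  # pV term folded into h_trans
    enthalpy = electronic_energy + zpe_val + thermal_corr
    entropy = s_trans + s_rot + s_vib
    gibbs = enthalpy - T * entropy / 1000.0
    return ThermoBreakdown(
        zpe=zpe_val,
        thermal_enthalpy_correction=thermal_corr,
        entropy_translational=s_trans,
        entropy_rotational=s_rot,
        entropy_vibrational=s_vib,
        enthalpy=enthalpy,
        entropy=entropy,
        gibbs=gibbs,
        electronic_energy=electronic_energy,
        conditions=conditions,
    )
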