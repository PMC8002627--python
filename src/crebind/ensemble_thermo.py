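"""RRHO thermochemistry and Boltzmann ensemble thermodynamics.

Per-structure Gibbs energies are built as G = E_total + g_rrho + g_solv,
where g_rrho is the ideal-gas rigid-rotor harmonic-oscillator correction
(Sackur-Tetrode translation, classical rigid rotor, quantum harmonic
vibrations).  Ensemble quantities follow from Boltzmann weighting:

    p_i  = exp(-(G_i - G_min)/RT) / sum_j exp(-(G_j - G_min)/RT)
    <G>  = sum_i p_i G_i
    F    = -RT ln sum_i exp(-G_i/RT)
    S_CR = -R sum_i p_i ln p_i          (natural logarithm)
    G_CR = -T S_CR

so that F = <G> - T S_CR holds identically: the conformational-rotational
entropy S_CR is exactly the gap between the population-averaged energy and
the partition-sum free energy of the discrete ensemble.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import (
    AMU_KG,
    AVOGADRO,
    BOLTZMANN,
    CM1_TO_KCAL,
    DEFAULT_TEMPERATURE,
    PLANCK,
    R_KCAL,
    SPEED_OF_LIGHT,
    STANDARD_PRESSURE,
    rt,
)
from .ensemble_io import Structure
from .structural_metrics import RotationalConstants

__all__ = [
    "ThermoResult",
    "BoltzmannSummary",
    "rrho_thermo",
    "gibbs_energy",
    "boltzmann_weights",
    "ensemble_summary",
]

logger = logging.getLogger(__name__)

_J_PER_MOL_TO_KCAL = 1.0 / 4184.0


@dataclass(frozen=True)
class ThermoResult:
    """RRHO correction terms for one structure (kcal/mol, kcal/(mol K))."""

    zpe: float
    h_corr: float
    s_trans: float
    s_rot: float
    s_vib: float
    g_rrho: float
    temperature: float

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib


@dataclass(frozen=True)
class BoltzmannSummary:
    """Boltzmann statistics of one ensemble at temperature T.

    ``f_ens`` is the partition-sum ensemble free energy, ``g_avg`` the
    population-weighted average, ``s_cr`` the conformational-rotational
    entropy and ``g_cr = -T s_cr`` its free-energy contribution.
    """

    weights: np.ndarray
    g_avg: float
    f_ens: float
    s_cr: float
    g_cr: float
    temperature: float

    @property
    def n(self) -> int:
        return len(self.weights)


def rrho_thermo(
    frequencies_cm1,
    masses_amu,
    rot_constants: RotationalConstants | None,
    T: float = DEFAULT_TEMPERATURE,
    symmetry_number: int = 1,
    pressure: float = STANDARD_PRESSURE,
    frequency_scale: float = 1.0,
) -> ThermoResult:
    """Ideal-gas RRHO thermochemistry.

    Parameters
    ----------
    frequencies_cm1
        Harmonic frequencies in cm^-1; must all be non-negative (imaginary
        modes must be dealt with upstream).  An empty list denotes an atom.
    masses_amu
        Atomic masses; only the total mass enters (translation).
    rot_constants
        Principal rotational constants, or ``None`` for a single atom.
    symmetry_number
        Rotational symmetry number (default 1: ensembles of distinct
        rotamer images are counted explicitly, not through sigma).
    frequency_scale
        Multiplicative scaling of all frequencies (default 1.0).

    Returns the zero-point energy, thermal enthalpy correction (including
    the pV = RT term), the three entropy components and the combined Gibbs
    correction g_rrho = zpe + h_corr - T (s_trans + s_rot + s_vib).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    freqs = np.asarray(frequencies_cm1, dtype=float) * frequency_scale
    bad = np.where(freqs < 0)[0]
    if bad.size:
        raise ValueError(f"negative (imaginary) frequencies at mode indices {bad.tolist()}")

    masses = np.atleast_1d(np.asarray(masses_amu, dtype=float))
    total_mass_kg = masses.sum() * AMU_KG
    kT = BOLTZMANN * T

    # translation: Sackur-Tetrode
    lam = PLANCK / math.sqrt(2.0 * math.pi * total_mass_kg * kT)  # thermal wavelength
    q_trans = (kT / pressure) / lam**3
    s_trans = AVOGADRO * BOLTZMANN * (math.log(q_trans) + 2.5) * _J_PER_MOL_TO_KCAL
    h_trans = 2.5 * R_KCAL * T  # 3/2 RT kinetic + RT pV term

    # rotation: classical rigid rotor
    if rot_constants is None:
        s_rot = 0.0
        h_rot = 0.0
    else:
        consts_mhz = rot_constants.finite()
        theta = PLANCK * consts_mhz * 1e6 / BOLTZMANN  # rotational temperatures, K
        if rot_constants.linear:
            q_rot = T / (theta[0] * symmetry_number)
            s_rot = R_KCAL * (math.log(q_rot) + 1.0)
            h_rot = R_KCAL * T
        else:
            q_rot = (math.sqrt(math.pi) / symmetry_number) * math.sqrt(
                T**3 / float(np.prod(theta))
            )
            s_rot = R_KCAL * (math.log(q_rot) + 1.5)
            h_rot = 1.5 * R_KCAL * T

    # vibration: quantum harmonic oscillators
    zpe = 0.5 * float(freqs.sum()) * CM1_TO_KCAL
    if freqs.size:
        pos = freqs[freqs > 0]
        x = PLANCK * pos * 100.0 * SPEED_OF_LIGHT / kT  # h nu / kT
        with np.errstate(over="ignore"):  # x/expm1(x) -> 0 for large x
            s_vib = R_KCAL * float(np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))
            h_vib = R_KCAL * T * float(np.sum(x / np.expm1(x)))
    else:
        s_vib = 0.0
        h_vib = 0.0

    h_corr = h_trans + h_rot + h_vib
    g = zpe + h_corr - T * (s_trans + s_rot + s_vib)
    return ThermoResult(zpe, h_corr, s_trans, s_rot, s_vib, g, T)


def gibbs_energy(
    structure: Structure,
    thermo: ThermoResult | None = None,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Per-structure Gibbs energy G = E_total + g_rrho + g_solv (kcal/mol).

    The RRHO term is taken from ``thermo`` if given, else from the
    structure's stored ``g_rrho``; if neither exists the electronic energy
    plus solvation is returned with a warning.  A missing solvation term
    contributes zero.
    """
    g = structure.energy_total
    if thermo is not None:
        if abs(thermo.temperature - T) > 1e-9:
            raise ValueError("thermo result computed at a different temperature")
        g += thermo.g_rrho
    elif structure.g_rrho is not None:
        g += structure.g_rrho
    else:
        logger.warning(
            "no RRHO correction for structure %r: using E + g_solv", structure.tag
        )
    if structure.g_solv is not None:
        g += structure.g_solv
    return g


def boltzmann_weights(G_list, T: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Normalized Boltzmann populations of free energies (kcal/mol) at T.

    Shift-invariant: computed from G_i - G_min.
    """
    G = np.asarray(G_list, dtype=float)
    if G.size == 0:
        raise ValueError("empty free-energy list")
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = -(G - G.min()) / rt(T)
    w = np.exp(x)
    return w / w.sum()


def ensemble_summary(G_list, T: float = DEFAULT_TEMPERATURE) -> BoltzmannSummary:
    """Full Boltzmann summary of an ensemble of free energies."""
    G = np.asarray(G_list, dtype=float)
    p = boltzmann_weights(G, T)
    g_avg = float(np.dot(p, G))
    f_ens = float(-rt(T) * logsumexp(-G / rt(T)))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    s_cr = float(-R_KCAL * plogp.sum())
    return BoltzmannSummary(
        weights=p, g_avg=g_avg, f_ens=f_ens, s_cr=s_cr, g_cr=-T * s_cr, temperature=T
    )
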