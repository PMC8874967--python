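"""Binding thermodynamics: K <-> dG conversions, cooperativity,
statistical factors, degeneracy corrections and van't Hoff analysis.

Conventions: energies kcal/mol, temperatures K, binding constants
dimensionless on the 1 M standard-concentration scale so that
``dG = -RT ln K`` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import R_KCAL

__all__ = [
    "CooperativityResult",
    "VantHoffFit",
    "delta_g_from_k",
    "k_from_delta_g",
    "cooperativity_rho",
    "statistical_factor",
    "degeneracy_correction",
    "vant_hoff_fit",
    "entropy_decomposition",
]


@dataclass(frozen=True)
class CooperativityResult:
    """Cumulative constants and the stepwise cooperativity parameter.

    ``rho = 4 beta2 / beta1^2`` with ``beta1 = K1``, ``beta2 = K1 K2``;
    ``rho < 1`` flags negative cooperativity between the two sites,
    ``rho = 1`` is purely statistical binding (K1 = 4 K2).
    """

    beta1: float
    beta2: float
    rho: float

    @property
    def negative_cooperativity(self) -> bool:
        return self.rho < 1.0


@dataclass(frozen=True)
class VantHoffFit:
    """Result of a linear van't Hoff fit of ln K against 1/T."""

    dh: float          # kcal/mol, from -slope * R
    dh_stderr: float   # kcal/mol, from the slope standard error
    slope: float       # d lnK / d(1/T), K
    intercept: float   # lnK at 1/T -> 0
    r_squared: float


def delta_g_from_k(k: float, temperature_K: float) -> float:
    """Standard binding free energy dG = -RT ln K (kcal/mol)."""
    if k <= 0:
        raise ValueError("binding constant must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return -R_KCAL * temperature_K * math.log(k)


def k_from_delta_g(dg: float, temperature_K: float) -> float:
    """Inverse of :func:`delta_g_from_k`: K = exp(-dG / RT)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-dg / (R_KCAL * temperature_K))


def cooperativity_rho(k1: float, k2: float) -> CooperativityResult:
    """Stepwise cooperativity parameter for a two-site receptor.

    ``rho = 4 beta2 / beta1^2 = 4 K2 / K1``.  A receptor with two
    identical non-interacting sites has K1 = 4 K2 (the second ion has
    half the vacancies to enter and twice the ways to leave), so
    ``rho = 1`` there and ``rho < 1`` means the first bound ion
    disfavours the second.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("binding constants must be positive")
    beta1 = k1
    beta2 = k1 * k2
    return CooperativityResult(beta1=beta1, beta2=beta2, rho=4.0 * beta2 / beta1**2)


def statistical_factor(temperature_K: float) -> float:
    """Purely combinatorial contribution RT ln 4 (kcal/mol) to ddG for
    two identical sites (~0.8 kcal/mol at room temperature)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature_K * math.log(4.0)


def degeneracy_correction(
    dg_sim_1: float, dg_sim_2: float, temperature_K: float
) -> tuple[float, float]:
    """Convert site-resolved simulated binding free energies to standard
    stepwise values.

    The empty receptor offers two equivalent sites for the first ion and
    the singly occupied receptor two equivalent ways of losing one, so
    the first step gains RT ln(1/2) and the second RT ln 2; the net
    shift of ddG = dG2 - dG1 is RT ln 4, the statistical factor.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    rt = R_KCAL * temperature_K
    return dg_sim_1 + rt * math.log(0.5), dg_sim_2 + rt * math.log(2.0)


def vant_hoff_fit(
    temperatures_K: Sequence[float], ln_k: Sequence[float]
) -> VantHoffFit:
    """Binding enthalpy from the linear van't Hoff equation.

    Ordinary least squares of ln K against 1/T; the slope equals
    -dH/R, so ``dH = -slope * R`` and its standard error follows from
    the slope's standard error.
    """
    t = np.asarray(temperatures_K, dtype=float)
    y = np.asarray(ln_k, dtype=float)
    if t.size != y.size:
        raise ValueError("temperatures and ln K must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 temperatures")
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive")
    res = stats.linregress(1.0 / t, y)
    return VantHoffFit(
        dh=-res.slope * R_KCAL,
        dh_stderr=res.stderr * R_KCAL,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def entropy_decomposition(dg: float, dh: float, temperature_K: float) -> tuple[float, float]:
    """Entropic term from dG and dH: returns (TdS, -TdS) in kcal/mol.

    ``TdS = dH - dG`` so that ``dG = dH - TdS`` reconstructs exactly.
    ``temperature_K`` is carried for interface symmetry and validation
    only; the decomposition itself is temperature-free arithmetic.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    tds = dh - dg
    return tds, -tds
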