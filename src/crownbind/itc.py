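"""Isothermal titration calorimetry: forward models and fitting.

Implements the two binding models used for a ditopic receptor titrated
with a monovalent cation:

* the *sequential binding sites* model with stepwise constants ``K1``,
  ``K2`` and stepwise enthalpies ``dH1``, ``dH2`` — ``K1`` governs the
  equilibrium between the empty and singly occupied receptor, ``K2`` the
  uptake of the second ion;
* the *single set of identical sites* model with stoichiometry ``n``,
  one site constant ``K`` and one per-site enthalpy ``dH``.

Binding constants are dimensionless (normalized by the 1 M standard
concentration), so all free-ligand algebra is carried out with
concentrations expressed in mol/L.  Heats are kcal; normalized injection
heats are kcal per mole of injectant.

The perfusion-cell bookkeeping follows the MicroCal displacement
convention: injecting displaces cell liquid, and the heat evolved by an
injection includes a correction for the displaced volume.  An alternate
exponential-dilution convention is available via ``convention=``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

import lmfit

__all__ = [
    "TitrationProtocol",
    "SequentialParams",
    "IdenticalSitesParams",
    "InjectionSeries",
    "FitResult",
    "dilute_concentrations",
    "solve_free_ligand",
    "site_occupancy_fractions",
    "cumulative_heat_sequential",
    "cumulative_heat_identical",
    "simulate_injection_heats",
    "subtract_dilution",
    "average_replicates",
    "fit_model",
    "fit_replicates",
    "reduced_chi_squared",
]

DilutionConvention = Literal["displacement", "exponential"]
ModelName = Literal["sequential", "identical"]


@dataclass(frozen=True)
class TitrationProtocol:
    """Physical setup of one ITC titration.

    Parameters
    ----------
    cell_volume_mL : active cell volume V0 (mL).
    syringe_mM : titrant concentration in the syringe (mM).
    cell_mM : receptor concentration initially in the cell (mM).
    injection_volumes_uL : volume of each injection, in order (uL).
    temperature_K : experiment temperature (K).
    discard_first : exclude the first (small) injection from fitting.
    """

    cell_volume_mL: float
    syringe_mM: float
    cell_mM: float
    injection_volumes_uL: tuple[float, ...]
    temperature_K: float = 298.15
    discard_first: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes_uL", tuple(float(v) for v in self.injection_volumes_uL)
        )
        if self.cell_volume_mL <= 0:
            raise ValueError("cell volume must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if not self.syringe_mM > self.cell_mM > 0:
            raise ValueError("require syringe_mM > cell_mM > 0")
        if not self.injection_volumes_uL:
            raise ValueError("at least one injection required")
        if any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)

    def cumulative_volumes_uL(self) -> np.ndarray:
        """Cumulative injected volume through each injection (uL)."""
        return np.cumsum(self.injection_volumes_uL)


@dataclass(frozen=True)
class SequentialParams:
    """Stepwise two-site parameters: K1, K2 dimensionless (1 M scale),
    dH1, dH2 in kcal/mol."""

    k1: float
    k2: float
    dh1: float
    dh2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("binding constants must be positive")

    @property
    def beta1(self) -> float:
        return self.k1

    @property
    def beta2(self) -> float:
        return self.k1 * self.k2


@dataclass(frozen=True)
class IdenticalSitesParams:
    """Single-set-of-identical-sites parameters: real-valued
    stoichiometry ``n_sites``, site constant ``k`` (1 M scale), per-site
    enthalpy ``dh`` (kcal/mol)."""

    n_sites: float
    k: float
    dh: float

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.k <= 0:
            raise ValueError("binding constant must be positive")


@dataclass(frozen=True)
class InjectionSeries:
    """Normalized, integrated heats of one titration.

    ``heats`` are kcal per mole of injectant, one per injection;
    ``molar_ratio`` is total ligand over total receptor in the cell
    after each injection; ``errors`` (optional) are per-injection
    measurement errors on the same scale as ``heats``.
    """

    heats: np.ndarray
    molar_ratio: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))
        object.__setattr__(self, "molar_ratio", np.asarray(self.molar_ratio, dtype=float))
        if self.errors is not None:
            object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))
        if self.heats.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar_ratio must have equal length")
        if self.errors is not None:
            if self.errors.shape != self.heats.shape:
                raise ValueError("errors must match heats in length")
            if np.any(self.errors < 0):
                raise ValueError("errors must be non-negative")

    def __len__(self) -> int:
        return self.heats.size


@dataclass
class FitResult:
    """Outcome of a weighted least-squares ITC fit."""

    params: SequentialParams | IdenticalSitesParams
    stderr: dict[str, float]
    residuals: np.ndarray
    chi2_over_nu: float
    model: ModelName
    success: bool
    message: str = ""
    n_fitted: int = 0
    replicate_params: list[SequentialParams | IdenticalSitesParams] = field(
        default_factory=list
    )


# --------------------------------------------------------------------------
# concentration bookkeeping


def dilute_concentrations(
    protocol: TitrationProtocol,
    i: int,
    convention: DilutionConvention = "displacement",
) -> tuple[float, float]:
    """Receptor and ligand concentration (mM) in the cell after injection ``i``.

    ``i`` is 1-based.  Under the displacement convention, with ``v`` the
    cumulative injected volume::

        Mt = M0 (1 - v/2V0) / (1 + v/2V0)
        Lt = L_syr (v/V0) / (1 + v/2V0)

    The exponential convention uses ``Mt = M0 exp(-v/V0)`` and
    ``Lt = L_syr (1 - exp(-v/V0))``.
    """
    if not 1 <= i <= protocol.n_injections:
        raise ValueError(f"injection index {i} out of range 1..{protocol.n_injections}")
    v = float(protocol.cumulative_volumes_uL()[i - 1]) * 1e-3  # mL
    v0 = protocol.cell_volume_mL
    if v >= 2.0 * v0:
        raise ValueError("cumulative injected volume >= 2 V0: dilution model breaks down")
    if convention == "displacement":
        x = v / (2.0 * v0)
        mt = protocol.cell_mM * (1.0 - x) / (1.0 + x)
        lt = protocol.syringe_mM * (v / v0) / (1.0 + x)
    elif convention == "exponential":
        mt = protocol.cell_mM * math.exp(-v / v0)
        lt = protocol.syringe_mM * (1.0 - math.exp(-v / v0))
    else:  # pragma: no cover - guarded by typing
        raise ValueError(f"unknown dilution convention {convention!r}")
    return mt, lt


# --------------------------------------------------------------------------
# equilibrium


def _mass_balance_residual(l_free: float, lt: float, mt: float, k1: float, k2: float) -> float:
    zeta = 1.0 + k1 * l_free + k1 * k2 * l_free * l_free
    bound = mt * (k1 * l_free + 2.0 * k1 * k2 * l_free * l_free) / zeta
    return l_free + bound - lt


def solve_free_ligand(lt: float, mt: float, k1: float, k2: float) -> float:
    """Free-ligand concentration (mol/L) satisfying the two-site mass balance.

    Solves ``Lt = L + Mt (K1 L + 2 K1 K2 L^2) / (1 + K1 L + K1 K2 L^2)``
    by a safeguarded Brent bracket on [0, Lt]; the left side is strictly
    increasing in L, so the root is unique.  Inputs are mol/L with
    dimensionless constants on the 1 M scale.
    """
    if lt < 0 or mt < 0:
        raise ValueError("concentrations must be non-negative")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("binding constants must be positive")
    if lt == 0.0:
        return 0.0
    lo, hi = 0.0, lt
    f_lo = _mass_balance_residual(lo, lt, mt, k1, k2)
    f_hi = _mass_balance_residual(hi, lt, mt, k1, k2)
    if f_lo > 0 or f_hi < 0:  # cannot occur for valid inputs; guard anyway
        raise RuntimeError("free-ligand solver failed: root not bracketed by [0, Lt]")
    root = brentq(
        _mass_balance_residual, lo, hi, args=(lt, mt, k1, k2),
        xtol=1e-18 * max(lt, 1e-30), rtol=8.9e-16, maxiter=200,
    )
    return float(min(max(root, 0.0), lt))


def site_occupancy_fractions(l_free: float, k1: float, k2: float) -> tuple[float, float, float]:
    """Population fractions (F0, F1, F2) of the receptor with 0/1/2 ions
    bound at free-ligand concentration ``l_free`` (mol/L)."""
    zeta = 1.0 + k1 * l_free + k1 * k2 * l_free * l_free
    f1 = k1 * l_free / zeta
    f2 = k1 * k2 * l_free * l_free / zeta
    return 1.0 - f1 - f2, f1, f2


def cumulative_heat_sequential(
    mt: float, l_free: float, params: SequentialParams, v0_L: float
) -> float:
    """Total heat content (kcal) of the cell at equilibrium.

    ``Q = V0 Mt (F1 dH1 + F2 (dH1 + dH2))`` with the occupancy fractions
    from the stepwise partition function.  ``mt``, ``l_free`` in mol/L,
    ``v0_L`` in litres.
    """
    _, f1, f2 = site_occupancy_fractions(l_free, params.k1, params.k2)
    return v0_L * mt * (f1 * params.dh1 + f2 * (params.dh1 + params.dh2))


def cumulative_heat_identical(
    mt: float, lt: float, params: IdenticalSitesParams, v0_L: float
) -> float:
    """Total heat content (kcal) under the identical-sites model.

    Free ligand solves the closed-form quadratic
    ``K L^2 + (1 + K (n Mt - Lt)) L - Lt = 0``; the heat is
    ``Q = V0 n Mt dH K L / (1 + K L)``.
    """
    n, k, dh = params.n_sites, params.k, params.dh
    if lt == 0.0:
        return 0.0
    b = 1.0 + k * (n * mt - lt)
    l_free = (-b + math.sqrt(b * b + 4.0 * k * lt)) / (2.0 * k)
    theta = k * l_free / (1.0 + k * l_free)
    return v0_L * n * mt * dh * theta


def simulate_injection_heats(
    protocol: TitrationProtocol,
    params: SequentialParams | IdenticalSitesParams,
    model: ModelName | None = None,
    convention: DilutionConvention = "displacement",
    displacement_correction: bool = True,
) -> InjectionSeries:
    """Forward-simulate normalized injection heats for a titration.

    Per-injection heat (kcal per mole of injectant)::

        dQ_i = Q_i - Q_{i-1} + (dV_i / V0) (Q_i + Q_{i-1}) / 2

    where Q_i is the cell heat content after injection i (Q_0 = 0) and
    the second term accounts for liquid displaced out of the cell.
    """
    if model is None:
        model = "sequential" if isinstance(params, SequentialParams) else "identical"
    if model == "sequential" and not isinstance(params, SequentialParams):
        raise TypeError("sequential model requires SequentialParams")
    if model == "identical" and not isinstance(params, IdenticalSitesParams):
        raise TypeError("identical model requires IdenticalSitesParams")

    v0_L = protocol.cell_volume_mL * 1e-3
    q_prev = 0.0
    heats = np.empty(protocol.n_injections)
    ratios = np.empty(protocol.n_injections)
    for i in range(1, protocol.n_injections + 1):
        mt_mM, lt_mM = dilute_concentrations(protocol, i, convention)
        mt, lt = mt_mM * 1e-3, lt_mM * 1e-3
        if model == "sequential":
            l_free = solve_free_ligand(lt, mt, params.k1, params.k2)
            q = cumulative_heat_sequential(mt, l_free, params, v0_L)
        else:
            q = cumulative_heat_identical(mt, lt, params, v0_L)
        dv_L = protocol.injection_volumes_uL[i - 1] * 1e-6
        dq = q - q_prev
        if displacement_correction:
            dq += (dv_L / v0_L) * (q + q_prev) / 2.0
        moles_injected = dv_L * protocol.syringe_mM * 1e-3
        heats[i - 1] = dq / moles_injected
        ratios[i - 1] = lt_mM / mt_mM
        q_prev = q
    return InjectionSeries(heats=heats, molar_ratio=ratios)


# --------------------------------------------------------------------------
# series arithmetic


def subtract_dilution(series: InjectionSeries, dilution: InjectionSeries) -> InjectionSeries:
    """Subtract blank (no-receptor) heats of dilution, element-wise.

    Errors, when present on both series, combine in quadrature.
    """
    if len(series) != len(dilution):
        raise ValueError("series and dilution must have equal injection counts")
    errors = None
    if series.errors is not None and dilution.errors is not None:
        errors = np.hypot(series.errors, dilution.errors)
    elif series.errors is not None:
        errors = series.errors.copy()
    elif dilution.errors is not None:
        errors = dilution.errors.copy()
    return InjectionSeries(
        heats=series.heats - dilution.heats,
        molar_ratio=series.molar_ratio.copy(),
        errors=errors,
    )


def average_replicates(replicates: Sequence[InjectionSeries]) -> InjectionSeries:
    """Per-injection mean and sample standard deviation across replicates.

    The SDs become the measurement errors used for weighting and for
    the reduced chi-squared statistic.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    n = len(replicates[0])
    if any(len(r) != n for r in replicates):
        raise ValueError("replicates must have equal injection counts")
    heats = np.vstack([r.heats for r in replicates])
    return InjectionSeries(
        heats=heats.mean(axis=0),
        molar_ratio=replicates[0].molar_ratio.copy(),
        errors=heats.std(axis=0, ddof=1),
    )


# --------------------------------------------------------------------------
# fitting


def reduced_chi_squared(
    residuals: np.ndarray, measurement_errors: np.ndarray, n_params: int
) -> float:
    """chi^2 / nu = sum((r_i / sigma_i)^2) / (N - n_params).

    Values much below one indicate overfitting; well above one, model
    misfit beyond measurement error.
    """
    residuals = np.asarray(residuals, dtype=float)
    sigma = np.asarray(measurement_errors, dtype=float)
    if residuals.shape != sigma.shape:
        raise ValueError("residuals and errors must have equal length")
    if np.any(sigma <= 0):
        raise ValueError("measurement errors must be positive")
    nu = residuals.size - n_params
    if nu <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(np.sum((residuals / sigma) ** 2) / nu)


def _effective_sigma(series: InjectionSeries, mask: np.ndarray) -> np.ndarray:
    """Per-injection sigma for weighting: replicate SDs where available,
    unit weights otherwise.

    Few-replicate SD estimates are heavy-tailed downwards (a lucky
    injection's tiny SD would dominate the fit), so SDs are floored at
    their median; this also covers exactly-zero SDs.
    """
    if series.errors is None:
        return np.ones(int(mask.sum()))
    sigma = series.errors[mask].copy()
    nonzero = sigma[sigma > 0]
    floor = float(np.median(nonzero)) if nonzero.size else 1.0
    return np.maximum(sigma, floor)


def _fit_mask(series: InjectionSeries, protocol: TitrationProtocol) -> np.ndarray:
    mask = np.ones(len(series), dtype=bool)
    if protocol.discard_first and len(series) > 1:
        mask[0] = False
    return mask


def _make_lmfit_params(
    model: ModelName, init: SequentialParams | IdenticalSitesParams
) -> lmfit.Parameters:
    # generous but finite bounds keep exp(ln K) representable while the
    # optimizer explores poorly constrained directions
    p = lmfit.Parameters()
    if model == "sequential":
        assert isinstance(init, SequentialParams)
        p.add("ln_k1", value=math.log(init.k1), min=-25.0, max=40.0)
        p.add("ln_k2", value=math.log(init.k2), min=-25.0, max=40.0)
        p.add("dh1", value=init.dh1, min=-500.0, max=500.0)
        p.add("dh2", value=init.dh2, min=-500.0, max=500.0)
    else:
        assert isinstance(init, IdenticalSitesParams)
        p.add("ln_n", value=math.log(init.n_sites), min=-10.0, max=10.0)
        p.add("ln_k", value=math.log(init.k), min=-25.0, max=40.0)
        p.add("dh", value=init.dh, min=-500.0, max=500.0)
    return p


def _params_from_lmfit(model: ModelName, p: lmfit.Parameters):
    if model == "sequential":
        return SequentialParams(
            k1=math.exp(p["ln_k1"].value),
            k2=math.exp(p["ln_k2"].value),
            dh1=p["dh1"].value,
            dh2=p["dh2"].value,
        )
    return IdenticalSitesParams(
        n_sites=math.exp(p["ln_n"].value), k=math.exp(p["ln_k"].value), dh=p["dh"].value
    )


def _stderr_from_lmfit(model: ModelName, p: lmfit.Parameters) -> dict[str, float]:
    """Delta-method standard errors on the natural (K, not ln K) scale."""
    out: dict[str, float] = {}
    if model == "sequential":
        pairs = [("k1", "ln_k1"), ("k2", "ln_k2"), ("dh1", "dh1"), ("dh2", "dh2")]
    else:
        pairs = [("n_sites", "ln_n"), ("k", "ln_k"), ("dh", "dh")]
    for name, key in pairs:
        se = p[key].stderr
        if se is None:
            out[name] = float("nan")
        elif key.startswith("ln_"):
            out[name] = math.exp(p[key].value) * se
        else:
            out[name] = se
    return out


def fit_model(
    series: InjectionSeries,
    protocol: TitrationProtocol,
    model: ModelName,
    init: SequentialParams | IdenticalSitesParams,
    convention: DilutionConvention = "displacement",
) -> FitResult:
    """Weighted least-squares fit of one binding model to one series.

    Minimizes ``sum(((y_obs - y_model) / sigma)^2)`` over the fitted
    injections (the first is excluded when the protocol discards it).
    Binding constants are fit on the log scale to enforce positivity.
    Parameter uncertainties here come from the covariance matrix; for
    the replicate-SD convention use :func:`fit_replicates`.
    """
    n_params = 4 if model == "sequential" else 3
    mask = _fit_mask(series, protocol)
    if int(mask.sum()) < n_params + 1:
        raise ValueError("too few injections to fit the model")
    sigma = _effective_sigma(series, mask)
    y_obs = series.heats[mask]

    def residual(p: lmfit.Parameters) -> np.ndarray:
        sim = simulate_injection_heats(
            protocol, _params_from_lmfit(model, p), model, convention
        )
        return (y_obs - sim.heats[mask]) / sigma

    out = lmfit.minimize(residual, _make_lmfit_params(model, init), method="leastsq")
    fitted = _params_from_lmfit(model, out.params)
    raw_resid = residual(out.params) * sigma
    chi2 = reduced_chi_squared(raw_resid, sigma, n_params)
    if not out.success:
        warnings.warn(f"ITC fit did not converge: {out.message}", stacklevel=2)
    return FitResult(
        params=fitted,
        stderr=_stderr_from_lmfit(model, out.params),
        residuals=raw_resid,
        chi2_over_nu=chi2,
        model=model,
        success=bool(out.success),
        message=str(out.message),
        n_fitted=int(mask.sum()),
    )


def fit_replicates(
    replicates: Sequence[InjectionSeries],
    protocol: TitrationProtocol,
    model: ModelName,
    init: SequentialParams | IdenticalSitesParams,
    convention: DilutionConvention = "displacement",
) -> FitResult:
    """Fit the replicate-averaged series; report replicate-SD errors.

    The central estimate fits the per-injection mean heats weighted by
    the replicate SDs.  Each replicate is then refit independently and
    the standard deviation of the per-replicate parameters across
    replicates is reported as the parameter uncertainty.
    """
    mean_series = average_replicates(replicates)
    central = fit_model(mean_series, protocol, model, init, convention)
    rep_params = []
    for rep in replicates:
        rep_fit = fit_model(rep, protocol, model, central.params, convention)
        rep_params.append(rep_fit.params)
    fields = (
        ("k1", "k2", "dh1", "dh2") if model == "sequential" else ("n_sites", "k", "dh")
    )
    stderr = {
        f: float(np.std([getattr(p, f) for p in rep_params], ddof=1)) for f in fields
    }
    return replace(central, stderr=stderr, replicate_params=rep_params)
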