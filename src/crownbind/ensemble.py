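"""Conformational-ensemble and solvation-shell analysis.

Covers four analyses of pre-computed simulation ensembles of a ditopic
receptor with 0, 1 or 2 bound cations:

* PCA of per-frame descriptor vectors and gating of the projected
  cloud with ellipses to obtain conformational-state probabilities
  (extended, collapsed and the two skewed states of the receptor);
* probability-weighted internal-energy decompositions,
  ``U_i = sum_j p_ij U_ij``, and the second difference
  ``ddU = (U_2 - U_1) - (U_1 - U_0)`` resolved per conformation;
* dipole-angle distributions of the k nearest solvation waters around
  each binding site;
* local/bulk ion partition coefficients ``K_p(d)`` relative to the
  receptor surface.

Periodic boundaries use the minimum-image convention in orthorhombic
boxes throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConformationEnsemble",
    "EllipseGate",
    "StateProbabilities",
    "ParticleFrame",
    "PCAResult",
    "pca_project",
    "assign_gates",
    "gate_probabilities",
    "fit_gates",
    "EnergyDecomposition",
    "weighted_energy_decomposition",
    "minimum_image",
    "cluster_dipole_angle",
    "dipole_angle_series",
    "AngleDensity",
    "angle_density",
    "partition_profile",
    "mean_site_separation",
]

REST_LABEL = "rest"


@dataclass(frozen=True)
class ConformationEnsemble:
    """Frames of fixed-length descriptor vectors with per-frame internal
    energies (complex only, kcal/mol) and a bound-state label in
    {0, 1, 2} counting bound cations."""

    descriptors: np.ndarray  # (n_frames, n_features)
    energies: np.ndarray  # (n_frames,)
    bound_state: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.descriptors, dtype=float))
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "descriptors", x)
        object.__setattr__(self, "energies", e)
        if x.shape[0] != e.size:
            raise ValueError("descriptors and energies must have equal frame counts")
        if self.bound_state not in (0, 1, 2):
            raise ValueError("bound_state must be 0, 1 or 2")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.size != e.size or np.any(w < 0) or w.sum() == 0:
                raise ValueError("weights must be non-negative, same length, not all zero")
            object.__setattr__(self, "weights", w / w.sum())

    @property
    def n_frames(self) -> int:
        return self.descriptors.shape[0]


@dataclass(frozen=True)
class EllipseGate:
    """Ellipse in 2-D principal-component space: center, semi-axes and a
    counter-clockwise rotation angle in degrees."""

    label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        th = np.deg2rad(self.angle_deg)
        c, s = np.cos(th), np.sin(th)
        u = pts[:, 0] * c + pts[:, 1] * s
        v = -pts[:, 0] * s + pts[:, 1] * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the ellipse (for overlap checks)."""
        r = np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * np.pi
        u = r * np.cos(phi) * self.semi_axes[0]
        v = r * np.sin(phi) * self.semi_axes[1]
        th = np.deg2rad(self.angle_deg)
        c, s = np.cos(th), np.sin(th)
        return np.column_stack(
            [u * c - v * s + self.center[0], u * s + v * c + self.center[1]]
        )


@dataclass(frozen=True)
class StateProbabilities:
    """Per-gate probabilities with block-averaged standard errors plus
    the residual probability of ungated frames."""

    labels: tuple[str, ...]
    p: np.ndarray
    se: np.ndarray
    p_rest: float
    se_rest: float

    def as_dict(self) -> dict[str, float]:
        d = {lab: float(v) for lab, v in zip(self.labels, self.p)}
        d[REST_LABEL] = self.p_rest
        return d


@dataclass(frozen=True)
class ParticleFrame:
    """One configuration: receptor atoms, ions (with species labels),
    waters with dipole vectors, an orthorhombic box and two binding-site
    reference points."""

    receptor: np.ndarray  # (n_rec, 3)
    ions: np.ndarray  # (n_ion, 3)
    ion_species: tuple[str, ...]
    waters: np.ndarray  # (n_wat, 3)
    water_dipoles: np.ndarray  # (n_wat, 3)
    box: np.ndarray  # (3,)
    sites: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        for name in ("receptor", "ions", "waters", "water_dipoles", "sites", "box"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "ion_species", tuple(self.ion_species))
        if self.ions.reshape(-1, 3).shape[0] != len(self.ion_species):
            raise ValueError("one species label required per ion")
        if self.waters.shape != self.water_dipoles.shape:
            raise ValueError("waters and water_dipoles must match in shape")
        if self.sites.shape != (2, 3):
            raise ValueError("exactly two binding-site references required")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    def wrapped(self) -> "ParticleFrame":
        """Copy with all coordinates wrapped into [0, box)."""
        def w(x: np.ndarray) -> np.ndarray:
            return np.mod(x, self.box) if x.size else x

        return ParticleFrame(
            receptor=w(self.receptor),
            ions=w(self.ions.reshape(-1, 3)),
            ion_species=self.ion_species,
            waters=w(self.waters),
            water_dipoles=self.water_dipoles,
            box=self.box,
            sites=w(self.sites),
        )


# --------------------------------------------------------------------------
# PCA and gating


@dataclass(frozen=True)
class PCAResult:
    coords: np.ndarray  # (n_frames, n_components)
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.coords @ self.components + self.mean


def pca_project(
    data: ConformationEnsemble | np.ndarray, n_components: int = 2
) -> PCAResult:
    """Project descriptor vectors onto their leading principal components.

    Mean-centered covariance eigendecomposition; components are ordered
    by decreasing eigenvalue with a deterministic sign convention (the
    largest-magnitude loading of each component is made positive).
    """
    x = data.descriptors if isinstance(data, ConformationEnsemble) else np.asarray(data, float)
    x = np.atleast_2d(x)
    if x.shape[0] < n_components + 1:
        raise ValueError("need more frames than components")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= 0 or evals[n_components - 1] <= 1e-12 * max(total, 1.0):
        raise ValueError("degenerate (zero-variance) descriptors: PCA is undefined")
    comps = evecs[:, :n_components].T
    for i in range(n_components):  # deterministic sign convention
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAResult(
        coords=xc @ comps.T,
        components=comps,
        explained_variance_ratio=evals[:n_components] / total,
        mean=mean,
    )


def _check_gate_overlap(
    gates: Sequence[EllipseGate], n_samples: int = 4000, tol: float = 1e-3
) -> None:
    rng = np.random.default_rng(0)
    for i, gi in enumerate(gates):
        pts = gi.sample(n_samples, rng)
        for gj in gates[i + 1 :]:
            frac = float(gj.contains(pts).mean())
            if frac > tol:
                warnings.warn(
                    f"gates {gi.label!r} and {gj.label!r} overlap by ~{frac:.2%} "
                    "of the former's area",
                    stacklevel=3,
                )


def assign_gates(points: np.ndarray, gates: Sequence[EllipseGate]) -> np.ndarray:
    """Label each 2-D point with the first gate containing it, or
    ``"rest"`` when no gate does."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.full(points.shape[0], REST_LABEL, dtype=object)
    unassigned = np.ones(points.shape[0], dtype=bool)
    for gate in gates:
        inside = gate.contains(points) & unassigned
        labels[inside] = gate.label
        unassigned &= ~inside
    return labels


def gate_probabilities(
    points: np.ndarray,
    gates: Sequence[EllipseGate],
    weights: np.ndarray | None = None,
    n_blocks: int = 10,
) -> StateProbabilities:
    """Probability of each gated conformational state.

    ``p_j`` is the (weighted) fraction of projected frames inside gate
    ``j``; standard errors come from block averaging over ``n_blocks``
    contiguous blocks of the frame sequence.  Probabilities plus the
    residual ``p_rest`` sum to one exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty ensemble")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    _check_gate_overlap(gates)

    labels = assign_gates(points, gates)
    gate_names = [g.label for g in gates]
    masks = [labels == name for name in gate_names]
    p = np.array([weights[m].sum() for m in masks])
    p_rest = 1.0 - p.sum()

    # block-averaged standard errors over contiguous blocks
    bounds = np.linspace(0, n, min(n_blocks, n) + 1).astype(int)
    nb = len(bounds) - 1
    block_p = np.empty((nb, len(gates) + 1))
    for b in range(nb):
        sl = slice(bounds[b], bounds[b + 1])
        wb = weights[sl]
        tot = wb.sum()
        if tot == 0:
            block_p[b] = np.nan
            continue
        for gi, m in enumerate(masks):
            block_p[b, gi] = wb[m[sl]].sum() / tot
        block_p[b, -1] = 1.0 - block_p[b, :-1].sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se_all = np.nanstd(block_p, axis=0, ddof=1) / np.sqrt(nb)
    return StateProbabilities(
        labels=tuple(gate_names),
        p=p,
        se=se_all[:-1],
        p_rest=float(p_rest),
        se_rest=float(se_all[-1]),
    )


def fit_gates(
    points: np.ndarray,
    n_gates: int,
    n_sigma: float = 2.0,
    labels: Sequence[str] | None = None,
    random_state: int = 0,
) -> list[EllipseGate]:
    """Seed ellipse gates from density peaks of a projected cloud.

    Fits a Gaussian mixture and converts each component covariance to an
    ``n_sigma`` ellipse; a starting point for gates that users would
    otherwise draw by hand.  Components are ordered by their center's
    first coordinate for determinism.
    """
    from sklearn.mixture import GaussianMixture

    points = np.atleast_2d(np.asarray(points, dtype=float))
    gm = GaussianMixture(
        n_components=n_gates, covariance_type="full", random_state=random_state, n_init=3
    ).fit(points)
    order = np.argsort(gm.means_[:, 0])
    gates = []
    for rank, idx in enumerate(order):
        evals, evecs = np.linalg.eigh(gm.covariances_[idx])
        angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        name = labels[rank] if labels is not None else f"g{rank}"
        gates.append(
            EllipseGate(
                label=name,
                center=(float(gm.means_[idx, 0]), float(gm.means_[idx, 1])),
                semi_axes=(
                    n_sigma * float(np.sqrt(evals[-1])),
                    n_sigma * float(np.sqrt(evals[0])),
                ),
                angle_deg=angle,
            )
        )
    return gates


# --------------------------------------------------------------------------
# energy decomposition


@dataclass(frozen=True)
class EnergyDecomposition:
    """Probability-weighted internal-energy bookkeeping across bound
    states 0/1/2.

    ``table`` has one row per conformation label (gates plus ``rest``)
    with columns ``p_<i>``, ``U_<i>``, ``pU_<i>`` for each bound state i
    and the differences ``d_pU_01``, ``d_pU_12``, ``dd_pU``;
    ``running_dd_pU`` accumulates ``dd_pU`` row by row and ends exactly
    at ``ddU``.
    """

    table: pd.DataFrame
    u: dict[int, float]
    du_01: float
    du_12: float
    ddu: float


def weighted_energy_decomposition(
    ensembles: Mapping[int, ConformationEnsemble],
    assignments: Mapping[int, np.ndarray],
    gate_labels: Sequence[str],
) -> EnergyDecomposition:
    """Decompose internal-energy changes over conformations.

    For each bound state ``i`` the mean internal energy satisfies
    ``U_i = sum_j p_ij U_ij`` exactly once ungated frames enter as the
    pseudo-conformation ``rest`` (empty conformations contribute
    ``p = 0`` with ``U`` taken as 0 so ``pU = 0``).  Differences
    ``dU_01 = U_1 - U_0``, ``dU_12 = U_2 - U_1``, the second difference
    ``ddU`` and its per-conformation resolution
    ``dd(p_j U_j) = d(p_j U_j)_12 - d(p_j U_j)_01`` telescope exactly.
    """
    for state in (0, 1, 2):
        if state not in ensembles or state not in assignments:
            raise ValueError(f"missing bound state {state}")
    labels = list(gate_labels) + [REST_LABEL]
    cols: dict[str, list[float]] = {}
    u_state: dict[int, float] = {}
    for state in (0, 1, 2):
        ens = ensembles[state]
        lab = np.asarray(assignments[state], dtype=object)
        if lab.size != ens.n_frames:
            raise ValueError("assignments must label every frame")
        w = ens.weights if ens.weights is not None else np.full(ens.n_frames, 1.0 / ens.n_frames)
        p_list, u_list = [], []
        for name in labels:
            m = lab == name
            p = float(w[m].sum())
            u = float((w[m] * ens.energies[m]).sum() / p) if p > 0 else 0.0
            p_list.append(p)
            u_list.append(u)
        cols[f"p_{state}"] = p_list
        cols[f"U_{state}"] = u_list
        cols[f"pU_{state}"] = [p * u for p, u in zip(p_list, u_list)]
        u_state[state] = float(np.dot(w, ens.energies))

    table = pd.DataFrame(cols, index=pd.Index(labels, name="conformation"))
    table["d_pU_01"] = table["pU_1"] - table["pU_0"]
    table["d_pU_12"] = table["pU_2"] - table["pU_1"]
    table["dd_pU"] = table["d_pU_12"] - table["d_pU_01"]
    table["running_dd_pU"] = table["dd_pU"].cumsum()
    return EnergyDecomposition(
        table=table,
        u=u_state,
        du_01=u_state[1] - u_state[0],
        du_12=u_state[2] - u_state[1],
        ddu=(u_state[2] - u_state[1]) - (u_state[1] - u_state[0]),
    )


# --------------------------------------------------------------------------
# solvation shells and partitioning


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    return delta - box * np.round(delta / box)


def cluster_dipole_angle(frame: ParticleFrame, k: int = 4) -> float:
    """Angle (degrees, [0, 180]) between the summed dipole moments of
    the k waters nearest each binding site.

    Distances use the minimum-image convention.  Returns NaN when either
    cluster's net dipole vanishes (undefined direction).
    """
    if frame.waters.shape[0] < k:
        raise ValueError(f"need at least k={k} waters per frame")
    sums = []
    for site in frame.sites:
        d = minimum_image(frame.waters - site, frame.box)
        idx = np.argpartition(np.einsum("ij,ij->i", d, d), k - 1)[:k]
        sums.append(frame.water_dipoles[idx].sum(axis=0))
    a, b = sums
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dipole_angle_series(frames: Sequence[ParticleFrame], k: int = 4) -> np.ndarray:
    """Per-frame cluster dipole angles; NaN frames flagged as such."""
    return np.array([cluster_dipole_angle(f, k) for f in frames])


@dataclass(frozen=True)
class AngleDensity:
    """Windowed probability density over [0, 180] degrees, normalized to
    integrate to one over [0, pi] radians."""

    centers_deg: np.ndarray
    density: np.ndarray
    se: np.ndarray
    window_half_width_deg: float


def angle_density(
    angles_deg: Sequence[float],
    window_half_width_deg: float = 15.0,
    n_blocks: int = 10,
) -> AngleDensity:
    """Probability density of angles in windows of +-half-width around
    markers spaced two half-widths apart (15, 45, ..., 165 by default).

    density = count / (N * window width in radians), so the densities
    times their window widths sum to 1.  NaN angles (undefined dipoles)
    are excluded.  Per-marker errors come from block averaging.
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("no (defined) angles supplied")
    if np.any((angles < 0) | (angles > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    hw = window_half_width_deg
    centers = np.arange(hw, 180.0, 2 * hw)
    width_rad = np.deg2rad(2 * hw)
    n = angles.size

    def window_counts(a: np.ndarray) -> np.ndarray:
        edges = np.concatenate([centers - hw, [centers[-1] + hw]])
        return np.histogram(a, bins=edges)[0]

    density = window_counts(angles) / (n * width_rad)
    bounds = np.linspace(0, n, min(n_blocks, n) + 1).astype(int)
    nb = len(bounds) - 1
    block_density = np.empty((nb, centers.size))
    for b in range(nb):
        blk = angles[bounds[b] : bounds[b + 1]]
        block_density[b] = (
            window_counts(blk) / (blk.size * width_rad) if blk.size else np.nan
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(block_density, axis=0, ddof=1) / np.sqrt(nb)
    return AngleDensity(
        centers_deg=centers, density=density, se=se, window_half_width_deg=hw
    )


def _surface_distances(
    points: np.ndarray, receptor: np.ndarray, box: np.ndarray, offset: float
) -> np.ndarray:
    """Distance of each point to the receptor surface (nearest heavy-atom
    center, optionally shifted outward by a van-der-Waals offset)."""
    if points.size == 0:
        return np.empty(0)
    d = minimum_image(points[:, None, :] - receptor[None, :, :], box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min(axis=1)
    return np.maximum(dist - offset, 0.0)


def partition_profile(
    frames: Sequence[ParticleFrame],
    species: str,
    d_grid: Sequence[float],
    surface_offset: float = 0.0,
) -> pd.DataFrame:
    """Local/bulk partition coefficient profile K_p(d) of an ion species.

    K_p(d) = (<n_surf,ion(d)> / N_ion) / (<n_surf,water(d)> / N_water)
    with populations counted within [0, d] of the receptor surface
    (distance to the nearest receptor atom center; ``surface_offset``
    subtracts a van-der-Waals radius when an excluded-volume surface is
    wanted) and averaged over frames.  Water is referenced by its oxygen
    position.  Where no water falls inside d the profile is undefined
    and reported as NaN.  At any d spanning the whole box K_p is 1
    exactly.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    d_grid = np.asarray(d_grid, dtype=float)
    n_ion_tot = n_wat_tot = 0
    ion_counts = np.zeros(d_grid.size)
    wat_counts = np.zeros(d_grid.size)
    found_species = False
    for frame in frames:
        sel = np.array([s == species for s in frame.ion_species], dtype=bool)
        ions = frame.ions.reshape(-1, 3)[sel]
        if ions.shape[0]:
            found_species = True
        di = _surface_distances(ions, frame.receptor, frame.box, surface_offset)
        dw = _surface_distances(frame.waters, frame.receptor, frame.box, surface_offset)
        n_ion_tot += ions.shape[0]
        n_wat_tot += frame.waters.shape[0]
        ion_counts += (di[:, None] <= d_grid[None, :]).sum(axis=0)
        wat_counts += (dw[:, None] <= d_grid[None, :]).sum(axis=0)
    if not found_species:
        raise ValueError(f"species {species!r} not present in any frame")
    with np.errstate(divide="ignore", invalid="ignore"):
        kp = (ion_counts / n_ion_tot) / (wat_counts / n_wat_tot)
    kp[wat_counts == 0] = np.nan
    return pd.DataFrame(
        {
            "d": d_grid,
            "kp": kp,
            "n_ion_mean": ion_counts / len(frames),
            "n_water_mean": wat_counts / len(frames),
        }
    )


def mean_site_separation(frames: Sequence[ParticleFrame]) -> float:
    """Arithmetic mean over frames of the minimum-image distance between
    the two binding-site reference points (angstrom)."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    dists = [
        float(np.linalg.norm(minimum_image(f.sites[0] - f.sites[1], f.box)))
        for f in frames
    ]
    return float(np.mean(dists))
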