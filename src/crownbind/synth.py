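"""Ground-truth-known synthetic data for every analysis stage.

Each generator is deterministic under a fixed seed and returns the data
together with a *truth record* holding the generating parameters, so
downstream recovery tests compare against the record rather than against
hard-coded numbers.

Default study conditions mirror the KCl titration: a 1.4631 mL cell of
0.39 mM receptor titrated with 247 mM K+ in one discarded 4 uL plus 28
productive 10 uL injections, stepwise truth K1 = 119, K2 = 17.2,
dH1 = -4.12, dH2 = -6.76 kcal/mol, three replicates, and per-injection
Gaussian noise of 5e-4 kcal/mol — the noise level consistent, through
the Fisher information of this (low-c) protocol, with the replicate-SD
parameter errors the experiment achieves (K1 to ~8%, dH2 to ~1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ConformationEnsemble, EllipseGate, ParticleFrame
from .itc import (
    IdenticalSitesParams,
    InjectionSeries,
    SequentialParams,
    TitrationProtocol,
    simulate_injection_heats,
)

__all__ = [
    "kcl_protocol",
    "ItcExperiment",
    "gen_itc_experiment",
    "EnsembleTruth",
    "ConformationSample",
    "gen_conformation_ensemble",
    "gen_partition_frames",
    "PartitionSample",
]


def kcl_protocol(n_injections: int = 28) -> TitrationProtocol:
    """The KCl titration protocol: 4 uL discarded first injection
    followed by ``n_injections`` 10 uL injections."""
    return TitrationProtocol(
        cell_volume_mL=1.4631,
        syringe_mM=247.0,
        cell_mM=0.39,
        injection_volumes_uL=(4.0,) + (10.0,) * n_injections,
        temperature_K=298.15,
        discard_first=True,
    )


@dataclass(frozen=True)
class ItcExperiment:
    """Replicated synthetic titration with its blank and truth record."""

    replicates: tuple[InjectionSeries, ...]
    dilution: InjectionSeries
    protocol: TitrationProtocol
    truth: dict


def gen_itc_experiment(
    seed: int,
    params: SequentialParams | IdenticalSitesParams | None = None,
    protocol: TitrationProtocol | None = None,
    sigma: float = 5e-4,
    n_replicates: int = 3,
    dilution_heat: float = -0.02,
    dilution_sigma: float = 1e-4,
) -> ItcExperiment:
    """Simulate a replicated ITC experiment with Gaussian heat noise.

    Replicate heats are model + constant dilution heat + noise, so the
    full pipeline (dilution subtraction, replicate averaging, fitting)
    is exercised end to end.  The default truth is the KCl scenario.
    """
    if sigma < 0 or dilution_sigma < 0:
        raise ValueError("noise levels must be non-negative")
    if params is None:
        params = SequentialParams(k1=119.0, k2=17.2, dh1=-4.12, dh2=-6.76)
    if protocol is None:
        protocol = kcl_protocol()
    rng = np.random.default_rng(seed)
    clean = simulate_injection_heats(protocol, params)
    replicates = tuple(
        InjectionSeries(
            heats=clean.heats + dilution_heat + rng.normal(0.0, sigma, len(clean)),
            molar_ratio=clean.molar_ratio.copy(),
        )
        for _ in range(n_replicates)
    )
    dilution = InjectionSeries(
        heats=dilution_heat + rng.normal(0.0, dilution_sigma, len(clean)),
        molar_ratio=clean.molar_ratio.copy(),
    )
    truth = {
        "params": params,
        "sigma": sigma,
        "dilution_heat": dilution_heat,
        "dilution_sigma": dilution_sigma,
        "n_replicates": n_replicates,
        "seed": seed,
        "clean_heats": clean.heats.copy(),
    }
    return ItcExperiment(
        replicates=replicates, dilution=dilution, protocol=protocol, truth=truth
    )


# --------------------------------------------------------------------------
# conformational ensembles

STATE_LABELS = ("EXT", "SK1", "SK2", "COL")

#: Cluster centers in the 2-D latent conformational plane; spread along
#: the first axis exceeds the second so PCA ordering is predictable.
_CENTERS = {
    "EXT": (-6.0, 0.0),
    "SK1": (0.0, 2.5),
    "SK2": (0.0, -2.5),
    "COL": (6.0, 0.0),
}
_CLUSTER_SIGMA = 0.6

#: Default conformational weights per bound state: the collapsed-analog
#: weight rises monotonically as cations bind.
_DEFAULT_WEIGHTS = {
    0: {"EXT": 0.40, "SK1": 0.25, "SK2": 0.25, "COL": 0.10},
    1: {"EXT": 0.32, "SK1": 0.24, "SK2": 0.24, "COL": 0.20},
    2: {"EXT": 0.22, "SK1": 0.22, "SK2": 0.22, "COL": 0.34},
}

#: Default per-conformation mean internal energies (kcal/mol) per bound
#: state; roughly -100 kcal/mol per bound cation, with the collapsed
#: conformation stabilizing faster so that ddU < 0 is dominated by a
#: negative collapsed-state term.
_DEFAULT_ENERGIES = {
    0: {"EXT": 0.0, "SK1": 2.0, "SK2": 2.0, "COL": 6.0},
    1: {"EXT": -100.0, "SK1": -99.0, "SK2": -99.0, "COL": -102.0},
    2: {"EXT": -198.0, "SK1": -197.0, "SK2": -197.0, "COL": -212.0},
}


@dataclass(frozen=True)
class EnsembleTruth:
    weights: dict[int, dict[str, float]]
    energies: dict[int, dict[str, float]]
    u_expected: dict[int, float]
    ddu_expected: float
    energy_sigma: float
    seed: int


@dataclass(frozen=True)
class ConformationSample:
    ensembles: dict[int, ConformationEnsemble]
    gates: tuple[EllipseGate, ...]
    latent: dict[int, np.ndarray]  # true 2-D cluster-plane coordinates
    truth: EnsembleTruth


def default_conformation_gates(radius: float = 2.4) -> tuple[EllipseGate, ...]:
    """Circular gates around the four latent cluster centers."""
    return tuple(
        EllipseGate(label=lab, center=_CENTERS[lab], semi_axes=(radius, radius))
        for lab in STATE_LABELS
    )


def gen_conformation_ensemble(
    seed: int,
    n_frames: int = 20_000,
    weights: dict[int, dict[str, float]] | None = None,
    energies: dict[int, dict[str, float]] | None = None,
    energy_sigma: float = 2.0,
    n_noise_dims: int = 3,
    noise_sigma: float = 0.15,
) -> ConformationSample:
    """Three four-cluster ensembles (bound states 0/1/2) with known truth.

    Frames are drawn from a 2-D Gaussian mixture (cluster SD 0.6 around
    well-separated centers) embedded as the first two coordinates of a
    descriptor vector padded with ``n_noise_dims`` low-variance noise
    dimensions; energies are the per-cluster means plus Gaussian noise.
    The expected mean energy of state i is the exact mixture expectation
    ``sum_j w_ij U_ij``, recorded in the truth record together with the
    implied ddU.
    """
    weights = weights if weights is not None else _DEFAULT_WEIGHTS
    energies = energies if energies is not None else _DEFAULT_ENERGIES
    rng = np.random.default_rng(seed)
    ensembles: dict[int, ConformationEnsemble] = {}
    latent: dict[int, np.ndarray] = {}
    u_expected: dict[int, float] = {}
    for state in (0, 1, 2):
        w = weights[state]
        if sum(w.values()) > 1.0 + 1e-12:
            raise ValueError("cluster weights must sum to <= 1")
        labels = rng.choice(STATE_LABELS, size=n_frames, p=[w[k] for k in STATE_LABELS])
        centers = np.array([_CENTERS[lab] for lab in labels])
        xy = centers + rng.normal(0.0, _CLUSTER_SIGMA, size=(n_frames, 2))
        noise = rng.normal(0.0, noise_sigma, size=(n_frames, n_noise_dims))
        u_mean = np.array([energies[state][lab] for lab in labels])
        u = u_mean + rng.normal(0.0, energy_sigma, size=n_frames)
        ensembles[state] = ConformationEnsemble(
            descriptors=np.hstack([xy, noise]), energies=u, bound_state=state
        )
        latent[state] = xy
        u_expected[state] = float(
            sum(w[lab] * energies[state][lab] for lab in STATE_LABELS)
        )
    ddu = (u_expected[2] - u_expected[1]) - (u_expected[1] - u_expected[0])
    truth = EnsembleTruth(
        weights={s: dict(weights[s]) for s in (0, 1, 2)},
        energies={s: dict(energies[s]) for s in (0, 1, 2)},
        u_expected=u_expected,
        ddu_expected=ddu,
        energy_sigma=energy_sigma,
        seed=seed,
    )
    return ConformationSample(
        ensembles=ensembles, gates=default_conformation_gates(), latent=latent, truth=truth
    )


# --------------------------------------------------------------------------
# particle frames


@dataclass(frozen=True)
class PartitionSample:
    frames: tuple[ParticleFrame, ...]
    truth: dict


def _receptor_cluster(box: np.ndarray) -> np.ndarray:
    """Fixed compact 8-atom cluster (2 A cube) at the box center."""
    corners = np.array(
        [[i, j, k] for i in (-1.0, 1.0) for j in (-1.0, 1.0) for k in (-1.0, 1.0)]
    )
    return box / 2.0 + corners


def _shell_volume_fraction(
    receptor: np.ndarray, box: np.ndarray, d: float, rng: np.random.Generator,
    n_samples: int = 200_000,
) -> float:
    """Monte-Carlo estimate of the box fraction within d of the receptor
    (union of spheres has no convenient closed form)."""
    pts = rng.random((n_samples, 3)) * box
    delta = pts[:, None, :] - receptor[None, :, :]
    delta -= box * np.round(delta / box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta)).min(axis=1)
    return float((dist <= d).mean())


def gen_partition_frames(
    seed: int,
    n_frames: int = 400,
    n_ions: int = 60,
    n_waters: int = 600,
    box_length: float = 30.0,
    enrichment: float = 3.0,
    shell_distance: float = 4.0,
    dipole_alignment: float = 0.0,
    site_separation: float = 11.5,
    species: str = "Cl",
    max_attempts: int = 2000,
) -> PartitionSample:
    """Particle frames with a controllable near-surface ion excess and
    controllable water-dipole alignment.

    The receptor is a fixed compact atom cluster at the box center;
    waters are uniform; each ion is placed uniformly within the shell
    (distance <= ``shell_distance`` of the receptor) with probability
    ``q`` and uniformly in the box otherwise, where ``q`` is chosen so
    the expected partition coefficient at the shell distance equals
    ``enrichment``: with ``f`` the shell volume fraction,
    ``K_p = (q + (1-q) f) / f`` so ``q = (enrichment - 1) f / (1 - f)``.
    Water dipoles are unit vectors drawn isotropically and tilted toward
    the site axis by ``dipole_alignment`` in [0, 1] (0 = isotropic).
    The truth record carries ``q``, the Monte-Carlo ``f`` and the
    implied expected K_p.
    """
    if not 0.0 <= dipole_alignment <= 1.0:
        raise ValueError("dipole_alignment must be in [0, 1]")
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    box = np.full(3, float(box_length))
    if n_ions + n_waters > 0 and box_length**3 < (n_ions + n_waters) * 1.0:
        raise ValueError("box too small for requested particle counts")
    rng = np.random.default_rng(seed)
    receptor = _receptor_cluster(box)
    f = _shell_volume_fraction(receptor, box, shell_distance, rng)
    q = (enrichment - 1.0) * f / (1.0 - f)
    if not 0.0 <= q <= 1.0:
        raise ValueError("requested enrichment is unreachable in this box")
    axis = np.array([1.0, 0.0, 0.0])
    sites = np.vstack(
        [box / 2.0 - axis * site_separation / 2.0, box / 2.0 + axis * site_separation / 2.0]
    )

    def sample_in_shell(n: int) -> np.ndarray:
        out = np.empty((n, 3))
        filled = 0
        for _ in range(max_attempts):
            if filled >= n:
                break
            cand = rng.random((max(4 * n, 64), 3)) * box
            delta = cand[:, None, :] - receptor[None, :, :]
            delta -= box * np.round(delta / box)
            dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta)).min(axis=1)
            hits = cand[dist <= shell_distance]
            take = min(hits.shape[0], n - filled)
            out[filled : filled + take] = hits[:take]
            filled += take
        else:
            raise RuntimeError("rejection sampling of shell positions failed")
        return out

    frames = []
    for _ in range(n_frames):
        in_shell = rng.random(n_ions) < q
        ions = rng.random((n_ions, 3)) * box
        n_shell = int(in_shell.sum())
        if n_shell:
            ions[in_shell] = sample_in_shell(n_shell)
        waters = rng.random((n_waters, 3)) * box
        u = rng.normal(size=(n_waters, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dip = u + dipole_alignment * axis
        dip /= np.linalg.norm(dip, axis=1, keepdims=True)
        frames.append(
            ParticleFrame(
                receptor=receptor,
                ions=ions,
                ion_species=(species,) * n_ions,
                waters=waters,
                water_dipoles=dip,
                box=box,
                sites=sites,
            )
        )
    truth = {
        "seed": seed,
        "enrichment": enrichment,
        "shell_distance": shell_distance,
        "shell_volume_fraction": f,
        "q": q,
        "expected_kp_at_shell": (q + (1.0 - q) * f) / f,
        "dipole_alignment": dipole_alignment,
        "site_separation": site_separation,
        "species": species,
    }
    return PartitionSample(frames=tuple(frames), truth=truth)
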