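"""File formats, run configuration and the pipeline orchestrator.

Formats (all plain text, UTF-8, '.' decimal, '#' comments):

* **Injection CSV** — one row per injection with columns ``injection``,
  ``dV_uL``, ``molar_ratio``, ``heat_kcal_per_mol`` and optional
  ``sigma_kcal_per_mol``.  The titration protocol rides along as a
  commented YAML header (``# protocol: ...`` lines), so a single file
  round-trips both the series and the setup.
* **Frame files** — extended-XYZ blocks whose atom lines carry
  ``label x y z mux muy muz`` (dipoles zero for non-waters) and whose
  comment line carries the box; a sidecar CSV maps each atom index to a
  role (``receptor``/``ion``/``water``/``site``) and species.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .continuum import IonPairGeometry, WATER, bjerrum_length, g_plus_plus, h_plus_plus, ts_plus_plus
from .ensemble import ParticleFrame
from .itc import InjectionSeries, SequentialParams, TitrationProtocol, fit_replicates, subtract_dilution
from .synth import gen_itc_experiment
from .thermo import cooperativity_rho, delta_g_from_k, entropy_decomposition

logger = logging.getLogger("crownbind")

__all__ = [
    "RunConfig",
    "write_injection_csv",
    "read_injection_csv",
    "read_protocol_yaml",
    "write_protocol_yaml",
    "write_xyz_frames",
    "read_xyz_frames",
    "pipeline_run",
]

_PROTOCOL_KEYS = {
    "cell_volume_mL": float,
    "syringe_mM": float,
    "cell_mM": float,
    "temperature_K": float,
    "discard_first": bool,
}


class RunConfig(BaseModel):
    """Strict-schema configuration of a pipeline run; unknown keys are
    rejected."""

    model_config = ConfigDict(extra="forbid")

    stages: list[Literal["synth-itc", "itc-fit", "thermo", "continuum"]] = []
    seed: int = 0
    out_dir: str = "."
    r_angstrom: float = 11.5
    temperature_K: float = 298.15
    verbose: bool = False


# --------------------------------------------------------------------------
# injection CSV


def _protocol_header_lines(protocol: TitrationProtocol) -> list[str]:
    return [
        "# protocol:",
        f"#   cell_volume_mL: {protocol.cell_volume_mL!r}",
        f"#   syringe_mM: {protocol.syringe_mM!r}",
        f"#   cell_mM: {protocol.cell_mM!r}",
        f"#   temperature_K: {protocol.temperature_K!r}",
        f"#   discard_first: {str(protocol.discard_first).lower()}",
    ]


def write_injection_csv(
    path: str | Path, series: InjectionSeries, protocol: TitrationProtocol
) -> None:
    """Write one titration (series + embedded protocol header)."""
    if len(series) != protocol.n_injections:
        raise ValueError("series length must match the protocol's injection count")
    lines = _protocol_header_lines(protocol)
    cols = "injection,dV_uL,molar_ratio,heat_kcal_per_mol"
    if series.errors is not None:
        cols += ",sigma_kcal_per_mol"
    lines.append(cols)
    for i in range(len(series)):
        row = (
            f"{i + 1},{float(protocol.injection_volumes_uL[i])!r},"
            f"{float(series.molar_ratio[i])!r},{float(series.heats[i])!r}"
        )
        if series.errors is not None:
            row += f",{float(series.errors[i])!r}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_injection_csv(path: str | Path) -> tuple[InjectionSeries, TitrationProtocol]:
    """Read a titration written by :func:`write_injection_csv`.

    Malformed rows are rejected with an error naming the first offending
    line number (1-based, counting every physical line in the file).
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    proto_yaml: list[str] = []
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(raw, start=1):
        if line.startswith("#"):
            proto_yaml.append(line.lstrip("#"))
            continue
        if not line.strip():
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        rows.append((lineno, [c.strip() for c in line.split(",")]))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    required = ["injection", "dV_uL", "molar_ratio", "heat_kcal_per_mol"]
    if header[: len(required)] != required:
        raise ValueError(f"{path}: header must start with {','.join(required)}")
    has_sigma = "sigma_kcal_per_mol" in header
    if not rows:
        raise ValueError(f"{path}: no injections found (header-only file)")

    meta = yaml.safe_load("\n".join(proto_yaml)) or {}
    proto_block = meta.get("protocol")
    if proto_block is None:
        raise ValueError(f"{path}: missing '# protocol:' header block")
    unknown = set(proto_block) - set(_PROTOCOL_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown protocol keys {sorted(unknown)}")

    dv, ratios, heats, sigmas = [], [], [], []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise ValueError(f"{path}: line {lineno}: expected {len(header)} fields")
        try:
            dv.append(float(cells[1]))
            ratios.append(float(cells[2]))
            heats.append(float(cells[3]))
            if has_sigma:
                sigmas.append(float(cells[4]))
        except ValueError as err:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({err})") from None
    protocol = TitrationProtocol(
        cell_volume_mL=float(proto_block["cell_volume_mL"]),
        syringe_mM=float(proto_block["syringe_mM"]),
        cell_mM=float(proto_block["cell_mM"]),
        injection_volumes_uL=tuple(dv),
        temperature_K=float(proto_block.get("temperature_K", 298.15)),
        discard_first=bool(proto_block.get("discard_first", True)),
    )
    series = InjectionSeries(
        heats=np.array(heats),
        molar_ratio=np.array(ratios),
        errors=np.array(sigmas) if has_sigma else None,
    )
    return series, protocol


def write_protocol_yaml(path: str | Path, protocol: TitrationProtocol) -> None:
    doc = {
        "cell_volume_mL": protocol.cell_volume_mL,
        "syringe_mM": protocol.syringe_mM,
        "cell_mM": protocol.cell_mM,
        "temperature_K": protocol.temperature_K,
        "discard_first": protocol.discard_first,
        "injection_volumes_uL": list(protocol.injection_volumes_uL),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_protocol_yaml(path: str | Path) -> TitrationProtocol:
    doc = yaml.safe_load(Path(path).read_text())
    allowed = set(_PROTOCOL_KEYS) | {"injection_volumes_uL"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown protocol keys {sorted(unknown)}")
    return TitrationProtocol(
        cell_volume_mL=float(doc["cell_volume_mL"]),
        syringe_mM=float(doc["syringe_mM"]),
        cell_mM=float(doc["cell_mM"]),
        injection_volumes_uL=tuple(float(v) for v in doc["injection_volumes_uL"]),
        temperature_K=float(doc.get("temperature_K", 298.15)),
        discard_first=bool(doc.get("discard_first", True)),
    )


# --------------------------------------------------------------------------
# particle frames (extended XYZ + sidecar)


def write_xyz_frames(
    xyz_path: str | Path, sidecar_path: str | Path, frames: Sequence[ParticleFrame]
) -> None:
    """Write frames as extended-XYZ blocks plus a role/species sidecar.

    Atom order within every frame: receptor, ions, waters, the two
    binding-site reference points.  The sidecar describes that order
    once (it must be identical across frames).
    """
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    roles = (
        ["receptor"] * first.receptor.shape[0]
        + ["ion"] * len(first.ion_species)
        + ["water"] * first.waters.shape[0]
        + ["site"] * 2
    )
    species = (
        ["REC"] * first.receptor.shape[0]
        + list(first.ion_species)
        + ["WAT"] * first.waters.shape[0]
        + ["SITE"] * 2
    )
    pd.DataFrame({"index": range(len(roles)), "role": roles, "species": species}).to_csv(
        sidecar_path, index=False
    )
    out = []
    for frame in frames:
        coords = np.vstack([frame.receptor, frame.ions.reshape(-1, 3), frame.waters, frame.sites])
        dip = np.zeros_like(coords)
        nw0 = frame.receptor.shape[0] + len(frame.ion_species)
        dip[nw0 : nw0 + frame.waters.shape[0]] = frame.water_dipoles
        out.append(str(coords.shape[0]))
        out.append("box= " + " ".join(repr(float(b)) for b in frame.box))
        for sp, xyz, mu in zip(species, coords, dip):
            out.append(
                f"{sp} " + " ".join(repr(float(v)) for v in xyz) + " " + " ".join(repr(float(v)) for v in mu)
            )
    Path(xyz_path).write_text("\n".join(out) + "\n")


def read_xyz_frames(
    xyz_path: str | Path, sidecar_path: str | Path
) -> list[ParticleFrame]:
    """Read frames written by :func:`write_xyz_frames`.

    Atom counts must be consistent across blocks and must match the
    sidecar; coordinates are wrapped into the box.
    """
    sidecar = pd.read_csv(sidecar_path)
    for col in ("index", "role", "species"):
        if col not in sidecar.columns:
            raise ValueError(f"{sidecar_path}: sidecar missing column {col!r}")
    roles = sidecar["role"].tolist()
    species = sidecar["species"].tolist()
    n_atoms = len(roles)

    lines = Path(xyz_path).read_text().splitlines()
    frames: list[ParticleFrame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        count = int(lines[pos].strip())
        if count != n_atoms:
            raise ValueError(
                f"{xyz_path}: frame {len(frames)}: {count} atoms but sidecar lists {n_atoms}"
            )
        comment = lines[pos + 1]
        if not comment.startswith("box="):
            raise ValueError(f"{xyz_path}: frame {len(frames)}: missing box in comment line")
        box = np.array([float(v) for v in comment.split("=", 1)[1].split()])
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise ValueError(f"{xyz_path}: truncated final frame")
        vals = np.array([[float(v) for v in ln.split()[1:7]] for ln in block])
        coords, dips = vals[:, :3], vals[:, 3:6]
        sel = {r: [i for i, role in enumerate(roles) if role == r] for r in
               ("receptor", "ion", "water", "site")}
        frames.append(
            ParticleFrame(
                receptor=coords[sel["receptor"]],
                ions=coords[sel["ion"]],
                ion_species=tuple(species[i] for i in sel["ion"]),
                waters=coords[sel["water"]],
                water_dipoles=dips[sel["water"]],
                box=box,
                sites=coords[sel["site"]],
            ).wrapped()
        )
        pos += 2 + count
    return frames


# --------------------------------------------------------------------------
# pipeline


def pipeline_run(config: RunConfig) -> dict:
    """Run the requested stages in dependency order and return a JSON-
    serializable report (fitted parameters, cooperativity, dG/dH/TdS
    tables and continuum values), stamped with version, seed and a
    config hash."""
    cfg_hash = hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:12]
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "stages": {},
    }
    experiment = None
    fit = None
    for stage in config.stages:
        logger.info("running stage %s", stage)
        if stage == "synth-itc":
            experiment = gen_itc_experiment(config.seed)
            report["stages"]["synth-itc"] = {
                "n_replicates": len(experiment.replicates),
                "n_injections": experiment.protocol.n_injections,
            }
        elif stage == "itc-fit":
            if experiment is None:
                experiment = gen_itc_experiment(config.seed)
            corrected = [
                subtract_dilution(rep, experiment.dilution)
                for rep in experiment.replicates
            ]
            init = SequentialParams(k1=50.0, k2=10.0, dh1=-2.0, dh2=-2.0)
            fit = fit_replicates(corrected, experiment.protocol, "sequential", init)
            p = fit.params
            report["stages"]["itc-fit"] = {
                "model": fit.model,
                "K1": p.k1,
                "K2": p.k2,
                "dH1": p.dh1,
                "dH2": p.dh2,
                "stderr": fit.stderr,
                "chi2_over_nu": fit.chi2_over_nu,
                "success": fit.success,
            }
        elif stage == "thermo":
            if fit is None:
                raise RuntimeError("thermo stage requires a prior itc-fit stage")
            p = fit.params
            t = config.temperature_K
            dg1 = delta_g_from_k(p.k1, t)
            dg2 = delta_g_from_k(p.k2, t)
            ddg = dg2 - dg1
            ddh = p.dh2 - p.dh1
            tds, _ = entropy_decomposition(ddg, ddh, t)
            report["stages"]["thermo"] = {
                "rho": cooperativity_rho(p.k1, p.k2).rho,
                "dG1": dg1,
                "dG2": dg2,
                "ddG": ddg,
                "ddH": ddh,
                "TddS": tds,
            }
        elif stage == "continuum":
            geom = IonPairGeometry(r=config.r_angstrom, temperature_K=config.temperature_K)
            g = g_plus_plus(geom, WATER)
            h = h_plus_plus(geom, WATER)
            tds, minus_tds = ts_plus_plus(geom, WATER)
            report["stages"]["continuum"] = {
                "G_plus_plus": g,
                "H_plus_plus": h,
                "TddS": tds,
                "minus_TddS": minus_tds,
                "bjerrum_A": bjerrum_length(config.temperature_K, WATER),
            }
    return report
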