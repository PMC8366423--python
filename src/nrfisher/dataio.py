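"""Readers, writers, configuration and built-in fixtures.

File conventions follow common reflectometry practice:

* reflectivity data: 3 or 4 whitespace/comma-delimited numeric columns
  (Q, R, dR[, dQ]); ``#`` starts a comment; the writer emits a
  self-describing header (angle, time, seed, whether raw counts back the
  uncertainties);
* flux profiles: two columns (wavelength Å, flux neutrons/s);
* model configs: YAML with SLDs given in the conventional 10⁻⁶ Å⁻² unit
  (``sld_e-6`` keys) and resolution as a percentage; everything is
  converted to true units (Å⁻², fractions) at this boundary and all
  internal arithmetic uses true units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .bilayer import BilayerParams
from .instrument import FluxProfile, MeasurementCondition, ReflectivityDataset
from .reflectivity import Layer, ReflectivityModel, Structure

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_flux_profile",
    "write_flux_profile",
    "load_model_config",
    "save_model_config",
    "load_bilayer_config",
    "load_run_config",
    "random_structure",
    "table1_model",
]

_SLD_UNIT = 1.0e-6  # config files carry SLDs in 10⁻⁶ Å⁻²


def _parse_numeric_rows(path):
    rows, header = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip().lower()] = val.strip()
                continue
            parts = stripped.replace(",", " ").split()
            try:
                rows.append(([float(p) for p in parts], lineno))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed row {stripped!r}") from err
    return rows, header


def read_dataset(path) -> ReflectivityDataset:
    """Read a (Q, R, dR[, dQ]) ASCII reflectivity file.

    Incident counts are reconstructed from the square-root-of-counts
    rule (s = R/dR², N = (R/dR)²) when the header declares
    ``counts: poisson``; otherwise they are flagged unavailable.
    Non-ascending Q is sorted with a warning.
    """
    rows, header = _parse_numeric_rows(path)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    widths = {len(vals) for vals, _ in rows}
    if not widths <= {3, 4}:
        bad = next(lineno for vals, lineno in rows if len(vals) not in (3, 4))
        raise ValueError(f"{path}:{bad}: expected 3 or 4 columns")
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.array([vals for vals, _ in rows])
    q, r, dr = data[:, 0], data[:, 1], data[:, 2]
    dq = data[:, 3] if data.shape[1] == 4 else None
    if np.any(dr < 0):
        bad = rows[int(np.argmax(dr < 0))][1]
        raise ValueError(f"{path}:{bad}: negative dR")
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: Q not strictly ascending; sorting")
        order = np.argsort(q, kind="stable")
        q, r, dr = q[order], r[order], dr[order]
        if dq is not None:
            dq = dq[order]

    incident = counts = None
    if header.get("counts", "").lower() == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            incident = np.where(dr > 0, r / dr**2, 0.0)
            counts = np.where(dr > 0, (r / dr) ** 2, 0.0)
    angle = float(header["angle"]) if "angle" in header else None
    time = float(header["time"]) if "time" in header else None
    return ReflectivityDataset(
        q=q, r=r, dr=dr, dq=dq, incident=incident, counts=counts,
        angle=angle, time=time, metadata=dict(header),
    )


def write_dataset(dataset: ReflectivityDataset, path, seed=None) -> None:
    """Write a dataset as self-describing (Q, R, dR[, dQ]) ASCII."""
    with open(path, "w") as fh:
        fh.write("# reflectivity dataset (Q / A^-1, R, dR%s)\n"
                 % (", dQ / A^-1" if dataset.dq is not None else ""))
        if dataset.angle is not None:
            fh.write(f"# angle: {dataset.angle}\n")
        if dataset.time is not None:
            fh.write(f"# time: {dataset.time}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if dataset.counts is not None:
            fh.write("# counts: poisson\n")
        cols = [dataset.q, dataset.r, dataset.dr]
        if dataset.dq is not None:
            cols.append(dataset.dq)
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")


def read_flux_profile(path, reference_angle: float = 0.3) -> FluxProfile:
    """Read a two-column (wavelength Å, flux) text file."""
    rows, header = _parse_numeric_rows(path)
    data = np.array([vals for vals, _ in rows])
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (wavelength, flux)")
    if "reference_angle" in header:
        reference_angle = float(header["reference_angle"])
    return FluxProfile(
        wavelengths=data[:, 0], flux=data[:, 1], reference_angle=reference_angle
    )


def write_flux_profile(flux: FluxProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# incident flux profile (wavelength / A, flux / n s^-1)\n")
        fh.write(f"# reference_angle: {flux.reference_angle}\n")
        for lam, phi in zip(flux.wavelengths, flux.flux):
            fh.write(f"{lam:.6f} {phi:.12e}\n")


def load_model_config(path) -> ReflectivityModel:
    """Load a layer-model YAML config into a ReflectivityModel."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    layers = [
        Layer(
            thickness=float(entry["thickness"]),
            sld=float(entry["sld_e-6"]) * _SLD_UNIT,
            roughness=float(entry.get("roughness", 0.0)),
        )
        for entry in cfg.get("structure", [])
    ]
    structure = Structure(
        fronting_sld=float(cfg.get("fronting_sld_e-6", 0.0)) * _SLD_UNIT,
        layers=layers,
        backing_sld=float(cfg["backing_sld_e-6"]) * _SLD_UNIT,
        backing_roughness=float(cfg.get("backing_roughness", 0.0)),
    )
    return ReflectivityModel(
        structure=structure,
        scale=float(cfg.get("scale", 1.0)),
        background=float(cfg.get("background", 0.0)),
        resolution_dq_q=float(cfg.get("resolution_dq_q_percent", 0.0)) / 100.0,
    )


def save_model_config(model: ReflectivityModel, path) -> None:
    cfg = {
        "fronting_sld_e-6": model.structure.fronting_sld / _SLD_UNIT,
        "structure": [
            {
                "thickness": l.thickness,
                "sld_e-6": l.sld / _SLD_UNIT,
                "roughness": l.roughness,
            }
            for l in model.structure.layers
        ],
        "backing_sld_e-6": model.structure.backing_sld / _SLD_UNIT,
        "backing_roughness": model.structure.backing_roughness,
        "scale": model.scale,
        "background": model.background,
        "resolution_dq_q_percent": model.resolution_dq_q * 100.0,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_bilayer_config(path) -> BilayerParams:
    """Load a bilayer YAML config (SLD-like fields in 10⁻⁶ Å⁻²)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    kwargs = {}
    for key, value in cfg.items():
        if key.endswith("_e-6"):
            kwargs[key[:-4]] = float(value) * _SLD_UNIT
        else:
            kwargs[key] = float(value)
    params = BilayerParams(**kwargs)
    params.validate()
    return params


@dataclass
class RunConfig:
    """One simulation/analysis run: model, flux, schedule, seed, outputs.

    ``model_config`` may be a YAML path or the name of a built-in model
    (``"table1"``); ``flux_path`` of ``None`` selects the synthetic flux
    profile.
    """

    model_config: str
    conditions: list
    flux_path: str | None = None
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.model_config != "table1" and not Path(self.model_config).exists():
            raise FileNotFoundError(f"model config not found: {self.model_config}")
        if self.flux_path is not None and not Path(self.flux_path).exists():
            raise FileNotFoundError(f"flux profile not found: {self.flux_path}")
        if not isinstance(self.seed, int):
            raise TypeError(f"seed must be an integer, got {self.seed!r}")
        if not self.conditions:
            raise ValueError("at least one measurement condition is required")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    conditions = [
        MeasurementCondition(
            angle=float(c["angle"]),
            time=float(c["time"]),
            n_points=int(c.get("n_points", 70)),
        )
        for c in cfg.get("conditions", [])
    ]
    run = RunConfig(
        model_config=str(cfg["model_config"]),
        conditions=conditions,
        flux_path=cfg.get("flux_path"),
        seed=int(cfg.get("seed", 0)),
        output_dir=str(cfg.get("output_dir", ".")),
        log_level=str(cfg.get("log_level", "INFO")),
    )
    run.validate()
    return run


SUBSTRATE_SLD = 2.047e-6  # Å⁻², silicon substrate used by the random fixtures


def random_structure(n_layers: int, seed=None) -> Structure:
    """Random test structure: uniform SLD/thickness/roughness per layer.

    Per layer: SLD ~ U[−1, 10]×10⁻⁶ Å⁻², thickness ~ U[20, 1000] Å,
    roughness ~ U[2, 8] Å, with an air fronting and a silicon backing of
    SLD 2.047×10⁻⁶ Å⁻² whose interfacial roughness is drawn from the
    same roughness distribution.
    """
    if not 1 <= n_layers <= 6:
        raise ValueError("n_layers must be between 1 and 6")
    rng = np.random.default_rng(seed)
    layers = [
        Layer(
            thickness=rng.uniform(20.0, 1000.0),
            sld=rng.uniform(-1.0, 10.0) * _SLD_UNIT,
            roughness=rng.uniform(2.0, 8.0),
        )
        for _ in range(n_layers)
    ]
    return Structure(
        fronting_sld=0.0,
        layers=layers,
        backing_sld=SUBSTRATE_SLD,
        backing_roughness=rng.uniform(2.0, 8.0),
    )


def table1_model() -> ReflectivityModel:
    """Built-in two-layer Si/Cu-on-quartz reference sample.

    The fitted thin-film heterostructure used throughout the examples:
    790.7 Å of Si (SLD 1.795×10⁻⁶ Å⁻², roughness 24.5 Å) over 297.9 Å of
    Cu (6.385×10⁻⁶ Å⁻², 3.50 Å) on a quartz substrate (3.354×10⁻⁶ Å⁻²,
    roughness 12.9 Å), with scale 0.783, background 8×10⁻⁷ and 2.5%
    dQ/Q resolution.
    """
    structure = Structure(
        fronting_sld=0.0,
        layers=[
            Layer(thickness=790.7, sld=1.795e-6, roughness=24.5),
            Layer(thickness=297.9, sld=6.385e-6, roughness=3.50),
        ],
        backing_sld=3.354e-6,
        backing_roughness=12.9,
    )
    return ReflectivityModel(
        structure=structure, scale=0.783, background=8.0e-7, resolution_dq_q=0.025
    )
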