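"""Supported DMPC-style lipid bilayer parameterized by solvent contrast.

A solid-supported phospholipid bilayer at the silicon/water interface,
described as Si | native SiO₂ | inner headgroups | tailgroups | outer
headgroups | bulk water.  The model is parameterized by the area per
molecule (APM) rather than per-layer volume fractions: with fixed
component molecular volumes V, each leaflet layer's thickness is V/APM,
so thickness and surface coverage stay mutually consistent as APM
varies.  Component dry SLDs are b/V from the (fixed) coherent
scattering lengths; each hydrated layer's SLD is mixed linearly towards
the bulk-water SLD by its total water volume fraction — water in
defects across the bilayer plus, for headgroups, water bound to the
hydrophilic headgroups.

Because every layer mixes with the *same* bulk-water SLD, the whole
structure is a function of the solvent contrast (−0.56×10⁻⁶ Å⁻² for
pure H₂O to 6.35×10⁻⁶ Å⁻² for pure D₂O), which makes contrast-variation
design scans possible: the same physical parameters generate one model
per solvent.

Component volumes and scattering lengths default to conventional
literature values for DMPC and are fixed (not fittable); they are
editable on construction for other lipids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fisher import Parameter, ParameterSet
from .reflectivity import Layer, ReflectivityModel, Structure

__all__ = [
    "SLD_H2O",
    "SLD_D2O",
    "BilayerParams",
    "BilayerReflectivityModel",
    "bilayer_structure",
    "contrast_sld_from_d2o_fraction",
    "bilayer_parameter_set",
]

SLD_H2O = -0.56e-6  # Å⁻², pure H2O
SLD_D2O = 6.35e-6  # Å⁻², pure D2O

# Fields that the fixed-molecular-volume assumption forbids freeing
FIXED_FIELDS = frozenset(
    {
        "si_sld",
        "sio2_sld",
        "headgroup_volume",
        "tailgroup_volume",
        "headgroup_scattering_length",
        "tailgroup_scattering_length",
    }
)


@dataclass
class BilayerParams:
    """Physical description of a supported bilayer plus its substrate.

    Lengths in Å, areas in Å², volumes in Å³, scattering lengths in Å,
    SLDs in Å⁻², hydrations as volume fractions in [0, 1].  Defaults are
    conventional literature values for a DMPC bilayer on silicon, not
    fitted ground truth.
    """

    # substrate
    si_sld: float = 2.047e-6
    sio2_sld: float = 3.41e-6
    sio2_thickness: float = 14.7
    sio2_hydration: float = 0.245
    sio2_roughness: float = 3.0
    # lipid, fixed molecular properties
    headgroup_volume: float = 320.9
    tailgroup_volume: float = 783.3
    headgroup_scattering_length: float = 6.41e-4
    tailgroup_scattering_length: float = -3.08e-4
    # fitted structural parameters
    area_per_molecule: float = 57.0
    headgroup_hydration: float = 0.27
    defect_hydration: float = 0.07
    bilayer_roughness: float = 6.5
    # bulk water
    contrast_sld: float = SLD_D2O

    def validate(self) -> None:
        for name in ("sio2_hydration", "headgroup_hydration", "defect_hydration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "sio2_thickness",
            "headgroup_volume",
            "tailgroup_volume",
            "area_per_molecule",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.headgroup_hydration + self.defect_hydration > 1.0:
            raise ValueError("total headgroup water fraction exceeds 1")

    @property
    def headgroup_thickness(self) -> float:
        return self.headgroup_volume / self.area_per_molecule

    @property
    def tailgroup_thickness(self) -> float:
        """Combined thickness of both leaflets' tails."""
        return 2.0 * self.tailgroup_volume / self.area_per_molecule


def _mix(dry_sld: float, water_fraction: float, solvent_sld: float) -> float:
    return (1.0 - water_fraction) * dry_sld + water_fraction * solvent_sld


def bilayer_structure(
    params: BilayerParams,
    contrast_sld: float | None = None,
    split_tails: bool = False,
) -> Structure:
    """Build the layer stack for one solvent contrast.

    ``contrast_sld`` overrides ``params.contrast_sld`` so several
    contrasts can share one parameter object.  With ``split_tails`` the
    two leaflets' tails form two identical layers instead of one merged
    layer (the SLD profile is unchanged; fringe bookkeeping only).
    """
    params.validate()
    solvent = params.contrast_sld if contrast_sld is None else contrast_sld

    head_dry = params.headgroup_scattering_length / params.headgroup_volume
    tail_dry = params.tailgroup_scattering_length / params.tailgroup_volume
    head_water = params.headgroup_hydration + params.defect_hydration
    head_sld = _mix(head_dry, head_water, solvent)
    tail_sld = _mix(tail_dry, params.defect_hydration, solvent)
    sio2_sld = _mix(params.sio2_sld, params.sio2_hydration, solvent)

    t_head = params.headgroup_thickness
    layers = [
        Layer(params.sio2_thickness, sio2_sld, params.sio2_roughness),
        Layer(t_head, head_sld, params.bilayer_roughness),
    ]
    if split_tails:
        t_tail = params.tailgroup_thickness / 2.0
        layers += [
            Layer(t_tail, tail_sld, params.bilayer_roughness),
            Layer(t_tail, tail_sld, params.bilayer_roughness),
        ]
    else:
        layers.append(
            Layer(params.tailgroup_thickness, tail_sld, params.bilayer_roughness)
        )
    layers.append(Layer(t_head, head_sld, params.bilayer_roughness))
    return Structure(
        fronting_sld=params.si_sld,
        layers=layers,
        backing_sld=solvent,
        backing_roughness=params.bilayer_roughness,
    )


@dataclass
class BilayerReflectivityModel:
    """Reflectivity model that rebuilds its structure from bilayer physics.

    Holds a (possibly shared) :class:`BilayerParams` plus per-contrast
    solvent SLD and instrumental dressing; the layer stack is derived
    afresh on every evaluation, so parameter changes on the shared
    physics object propagate to all contrasts.
    """

    bilayer: BilayerParams
    contrast_sld: float | None = None
    scale: float = 1.0
    background: float = 1.0e-6
    resolution_dq_q: float = 0.02
    split_tails: bool = False

    def as_reflectivity_model(self) -> ReflectivityModel:
        return ReflectivityModel(
            structure=bilayer_structure(
                self.bilayer, self.contrast_sld, self.split_tails
            ),
            scale=self.scale,
            background=self.background,
            resolution_dq_q=self.resolution_dq_q,
        )

    def reflectivity(self, q_values) -> np.ndarray:
        return self.as_reflectivity_model().reflectivity(q_values)


def contrast_sld_from_d2o_fraction(x: float) -> float:
    """Solvent SLD of an H₂O/D₂O mixture with D₂O volume fraction ``x``."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"D2O fraction must be in [0, 1], got {x}")
    return (1.0 - x) * SLD_H2O + x * SLD_D2O


# default fit bounds where a ±25% window is unphysical
_FRACTION_FIELDS = ("sio2_hydration", "headgroup_hydration", "defect_hydration")


def bilayer_parameter_set(params: BilayerParams, free_names) -> ParameterSet:
    """Free the named BilayerParams fields as one shared ParameterSet.

    Every returned parameter is bound to the single ``params`` object,
    so models for different contrasts built on that object share them —
    the joint multi-contrast Fisher information follows directly.
    Component volumes and scattering lengths cannot be freed: the
    parameterization assumes known, constant molecular volumes (the APM
    alone carries the structural freedom).
    """
    free_names = list(free_names)
    if not free_names:
        raise ValueError("free_names must name at least one parameter")
    out = []
    for name in free_names:
        if name in FIXED_FIELDS:
            raise ValueError(
                f"{name!r} is fixed: molecular volumes and scattering lengths are "
                "assumed known and constant; free area_per_molecule (and "
                "hydrations) instead"
            )
        if not hasattr(params, name):
            raise ValueError(f"BilayerParams has no field {name!r}")
        value = getattr(params, name)
        if name in _FRACTION_FIELDS:
            bounds = (max(0.0, value - 0.15), min(1.0, value + 0.15))
        else:
            bounds = (0.75 * value, 1.25 * value)
        out.append(Parameter(name=name, bindings=[(params, name)], bounds=bounds))
    return ParameterSet(out)
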