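"""Counting-statistics-faithful experiment simulation.

A time-of-flight reflectometer measures at a fixed angle θ and records
neutron events across its wavelength band; each wavelength maps to a
momentum transfer Q = 4π sin θ / λ and events are histogrammed into Q
bins.  Given the instrument's incident flux as a function of wavelength,
the expected number of incident neutrons in bin *i* over a counting time
τ is s_i = μ_i τ, where μ_i sums the flux of the wavelengths falling in
the bin.  The expected *reflected* count is s_i r_i with r_i the model
reflectivity at the bin centre, and the recorded count N_i is a Poisson
draw with that mean.  The reported reflectivity and its uncertainty are
N_i / s_i and sqrt(N_i) / s_i — the square-root-of-counts rule.

Collimation slits open proportionally to the measurement angle, so the
incident intensity at angle θ is the characterised profile scaled by
(θ/θ_ref)².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .reflectivity import ReflectivityModel, model_reflectivity

__all__ = [
    "FluxProfile",
    "MeasurementCondition",
    "ReflectivityDataset",
    "q_from_wavelength",
    "geometric_q_bins",
    "angle_intensity_factor",
    "simulate_measurement",
    "simulate_experiment",
    "synthetic_flux_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class FluxProfile:
    """Incident flux (neutrons s⁻¹ per wavelength bin) at a reference angle."""

    wavelengths: np.ndarray  # Å, strictly ascending
    flux: np.ndarray  # neutrons / s per wavelength entry
    reference_angle: float = 0.3  # degrees

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.wavelengths.size < 2:
            raise ValueError("flux profile needs at least 2 wavelength points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(self.flux < 0):
            raise ValueError("flux must be non-negative")
        if self.wavelengths.shape != self.flux.shape:
            raise ValueError("wavelengths and flux must have the same length")


@dataclass
class MeasurementCondition:
    """One angle/time/binning setting of a simulated measurement."""

    angle: float  # degrees
    time: float  # seconds
    n_points: int = 70
    q_bin_centres: np.ndarray | None = None  # optional explicit centres, Å⁻¹

    def __post_init__(self) -> None:
        if not 0 < self.angle < 90:
            raise ValueError(f"angle must be in (0, 90) degrees, got {self.angle}")
        if not self.time > 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass
class ReflectivityDataset:
    """One simulated (or loaded) reflectivity curve with its count bookkeeping.

    ``incident`` holds s_i, the expected incident neutrons per bin; where
    counts are available, ``r = counts / incident`` and
    ``dr = sqrt(counts) / incident`` hold exactly.
    """

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    incident: np.ndarray | None = None
    counts: np.ndarray | None = None
    dq: np.ndarray | None = None
    angle: float | None = None
    time: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if self.incident is not None:
            self.incident = np.asarray(self.incident, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if np.any(self.r < 0) or np.any(self.dr < 0):
            raise ValueError("reflectivity and uncertainty must be non-negative")

    def __len__(self) -> int:
        return self.q.size


def q_from_wavelength(wavelength, angle: float):
    """Momentum transfer Q = 4π sin θ / λ (λ in Å, θ in degrees, Q in Å⁻¹)."""
    lam = np.asarray(wavelength, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    return 4.0 * np.pi * np.sin(np.radians(angle)) / lam


def geometric_q_bins(q_min: float, q_max: float, n_bins: int):
    """Geometrically spaced bin edges and geometric-mean centres.

    Returns ``(edges, centres)`` with ``n_bins + 1`` edges in geometric
    progression from q_min to q_max; each centre is the geometric mean of
    its bounding edges.
    """
    if not (0 < q_min < q_max):
        raise ValueError(f"need 0 < q_min < q_max, got [{q_min}, {q_max}]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.geomspace(q_min, q_max, n_bins + 1)
    centres = np.sqrt(edges[:-1] * edges[1:])
    return edges, centres


def angle_intensity_factor(angle: float, reference_angle: float) -> float:
    """Slit-opening intensity scaling (θ/θ_ref)² between measurement angles."""
    if angle <= 0 or reference_angle <= 0:
        raise ValueError("angles must be > 0")
    return (angle / reference_angle) ** 2


def _bin_incident_rates(flux: FluxProfile, cond: MeasurementCondition):
    """Q-bin centres and per-bin incident rates μ_i (neutrons/s) at this angle.

    Each wavelength's flux is assigned wholly to the Q bin containing it
    (histogramming of time-of-flight events; no fractional splitting).
    """
    q_lambda = q_from_wavelength(flux.wavelengths, cond.angle)
    factor = angle_intensity_factor(cond.angle, flux.reference_angle)
    usable = flux.flux > 0
    if not np.any(usable):
        return np.array([]), np.array([])

    if cond.q_bin_centres is not None:
        centres = np.asarray(cond.q_bin_centres, dtype=float)
        inner = np.sqrt(centres[:-1] * centres[1:])
        edges = np.concatenate(
            ([centres[0] ** 2 / inner[0]] if centres.size > 1 else [centres[0] * 0.99],
             inner,
             [centres[-1] ** 2 / inner[-1]] if centres.size > 1 else [centres[-1] * 1.01])
        )
    else:
        q_lo, q_hi = q_lambda[usable].min(), q_lambda[usable].max()
        edges, centres = geometric_q_bins(q_lo, q_hi, cond.n_points)

    idx = np.searchsorted(edges, q_lambda, side="right") - 1
    idx = np.clip(idx, 0, len(centres) - 1)
    # points exactly on the top edge belong to the last bin
    inside = (q_lambda >= edges[0]) & (q_lambda <= edges[-1])
    mu = np.bincount(idx[inside], weights=flux.flux[inside], minlength=len(centres))
    return centres, mu * factor


def simulate_measurement(
    model: ReflectivityModel,
    flux: FluxProfile,
    cond: MeasurementCondition,
    seed=None,
) -> ReflectivityDataset:
    """Simulate one reflectivity measurement at a single angle.

    Per bin: s_i = μ_i τ expected incident neutrons, expected reflected
    count s_i r_i with r_i the model curve at the bin centre, observed
    count N_i ~ Poisson(s_i r_i).  Bins that receive no flux are dropped
    with a warning.  ``seed`` may be an int, a ``numpy`` Generator or a
    ``SeedSequence``; the same seed reproduces the dataset bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    centres, mu = _bin_incident_rates(flux, cond)
    if centres.size == 0:
        warnings.warn("flux profile carries no neutrons; empty dataset returned")
        return ReflectivityDataset(
            q=np.array([]), r=np.array([]), dr=np.array([]),
            incident=np.array([]), counts=np.array([]),
            angle=cond.angle, time=cond.time,
        )

    empty = mu == 0
    if np.any(empty):
        logger.warning(
            "%d of %d Q bins received no flux and were dropped", empty.sum(), mu.size
        )
        centres, mu = centres[~empty], mu[~empty]

    s = mu * cond.time
    r_model = model_reflectivity(centres, model)
    counts = rng.poisson(s * r_model).astype(float)
    return ReflectivityDataset(
        q=centres,
        r=counts / s,
        dr=np.sqrt(counts) / s,
        incident=s,
        counts=counts,
        angle=cond.angle,
        time=cond.time,
    )


def expected_counts(model: ReflectivityModel, flux: FluxProfile,
                    cond: MeasurementCondition) -> ReflectivityDataset:
    """Noise-free counterpart of :func:`simulate_measurement`.

    Counts are set to their expectation s_i r_i instead of a Poisson
    draw; used for deterministic Fisher-information calculations and
    zero-noise fitting checks.
    """
    centres, mu = _bin_incident_rates(flux, cond)
    empty = mu == 0
    centres, mu = centres[~empty], mu[~empty]
    s = mu * cond.time
    r_model = model_reflectivity(centres, model)
    counts = s * r_model
    return ReflectivityDataset(
        q=centres, r=r_model, dr=np.sqrt(counts) / s,
        incident=s, counts=counts, angle=cond.angle, time=cond.time,
    )


def simulate_experiment(
    models,
    flux: FluxProfile,
    conditions,
    seed=None,
    stitch: bool = False,
):
    """Simulate a full experiment: every model at every condition.

    Returns a list of datasets ordered model-major, condition-minor; each
    draws from an independent sub-stream of ``seed``.  With
    ``stitch=True`` the per-angle datasets of each model are additionally
    merged into one ascending-Q dataset (overlapping Q regions kept;
    ``metadata['angles']`` records each point's angle of origin); Fisher
    calculations should use the per-angle datasets, whose incident counts
    are exact.
    """
    models = list(np.atleast_1d(models))
    conditions = list(np.atleast_1d(conditions))
    if not models or not conditions:
        raise ValueError("need at least one model and one condition")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(models) * len(conditions))
    datasets = []
    for im, model in enumerate(models):
        per_angle = []
        for ic, cond in enumerate(conditions):
            ds = simulate_measurement(
                model, flux, cond, seed=streams[im * len(conditions) + ic]
            )
            per_angle.append(ds)
        if stitch:
            datasets.append(stitch_datasets(per_angle))
        else:
            datasets.extend(per_angle)
    return datasets


def stitch_datasets(datasets) -> ReflectivityDataset:
    """Merge per-angle datasets into one ascending-Q convenience view."""
    q = np.concatenate([d.q for d in datasets])
    order = np.argsort(q, kind="stable")
    angles = np.concatenate([np.full(len(d), d.angle, dtype=float) for d in datasets])
    out = ReflectivityDataset(
        q=_strictly_ascending(q[order]),
        r=np.concatenate([d.r for d in datasets])[order],
        dr=np.concatenate([d.dr for d in datasets])[order],
        incident=np.concatenate([d.incident for d in datasets])[order],
        counts=np.concatenate([d.counts for d in datasets])[order],
        metadata={"angles": angles[order], "stitched": True},
    )
    return out


def _strictly_ascending(q: np.ndarray) -> np.ndarray:
    # nudge exact duplicates so the ascending-Q invariant holds
    out = q.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = np.nextafter(out[i - 1], np.inf)
    return out


def synthetic_flux_profile(
    lambda_min: float = 1.0,
    lambda_max: float = 14.0,
    n: int = 1000,
    peak_wavelength: float = 3.0,
    total_flux: float = 5.0e5,
    reference_angle: float = 0.3,
) -> FluxProfile:
    """Smooth synthetic incident-flux profile for a time-of-flight source.

    A Maxwellian moderator spectrum, φ(λ) ∝ λ⁻⁵ exp[−(λ_c/λ)²] with the
    characteristic wavelength chosen so the peak sits at
    ``peak_wavelength``, normalised so the summed bin flux equals
    ``total_flux`` (neutrons/s at ``reference_angle``).  Stands in for a
    measured instrument flux table wherever one is not supplied.
    """
    if not lambda_min < lambda_max:
        raise ValueError("need lambda_min < lambda_max")
    lam = np.linspace(lambda_min, lambda_max, n)
    lam_c = peak_wavelength * np.sqrt(5.0 / 2.0)
    phi = lam**-5 * np.exp(-((lam_c / lam) ** 2))
    phi *= total_flux / phi.sum()
    return FluxProfile(wavelengths=lam, flux=phi, reference_angle=reference_angle)
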