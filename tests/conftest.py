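"""Shared fixtures and independent numerical oracles.

The oracle functions here are deliberately written from different
formulations than the library code they check: closed-form Fresnel and
one-layer interference expressions, and a Parratt recursion instead of
the characteristic-matrix product.
"""

import numpy as np
import pytest

import nrfisher as nf


# ---------------------------------------------------------------- oracles


def fresnel_oracle(q, rho_fronting, rho_backing, sigma=0.0):
    """Closed-form Fresnel reflectivity of a bare (rough) interface."""
    q = np.asarray(q, dtype=float)
    k0 = np.sqrt((q / 2.0) ** 2 + 0j)
    k1 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_backing - rho_fronting) + 0j)
    r = (k0 - k1) / (k0 + k1) * np.exp(-2.0 * k0 * k1 * sigma**2)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def one_layer_oracle(q, rho_f, rho_1, rho_b, thickness, sigma_top=0.0, sigma_bot=0.0):
    """Analytic single-layer interference formula (two-beam summation)."""
    q = np.asarray(q, dtype=float)
    k0 = np.sqrt((q / 2.0) ** 2 + 0j)
    k1 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_1 - rho_f) + 0j)
    k2 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_b - rho_f) + 0j)
    r01 = (k0 - k1) / (k0 + k1) * np.exp(-2.0 * k0 * k1 * sigma_top**2)
    r12 = (k1 - k2) / (k1 + k2) * np.exp(-2.0 * k1 * k2 * sigma_bot**2)
    phase = np.exp(2j * k1 * thickness)
    r = (r01 + r12 * phase) / (1.0 + r01 * r12 * phase)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def parratt_oracle(q, structure):
    """Parratt recursive reflectivity, backing-first (independent recursion)."""
    q = np.asarray(q, dtype=float)
    slds = structure.slds()
    thick = np.concatenate([[0.0], structure.thicknesses(), [0.0]])
    rough = structure.interface_roughnesses()
    k = np.sqrt(
        (q[:, None] / 2.0) ** 2 - 4.0 * np.pi * (slds[None, :] - slds[0]) + 0j
    )
    n_media = len(slds)
    r_tot = np.zeros_like(q, dtype=complex)
    for j in range(n_media - 2, -1, -1):
        kj, kj1 = k[:, j], k[:, j + 1]
        rf = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * rough[j] ** 2)
        phase = np.exp(2j * kj1 * thick[j + 1])
        r_tot = (rf + r_tot * phase) / (1.0 + rf * r_tot * phase)
    return np.clip(np.abs(r_tot) ** 2, 0.0, 1.0)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def flux():
    return nf.synthetic_flux_profile()


@pytest.fixture(scope="session")
def table1():
    return nf.table1_model()


@pytest.fixture(scope="session")
def two_angle_conditions():
    """Standard two-angle schedule: 0.7deg for 7.5 min, 2.0deg for 30 min."""
    return [
        nf.MeasurementCondition(angle=0.7, time=450.0, n_points=70),
        nf.MeasurementCondition(angle=2.0, time=1800.0, n_points=70),
    ]


def table1_parameter_set(model):
    """Thicknesses and SLDs of both films freed, +/-25% bounds."""
    layers = model.structure.layers
    out = []
    for i, layer in enumerate(layers, start=1):
        for field in ("thickness", "sld"):
            v = getattr(layer, field)
            out.append(
                nf.Parameter(
                    name=f"layer{i}_{field}",
                    bindings=[(layer, field)],
                    bounds=(0.75 * v, 1.25 * v),
                )
            )
    return nf.ParameterSet(out)


@pytest.fixture()
def table1_expected(table1, flux, two_angle_conditions):
    """Noise-free datasets for the reference sample at the standard schedule."""
    return [nf.expected_counts(table1, flux, c) for c in two_angle_conditions]


def one_layer_fixture(seed=7):
    """Seed-fixed single-layer sample with well-separated SLDs, plus free set."""
    structure = nf.random_structure(1, seed=seed)
    layer = structure.layers[0]
    model = nf.ReflectivityModel(
        structure, scale=1.0, background=1e-6, resolution_dq_q=0.02
    )
    params = nf.ParameterSet(
        [
            nf.Parameter(
                "thickness",
                [(layer, "thickness")],
                (0.75 * layer.thickness, 1.25 * layer.thickness),
            ),
            nf.Parameter("sld", [(layer, "sld")], (0.75 * layer.sld, 1.25 * layer.sld)),
            nf.Parameter(
                "roughness",
                [(layer, "roughness")],
                (0.75 * layer.roughness, 1.25 * layer.roughness),
            ),
        ]
    )
    return model, params
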