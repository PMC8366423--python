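"""Closed-form reflectivity oracles, independent of the library kernel."""

import numpy as np


def fresnel_oracle(q, rho_fronting, rho_backing, sigma=0.0):
    """Fresnel reflectivity of a bare interface with Gaussian roughness."""
    q = np.asarray(q, dtype=float)
    k0 = np.sqrt((q / 2.0) ** 2 + 0j)
    k1 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_backing - rho_fronting) + 0j)
    r = (k0 - k1) / (k0 + k1) * np.exp(-2.0 * k0 * k1 * sigma**2)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def one_layer_oracle(q, rho_f, rho_1, rho_b, thickness, sigma_top=0.0, sigma_bot=0.0):
    """Analytic single-layer interference reflectivity."""
    q = np.asarray(q, dtype=float)
    k0 = np.sqrt((q / 2.0) ** 2 + 0j)
    k1 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_1 - rho_f) + 0j)
    k2 = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho_b - rho_f) + 0j)
    r01 = (k0 - k1) / (k0 + k1) * np.exp(-2.0 * k0 * k1 * sigma_top**2)
    r12 = (k1 - k2) / (k1 + k2) * np.exp(-2.0 * k1 * k2 * sigma_bot**2)
    phase = np.exp(2j * k1 * thickness)
    r = (r01 + r12 * phase) / (1.0 + r01 * r12 * phase)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)
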