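"""Experimental-design analyses built on the Fisher information.

Four questions an experimenter can ask before (or during) beamtime:

* **How do uncertainties shrink with counting time?**  The FI matrix is
  linear in the incident counts, hence in time, so every Cramér–Rao
  uncertainty obeys ε ∝ τ^(−1/2): ln ε = ln α − ½ ln τ.
  :func:`uncertainty_vs_time` verifies and exploits this, enabling
  projection of uncertainties to future counting times and early
  stopping decisions.
* **Which solvent contrast should I measure (next)?**
  :func:`contrast_scan` computes the per-parameter FI across a grid of
  bulk-water SLDs, optionally jointly with contrasts already measured.
* **Is my fitted estimator biased?**  :func:`estimate_fit_bias` repeats
  simulate-and-fit cycles and compares the mean fit to the truth.
* **Does simulated data match measured data?**  :func:`compare_datasets`
  runs a Hotelling t² test on Anscombe variance-stabilised counts.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .bilayer import BilayerParams, BilayerReflectivityModel, bilayer_parameter_set
from .fisher import ParameterSet, fisher_matrix, fit_model
from .instrument import (
    FluxProfile,
    MeasurementCondition,
    expected_counts,
    simulate_experiment,
)

__all__ = [
    "TimeScanResult",
    "ContrastScanResult",
    "uncertainty_vs_time",
    "fit_loglog_slope",
    "contrast_scan",
    "estimate_fit_bias",
    "compare_datasets",
    "anscombe",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeScanResult:
    """Per-parameter FI uncertainties across a ladder of time multipliers."""

    time_factors: np.ndarray  # strictly ascending, > 0
    parameter_names: list
    uncertainties: np.ndarray  # (n_factors, M)
    slopes: np.ndarray  # (M,) fitted d ln eps / d ln tau
    intercepts: np.ndarray  # (M,) ln alpha

    def projected_uncertainty(self, name: str, time_factor: float) -> float:
        """ε predicted from the fitted power law at an arbitrary multiplier."""
        j = self.parameter_names.index(name)
        return float(
            np.exp(self.intercepts[j] + self.slopes[j] * np.log(time_factor))
        )


def fit_loglog_slope(times, uncertainties):
    """OLS slope and intercept of ln ε against ln τ."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(uncertainties, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(t <= 0) or np.any(e <= 0):
        raise ValueError("times and uncertainties must be positive")
    slope, intercept = np.polyfit(np.log(t), np.log(e), 1)
    return float(slope), float(intercept)


def _expected_datasets(models, flux, conditions):
    """Noise-free datasets for every (model, condition) pair, paired model list."""
    paired_models, datasets = [], []
    for m in models:
        for c in conditions:
            datasets.append(expected_counts(_dressed(m), flux, c))
            paired_models.append(m)
    return paired_models, datasets


def _dressed(model):
    # BilayerReflectivityModel and ReflectivityModel both expose .reflectivity;
    # expected_counts only needs that plus the dressing fields it reads via
    # model_reflectivity, so convert bilayer models explicitly.
    return model.as_reflectivity_model() if hasattr(model, "as_reflectivity_model") else model


def uncertainty_vs_time(
    models,
    flux: FluxProfile,
    base_conditions,
    time_factors,
    params: ParameterSet,
) -> TimeScanResult:
    """Deterministic FI uncertainties as every condition time is scaled.

    For each factor c the full schedule's times are multiplied by c and
    the Cramér–Rao uncertainties recomputed from model reflectances (no
    noise is drawn).  A log-log regression per parameter returns the
    scaling exponent, which the Poisson FI fixes at −½ exactly.
    """
    factors = np.asarray(time_factors, dtype=float)
    if np.any(factors <= 0) or np.any(np.diff(factors) <= 0):
        raise ValueError("time_factors must be positive and strictly ascending")
    models = list(np.atleast_1d(models))
    base_conditions = list(np.atleast_1d(base_conditions))
    eps = np.empty((factors.size, len(params)))
    for i, c in enumerate(factors):
        conds = [replace(cond, time=cond.time * c) for cond in base_conditions]
        paired, datasets = _expected_datasets(models, flux, conds)
        eps[i] = fisher_matrix(paired, datasets, params).uncertainties
    slopes = np.empty(len(params))
    intercepts = np.empty(len(params))
    for j in range(len(params)):
        slopes[j], intercepts[j] = fit_loglog_slope(factors, eps[:, j])
    return TimeScanResult(
        time_factors=factors,
        parameter_names=params.names,
        uncertainties=eps,
        slopes=slopes,
        intercepts=intercepts,
    )


@dataclass
class ContrastScanResult:
    """Per-parameter FI across candidate solvent contrasts."""

    contrasts: np.ndarray  # Å⁻² grid
    parameter_names: list
    fi_diagonal: np.ndarray  # (n_grid, M), nats per parameter-unit²
    prior_contrasts: list
    conditions: list

    def minimum_contrast(self, name: str) -> float:
        """Grid contrast at which a parameter's FI is smallest."""
        j = self.parameter_names.index(name)
        return float(self.contrasts[np.argmin(self.fi_diagonal[:, j])])


def contrast_scan(
    bilayer: BilayerParams,
    contrasts,
    flux: FluxProfile,
    conditions,
    free_names,
    prior_contrasts=(),
    scale: float = 1.0,
    background: float = 1.0e-6,
    resolution_dq_q: float = 0.02,
) -> ContrastScanResult:
    """Per-parameter FI for each candidate bulk-water contrast.

    For every grid SLD a model set is built from the already-measured
    contrasts (``prior_contrasts``) plus the candidate, all sharing one
    set of bilayer parameters; the joint FI diagonal is recorded.  An
    empty prior list scores an initial contrast choice; seeding it with
    the D₂O SLD scores the second choice.  Deterministic (model
    reflectances and expected counts only).
    """
    grid = np.asarray(contrasts, dtype=float)
    conditions = list(np.atleast_1d(conditions))
    prior_contrasts = list(prior_contrasts)
    fi = np.empty((grid.size, len(list(free_names))))
    names = None
    for i, candidate in enumerate(grid):
        work = copy.deepcopy(bilayer)
        params = bilayer_parameter_set(work, free_names)
        names = params.names
        models = [
            BilayerReflectivityModel(
                work, contrast_sld=sld, scale=scale,
                background=background, resolution_dq_q=resolution_dq_q,
            )
            for sld in prior_contrasts + [candidate]
        ]
        paired, datasets = _expected_datasets(models, flux, conditions)
        fi[i] = np.diag(fisher_matrix(paired, datasets, params).g)
    return ContrastScanResult(
        contrasts=grid,
        parameter_names=names,
        fi_diagonal=fi,
        prior_contrasts=prior_contrasts,
        conditions=conditions,
    )


@dataclass
class FitBiasResult:
    parameter_names: list
    true_values: np.ndarray
    bias: np.ndarray
    standard_error: np.ndarray
    n_replicates: int
    n_failures: int


def estimate_fit_bias(
    models,
    flux: FluxProfile,
    conditions,
    params: ParameterSet,
    n_replicates: int = 50,
    seed=None,
    noiseless: bool = False,
    **fit_options,
) -> FitBiasResult:
    """Bias of the fitted estimator over repeated simulated experiments.

    Each replicate simulates a fresh noisy experiment from the current
    (true) parameter values and refits from scratch; the bias is the
    mean fitted value minus the truth, with its standard error.  More
    than 10% replicate failures aborts.  With ``noiseless=True`` the
    counts are set to their expectation instead of Poisson draws, which
    isolates optimiser error from counting noise.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    models = list(np.atleast_1d(models))
    conditions = list(np.atleast_1d(conditions))
    truth = params.values.copy()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_replicates)
    fitted, failures = [], 0
    try:
        for rep in range(n_replicates):
            params.values = truth
            sim_seed, fit_seed = streams[rep].spawn(2)
            if noiseless:
                datasets = [
                    expected_counts(_dressed(m), flux, c)
                    for m in models
                    for c in conditions
                ]
            else:
                datasets = simulate_experiment(
                    [_dressed(m) for m in models], flux, conditions, seed=sim_seed
                )
            paired = [m for m in models for _ in conditions]
            try:
                res = fit_model(datasets, paired, params, seed=fit_seed, **fit_options)
                fitted.append(res.values)
            except Exception as err:  # pragma: no cover - defensive
                failures += 1
                logger.warning("replicate %d fit failed: %s", rep, err)
                if failures > 0.1 * n_replicates:
                    raise RuntimeError(
                        f"{failures} of {rep + 1} replicate fits failed"
                    ) from err
    finally:
        params.values = truth
    fitted = np.asarray(fitted)
    bias = fitted.mean(axis=0) - truth
    se = fitted.std(axis=0, ddof=1) / np.sqrt(fitted.shape[0])
    return FitBiasResult(
        parameter_names=params.names,
        true_values=truth,
        bias=bias,
        standard_error=se,
        n_replicates=n_replicates,
        n_failures=failures,
    )


def anscombe(counts):
    """Anscombe variance-stabilising transform of Poisson counts, 2√(N + 3/8)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return 2.0 * np.sqrt(counts + 3.0 / 8.0)


def compare_datasets(datasets_a, datasets_b):
    """Hotelling t² comparison of two experiments' counting statistics.

    ``datasets_a`` and ``datasets_b`` are matched per-angle dataset lists
    (same angles, same binning, same number of bins per angle).  Counts
    are Anscombe transformed; the per-bin paired differences form one
    p-variate observation per bin (one variate per angle) and a
    one-sample Hotelling t² tests whether the mean difference vector is
    zero, with p-value from the exact F reference distribution.
    Returns ``(t2, p_value)``.
    """
    a = list(np.atleast_1d(datasets_a))
    b = list(np.atleast_1d(datasets_b))
    if len(a) != len(b):
        raise ValueError("experiments have different numbers of angle datasets")
    diffs = []
    for da, db in zip(a, b):
        if len(da) != len(db) or not np.allclose(da.q, db.q, rtol=1e-10):
            raise ValueError("datasets do not share the same Q bins")
        if da.counts is None or db.counts is None:
            raise ValueError("both datasets need raw counts for the Anscombe test")
        diffs.append(anscombe(da.counts) - anscombe(db.counts))
    n_bins = {d.size for d in diffs}
    if len(n_bins) != 1:
        raise ValueError("angle datasets must share a common number of bins")
    D = np.column_stack(diffs)  # (n, p): bins x angles
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need more bins ({n}) than angle datasets ({p})")
    dbar = D.mean(axis=0)
    if np.allclose(D, 0.0):
        return 0.0, 1.0
    S = np.cov(D, rowvar=False).reshape(p, p)
    t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    f_stat = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_stat, p, n - p))
    return t2, p_value
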