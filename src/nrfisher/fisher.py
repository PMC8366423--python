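"""Fisher information of Poisson-counted reflectivity data.

With per-bin incident counts s_i and model reflectivities r_i(ξ), the
observed counts are independent Poisson variables with means s_i r_i.
The Fisher-information matrix of the M model parameters ξ is then

    g = Jᵀ M J,

where J is the N×M Jacobian ∂r_i/∂ξ_j and M = diag(s_i / r_i).  The
inverse of g bounds the parameter covariance (Cramér–Rao), so parameter
uncertainties follow as ε_j = sqrt((g⁻¹)_jj) and pairwise k-sigma
confidence ellipses from 2×2 blocks of g⁻¹.  g is also the quadratic
form of the leading term of the Kullback–Leibler divergence between the
count distributions at nearby parameter vectors,
D(ξ ‖ ξ+Δ) ≈ ½ Δᵀ g Δ; the exact Poisson KL divergence implemented here
serves as an independent check of the whole construction.

Parameters are bound by reference to attributes of model objects (a
layer thickness, a bilayer's area per molecule, ...), so one parameter
may be shared across several models — the joint multi-dataset FI then
falls out of concatenating bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize

__all__ = [
    "Parameter",
    "ParameterSet",
    "FisherAnalysis",
    "ConfidenceEllipse",
    "jacobian",
    "fisher_matrix",
    "kl_divergence_counts",
    "poisson_kl",
    "parameter_uncertainties",
    "confidence_ellipse",
    "negative_log_likelihood",
    "fit_model",
    "mh_sampler_oracle",
]

logger = logging.getLogger(__name__)

# relative finite-difference step for the Jacobian
FD_RELATIVE_STEP = 0.005
# condition number beyond which g is treated as singular
CONDITION_LIMIT = 1e10


class SingularFisherMatrix(np.linalg.LinAlgError):
    """Raised when g is too ill-conditioned to invert meaningfully."""


@dataclass
class Parameter:
    """A named scalar bound to one or more ``(object, attribute)`` targets.

    All bindings are written on assignment, so a parameter listed once
    but bound into several models is genuinely shared between them.
    """

    name: str
    bindings: list  # [(obj, attr), ...]
    bounds: tuple | None = None

    def __post_init__(self) -> None:
        if not self.bindings:
            raise ValueError(f"parameter {self.name!r} has no bindings")
        for obj, attr in self.bindings:
            if not hasattr(obj, attr):
                raise AttributeError(f"{obj!r} has no attribute {attr!r}")

    @property
    def value(self) -> float:
        return float(getattr(*self.bindings[0]))

    @value.setter
    def value(self, v: float) -> None:
        for obj, attr in self.bindings:
            setattr(obj, attr, float(v))


class ParameterSet:
    """Ordered collection of free parameters with bounds."""

    def __init__(self, parameters):
        self.parameters = list(parameters)
        if not self.parameters:
            raise ValueError("a ParameterSet needs at least one parameter")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    def __len__(self) -> int:
        return len(self.parameters)

    def __iter__(self):
        return iter(self.parameters)

    def __getitem__(self, key):
        if isinstance(key, str):
            for p in self.parameters:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.parameters[key]

    @property
    def names(self):
        return [p.name for p in self.parameters]

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters])

    @values.setter
    def values(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.size != len(self):
            raise ValueError("value vector length mismatch")
        for p, v in zip(self.parameters, values):
            p.value = v

    @property
    def bounds(self):
        return [p.bounds for p in self.parameters]


def _concat_model_reflectivity(models, datasets) -> np.ndarray:
    """Concatenated model curves, one model evaluated per dataset's Q grid."""
    return np.concatenate(
        [np.asarray(m.reflectivity(d.q)) for m, d in zip(models, datasets)]
    )


def jacobian(models, datasets, params: ParameterSet) -> np.ndarray:
    """Central finite-difference Jacobian of the concatenated reflectances.

    Column j perturbs parameter ξ_j by ±0.5% of its value (an absolute
    step of 0.5% of the bound width when the value is zero) and differences
    the full concatenated model curve.  Rows span the bins of all
    datasets, in order.
    """
    models, datasets = _as_pairs(models, datasets)
    n_rows = sum(len(d) for d in datasets)
    J = np.empty((n_rows, len(params)))
    for j, p in enumerate(params):
        x0 = p.value
        if x0 != 0.0:
            step = FD_RELATIVE_STEP * abs(x0)
        elif p.bounds is not None:
            step = FD_RELATIVE_STEP * (p.bounds[1] - p.bounds[0])
        else:
            raise ValueError(
                f"parameter {p.name!r} is zero and unbounded: no finite-difference "
                "step can be formed"
            )
        try:
            p.value = x0 + step
            r_hi = _concat_model_reflectivity(models, datasets)
            p.value = x0 - step
            r_lo = _concat_model_reflectivity(models, datasets)
        except Exception as err:
            raise RuntimeError(
                f"model evaluation failed while perturbing {p.name!r}: {err}"
            ) from err
        finally:
            p.value = x0
        J[:, j] = (r_hi - r_lo) / (2.0 * step)
    return J


@dataclass
class FisherAnalysis:
    """Result bundle: Jacobian, FI matrix and derived uncertainty measures."""

    parameters: ParameterSet
    jacobian: np.ndarray  # N x M
    counts_ratio: np.ndarray  # diagonal of M, s_i / r_i, length N
    g: np.ndarray  # M x M, nats per parameter-unit^2
    _covariance: np.ndarray | None = field(default=None, repr=False)

    @property
    def covariance(self) -> np.ndarray:
        if self._covariance is None:
            self._covariance = _invert_fisher(self.g, self.parameters.names)
        return self._covariance

    @property
    def uncertainties(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def report(self) -> str:
        """Human-readable parameter table (name, value, ε, FI diagonal)."""
        eps = self.uncertainties
        lines = [f"{'parameter':<28}{'value':>14}{'epsilon':>14}{'FI diag':>14}"]
        for name, v, e, gd in zip(
            self.parameters.names, self.parameters.values, eps, np.diag(self.g)
        ):
            lines.append(f"{name:<28}{v:>14.6g}{e:>14.6g}{gd:>14.6g}")
        return "\n".join(lines)


def _as_pairs(models, datasets):
    models = list(np.atleast_1d(models))
    datasets = list(np.atleast_1d(datasets))
    if len(models) == 1 and len(datasets) > 1:
        models = models * len(datasets)
    if len(models) != len(datasets):
        raise ValueError("need one model per dataset (or a single shared model)")
    return models, datasets


def fisher_matrix(models, datasets, params: ParameterSet) -> FisherAnalysis:
    """FI matrix g = Jᵀ M J over the concatenated bins of all datasets.

    Uses *model* reflectances and expected incident counts only, so the
    result is independent of any particular noise realisation.  Every
    model reflectance must be positive (an additive background > 0
    guarantees this at high Q).
    """
    models, datasets = _as_pairs(models, datasets)
    for d in datasets:
        if d.incident is None:
            raise ValueError("datasets must carry per-bin incident counts")
    r = _concat_model_reflectivity(models, datasets)
    if np.any(r <= 0):
        raise ValueError(
            "model reflectance <= 0 in some bin; the Poisson rate s_i r_i must be "
            "positive (set a nonzero background)"
        )
    s = np.concatenate([np.asarray(d.incident, dtype=float) for d in datasets])
    n, m = r.size, len(params)
    if n < m:
        warnings.warn(
            f"fewer bins ({n}) than parameters ({m}); g will be singular"
        )
    J = jacobian(models, datasets, params)
    ratio = s / r
    g = J.T @ (ratio[:, None] * J)
    g = 0.5 * (g + g.T)  # enforce exact symmetry
    return FisherAnalysis(parameters=params, jacobian=J, counts_ratio=ratio, g=g)


def poisson_kl(lam_a, lam_b) -> float:
    """Exact KL divergence D(a‖b) between independent Poisson count vectors."""
    lam_a = np.asarray(lam_a, dtype=float)
    lam_b = np.asarray(lam_b, dtype=float)
    if np.any(lam_a <= 0) or np.any(lam_b <= 0):
        raise ValueError("Poisson rates must be positive")
    return float(np.sum(lam_a * np.log(lam_a / lam_b) - lam_a + lam_b))


def kl_divergence_counts(models, datasets, params: ParameterSet, values_other) -> float:
    """Exact Poisson KL divergence D(ξ ‖ ξ′) between the count distributions.

    ξ is the parameters' current value vector and ξ′ = ``values_other``;
    rates are λ_i = s_i r_i(ξ).  Serves as the brute-force oracle for the
    quadratic form ½ Δᵀ g Δ.
    """
    models, datasets = _as_pairs(models, datasets)
    s = np.concatenate([np.asarray(d.incident, dtype=float) for d in datasets])
    x0 = params.values
    try:
        lam_a = s * _concat_model_reflectivity(models, datasets)
        params.values = values_other
        lam_b = s * _concat_model_reflectivity(models, datasets)
    finally:
        params.values = x0
    return poisson_kl(lam_a, lam_b)


def _invert_fisher(g: np.ndarray, names) -> np.ndarray:
    # precondition by the diagonal so that the condition number measures
    # genuine parameter degeneracy, not unit disparity (SLDs in A^-2 sit
    # ~12 orders of magnitude below thicknesses in A)
    d = np.sqrt(np.diag(g))
    dead = d <= 0
    if np.any(dead):
        raise SingularFisherMatrix(
            "no information about parameter(s): "
            + ", ".join(n for n, z in zip(names, dead) if z)
        )
    g_hat = g / np.outer(d, d)
    evals, evecs = np.linalg.eigh(g_hat)
    cond = evals[-1] / evals[0] if evals[0] > 0 else np.inf
    logger.debug("Fisher matrix condition number (scaled): %.3g", cond)
    if cond > CONDITION_LIMIT:
        weights = evecs[:, 0]
        worst = ", ".join(
            f"{n} ({w:+.2f})" for n, w in zip(names, weights) if abs(w) > 0.1
        )
        raise SingularFisherMatrix(
            f"Fisher matrix is singular to working precision (condition "
            f"{cond:.2g}); degenerate parameter combination: {worst}"
        )
    cov_hat = (evecs / evals) @ evecs.T
    return cov_hat / np.outer(d, d)


def parameter_uncertainties(g: np.ndarray, names=None) -> np.ndarray:
    """Cramér–Rao uncertainties ε_j = sqrt((g⁻¹)_jj)."""
    g = np.asarray(g, dtype=float)
    if names is None:
        names = [f"p{j}" for j in range(g.shape[0])]
    return np.sqrt(np.diag(_invert_fisher(g, names)))


@dataclass
class ConfidenceEllipse:
    """k-sigma confidence ellipse for one parameter pair."""

    pair: tuple
    k: float
    centre: np.ndarray
    covariance: np.ndarray  # 2x2 marginal block
    semi_axes: np.ndarray  # lengths, descending
    axis_directions: np.ndarray  # columns are unit vectors

    def boundary(self, n_points: int = 100) -> np.ndarray:
        """Closed (n_points, 2) curve satisfying (x-c)ᵀ C⁻¹ (x-c) = k²."""
        t = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.stack([np.cos(t), np.sin(t)])
        pts = (self.axis_directions * self.semi_axes) @ circle
        return (self.centre[:, None] + pts).T


def confidence_ellipse(
    analysis: FisherAnalysis, i, j, k: float = 1.0, conditional: bool = False
) -> ConfidenceEllipse:
    """Pairwise k-sigma ellipse from the (i, j) covariance block.

    By default uses the *marginal* 2×2 block of g⁻¹ (what a corner plot's
    2-D marginal shows); ``conditional=True`` instead inverts the (i, j)
    block of g, giving the ellipse with every other parameter held fixed.
    """
    names = analysis.parameters.names
    i = names.index(i) if isinstance(i, str) else i
    j = names.index(j) if isinstance(j, str) else j
    if i == j:
        raise ValueError("need two distinct parameters")
    idx = np.array([i, j])
    if conditional:
        block = np.linalg.inv(analysis.g[np.ix_(idx, idx)])
    else:
        block = analysis.covariance[np.ix_(idx, idx)]
    evals, evecs = np.linalg.eigh(block)
    if np.any(evals <= 0):
        raise SingularFisherMatrix("covariance block is not positive definite")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return ConfidenceEllipse(
        pair=(names[i], names[j]),
        k=float(k),
        centre=analysis.parameters.values[idx],
        covariance=block,
        semi_axes=k * np.sqrt(evals),
        axis_directions=evecs,
    )


def negative_log_likelihood(dataset, model) -> float:
    """Gaussian negative log-likelihood of a dataset under a model curve.

    ½ Σ_i [((r_i − r_model,i)/δr_i)² + ln(2π δr_i²)]; smaller is better.
    """
    dr = np.asarray(dataset.dr, dtype=float)
    if np.any(dr <= 0):
        raise ValueError("every data point needs a positive uncertainty")
    resid = (np.asarray(dataset.r) - np.asarray(model.reflectivity(dataset.q))) / dr
    return float(0.5 * np.sum(resid**2 + np.log(2.0 * np.pi * dr**2)))


def _drop_zero_uncertainty(datasets):
    """Remove zero-count bins (dr = 0), which carry no Gaussian likelihood."""
    out = []
    n_dropped = 0
    for d in datasets:
        keep = np.asarray(d.dr) > 0
        if np.all(keep):
            out.append(d)
            continue
        n_dropped += int((~keep).sum())
        out.append(
            type(d)(
                q=d.q[keep], r=d.r[keep], dr=d.dr[keep],
                incident=None if d.incident is None else d.incident[keep],
                counts=None if d.counts is None else d.counts[keep],
                angle=d.angle, time=d.time,
            )
        )
    if n_dropped:
        logger.warning("excluded %d zero-count bins from the likelihood", n_dropped)
    return out


def _total_nll(x, models, datasets, params) -> float:
    params.values = x
    return sum(negative_log_likelihood(d, m) for m, d in zip(models, datasets))


@dataclass
class FitResult:
    parameters: ParameterSet
    values: np.ndarray
    objective: float
    success: bool
    message: str
    n_evaluations: int


def fit_model(
    datasets,
    models,
    params: ParameterSet,
    seed=None,
    maxiter: int = 150,
    popsize: int = 15,
    tol: float = 0.005,
    polish: bool = True,
) -> FitResult:
    """Fit free parameters by bounded differential evolution.

    Minimises the summed negative log-likelihood over all datasets.
    Bounds must be finite on every parameter; the optimiser is
    population-based, bound-respecting and reproducible for a fixed
    ``seed``.  On non-convergence the best-so-far values are still
    written back to ``params`` and reported, with ``success=False``.
    """
    models, datasets = _as_pairs(models, datasets)
    datasets = _drop_zero_uncertainty(datasets)
    bounds = params.bounds
    if any(b is None or not np.all(np.isfinite(b)) for b in bounds):
        raise ValueError("every free parameter needs finite bounds")
    rng = np.random.default_rng(seed)
    result = differential_evolution(
        _total_nll,
        bounds,
        args=(models, datasets, params),
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        polish=False,
        init="sobol",
        seed=rng,
    )
    if polish:
        # tight local refinement in bound-normalised coordinates (parameter
        # magnitudes span ~12 orders, so absolute finite-difference steps
        # would be useless); DE's built-in polish stops too early for
        # uncertainty-scale accuracy
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        span = hi - lo
        refined = minimize(
            lambda z: _total_nll(lo + z * span, models, datasets, params),
            (result.x - lo) / span,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(bounds),
            options={"ftol": 1e-15, "gtol": 1e-12, "eps": 1e-10, "maxiter": 500},
        )
        if refined.fun <= result.fun:
            result.x, result.fun = lo + refined.x * span, refined.fun
            result.nfev += refined.nfev
    params.values = result.x
    if not result.success:
        logger.warning("fit did not converge: %s", result.message)
    return FitResult(
        parameters=params,
        values=result.x.copy(),
        objective=float(result.fun),
        success=bool(result.success),
        message=str(result.message),
        n_evaluations=int(result.nfev),
    )


def mh_sampler_oracle(
    datasets,
    models,
    params: ParameterSet,
    n_steps: int = 100_000,
    seed=None,
    burn_fraction: float = 0.3,
):
    """Random-walk Metropolis–Hastings posterior sample (test utility).

    Targets the Gaussian likelihood times a uniform prior spanning each
    parameter's bounds.  During burn-in only, per-parameter proposal
    scales adapt to the spread of the recent chain history and a global
    factor steers the acceptance rate towards ~30%; the scales are then
    frozen, keeping the retained chain Markovian.  Returns
    ``(samples, sd)`` with ``samples`` of shape (n_kept, M).
    """
    models, datasets = _as_pairs(models, datasets)
    datasets = _drop_zero_uncertainty(datasets)
    bounds = np.asarray(params.bounds, dtype=float)
    if bounds.ndim != 2 or np.any(~np.isfinite(bounds)):
        raise ValueError("every parameter needs finite bounds for the uniform prior")
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)
    x = params.values.copy()
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("starting values outside prior bounds")
    scales = (hi - lo) / 50.0
    n_burn = int(burn_fraction * n_steps)

    x0 = params.values.copy()
    try:
        logp = -_total_nll(x, models, datasets, params)
        kept = []
        history = []
        accepted = accepted_total = 0
        window = 500
        for step in range(n_steps):
            prop = x + scales * rng.standard_normal(x.size)
            if np.all(prop >= lo) & np.all(prop <= hi):
                logp_prop = -_total_nll(prop, models, datasets, params)
                if np.log(rng.random()) < logp_prop - logp:
                    x, logp = prop, logp_prop
                    accepted += 1
                    accepted_total += 1
            if step < n_burn:
                history.append(x.copy())
                if (step + 1) % window == 0:
                    rate = accepted / window
                    recent = np.asarray(history[-window:])
                    spread = recent.std(axis=0)
                    # re-aim each scale at the local posterior width, with
                    # a global factor steering the acceptance rate
                    mask = spread > 0
                    scales[mask] = 2.4 / np.sqrt(x.size) * spread[mask]
                    scales *= np.exp(1.5 * (rate - 0.3))
                    accepted = 0
            else:
                kept.append(x.copy())
    finally:
        params.values = x0

    samples = np.asarray(kept)
    rate_total = accepted_total / n_steps
    if not 0.05 <= rate_total <= 0.8:
        warnings.warn(
            f"MH acceptance rate {rate_total:.3f} outside [0.05, 0.8]; "
            "posterior summaries may be unreliable"
        )
    return samples, samples.std(axis=0, ddof=1)
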