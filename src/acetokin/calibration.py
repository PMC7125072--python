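"""Bayesian MCMC calibration of kinetic models to batch time courses.

The objective is the sum of normalised squared differences between model
prediction and observation: each residual is divided by the observation's
standard deviation when one is available (the error bars of replicated
experiments), otherwise by the mean of that variable over the time course,
which makes mM metabolite residuals and g L^-1 biomass residuals
commensurable.  Sampling uses adaptive-covariance random-walk Metropolis on
log-transformed parameters (all kinetic parameters are positive and span
orders of magnitude), with flat priors on the log scale within configurable
bounds and covariance adaptation frozen after burn-in.  "95% confidence
interval" is reported as the central 95% posterior credible interval; the
point estimate defaults to the minimum-objective sample (the posterior
median is also reported — on ridge-shaped posteriors the two can differ
substantially).

Convergence is assessed with the split-R-hat statistic per parameter, and
pairwise posterior correlations expose practical non-identifiability: on a
single batch time course the Monod mu_max and K_H are determined only
through their ratio, producing |corr| near 1 and credible intervals wider
than the estimates themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from types import SimpleNamespace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from sklearn.base import BaseEstimator

from .kinetics import (
    STRUCTURES,
    DEFAULT_FIT_STRUCTURES,
    CultureState,
    ModelSpec,
    YeastExtensionParams,
    base_derivatives,
    extended_derivatives,
)
from .simulation import IntegrationError, integrate_fast, simulate

__all__ = [
    "TimeSeriesDataset",
    "FitConfig",
    "FitResult",
    "CalibrationError",
    "objective",
    "mcmc_fit",
    "r_squared",
    "parameter_correlation",
    "convergence_diagnostic",
    "MCMCCalibrator",
]

_VAR_INDEX = {"H": 0, "P": 1, "X": 2, "E": 3}
VARIABLES = ("H", "P", "X", "E")


class CalibrationError(RuntimeError):
    """Raised for degenerate sampler configurations or unusable data."""


# --------------------------------------------------------------------------
# dataset
# --------------------------------------------------------------------------


@dataclass
class TimeSeriesDataset:
    """Observed batch time course.

    Parameters
    ----------
    times : array of float
        Strictly increasing observation times, hours.
    observed : mapping variable -> array
        Values per time (NaN marks a missing observation).  Variables are
        'H' (mM), 'P' (mM), 'X' (g L^-1), optionally 'E' (mM).
    sd : mapping variable -> array, optional
        Per-observation standard deviations (replicate error bars).
        Entries that are NaN or 0 fall back to mean normalisation in the
        objective.
    n_replicates : mapping variable -> array, optional
        Replicate counts per observation.
    """

    times: np.ndarray
    observed: Dict[str, np.ndarray]
    sd: Optional[Dict[str, np.ndarray]] = None
    n_replicates: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.observed:
            raise ValueError("at least one observed variable is required")
        clean = {}
        for var, vals in self.observed.items():
            if var not in _VAR_INDEX:
                raise ValueError(f"unknown variable {var!r}; valid: H, P, X, E")
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise ValueError(f"observed[{var!r}] length mismatch with times")
            clean[var] = vals
        self.observed = clean
        if not any(np.isfinite(v).sum() >= 3 for v in self.observed.values()):
            raise ValueError("at least one variable must be observed at >= 3 times")
        for attr in ("sd", "n_replicates"):
            d = getattr(self, attr)
            if d is None:
                continue
            out = {}
            for var, vals in d.items():
                vals = np.asarray(vals, dtype=float)
                if vals.shape != self.times.shape:
                    raise ValueError(f"{attr}[{var!r}] length mismatch with times")
                out[var] = vals
            setattr(self, attr, out)
        if self.sd is not None:
            for var, vals in self.sd.items():
                if np.any(vals[np.isfinite(vals)] < 0):
                    raise ValueError(f"sd[{var!r}] must be >= 0")

    def variables(self) -> Tuple[str, ...]:
        return tuple(self.observed)

    @property
    def has_extension(self) -> bool:
        return "E" in self.observed

    def first_observations(self) -> Dict[str, float]:
        """Earliest finite observation per variable."""
        out = {}
        for var, vals in self.observed.items():
            finite = np.flatnonzero(np.isfinite(vals))
            if finite.size:
                out[var] = float(vals[finite[0]])
        return out

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame: time_h, variable, value, sd, n."""
        rows = []
        for var, vals in self.observed.items():
            for i, t in enumerate(self.times):
                if not np.isfinite(vals[i]):
                    continue
                row = {"time_h": float(t), "variable": var, "value": float(vals[i])}
                if self.sd is not None and var in self.sd:
                    row["sd"] = float(self.sd[var][i])
                if self.n_replicates is not None and var in self.n_replicates:
                    row["n"] = self.n_replicates[var][i]
                rows.append(row)
        return pd.DataFrame(rows).sort_values(["time_h", "variable"]).reset_index(
            drop=True
        )

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "TimeSeriesDataset":
        required = {"time_h", "variable", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tidy dataset missing column(s): {sorted(missing)}")
        times = np.unique(df["time_h"].to_numpy(dtype=float))
        idx = {t: i for i, t in enumerate(times)}
        observed: Dict[str, np.ndarray] = {}
        sd: Dict[str, np.ndarray] = {}
        nrep: Dict[str, np.ndarray] = {}
        for var, g in df.groupby("variable"):
            arr = np.full(times.size, np.nan)
            for _, row in g.iterrows():
                arr[idx[float(row["time_h"])]] = row["value"]
            observed[str(var)] = arr
            if "sd" in g.columns and g["sd"].notna().any():
                s = np.full(times.size, np.nan)
                for _, row in g.iterrows():
                    s[idx[float(row["time_h"])]] = row.get("sd", np.nan)
                sd[str(var)] = s
            if "n" in g.columns and g["n"].notna().any():
                n = np.full(times.size, np.nan)
                for _, row in g.iterrows():
                    n[idx[float(row["time_h"])]] = row.get("n", np.nan)
                nrep[str(var)] = n
        return cls(
            times=times,
            observed=observed,
            sd=sd or None,
            n_replicates=nrep or None,
        )


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------


def _model_matrix(
    spec: ModelSpec, initial: CultureState, times: np.ndarray,
    rtol: float, atol: float,
) -> np.ndarray:
    y0 = initial.as_array()
    return integrate_fast(spec, y0, times, rtol=rtol, atol=atol)


def _scales(data: TimeSeriesDataset, var: str) -> np.ndarray:
    """Per-point normalisation scales for one variable."""
    obs = data.observed[var]
    mask = np.isfinite(obs)
    mean_scale = float(np.mean(np.abs(obs[mask]))) if mask.any() else 1.0
    if mean_scale == 0.0:
        mean_scale = 1.0
    scales = np.full(obs.shape, mean_scale)
    if data.sd is not None and var in data.sd:
        s = data.sd[var]
        ok = np.isfinite(s) & (s > 0)
        scales[ok] = s[ok]
    return scales


def objective(
    spec: ModelSpec,
    initial: CultureState,
    data: TimeSeriesDataset,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """Sum of normalised squared model-data differences.

    Missing observations contribute zero.  Integration failure returns
    +inf so the proposal is rejected rather than aborting the chain.
    """
    try:
        ys = _model_matrix(spec, initial, data.times, rtol, atol)
    except IntegrationError:
        return math.inf
    total = 0.0
    for var, obs in data.observed.items():
        col = _VAR_INDEX[var]
        if col >= ys.shape[1]:
            raise ValueError(f"model has no variable {var!r}")
        mask = np.isfinite(obs)
        if not mask.any():
            continue
        scales = _scales(data, var)
        resid = (ys[mask, col] - obs[mask]) / scales[mask]
        total += float(np.sum(resid * resid))
    if not math.isfinite(total):
        return math.inf
    return total


class _ObjectiveEvaluator:
    """Precomputed objective for the sampler's inner loop.

    Equivalent to :func:`objective` but with masks, normalisation scales and
    parameter records built once per fit instead of once per proposal.
    """

    def __init__(self, spec_template, initial, data, rtol, atol):
        self.structure = spec_template.structure
        self.extended = spec_template.extension is not None
        self.y0 = np.asarray(initial.as_array(), dtype=float)
        self.times = data.times
        self.rtol = rtol
        self.atol = atol
        self.params = SimpleNamespace(**spec_template.params.to_dict())
        self.ext = (
            SimpleNamespace(**spec_template.extension.to_dict())
            if self.extended
            else None
        )
        self.terms = []
        for var, obs in data.observed.items():
            col = _VAR_INDEX[var]
            if col >= self.y0.size:
                raise ValueError(f"model has no variable {var!r}")
            mask = np.isfinite(obs)
            if mask.any():
                scales = _scales(data, var)
                self.terms.append((col, mask, obs[mask], scales[mask]))

    def set_values(self, values: Mapping[str, float]) -> None:
        for k, v in values.items():
            setattr(self.params, k, v)
        if self.ext is not None:
            for k in ("eta_E", "Y_E", "b_EP"):
                if k in values:
                    setattr(self.ext, k, values[k])

    def __call__(self) -> float:
        structure, p = self.structure, self.params
        if self.extended:
            ext = self.ext

            def f(y, t):
                return extended_derivatives(
                    structure, y[0], y[1], y[2], y[3], p, ext
                )

        else:

            def f(y, t):
                return base_derivatives(structure, y[0], y[1], y[2], p)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ys, info = odeint(
                f, self.y0, self.times,
                rtol=self.rtol, atol=self.atol, full_output=True, mxstep=5000,
            )
        if info["message"] != "Integration successful.":
            return math.inf
        ys = np.clip(ys, 0.0, None)
        total = 0.0
        for col, mask, obs, scales in self.terms:
            resid = (ys[mask, col] - obs) / scales
            total += float(resid @ resid)
        if not math.isfinite(total):
            return math.inf
        return total


# --------------------------------------------------------------------------
# fit configuration and result
# --------------------------------------------------------------------------


@dataclass
class FitConfig:
    """MCMC settings.

    ``n_iterations`` defaults to the full-length production run (10^6);
    tests and examples pass much smaller values.  Priors are uniform on
    log-parameters, by default spanning ``prior_log10_halfwidth`` decades
    either side of the initial guess; explicit natural-scale bounds per
    parameter override that.
    """

    n_iterations: int = 1_000_000
    n_chains: int = 4
    burn_in_fraction: float = 0.2
    proposal_scale: Union[float, Mapping[str, float]] = 0.1
    prior_bounds: Optional[Mapping[str, Tuple[float, float]]] = None
    prior_log10_halfwidth: float = 3.0
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-8
    rhat_threshold: float = 1.05
    point_estimator: str = "min_objective"  # or "posterior_median"
    adapt: bool = True

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.point_estimator not in ("min_objective", "posterior_median"):
            raise ValueError("point_estimator must be min_objective or posterior_median")
        if self.prior_bounds is not None:
            for k, (lo, hi) in self.prior_bounds.items():
                if not (0 < lo < hi):
                    raise ValueError(
                        f"prior_bounds[{k!r}] must be positive and ordered"
                    )


@dataclass
class FitResult:
    """Posterior summary of one calibration run."""

    structure: str
    param_names: Tuple[str, ...]
    best_fit: Dict[str, float]
    posterior_median: Dict[str, float]
    chains: Dict[str, np.ndarray]  # (n_chains, n_kept), natural scale
    ci95: Dict[str, Tuple[float, float]]
    r_squared: Dict[str, float]
    #: Pearson correlation of log-parameters across pooled posterior samples
    correlation: pd.DataFrame
    rhat: Dict[str, float]
    converged: Dict[str, bool]
    objective_at_best: float
    acceptance_rate: float
    predicted: Dict[str, np.ndarray]
    data_times: np.ndarray
    spec: ModelSpec
    fixed: Dict[str, float]
    seed: int
    point_estimator: str

    @property
    def best_spec(self) -> ModelSpec:
        return self.spec

    def terminal_acetate(self) -> float:
        """Predicted acetate at the final observation time, mM."""
        if "P" not in self.predicted:
            raise ValueError("fit carries no acetate (P) prediction")
        return float(self.predicted["P"][-1])

    def summary(self) -> pd.DataFrame:
        """Per-parameter table: best fit, 95% interval, R-hat, converged."""
        rows = []
        for name in self.param_names:
            lo, hi = self.ci95[name]
            rows.append(
                {
                    "parameter": name,
                    "best_fit": self.best_fit[name],
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "posterior_median": self.posterior_median[name],
                    "rhat": self.rhat[name],
                    "converged": self.converged[name],
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "structure": self.structure,
            "point_estimator": self.point_estimator,
            "best_fit": self.best_fit,
            "posterior_median": self.posterior_median,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r_squared": self.r_squared,
            "rhat": self.rhat,
            "converged": self.converged,
            "correlation": {
                "names": list(self.correlation.columns),
                "matrix": self.correlation.to_numpy().tolist(),
            },
            "objective_at_best": self.objective_at_best,
            "acceptance_rate": self.acceptance_rate,
            "fixed": self.fixed,
            "seed": self.seed,
            "data_times": self.data_times.tolist(),
            "predicted": {k: np.asarray(v).tolist() for k, v in self.predicted.items()},
            "terminal_acetate_mM": (
                float(self.predicted["P"][-1]) if "P" in self.predicted else None
            ),
        }


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def r_squared(
    model_values: np.ndarray, data: TimeSeriesDataset, variable: str
) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot for one variable.

    ``model_values`` are model predictions at ``data.times``.  SS_tot is
    taken about the observed mean.  Raises for fewer than two observations
    or zero observed variance.
    """
    obs = data.observed[variable]
    mask = np.isfinite(obs)
    if mask.sum() < 2:
        raise ValueError(f"R^2 requires >= 2 observations of {variable!r}")
    o = obs[mask]
    m = np.asarray(model_values, dtype=float)[mask]
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError(f"R^2 undefined: zero variance in {variable!r} observations")
    ss_res = float(np.sum((o - m) ** 2))
    return 1.0 - ss_res / ss_tot


def parameter_correlation(chains: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation between parameter pairs across pooled samples.

    A constant chain has undefined correlation; its entries are NaN.
    """
    names = list(chains)
    cols = []
    for name in names:
        arr = np.asarray(chains[name], dtype=float).ravel()
        cols.append(arr)
    n = min(c.size for c in cols)
    if n < 2:
        raise ValueError("parameter correlation requires >= 2 samples")
    mat = np.vstack([c[:n] for c in cols])
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = mat.std(axis=1)
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def _split_chains(arr: np.ndarray) -> np.ndarray:
    """Split each chain in half, (m, n) -> (2m, n//2)."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    n = arr.shape[1]
    half = n // 2
    return np.vstack([arr[:, :half], arr[:, n - half:]])


def split_rhat(arr: np.ndarray) -> float:
    """Split-R-hat (potential scale reduction) for one parameter.

    ``arr`` is (n_chains, n_samples) or 1-D (a single chain, split in two).
    Identical constant chains give exactly 1.0.
    """
    chains = _split_chains(arr)
    m, n = chains.shape
    if n < 2:
        raise CalibrationError("convergence diagnostic requires >= 4 samples per chain")
    means = chains.mean(axis=1)
    w = float(np.mean(chains.var(axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * w + b_over_n
    # values below 1 are finite-sample noise (e.g. identical chains give
    # sqrt((n-1)/n)); clamp so perfect agreement reads exactly 1
    return max(math.sqrt(var_plus / w), 1.0)


def convergence_diagnostic(
    chains: Mapping[str, np.ndarray], threshold: float = 1.05
) -> Tuple[Dict[str, float], Dict[str, bool]]:
    """Per-parameter split-R-hat and a converged flag (R-hat < threshold)."""
    rhat = {}
    flags = {}
    for name, arr in chains.items():
        r = split_rhat(arr)
        rhat[name] = r
        flags[name] = bool(r < threshold)
    return rhat, flags


# --------------------------------------------------------------------------
# parameter vector plumbing
# --------------------------------------------------------------------------


def _spec_param_dict(spec: ModelSpec) -> Dict[str, float]:
    d = spec.params.to_dict()
    if spec.extension is not None:
        d.update(spec.extension.to_dict())
    return d


def _rebuild_spec(spec: ModelSpec, values: Mapping[str, float]) -> ModelSpec:
    base_names = {f.name for f in fields(spec.params)}
    base = {k: v for k, v in values.items() if k in base_names}
    params = type(spec.params)(**base)
    ext = None
    if spec.extension is not None:
        ext_names = {f.name for f in fields(spec.extension)}
        ext = YeastExtensionParams(
            **{k: v for k, v in values.items() if k in ext_names}
        )
    return ModelSpec(structure=spec.structure, params=params, extension=ext)


def _prior_log_bounds(
    names: Sequence[str],
    init: Mapping[str, float],
    cfg: FitConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, name in enumerate(names):
        if cfg.prior_bounds is not None and name in cfg.prior_bounds:
            a, b = cfg.prior_bounds[name]
            lo[i], hi[i] = math.log(a), math.log(b)
        else:
            c = math.log(init[name])
            w = cfg.prior_log10_halfwidth * math.log(10.0)
            lo[i], hi[i] = c - w, c + w
    return lo, hi


# --------------------------------------------------------------------------
# adaptive Metropolis core
# --------------------------------------------------------------------------


def _run_chain(
    logpost,
    theta0: np.ndarray,
    n_iterations: int,
    burn: int,
    step0: np.ndarray,
    bounds: Tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    adapt: bool,
):
    """Single adaptive-covariance random-walk Metropolis chain in log space.

    Records the state at the start of each iteration (n_iterations samples
    total, the first being the initial point).  Covariance adaptation
    (scaled empirical covariance, Haario-style) runs during burn-in only.
    """
    d = theta0.size
    lo, hi = bounds
    theta = theta0.copy()
    lp = logpost(theta)
    if not math.isfinite(lp):
        raise CalibrationError(
            "initial parameters have non-finite posterior (outside prior "
            "bounds or integration failure); adjust the initial guess or bounds"
        )
    samples = np.empty((n_iterations, d))
    logposts = np.empty(n_iterations)
    n_accept = 0
    best_theta = theta.copy()
    best_lp = lp

    # adaptation state: running mean / covariance of burn-in samples
    sd_scale = 2.38**2 / d
    eps = 1e-10
    mean = theta.copy()
    cov = np.diag(step0**2)
    chol = np.linalg.cholesky(cov + eps * np.eye(d))
    count = 1

    for it in range(n_iterations):
        samples[it] = theta
        logposts[it] = lp
        if lp > best_lp:
            best_lp = lp
            best_theta = theta.copy()
        if it == n_iterations - 1:
            break  # the final move would never be recorded
        prop = theta + chol @ rng.standard_normal(d)
        if np.all(prop >= lo) and np.all(prop <= hi):
            lp_prop = logpost(prop)
            if math.log(max(rng.uniform(), 1e-300)) < lp_prop - lp:
                theta = prop
                lp = lp_prop
                n_accept += 1
        if adapt and it < burn:
            count += 1
            delta = theta - mean
            mean += delta / count
            cov += (np.outer(delta, theta - mean) - cov) / count
            if count > max(2 * d, 20) and it % 25 == 0:
                try:
                    chol = np.linalg.cholesky(
                        sd_scale * cov + eps * np.eye(d)
                    )
                except np.linalg.LinAlgError:
                    pass
    return samples, logposts, n_accept, best_theta, best_lp


def _run_mcmc(
    spec_template: ModelSpec,
    initial: CultureState,
    data: TimeSeriesDataset,
    cfg: FitConfig,
    fixed: Optional[Mapping[str, float]] = None,
    allow_nonidentifiable: bool = False,
) -> FitResult:
    if (
        spec_template.structure not in DEFAULT_FIT_STRUCTURES
        and not allow_nonidentifiable
    ):
        raise CalibrationError(
            f"structure {spec_template.structure!r} is excluded from default "
            "fitting (mu_max and K_H cannot be estimated separately from a "
            "single batch time course); pass allow_nonidentifiable=True to "
            "fit it anyway"
        )
    fixed = dict(fixed or {})
    init_all = _spec_param_dict(spec_template)
    unknown = set(fixed) - set(init_all)
    if unknown:
        raise ValueError(f"fixed parameter(s) not in model: {sorted(unknown)}")
    init_all.update(fixed)
    free_names = tuple(n for n in init_all if n not in fixed)
    if not free_names:
        raise CalibrationError("no free parameters to fit")

    theta0 = np.array([math.log(init_all[n]) for n in free_names])
    bounds = _prior_log_bounds(free_names, init_all, cfg)
    if isinstance(cfg.proposal_scale, Mapping):
        step0 = np.array(
            [float(cfg.proposal_scale.get(n, 0.1)) for n in free_names]
        )
    else:
        step0 = np.full(len(free_names), float(cfg.proposal_scale))
    if np.any(step0 <= 0):
        raise CalibrationError("proposal_scale must be strictly positive")

    # Gaussian likelihood on the normalised residuals with an unknown global
    # noise scale sigma, marginalised under a Jeffreys prior 1/sigma:
    # p(data | params) ~ obj^(-N/2).  This makes the posterior width track
    # the actual residual scatter instead of trusting the normalisation
    # constants (variable means, replicate SDs) as literal noise SDs.
    n_obs = sum(int(np.isfinite(v).sum()) for v in data.observed.values())
    evaluator = _ObjectiveEvaluator(
        spec_template, initial, data, cfg.rtol, cfg.atol
    )
    evaluator.set_values(init_all)
    values = dict(init_all)

    def logpost(theta: np.ndarray) -> float:
        for n, v in zip(free_names, theta):
            values[n] = math.exp(v)
        evaluator.set_values(values)
        obj = evaluator()
        if not math.isfinite(obj):
            return -math.inf
        # small floor keeps the target proper when residuals hit
        # integrator precision (noise-free data)
        return -0.5 * n_obs * math.log(obj / n_obs + 1e-12)

    burn = int(math.floor(cfg.burn_in_fraction * cfg.n_iterations))
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    kept = []
    total_accept = 0
    best_lp = -math.inf
    best_theta = theta0

    # compiled path for base structures (identical algorithm; see _fastpath)
    from . import _fastpath as _fp

    use_fast = (
        _fp.NUMBA_AVAILABLE
        and spec_template.extension is None
        and spec_template.structure in _fp.STRUCTURE_CODES
        and all(_VAR_INDEX[v] < 3 for v in data.observed)
    )
    if use_fast:
        code = _fp.STRUCTURE_CODES[spec_template.structure]
        field_names = [f.name for f in fields(spec_template.params)]
        pvec0 = np.array([init_all[n] for n in field_names], dtype=float)
        free_idx = np.array(
            [field_names.index(n) for n in free_names], dtype=np.int64
        )
        n_times = data.times.size
        obs_mat = np.full((n_times, 3), np.nan)
        scale_mat = np.ones((n_times, 3))
        for var, obs in data.observed.items():
            col = _VAR_INDEX[var]
            obs_mat[:, col] = obs
            scale_mat[:, col] = _scales(data, var)
        y0_arr = np.asarray(initial.as_array(), dtype=float)

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        t0 = theta0.copy()
        if c > 0:  # jitter extra chains for overdispersed starts
            t0 = t0 + 0.5 * rng.standard_normal(t0.size)
            t0 = np.clip(t0, bounds[0], bounds[1])
        if use_fast:
            chain_seed = int(seeds[c].generate_state(1)[0])
            samples, n_acc, bt, blp, ok_start = _fp.run_chain_nb(
                code, pvec0, free_idx, t0, bounds[0], bounds[1], step0,
                cfg.n_iterations, burn, cfg.adapt, chain_seed,
                y0_arr, data.times, obs_mat, scale_mat,
                cfg.rtol, cfg.atol, n_obs,
            )
            if not ok_start:
                raise CalibrationError(
                    "initial parameters have non-finite posterior (outside "
                    "prior bounds or integration failure); adjust the "
                    "initial guess or bounds"
                )
        else:
            samples, _, n_acc, bt, blp = _run_chain(
                logpost, t0, cfg.n_iterations, burn, step0, bounds, rng,
                cfg.adapt,
            )
        kept.append(samples[burn:])
        total_accept += n_acc
        if blp > best_lp:
            best_lp = blp
            best_theta = bt

    min_obj_values = dict(init_all)
    for n, v in zip(free_names, best_theta):
        min_obj_values[n] = math.exp(v)
    obj_min_sample = objective(
        _rebuild_spec(spec_template, min_obj_values), initial, data,
        rtol=cfg.rtol, atol=cfg.atol,
    )
    if (
        total_accept == 0
        and cfg.n_iterations * cfg.n_chains >= 100
        and obj_min_sample / n_obs > 1e-6
    ):
        # a chain pinned to an essentially perfect fit (noise-free data) is
        # converged, not degenerate; a chain pinned to a bad fit is
        raise CalibrationError(
            "all proposals rejected: degenerate proposal scale or prior "
            "bounds excluding all finite-objective parameters"
        )

    kept_arr = np.stack(kept)  # (n_chains, n_kept, d)
    chains = {
        name: np.exp(kept_arr[:, :, i]) for i, name in enumerate(free_names)
    }
    pooled = {name: arr.reshape(-1) for name, arr in chains.items()}

    ci95 = {
        name: (
            float(np.percentile(pooled[name], 2.5)),
            float(np.percentile(pooled[name], 97.5)),
        )
        for name in free_names
    }
    posterior_median = {
        name: float(np.median(pooled[name])) for name in free_names
    }

    if cfg.point_estimator == "posterior_median":
        point = dict(init_all)
        point.update(posterior_median)
    else:
        point = min_obj_values
    best_free = {n: float(point[n]) for n in free_names}

    best_spec = _rebuild_spec(spec_template, point)
    obj_best = objective(best_spec, initial, data, rtol=cfg.rtol, atol=cfg.atol)

    # diagnostics
    if kept_arr.shape[1] >= 4:
        rhat, converged = convergence_diagnostic(chains, cfg.rhat_threshold)
    else:
        rhat = {n: float("nan") for n in free_names}
        converged = {n: False for n in free_names}
    # correlations on the log scale the sampler operates on: for positive
    # parameters ranging over decades, natural-scale Pearson is dominated
    # by the largest samples and understates ridge non-identifiability
    try:
        corr = parameter_correlation(
            {n: np.log(pooled[n]) for n in free_names}
        )
    except ValueError:
        corr = pd.DataFrame(
            np.full((len(free_names),) * 2, np.nan),
            index=free_names,
            columns=free_names,
        )

    # goodness of fit at the point estimate
    ys = _model_matrix(best_spec, initial, data.times, cfg.rtol, cfg.atol)
    predicted = {}
    r2 = {}
    for var in data.variables():
        col = _VAR_INDEX[var]
        predicted[var] = ys[:, col]
        try:
            r2[var] = r_squared(ys[:, col], data, var)
        except ValueError:
            r2[var] = float("nan")

    return FitResult(
        structure=spec_template.structure,
        param_names=free_names,
        best_fit=best_free,
        posterior_median=posterior_median,
        chains=chains,
        ci95=ci95,
        r_squared=r2,
        correlation=corr,
        rhat=rhat,
        converged=converged,
        objective_at_best=float(obj_best),
        acceptance_rate=total_accept / (cfg.n_iterations * cfg.n_chains),
        predicted=predicted,
        data_times=data.times.copy(),
        spec=best_spec,
        fixed={k: float(v) for k, v in fixed.items()},
        seed=cfg.seed,
        point_estimator=cfg.point_estimator,
    )


def mcmc_fit(
    spec_template: ModelSpec,
    initial: CultureState,
    data: TimeSeriesDataset,
    cfg: FitConfig,
    fixed: Optional[Mapping[str, float]] = None,
    allow_nonidentifiable: bool = False,
) -> FitResult:
    """Fit a model spec to a dataset by MCMC.

    ``spec_template`` supplies the structure and the initial parameter
    guess; ``fixed`` pins named parameters at given values (used when
    fitting only the yeast-extract extension on top of a previously
    calibrated base model).  Deterministic given ``cfg.seed``.
    """
    return _run_mcmc(
        spec_template, initial, data, cfg,
        fixed=fixed, allow_nonidentifiable=allow_nonidentifiable,
    )


# --------------------------------------------------------------------------
# sklearn-style estimator
# --------------------------------------------------------------------------


class MCMCCalibrator(BaseEstimator):
    """Calibrate a batch-culture kinetic model by adaptive-Metropolis MCMC.

    scikit-learn-style estimator: hyperparameters in ``__init__``, data in
    :meth:`fit`, fitted state in trailing-underscore attributes, and
    ``get_params``/``set_params`` for pipeline and search compatibility.

    Parameters
    ----------
    structure : str
        One of 'monod', 'first_order', 't1', 't2', 't3' (non-linearised
        variants 't1_nonlinear'/'t2_nonlinear' require
        ``allow_nonidentifiable=True``).
    initial_params : mapping, optional
        Initial parameter guess (flat dict); defaults to the published
        reference values for the structure.
    extension_params : mapping, optional
        Yeast-extract extension guess (eta_E, Y_E, b_EP); enables the
        two-substrate model.
    fixed_params : mapping, optional
        Parameters pinned at fixed values (not sampled).
    initial_state : CultureState or mapping, optional
        State at the first observation time; by default taken from the
        first observation of each variable.
    default_initial : mapping, optional
        Fallback values for state variables missing from the data when
        deriving the initial state.
    n_iterations, n_chains, burn_in_fraction, proposal_scale,
    prior_bounds, prior_log10_halfwidth, rtol, atol, rhat_threshold,
    point_estimator, adapt :
        See :class:`FitConfig`.
    random_state : int
        Seed; identical seed + data + settings give bit-identical results.

    Attributes
    ----------
    result_ : FitResult
    best_fit_ : dict of parameter point estimates
    ci95_ : dict of central 95% credible intervals
    chains_ : dict of posterior sample arrays (n_chains, n_kept)
    r_squared_ : per-variable goodness of fit
    correlation_ : posterior parameter correlation matrix
    rhat_, converged_ : split-R-hat diagnostics
    objective_at_best_ : objective value at the point estimate
    spec_ : ModelSpec at the point estimate

    Examples
    --------
    >>> from acetokin.synthetic import bernalier_like_scenario, generate_dataset
    >>> cfg = bernalier_like_scenario()
    >>> data, truth = generate_dataset(cfg)
    >>> cal = MCMCCalibrator("t1", n_iterations=2000, n_chains=1,
    ...                      random_state=0)
    >>> result = cal.fit(data).result_
    """

    def __init__(
        self,
        structure: str = "first_order",
        initial_params: Optional[Mapping[str, float]] = None,
        extension_params: Optional[Mapping[str, float]] = None,
        fixed_params: Optional[Mapping[str, float]] = None,
        initial_state: Union[CultureState, Mapping[str, float], None] = None,
        default_initial: Optional[Mapping[str, float]] = None,
        n_iterations: int = 1_000_000,
        n_chains: int = 4,
        burn_in_fraction: float = 0.2,
        proposal_scale: Union[float, Mapping[str, float]] = 0.1,
        prior_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        prior_log10_halfwidth: float = 3.0,
        rtol: float = 1e-6,
        atol: float = 1e-8,
        rhat_threshold: float = 1.05,
        point_estimator: str = "min_objective",
        adapt: bool = True,
        allow_nonidentifiable: bool = False,
        random_state: int = 0,
    ):
        self.structure = structure
        self.initial_params = initial_params
        self.extension_params = extension_params
        self.fixed_params = fixed_params
        self.initial_state = initial_state
        self.default_initial = default_initial
        self.n_iterations = n_iterations
        self.n_chains = n_chains
        self.burn_in_fraction = burn_in_fraction
        self.proposal_scale = proposal_scale
        self.prior_bounds = prior_bounds
        self.prior_log10_halfwidth = prior_log10_halfwidth
        self.rtol = rtol
        self.atol = atol
        self.rhat_threshold = rhat_threshold
        self.point_estimator = point_estimator
        self.adapt = adapt
        self.allow_nonidentifiable = allow_nonidentifiable
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _template(self) -> ModelSpec:
        from .literature import reference_params

        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; "
                f"valid: {sorted(STRUCTURES)}"
            )
        if self.initial_params is not None:
            params = STRUCTURES[self.structure].from_dict(
                dict(self.initial_params)
            )
        else:
            params = reference_params(self.structure)
        ext = None
        if self.extension_params is not None:
            if isinstance(self.extension_params, YeastExtensionParams):
                ext = self.extension_params
            else:
                ext = YeastExtensionParams.from_dict(dict(self.extension_params))
        return ModelSpec(structure=self.structure, params=params, extension=ext)

    def _initial_state(self, data: TimeSeriesDataset, extended: bool) -> CultureState:
        if isinstance(self.initial_state, CultureState):
            return self.initial_state
        if self.initial_state is not None:
            return CultureState(**dict(self.initial_state))
        first = data.first_observations()
        defaults = dict(self.default_initial or {})
        state = {}
        needed = ["H", "P", "X"] + (["E"] if extended else [])
        for var in needed:
            if var in first:
                state[var] = first[var]
            elif var in defaults:
                state[var] = float(defaults[var])
            else:
                raise ValueError(
                    f"initial state for {var!r} not observed at the first "
                    "time point; supply initial_state or default_initial"
                )
        return CultureState(**state)

    def _config(self) -> FitConfig:
        return FitConfig(
            n_iterations=self.n_iterations,
            n_chains=self.n_chains,
            burn_in_fraction=self.burn_in_fraction,
            proposal_scale=self.proposal_scale,
            prior_bounds=self.prior_bounds,
            prior_log10_halfwidth=self.prior_log10_halfwidth,
            seed=self.random_state,
            rtol=self.rtol,
            atol=self.atol,
            rhat_threshold=self.rhat_threshold,
            point_estimator=self.point_estimator,
            adapt=self.adapt,
        )

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None) -> "MCMCCalibrator":
        """Run the MCMC calibration.

        ``X`` is a :class:`TimeSeriesDataset` or a tidy long-format
        DataFrame (columns time_h, variable, value[, sd, n]); ``y`` is
        ignored (present for sklearn API compatibility).
        """
        if isinstance(X, TimeSeriesDataset):
            data = X
        elif isinstance(X, pd.DataFrame):
            data = TimeSeriesDataset.from_tidy(X)
        else:
            raise TypeError(
                "X must be a TimeSeriesDataset or tidy DataFrame, "
                f"got {type(X).__name__}"
            )
        template = self._template()
        initial = self._initial_state(data, template.has_extension)
        result = _run_mcmc(
            template,
            initial,
            data,
            self._config(),
            fixed=self.fixed_params,
            allow_nonidentifiable=self.allow_nonidentifiable,
        )
        self.result_ = result
        self.best_fit_ = result.best_fit
        self.posterior_median_ = result.posterior_median
        self.chains_ = result.chains
        self.ci95_ = result.ci95
        self.r_squared_ = result.r_squared
        self.correlation_ = result.correlation
        self.rhat_ = result.rhat
        self.converged_ = result.converged
        self.objective_at_best_ = result.objective_at_best
        self.spec_ = result.spec
        self.initial_state_ = initial
        return self

    def predict(self, times) -> pd.DataFrame:
        """Simulate the fitted model at the given times (hours)."""
        if not hasattr(self, "spec_"):
            raise RuntimeError("this MCMCCalibrator instance is not fitted yet")
        traj = simulate(self.spec_, self.initial_state_, np.asarray(times, float))
        return traj.to_frame()

    def score(self, X, y=None) -> float:
        """Mean per-variable R^2 of the fitted model on a dataset."""
        if not hasattr(self, "spec_"):
            raise RuntimeError("this MCMCCalibrator instance is not fitted yet")
        data = X if isinstance(X, TimeSeriesDataset) else TimeSeriesDataset.from_tidy(X)
        ys = _model_matrix(self.spec_, self.initial_state_, data.times,
                           self.rtol, self.atol)
        vals = []
        for var in data.variables():
            try:
                vals.append(r_squared(ys[:, _VAR_INDEX[var]], data, var))
            except ValueError:
                continue
        if not vals:
            raise ValueError("no variable with computable R^2")
        return float(np.mean(vals))
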