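"""Synthetic batch-culture time courses for testing and benchmarking.

The original calibration and validation measurements exist only as
published figures, so this module generates datasets with the same
statistical structure: a handful of sampling times over tens of hours,
monotone-declining hydrogen from a few hundred mM, stoichiometrically
coupled acetate rise, sigmoid-then-declining biomass, and multiplicative
replicate noise (figure error bars scale roughly with the signal).  Every
generated dataset ships with its noise-free ground-truth trajectory so
recovery tests can compare against the exact generating values.

Scenario constants that the sources do not state (initial concentrations,
sampling grid, noise level) are invented defaults, recorded as such in the
scenario description — they are stand-ins, not reproductions of the
original experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .calibration import TimeSeriesDataset
from .kinetics import CultureState, ModelSpec
from .literature import (
    T1_BEST_FIT,
    T3_BEST_FIT,
    T2_BEST_FIT,
    YEAST_EXTENSION_T2,
    YEAST_EXTENSION_T2_KD,
    YEAST_EXTENSION_T3,
    YEAST_EXTENSION_T3_KD,
)
from .simulation import Trajectory, simulate

__all__ = [
    "ScenarioConfig",
    "generate_dataset",
    "bernalier_like_scenario",
    "dsmz_like_scenario",
]


@dataclass
class ScenarioConfig:
    """Recipe for one synthetic batch experiment.

    noise_cv may be a single fractional coefficient of variation applied
    to every variable, or a per-variable mapping.
    """

    spec: ModelSpec
    initial: CultureState
    sampling_times: np.ndarray
    noise_cv: Union[float, Dict[str, float]] = 0.1
    n_replicates: int = 3
    seed: int = 0
    description: str = ""

    def __post_init__(self):
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if self.sampling_times.ndim != 1 or self.sampling_times.size < 2:
            raise ValueError("sampling_times must be 1-D with >= 2 points")
        if not np.all(np.diff(self.sampling_times) > 0):
            raise ValueError("sampling_times must be strictly increasing")
        cvs = (
            self.noise_cv.values()
            if isinstance(self.noise_cv, dict)
            else [self.noise_cv]
        )
        if any(cv < 0 for cv in cvs):
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def cv_for(self, var: str) -> float:
        if isinstance(self.noise_cv, dict):
            return float(self.noise_cv.get(var, 0.0))
        return float(self.noise_cv)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "initial": {
                k: v
                for k, v in zip("HPXE", self.initial.as_array() + [None])
                if v is not None
            },
            "sampling_times": self.sampling_times.tolist(),
            "noise_cv": self.noise_cv,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "description": self.description,
        }


def generate_dataset(
    cfg: ScenarioConfig,
) -> Tuple[TimeSeriesDataset, Trajectory]:
    """Simulate a scenario and add replicate observation noise.

    Each replicate observation is truth * (1 + eps) with
    eps ~ Normal(0, noise_cv), truncated at zero.  The dataset carries the
    per-point replicate mean and standard deviation (ddof=1, omitted for a
    single replicate).  Deterministic given ``cfg.seed``.

    Returns the noisy dataset paired with its noise-free ground-truth
    trajectory.
    """
    truth = simulate(cfg.spec, cfg.initial, cfg.sampling_times)
    rng = np.random.default_rng(cfg.seed)
    variables = ["H", "P", "X"] + (["E"] if truth.has_extension else [])
    observed: Dict[str, np.ndarray] = {}
    sd: Dict[str, np.ndarray] = {}
    nrep: Dict[str, np.ndarray] = {}
    for var in variables:
        clean = truth.variable(var)
        cv = cfg.cv_for(var)
        if cv == 0.0:
            # identical replicates: keep the truth bit-exact
            observed[var] = clean.copy()
            if cfg.n_replicates > 1:
                sd[var] = np.zeros_like(clean)
        else:
            reps = clean[None, :] * (
                1.0 + cv * rng.standard_normal((cfg.n_replicates, clean.size))
            )
            reps = np.clip(reps, 0.0, None)
            observed[var] = reps.mean(axis=0)
            if cfg.n_replicates > 1:
                sd[var] = reps.std(axis=0, ddof=1)
        nrep[var] = np.full(clean.size, cfg.n_replicates, dtype=float)
    return (
        TimeSeriesDataset(
            times=cfg.sampling_times.copy(),
            observed=observed,
            sd=sd or None,
            n_replicates=nrep,
        ),
        truth,
    )


def bernalier_like_scenario(
    noise_cv: Union[float, Dict[str, float]] = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> ScenarioConfig:
    """Calibration-style batch monoculture scenario.

    Hard-threshold (T1) dynamics with the published best-fit parameters
    (eta=0.0008 h^-1 mM^-1, Y=0.0014 g L^-1 mM^-1, k_d=0.014 h^-1,
    H_t=86.2 mM): hydrogen starts at a few hundred mM and declines toward
    the ~86 mM threshold over tens of hours while acetate accumulates at a
    quarter of the hydrogen consumed.  Initial state (H=400 mM, P=0,
    X=0.01 g L^-1) and the 8-point 0-80 h sampling grid are invented
    defaults, not measured conditions.
    """
    return ScenarioConfig(
        spec=ModelSpec("t1", T1_BEST_FIT),
        initial=CultureState(H=400.0, P=0.0, X=0.01),
        sampling_times=np.linspace(0.0, 80.0, 8),
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
        description=(
            "Synthetic batch monoculture, T1 hard-threshold dynamics with "
            "published best-fit parameters; initial state and sampling grid "
            "are invented defaults."
        ),
    )


def dsmz_like_scenario(
    base: str = "t3",
    E0: float = 100.0,
    noise_cv: Union[float, Dict[str, float]] = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> ScenarioConfig:
    """Yeast-extract-rich (DSMZ-style) scenario with the two-substrate model.

    Base structure 't2' or 't3' with its published best fit, augmented by
    the illustrative yeast-extract extension sets (T2: eta_E=0.0018,
    Y_E=0.02, b_EP=0.43, k_d=0.112; T3: eta_E=0.002, Y_E=0.013, b_EP=0.5,
    k_d=0.08).  Those extension values are hypothetical, not fitted
    estimates.  ``E0`` is the initial yeast-extract pool in mM (the DSMZ
    medium is yeast-extract rich; the default of 100 mM is an invented
    stand-in since yeast extract has no single molar mass).
    """
    if base == "t3":
        params = T3_BEST_FIT
        ext = YEAST_EXTENSION_T3
        kd = YEAST_EXTENSION_T3_KD
    elif base == "t2":
        params = T2_BEST_FIT
        ext = YEAST_EXTENSION_T2
        kd = YEAST_EXTENSION_T2_KD
    else:
        raise ValueError("base must be 't2' or 't3'")
    if E0 < 0:
        raise ValueError("E0 must be >= 0")
    params = type(params)(**{**params.to_dict(), "k_d": kd})
    extension = ext if E0 > 0 else None
    return ScenarioConfig(
        spec=ModelSpec(base, params, extension=extension),
        initial=CultureState(
            H=400.0, P=0.0, X=0.01, E=E0 if E0 > 0 else None
        ),
        sampling_times=np.linspace(0.0, 100.0, 10),
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
        description=(
            f"Synthetic yeast-extract-rich batch culture, {base.upper()} base "
            "with hypothetical yeast-extract extension parameters; initial "
            "state, E0 and sampling grid are invented defaults."
        ),
    )
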