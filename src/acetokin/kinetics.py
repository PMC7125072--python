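"""Kinetic model structures for hydrogen-consuming reductive acetogens.

A batch monoculture is described by three state variables: dissolved
hydrogen ``H`` (mM), acetate ``P`` (mM) and cell dry weight ``X``
(g L^-1).  Acetogenesis follows the Wood-Ljungdahl stoichiometry
4 H2 + 2 CO2 -> acetate + H+ + 2 H2O, so every model couples acetate
production to hydrogen consumption as dP/dt = -(1/4) dH/dt, and biomass
grows in proportion to substrate consumed (yield ``Y``) while dying at a
constant first-order rate ``k_d``:

    dP/dt = -(1/4) dH/dt
    dX/dt = -Y dH/dt - k_d X

The structures differ only in the hydrogen-uptake law:

``monod``         dH/dt = -(mu_max X / Y) * H / (K_H + H)
``first_order``   dH/dt = -eta X H / Y                 (eta ~ mu_max/K_H)
``t1``            dH/dt = -eta X max(H - H_t, 0) / Y   (hard threshold)
``t2``            dH/dt = -eta X H F(H) / Y,  F = 1/(1 + exp(A (T - H)))
``t3``            reversible Michaelis-Menten:
                  dH/dt = -(X/Y) (mu_max_H H/K_H - mu_max_R P/K_R)
                                 / (1 + H/K_H + P/K_R)

The threshold structures T1-T3 encode the observation that acetogens
stop harvesting hydrogen below a minimum concentration; T3 does so by
treating acetogenesis as a reversible reaction whose net flux vanishes
at a fixed acetate:hydrogen ratio.

An optional two-substrate extension adds a yeast-extract pool ``E``
(mM), consumed by first-order kinetics and contributing both acetate
(``b_EP`` mol acetate per mol extract) and biomass (yield ``Y_E``):

    dE/dt = -eta_E X E / Y_E
    dP/dt = -(1/4) dH/dt - b_EP dE/dt
    dX/dt = -Y dH/dt - Y_E dE/dt - k_d X

The hydrogen equation is unchanged by the extension.

Non-linearised threshold variants (``t1_nonlinear``, ``t2_nonlinear``)
retain the full Monod saturation term.  They are provided for
completeness but excluded from default fitting: mu_max and K_H cannot be
estimated separately from a single batch time course (see
:mod:`acetokin.calibration`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple, Optional, Union

__all__ = [
    "CultureState",
    "StateDerivative",
    "MonodParams",
    "FirstOrderParams",
    "T1Params",
    "T2Params",
    "T3Params",
    "T1NonlinearParams",
    "T2NonlinearParams",
    "YeastExtensionParams",
    "ModelSpec",
    "STRUCTURES",
    "DEFAULT_FIT_STRUCTURES",
    "monod_rhs",
    "first_order_rhs",
    "t1_rhs",
    "t2_rhs",
    "t2_gate",
    "t3_rhs",
    "extended_rhs",
    "hydrogen_uptake_rate",
    "base_derivatives",
]


class StateDerivative(NamedTuple):
    """Time derivative of a culture state, units per hour."""

    dH: float
    dP: float
    dX: float
    dE: Optional[float] = None


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _check_positive(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if value <= 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return value


def _check_nonnegative(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if value < 0.0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class CultureState:
    """Instantaneous concentrations in one batch culture.

    Parameters
    ----------
    H : float
        Hydrogen concentration, mM.
    P : float
        Acetate concentration, mM.
    X : float
        Cell concentration, g L^-1 cell dry weight.
    E : float, optional
        Yeast-extract concentration, mM.  Present only for the
        two-substrate extended models.
    """

    H: float
    P: float
    X: float
    E: Optional[float] = None

    def __post_init__(self):
        _check_nonnegative("H", self.H)
        _check_nonnegative("P", self.P)
        _check_nonnegative("X", self.X)
        if self.E is not None:
            _check_nonnegative("E", self.E)

    @property
    def has_extension(self) -> bool:
        return self.E is not None

    def as_array(self):
        if self.E is None:
            return [self.H, self.P, self.X]
        return [self.H, self.P, self.X, self.E]


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------


class _ParamRecord:
    """Mixin: positivity validation plus flat-dict (JSON) round-trip."""

    def __post_init__(self):
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict):
        expected = {f.name for f in fields(cls)}
        given = set(d)
        missing = expected - given
        if missing:
            raise ValueError(
                f"{cls.__name__} missing parameter key(s): {sorted(missing)}"
            )
        extra = given - expected
        if extra:
            raise ValueError(
                f"{cls.__name__} got unexpected parameter key(s): {sorted(extra)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})

    def free_names(self) -> tuple:
        return tuple(f.name for f in fields(self))


@dataclass(frozen=True)
class MonodParams(_ParamRecord):
    """Monod growth on hydrogen.

    mu_max : maximum growth rate, h^-1
    K_H    : half-saturation constant for hydrogen, mM
    Y      : biomass yield on hydrogen, g L^-1 mM^-1
    k_d    : death rate, h^-1
    """

    mu_max: float
    K_H: float
    Y: float
    k_d: float


@dataclass(frozen=True)
class FirstOrderParams(_ParamRecord):
    """First-order (linearised Monod) uptake; eta ~ mu_max / K_H, h^-1 mM^-1."""

    eta: float
    Y: float
    k_d: float


@dataclass(frozen=True)
class T1Params(_ParamRecord):
    """Hard hydrogen threshold: uptake proportional to max(H - H_t, 0)."""

    eta: float
    Y: float
    k_d: float
    H_t: float


@dataclass(frozen=True)
class T2Params(_ParamRecord):
    """Sigmoid-gated first-order uptake (Ribes-style smooth threshold).

    A : gate steepness, mM^-1
    T : gate midpoint, mM
    """

    eta: float
    Y: float
    k_d: float
    A: float
    T: float


@dataclass(frozen=True)
class T3Params(_ParamRecord):
    """Reversible Michaelis-Menten acetogenesis.

    mu_max_H / K_H : forward (hydrogen-consuming) rate and half-saturation
    mu_max_R / K_R : reverse (acetate-consuming) rate and half-saturation
    """

    mu_max_H: float
    mu_max_R: float
    K_H: float
    K_R: float
    Y: float
    k_d: float


@dataclass(frozen=True)
class T1NonlinearParams(_ParamRecord):
    """Full-Monod hard threshold (non-linearised T1); non-identifiable from
    single batch data and excluded from default fitting."""

    mu_max: float
    K_H: float
    Y: float
    k_d: float
    H_t: float


@dataclass(frozen=True)
class T2NonlinearParams(_ParamRecord):
    """Full-Monod sigmoid-gated threshold (non-linearised T2); excluded from
    default fitting for the same identifiability reason."""

    mu_max: float
    K_H: float
    Y: float
    k_d: float
    H_t: float
    A: float
    T: float


@dataclass(frozen=True)
class YeastExtensionParams(_ParamRecord):
    """Two-substrate extension: first-order growth on yeast extract.

    eta_E : first-order uptake rate on yeast extract, h^-1 mM^-1
    Y_E   : biomass yield on yeast extract, g L^-1 mM^-1
    b_EP  : mol acetate produced per mol yeast extract consumed
    """

    eta_E: float
    Y_E: float
    b_EP: float


ParamsLike = Union[
    MonodParams,
    FirstOrderParams,
    T1Params,
    T2Params,
    T3Params,
    T1NonlinearParams,
    T2NonlinearParams,
]

#: structure tag -> parameter record type
STRUCTURES = {
    "monod": MonodParams,
    "first_order": FirstOrderParams,
    "t1": T1Params,
    "t2": T2Params,
    "t3": T3Params,
    "t1_nonlinear": T1NonlinearParams,
    "t2_nonlinear": T2NonlinearParams,
}

#: structures supported by default calibration (the non-linearised variants
#: require an explicit opt-in flag)
DEFAULT_FIT_STRUCTURES = ("monod", "first_order", "t1", "t2", "t3")


@dataclass(frozen=True)
class ModelSpec:
    """A named kinetic structure, its parameters, and an optional extension."""

    structure: str
    params: ParamsLike
    extension: Optional[YeastExtensionParams] = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; "
                f"valid: {sorted(STRUCTURES)}"
            )
        expected = STRUCTURES[self.structure]
        if not isinstance(self.params, expected):
            raise ValueError(
                f"structure {self.structure!r} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )
        if self.extension is not None and not isinstance(
            self.extension, YeastExtensionParams
        ):
            raise ValueError("extension must be YeastExtensionParams")

    @property
    def has_extension(self) -> bool:
        return self.extension is not None

    def to_dict(self) -> dict:
        d = {"structure": self.structure, "params": self.params.to_dict()}
        if self.extension is not None:
            d["extension"] = self.extension.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        structure = d["structure"]
        if structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {structure!r}; valid: {sorted(STRUCTURES)}"
            )
        params = STRUCTURES[structure].from_dict(d["params"])
        ext = d.get("extension")
        extension = YeastExtensionParams.from_dict(ext) if ext else None
        return cls(structure=structure, params=params, extension=extension)


# --------------------------------------------------------------------------
# hydrogen uptake laws (scalar core, used by both API and integrator)
# --------------------------------------------------------------------------


def _sigmoid(z: float) -> float:
    # overflow-safe logistic
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def t2_gate(H: float, p: T2Params) -> float:
    """Sigmoid uptake gate F(H) = 1 / (1 + exp(A (T - H))), in (0, 1)."""
    H = _check_finite("H", H)
    return _sigmoid(p.A * (H - p.T))


def _dH(structure: str, H: float, P: float, X: float, p) -> float:
    """Hydrogen derivative for one structure; assumes clipped inputs."""
    if structure == "monod":
        return -(p.mu_max * X / p.Y) * H / (p.K_H + H)
    if structure == "first_order":
        return -p.eta * X * H / p.Y
    if structure == "t1":
        Hs = H - p.H_t
        if Hs <= 0.0:
            return 0.0
        return -p.eta * Hs * X / p.Y
    if structure == "t2":
        return -p.eta * X * H * _sigmoid(p.A * (H - p.T)) / p.Y
    if structure == "t3":
        num = p.mu_max_H * H / p.K_H - p.mu_max_R * P / p.K_R
        den = 1.0 + H / p.K_H + P / p.K_R
        return -(X / p.Y) * num / den
    if structure == "t1_nonlinear":
        Hs = max(H - p.H_t, 0.0)
        return -(p.mu_max * X / p.Y) * Hs / (p.K_H + Hs)
    if structure == "t2_nonlinear":
        # smooth-threshold Monod: effective substrate H - H_t*f gated by F
        f = _sigmoid(p.A * (H - p.H_t))
        F = _sigmoid(p.A * (H - p.T))
        Heff = H - p.H_t * f
        return -(p.mu_max * X / p.Y) * (Heff / (p.K_H + Heff)) * F
    raise ValueError(f"unknown structure {structure!r}")


def base_derivatives(
    structure: str, H: float, P: float, X: float, p
) -> tuple:
    """(dH, dP, dX) for a base (non-extended) structure.

    Negative state components from integrator overshoot are clipped to 0
    before evaluation, keeping the derivatives well defined.
    """
    H = max(H, 0.0)
    P = max(P, 0.0)
    X = max(X, 0.0)
    dH = _dH(structure, H, P, X, p)
    dP = -0.25 * dH
    dX = -p.Y * dH - p.k_d * X
    return dH, dP, dX


def extended_derivatives(
    structure: str, H: float, P: float, X: float, E: float, p, ext
) -> tuple:
    """(dH, dP, dX, dE) with the yeast-extract extension applied."""
    H = max(H, 0.0)
    P = max(P, 0.0)
    X = max(X, 0.0)
    E = max(E, 0.0)
    dH = _dH(structure, H, P, X, p)
    dE = -ext.eta_E * X * E / ext.Y_E
    dP = -0.25 * dH - ext.b_EP * dE
    dX = -p.Y * dH - ext.Y_E * dE - p.k_d * X
    return dH, dP, dX, dE


# --------------------------------------------------------------------------
# public per-structure operations
# --------------------------------------------------------------------------


def _validate_state_params(state: CultureState, p) -> None:
    # dataclass constructors already validate; guard against raw objects
    for name in ("H", "P", "X"):
        _check_finite(name, getattr(state, name))
    for f in fields(p):
        _check_finite(f.name, getattr(p, f.name))


def monod_rhs(state: CultureState, p: MonodParams) -> StateDerivative:
    """Monod-kinetics state derivative (dH/dt, dP/dt, dX/dt)."""
    _validate_state_params(state, p)
    return StateDerivative(*base_derivatives("monod", state.H, state.P, state.X, p))


def first_order_rhs(state: CultureState, p: FirstOrderParams) -> StateDerivative:
    """First-order-kinetics state derivative."""
    _validate_state_params(state, p)
    return StateDerivative(
        *base_derivatives("first_order", state.H, state.P, state.X, p)
    )


def t1_rhs(state: CultureState, p: T1Params) -> StateDerivative:
    """Hard-threshold state derivative; dH/dt = 0 whenever H <= H_t."""
    _validate_state_params(state, p)
    return StateDerivative(*base_derivatives("t1", state.H, state.P, state.X, p))


def t2_rhs(state: CultureState, p: T2Params) -> StateDerivative:
    """Sigmoid-gated state derivative."""
    _validate_state_params(state, p)
    return StateDerivative(*base_derivatives("t2", state.H, state.P, state.X, p))


def t3_rhs(state: CultureState, p: T3Params) -> StateDerivative:
    """Reversible Michaelis-Menten state derivative."""
    _validate_state_params(state, p)
    return StateDerivative(*base_derivatives("t3", state.H, state.P, state.X, p))


def extended_rhs(state: CultureState, spec: ModelSpec) -> StateDerivative:
    """State derivative including dE/dt for an extended ModelSpec."""
    if spec.extension is None:
        raise ValueError("extended_rhs requires a ModelSpec with an extension")
    if state.E is None:
        raise ValueError("extended model requires a state with E")
    _validate_state_params(state, spec.params)
    _check_finite("E", state.E)
    return StateDerivative(
        *extended_derivatives(
            spec.structure, state.H, state.P, state.X, state.E,
            spec.params, spec.extension,
        )
    )


def hydrogen_uptake_rate(spec: ModelSpec, state: CultureState) -> float:
    """dH/dt for any spec/state combination (extension leaves it unchanged)."""
    return _dH(
        spec.structure,
        max(state.H, 0.0),
        max(state.P, 0.0),
        max(state.X, 0.0),
        spec.params,
    )


def rhs(state: CultureState, spec: ModelSpec) -> StateDerivative:
    """Dispatch to the structure's derivative; handles extensions."""
    if spec.has_extension:
        return extended_rhs(state, spec)
    _validate_state_params(state, spec.params)
    return StateDerivative(
        *base_derivatives(spec.structure, state.H, state.P, state.X, spec.params)
    )
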