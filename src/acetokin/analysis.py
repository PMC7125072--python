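"""Closed-form analyses: unit conversions, stoichiometry bounds, steady state.

Covers the desk calculations that accompany the kinetic models: optical
density to cell dry weight, g L^-1 to mM conversions, the ideal-gas
hydrogen inventory of a serum-bottle headspace, the stoichiometric ceiling
on acetate from that inventory (4 H2 -> 1 acetate), the non-trivial steady
state of the reversible Michaelis-Menten model, and the Ribes-style default
sigmoid tuning derived from a threshold estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from .calibration import FitResult
from .kinetics import T2Params, T3Params

__all__ = [
    "GAS_CONSTANT",
    "MOLAR_MASS",
    "OD_TO_CDW_FACTOR",
    "CULTURE_TEMPERATURE_K",
    "HeadspaceSpec",
    "od_to_cdw",
    "gram_per_litre_to_mM",
    "mM_to_gram_per_litre",
    "headspace_h2_moles",
    "max_acetate_mM",
    "t3_steady_state_ratio",
    "ribes_default_tuning",
    "compare_media",
]

#: ideal gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314

#: molar masses, g mol^-1
MOLAR_MASS = {"hydrogen": 2.016, "acetate": 59.044}

#: cell dry weight (g L^-1) per unit optical density for B. hydrogenotrophica
OD_TO_CDW_FACTOR = 0.37

#: default culture temperature (37 C) for headspace gas inventories
CULTURE_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class HeadspaceSpec:
    """Gas headspace of a sealed culture vessel.

    volume : headspace volume, L
    pressure : total pressure, kPa
    h2_fraction : mole fraction of H2 in the gas mix (0-1)
    temperature : K
    medium_volume : liquid medium volume, L
    """

    volume: float
    pressure: float
    h2_fraction: float
    temperature: float = CULTURE_TEMPERATURE_K
    medium_volume: float = 0.1

    def __post_init__(self):
        for name in ("volume", "pressure", "temperature", "medium_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.h2_fraction <= 1:
            raise ValueError("h2_fraction must be within [0, 1]")


def od_to_cdw(od: float) -> float:
    """Convert optical density to cell dry weight, g L^-1 (CDW = 0.37 * OD)."""
    if od < 0:
        raise ValueError(f"optical density must be >= 0, got {od!r}")
    return OD_TO_CDW_FACTOR * od


def gram_per_litre_to_mM(value: float, species: str) -> float:
    """Convert g L^-1 to mM for 'hydrogen' (2.016 g/mol) or 'acetate' (59.044)."""
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value!r}")
    try:
        molar_mass = MOLAR_MASS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; valid: {sorted(MOLAR_MASS)}"
        ) from None
    return value / molar_mass * 1000.0


def mM_to_gram_per_litre(value: float, species: str) -> float:
    """Inverse of :func:`gram_per_litre_to_mM`."""
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value!r}")
    try:
        molar_mass = MOLAR_MASS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; valid: {sorted(MOLAR_MASS)}"
        ) from None
    return value * molar_mass / 1000.0


def headspace_h2_moles(spec: HeadspaceSpec) -> float:
    """Moles of H2 in the headspace by the ideal gas law.

    n = x_H2 * p * V / (R * T) with p in Pa and V in m^3; with p in kPa and
    V in L the unit factors cancel.
    """
    return (
        spec.h2_fraction
        * spec.pressure
        * spec.volume
        / (GAS_CONSTANT * spec.temperature)
    )


def max_acetate_mM(h2_moles: float, medium_volume: float) -> float:
    """Stoichiometric ceiling on acetate (mM) from a hydrogen inventory.

    Wood-Ljungdahl stoichiometry consumes 4 mol H2 per mol acetate, so at
    most h2_moles/4 mol of acetate can appear in ``medium_volume`` litres.
    Acetate beyond this bound cannot come from acetogenesis on the
    available hydrogen and indicates another carbon source (e.g. yeast
    extract) is being fermented.
    """
    if h2_moles <= 0 or medium_volume <= 0:
        raise ValueError("h2_moles and medium_volume must be positive")
    return h2_moles / 4.0 / medium_volume * 1000.0


def t3_steady_state_ratio(p: T3Params) -> float:
    """Acetate:hydrogen ratio P/H at which the reversible flux vanishes.

    The net hydrogen flux of the reversible Michaelis-Menten model is
    proportional to mu_max_H*H/K_H - mu_max_R*P/K_R; it is zero exactly
    when P/H = (mu_max_H * K_R) / (mu_max_R * K_H).  Trajectories with
    biomass present are attracted to this metabolite ratio: below it
    hydrogen is consumed, above it the net reaction reverses.
    """
    return (p.mu_max_H * p.K_R) / (p.mu_max_R * p.K_H)


def ribes_default_tuning(H_t: float) -> tuple:
    """Default sigmoid-gate tuning (A, T) from a threshold estimate.

    The Ribes-style recommendation ties the gate to the substrate
    threshold: steepness A = 100 / H_t (mM^-1) and midpoint T = 1.1 * H_t
    (mM).  Useful as a starting point, though fitted values for a given
    organism can differ from these by an order of magnitude.
    """
    if H_t <= 0:
        raise ValueError(f"H_t must be positive, got {H_t!r}")
    return (100.0 / H_t, 1.1 * H_t)


def _media_entry(name: str, fit: FitResult, bound: float) -> dict:
    terminal = fit.terminal_acetate()
    exceeds = terminal > bound
    return {
        "medium": name,
        "structure": fit.structure,
        "terminal_acetate_mM": terminal,
        "stoichiometric_bound_mM": bound,
        "exceeds_bound": exceeds,
        "excess_mM": max(terminal - bound, 0.0),
        "r_squared": dict(fit.r_squared),
    }


def compare_media(
    fit_ga: FitResult,
    fit_dsmz: FitResult,
    bound: float,
    names: tuple = ("GA", "DSMZ"),
) -> dict:
    """Compare two media fits against the hydrogen stoichiometry bound.

    Flags any fit whose predicted terminal acetate exceeds the
    acetogenesis ceiling ``bound`` (mM) — evidence that acetate is being
    produced from carbon sources other than H2/CO2 — and tabulates the
    per-variable R^2 of both fits side by side.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    entries = [
        _media_entry(names[0], fit_ga, bound),
        _media_entry(names[1], fit_dsmz, bound),
    ]
    report = {
        "bound_mM": bound,
        "media": entries,
        "flagged": [e["medium"] for e in entries if e["exceeds_bound"]],
        "r_squared": {
            names[0]: dict(fit_ga.r_squared),
            names[1]: dict(fit_dsmz.r_squared),
        },
    }
    return report


def format_media_report(report: dict) -> str:
    """Human-readable rendering of a :func:`compare_media` report."""
    lines = [f"Stoichiometric acetate bound: {report['bound_mM']:.1f} mM"]
    for e in report["media"]:
        status = (
            f"EXCEEDS bound by {e['excess_mM']:.1f} mM "
            "(acetate from non-H2 carbon sources)"
            if e["exceeds_bound"]
            else "within bound"
        )
        lines.append(
            f"  {e['medium']} ({e['structure']}): terminal acetate "
            f"{e['terminal_acetate_mM']:.1f} mM - {status}"
        )
        r2 = ", ".join(f"{k}={v:.2f}" for k, v in e["r_squared"].items())
        lines.append(f"    R^2: {r2}")
    return "\n".join(lines)
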