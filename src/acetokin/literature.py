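"""Published reference parameter values for *Blautia hydrogenotrophica*.

Best-fit parameter estimates (with 95% intervals) from MCMC calibration of
each model structure against batch monoculture time-course data (Bernalier
et al. style experiments: H2/CO2 headspace, hydrogen, acetate and cell dry
weight followed over tens of hours).  These serve as defaults for the
synthetic-data scenarios and as the generating values in parameter-recovery
tests.  They are point estimates from a single calibration dataset, not
physical constants.
"""

from __future__ import annotations

from .kinetics import (
    FirstOrderParams,
    MonodParams,
    T1Params,
    T2Params,
    T3Params,
    YeastExtensionParams,
)

__all__ = [
    "FIRST_ORDER_BEST_FIT",
    "T1_BEST_FIT",
    "T2_BEST_FIT",
    "T3_BEST_FIT",
    "MONOD_SYNTHETIC_REFERENCE",
    "BEST_FIT_CI95",
    "MONOD_REPORTED_DIAGNOSTICS",
    "YEAST_EXTENSION_T2",
    "YEAST_EXTENSION_T2_KD",
    "YEAST_EXTENSION_T3",
    "YEAST_EXTENSION_T3_KD",
    "LECLERC_THRESHOLD",
    "reference_params",
]

#: first-order kinetics best fit
FIRST_ORDER_BEST_FIT = FirstOrderParams(eta=0.0008, Y=0.0037, k_d=0.087)

#: hard-threshold (T1) best fit; H_t is the estimated hydrogen threshold
T1_BEST_FIT = T1Params(eta=0.0008, Y=0.0014, k_d=0.014, H_t=86.2)

#: sigmoid-gated (T2) best fit
T2_BEST_FIT = T2Params(eta=0.0054, Y=0.0017, k_d=0.019, A=0.015, T=336.0)

#: reversible Michaelis-Menten (T3) best fit
T3_BEST_FIT = T3Params(
    mu_max_H=0.451, mu_max_R=0.002, K_H=295.8, K_R=4.5, Y=0.0018, k_d=0.022
)

#: SYNTHETIC Monod reference set (no reliable published Monod estimate
#: exists: mu_max and K_H are not separately identifiable from single batch
#: data, only their ratio).  Chosen so mu_max / K_H equals the published
#: first-order rate eta = 0.0008 h^-1 mM^-1, with K_H on the order of the
#: initial hydrogen concentration.  Used only for generating synthetic data.
MONOD_SYNTHETIC_REFERENCE = MonodParams(mu_max=0.24, K_H=300.0, Y=0.0037, k_d=0.087)

#: 95% intervals accompanying the best fits above
BEST_FIT_CI95 = {
    "first_order": {
        "eta": (0.0007, 0.0031),
        "Y": (0.0026, 0.0363),
        "k_d": (0.067, 0.514),
    },
    "t1": {
        "eta": (0.0007, 0.0032),
        "Y": (0.0013, 0.0192),
        "k_d": (0.011, 0.306),
        "H_t": (6.1, 132.6),
    },
    "t2": {
        "eta": (0.0018, 0.0553),
        "Y": (0.0012, 0.0274),
        "k_d": (0.012, 0.357),
        "A": (0.0002, 0.1096),
        "T": (48.0, 3509.0),
    },
    "t3": {
        "mu_max_H": (0.24, 5.025),
        "mu_max_R": (0.001, 0.058),
        "K_H": (55.3, 395.8),
        "K_R": (0.14, 6.4),
        "Y": (0.0009, 0.0072),
        "k_d": (0.004, 0.089),
    },
}

#: diagnostics reported for the unconstrained Monod fit: a half-saturation
#: estimate far above any realistic dissolved-hydrogen level, an enormous
#: interval, and strong mu_max-K_H correlation — the signature of ridge
#: non-identifiability that motivates the first-order linearisation.
MONOD_REPORTED_DIAGNOSTICS = {
    "K_H_mM": 37328.0,
    "K_H_ci95_mM": (1770.0, 77680.0),
    "corr_mu_max_K_H": 0.93,
}

#: hypothetical yeast-extract extension sets used for the two-substrate
#: DSMZ-medium simulations (illustrative values, not fitted estimates; the
#: death rate k_d replacing the base-model value is listed alongside)
YEAST_EXTENSION_T2 = YeastExtensionParams(eta_E=0.0018, Y_E=0.02, b_EP=0.43)
YEAST_EXTENSION_T2_KD = 0.112
YEAST_EXTENSION_T3 = YeastExtensionParams(eta_E=0.002, Y_E=0.013, b_EP=0.5)
YEAST_EXTENSION_T3_KD = 0.08

#: literature hydrogen-uptake threshold for B. hydrogenotrophica
#: (Leclerc et al.): measured as 1100 +/- 200 ppm, quoted in the modelling
#: literature as 70 +/- 12.7 mM.  Stored as a citation constant only —
#: the ppm -> mM conversion basis is not stated, so it is not recomputed.
LECLERC_THRESHOLD = {
    "value_mM": 70.0,
    "sd_mM": 12.7,
    "measured": "1100 +/- 200 ppm",
    "source": "Leclerc et al., threshold for hydrogen uptake",
}


def reference_params(structure: str):
    """Reference parameter record for a base structure.

    Published best fits for first_order/t1/t2/t3; the synthetic Monod
    reference for ``monod``.
    """
    table = {
        "monod": MONOD_SYNTHETIC_REFERENCE,
        "first_order": FIRST_ORDER_BEST_FIT,
        "t1": T1_BEST_FIT,
        "t2": T2_BEST_FIT,
        "t3": T3_BEST_FIT,
    }
    try:
        return table[structure]
    except KeyError:
        raise ValueError(
            f"no reference parameters for {structure!r}; valid: {sorted(table)}"
        ) from None
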