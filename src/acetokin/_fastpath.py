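"""Compiled (numba) sampling path for base-structure calibrations.

The MCMC inner loop evaluates the model tens of thousands of times per
fit; a pure-Python ODE callback caps throughput near a millisecond per
iteration.  This module compiles the whole loop — a Dormand-Prince RK45
integrator, the normalised-squared-difference objective, and the adaptive
Metropolis chain — so realistic chain lengths are affordable on one CPU.
Chains are deterministic given their seed (numba's per-thread RNG).

Used automatically for non-extended structures; extended (yeast-extract)
fits, and any environment without numba, use the interpreted path in
:mod:`acetokin.calibration`, which implements the identical algorithm.

Parameter vector layouts (dataclass field order):
  code 0 monod:       [mu_max, K_H, Y, k_d]
  code 1 first_order: [eta, Y, k_d]
  code 2 t1:          [eta, Y, k_d, H_t]
  code 3 t2:          [eta, Y, k_d, A, T]
  code 4 t3:          [mu_max_H, mu_max_R, K_H, K_R, Y, k_d]
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


STRUCTURE_CODES = {"monod": 0, "first_order": 1, "t1": 2, "t2": 3, "t3": 4}

#: per-objective step budget; exhausted -> +inf (proposal rejected)
MAX_STEPS = 200_000


@njit(cache=True)
def _deriv(code, y, p, out):
    H = y[0] if y[0] > 0.0 else 0.0
    P = y[1] if y[1] > 0.0 else 0.0
    X = y[2] if y[2] > 0.0 else 0.0
    if code == 0:
        dH = -(p[0] * X / p[2]) * H / (p[1] + H)
        Y = p[2]
        kd = p[3]
    elif code == 1:
        dH = -p[0] * X * H / p[1]
        Y = p[1]
        kd = p[2]
    elif code == 2:
        Hs = H - p[3]
        dH = -p[0] * Hs * X / p[1] if Hs > 0.0 else 0.0
        Y = p[1]
        kd = p[2]
    elif code == 3:
        z = p[3] * (H - p[4])
        if z >= 0.0:
            F = 1.0 / (1.0 + math.exp(-z))
        else:
            ez = math.exp(z)
            F = ez / (1.0 + ez)
        dH = -p[0] * X * H * F / p[1]
        Y = p[1]
        kd = p[2]
    else:
        num = p[0] * H / p[2] - p[1] * P / p[3]
        den = 1.0 + H / p[2] + P / p[3]
        dH = -(X / p[4]) * num / den
        Y = p[4]
        kd = p[5]
    out[0] = dH
    out[1] = -0.25 * dH
    out[2] = -Y * dH - kd * X


@njit(cache=True)
def _objective_nb(code, p, y0, times, obs, scales, rtol, atol):
    """RK45 (Dormand-Prince 5(4)) solve with objective accumulation.

    obs/scales are (n_times, 3) with NaN marking missing observations.
    Returns +inf on step-budget exhaustion or non-finite state.
    """
    n = times.shape[0]
    y = y0.copy()
    total = 0.0
    for j in range(3):
        o = obs[0, j]
        if not math.isnan(o):
            v = y[j] if y[j] > 0.0 else 0.0
            r = (v - o) / scales[0, j]
            total += r * r

    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    k5 = np.empty(3)
    k6 = np.empty(3)
    k7 = np.empty(3)
    ytmp = np.empty(3)
    ynew = np.empty(3)
    steps = 0
    dt = (times[n - 1] - times[0]) * 1e-3
    if dt <= 0.0:
        dt = 1e-3

    for seg in range(1, n):
        t = times[seg - 1]
        t_end = times[seg]
        while t < t_end:
            if steps >= MAX_STEPS:
                return math.inf
            steps += 1
            h = dt
            if h > t_end - t:
                h = t_end - t
            _deriv(code, y, p, k1)
            for j in range(3):
                ytmp[j] = y[j] + h * 0.2 * k1[j]
            _deriv(code, ytmp, p, k2)
            for j in range(3):
                ytmp[j] = y[j] + h * (0.075 * k1[j] + 0.225 * k2[j])
            _deriv(code, ytmp, p, k3)
            for j in range(3):
                ytmp[j] = y[j] + h * (
                    (44.0 / 45.0) * k1[j]
                    - (56.0 / 15.0) * k2[j]
                    + (32.0 / 9.0) * k3[j]
                )
            _deriv(code, ytmp, p, k4)
            for j in range(3):
                ytmp[j] = y[j] + h * (
                    (19372.0 / 6561.0) * k1[j]
                    - (25360.0 / 2187.0) * k2[j]
                    + (64448.0 / 6561.0) * k3[j]
                    - (212.0 / 729.0) * k4[j]
                )
            _deriv(code, ytmp, p, k5)
            for j in range(3):
                ytmp[j] = y[j] + h * (
                    (9017.0 / 3168.0) * k1[j]
                    - (355.0 / 33.0) * k2[j]
                    + (46732.0 / 5247.0) * k3[j]
                    + (49.0 / 176.0) * k4[j]
                    - (5103.0 / 18656.0) * k5[j]
                )
            _deriv(code, ytmp, p, k6)
            for j in range(3):
                ynew[j] = y[j] + h * (
                    (35.0 / 384.0) * k1[j]
                    + (500.0 / 1113.0) * k3[j]
                    + (125.0 / 192.0) * k4[j]
                    - (2187.0 / 6784.0) * k5[j]
                    + (11.0 / 84.0) * k6[j]
                )
            _deriv(code, ynew, p, k7)
            # embedded 4th-order error estimate
            errnorm = 0.0
            ok = True
            for j in range(3):
                e = h * (
                    (71.0 / 57600.0) * k1[j]
                    - (71.0 / 16695.0) * k3[j]
                    + (71.0 / 1920.0) * k4[j]
                    - (17253.0 / 339200.0) * k5[j]
                    + (22.0 / 525.0) * k6[j]
                    - (1.0 / 40.0) * k7[j]
                )
                ya = abs(y[j])
                yb = abs(ynew[j])
                sc = atol + rtol * (ya if ya > yb else yb)
                q = e / sc
                errnorm += q * q
                if not math.isfinite(ynew[j]):
                    ok = False
            errnorm = math.sqrt(errnorm / 3.0)
            if ok and errnorm <= 1.0:
                t += h
                for j in range(3):
                    y[j] = ynew[j]
                fac = 5.0 if errnorm == 0.0 else 0.9 * errnorm ** -0.2
                if fac > 5.0:
                    fac = 5.0
                dt = h * fac
            else:
                fac = 0.2 if not ok else max(0.9 * errnorm ** -0.2, 0.2)
                dt = h * fac
                if dt <= 1e-14 * (times[n - 1] - times[0]):
                    return math.inf
        for j in range(3):
            o = obs[seg, j]
            if not math.isnan(o):
                v = y[j] if y[j] > 0.0 else 0.0
                r = (v - o) / scales[seg, j]
                total += r * r
    if not math.isfinite(total):
        return math.inf
    return total


@njit(cache=True)
def _logpost_nb(code, pvec, free_idx, theta, y0, times, obs, scales,
                rtol, atol, n_obs):
    for i in range(theta.shape[0]):
        pvec[free_idx[i]] = math.exp(theta[i])
    obj = _objective_nb(code, pvec, y0, times, obs, scales, rtol, atol)
    if not math.isfinite(obj):
        return -math.inf
    return -0.5 * n_obs * math.log(obj / n_obs + 1e-12)


@njit(cache=True)
def run_chain_nb(code, pvec0, free_idx, theta0, lo, hi, step0,
                 n_iterations, burn, adapt, seed,
                 y0, times, obs, scales, rtol, atol, n_obs):
    """Adaptive-covariance random-walk Metropolis chain in log space.

    Mirrors the interpreted implementation: records the state at the start
    of each iteration, adapts a scaled empirical covariance during burn-in
    only, and tracks the best recorded sample.  Returns
    (samples, n_accept, best_theta, best_lp, ok_start).
    """
    np.random.seed(seed)
    d = theta0.shape[0]
    pvec = pvec0.copy()
    theta = theta0.copy()
    lp = _logpost_nb(code, pvec, free_idx, theta, y0, times, obs, scales,
                     rtol, atol, n_obs)
    samples = np.empty((n_iterations, d))
    n_accept = 0
    best_theta = theta.copy()
    best_lp = lp
    if not math.isfinite(lp):
        return samples, -1, best_theta, best_lp, False

    sd_scale = 2.38**2 / d
    eps = 1e-10
    mean = theta.copy()
    cov = np.zeros((d, d))
    for i in range(d):
        cov[i, i] = step0[i] * step0[i]
    reg = cov.copy()
    for i in range(d):
        reg[i, i] += eps
    chol = np.linalg.cholesky(reg)
    count = 1
    adapt_after = max(2 * d, 20)
    delta = np.empty(d)

    for it in range(n_iterations):
        for i in range(d):
            samples[it, i] = theta[i]
        if lp > best_lp:
            best_lp = lp
            for i in range(d):
                best_theta[i] = theta[i]
        if it == n_iterations - 1:
            break
        z = np.random.standard_normal(d)
        prop = theta + chol @ z
        inside = True
        for i in range(d):
            if prop[i] < lo[i] or prop[i] > hi[i]:
                inside = False
                break
        if inside:
            lp_prop = _logpost_nb(code, pvec, free_idx, prop, y0, times,
                                  obs, scales, rtol, atol, n_obs)
            u = np.random.random()
            if u < 1e-300:
                u = 1e-300
            if math.log(u) < lp_prop - lp:
                for i in range(d):
                    theta[i] = prop[i]
                lp = lp_prop
                n_accept += 1
        if adapt and it < burn:
            count += 1
            for i in range(d):
                delta[i] = theta[i] - mean[i]
            for i in range(d):
                mean[i] += delta[i] / count
            for i in range(d):
                for j in range(d):
                    cov[i, j] += (delta[i] * (theta[j] - mean[j]) - cov[i, j]) / count
            if count > adapt_after and it % 25 == 0:
                for i in range(d):
                    for j in range(d):
                        reg[i, j] = sd_scale * cov[i, j]
                    reg[i, i] += eps
                try:
                    chol = np.linalg.cholesky(reg)
                except Exception:
                    pass
    return samples, n_accept, best_theta, best_lp, True
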