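"""IRF-convolved kinetic model functions and shared-parameter global fitting.

All model functions are causal responses convolved with a Gaussian instrument
response function (IRF) of standard deviation ``sigma = FWHM / (2 sqrt(2 ln 2))``.
Closed forms are used throughout:

* Gaussian (x) causal exponential:
  ``0.5 exp(s^2/2t^2 - u/t) erfc((s/t - u/s)/sqrt 2)``, ``u = t - t0``.
* Gaussian (x) causal damped cosine: the same closed form with a complex decay
  rate ``a = 1/tau_d - 2 pi i / T``, taking the real part.

Both are evaluated through the scaled complementary error function ``erfcx``
so they stay finite for delays far before and far after time zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

__all__ = [
    "KineticParams",
    "FitResult",
    "fwhm_to_sigma",
    "conv_step",
    "conv_exp",
    "conv_rise_plateau",
    "conv_damped_cos",
    "conv_biexp_rise",
    "rsv_model",
    "global_fit",
    "fit_biexp_rise",
    "period_to_frequency",
]

_SQRT2 = math.sqrt(2.0)
_C_CM_PER_S = 2.99792458e10


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class KineticParams:
    """Time constants of the three-species model (all in ps).

    ``irf_fwhm``: Gaussian IRF full width at half maximum (0.2 ps).
    ``tau_inst``: time constant of the quasi-instantaneous rise (0.02 ps),
    fixed, representing formation within the IRF.
    ``tau_decay``: exponential decay of the transient species (47.1 ps).
    ``period`` / ``tau_damp``: period and damping of the oscillatory species
    (5.55 / 2.68 ps).
    ``tau_rise1`` / ``tau_rise2`` / ``rise_weight``: biexponential rise of the
    vibrationally hot species (1.143 / 11.32 ps, weight of the fast branch).
    """

    irf_fwhm: float = 0.2
    tau_inst: float = 0.02
    tau_decay: float = 47.1
    period: float = 5.55
    tau_damp: float = 2.68
    tau_rise1: float = 1.143
    tau_rise2: float = 11.32
    rise_weight: float = 0.5
    t0: float = 0.0
    phase: float = 0.0

    def __post_init__(self):
        for name in (
            "irf_fwhm", "tau_inst", "tau_decay", "period",
            "tau_damp", "tau_rise1", "tau_rise2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sigma(self) -> float:
        return fwhm_to_sigma(self.irf_fwhm)


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares kinetic fit."""

    params: KineticParams
    amplitudes: list[tuple[float, ...]]
    covariance: np.ndarray
    param_names: list[str]
    stderr: dict[str, float]
    residual_rms: float
    fitted_curves: list[np.ndarray]
    converged: bool = True


# ---------------------------------------------------------------------------
# Closed-form convolutions


def conv_step(t, t0: float, sigma: float):
    """Gaussian IRF convolved with the unit step at t0."""
    u = np.asarray(t, float) - t0
    return 0.5 * special.erfc(-u / (sigma * _SQRT2))


def conv_exp(t, t0: float, tau: float, sigma: float):
    """Gaussian IRF convolved with ``exp(-u/tau) H(u)``; overflow-safe."""
    if tau <= 0 or sigma <= 0:
        raise ValueError("tau and sigma must be positive")
    u = np.asarray(t, float) - t0
    z = (sigma / tau - u / sigma) / _SQRT2
    out = np.empty_like(u)
    early = z > 0.0  # before/near t0: erfcx form avoids exp overflow
    out[early] = (
        0.5 * special.erfcx(z[early]) * np.exp(-(u[early] ** 2) / (2 * sigma**2))
    )
    late = ~early
    out[late] = (
        0.5
        * special.erfc(z[late])
        * np.exp(sigma**2 / (2 * tau**2) - u[late] / tau)
    )
    return out


def conv_rise_plateau(t, t0: float, tau_inst: float, sigma: float):
    """IRF (x) ``(1 - exp(-u/tau_inst)) H(u)``: rise to a unit plateau."""
    return conv_step(t, t0, sigma) - conv_exp(t, t0, tau_inst, sigma)


def conv_damped_cos(t, t0: float, period: float, tau_damp: float,
                    phase: float, sigma: float):
    """IRF (x) ``exp(-u/tau_d) cos(2 pi u/T + phase) H(u)``.

    Evaluated as the real part of the complex-rate closed form; the scaled
    complementary error function keeps the evaluation finite everywhere.
    """
    if period <= 0 or tau_damp <= 0 or sigma <= 0:
        raise ValueError("period, tau_damp and sigma must be positive")
    u = np.asarray(t, float) - t0
    a = 1.0 / tau_damp - 2j * np.pi / period
    zc = (sigma * a - u / sigma) / _SQRT2
    gauss = np.exp(-(u**2) / (2 * sigma**2))
    out = np.empty_like(u, dtype=complex)
    early = zc.real > 0.0
    out[early] = 0.5 * special.erfcx(zc[early]) * gauss[early]
    late = ~early
    # erfc(z) = 2 - erfc(-z); the first term carries the decaying oscillation
    out[late] = (
        np.exp(sigma**2 * a**2 / 2.0 - u[late] * a)
        - 0.5 * special.erfcx(-zc[late]) * gauss[late]
    )
    return (np.exp(1j * phase) * out).real


def conv_biexp_rise(t, t0: float, tau1: float, tau2: float, weight: float,
                    sigma: float):
    """IRF (x) ``(1 - w exp(-u/tau1) - (1-w) exp(-u/tau2)) H(u)``.

    Rises to a unit plateau with two time constants; models the growth of the
    vibrationally hot population.
    """
    return (
        conv_step(t, t0, sigma)
        - weight * conv_exp(t, t0, tau1, sigma)
        - (1.0 - weight) * conv_exp(t, t0, tau2, sigma)
    )


def rsv_model(t, params: KineticParams,
              amplitudes: tuple[float, float, float],
              rise: str = "plateau"):
    """Model for an RSV time profile: rise + decay + damped cosine.

    ``amplitudes = (a_rise, a_decay, a_osc)`` weight the rising term, the
    exponential decay (``tau_decay``) and the damped cosine (``period``,
    ``tau_damp``).  The rising term is the IRF-convolved unit plateau with
    time constant ``tau_inst`` (``rise='plateau'``, the form used for RSV
    fitting) or the biexponential rise of the hot species
    (``rise='biexp'``, for traces that contain thermal kinetics).
    """
    a_rise, a_decay, a_osc = amplitudes
    s = params.sigma
    out = np.zeros_like(np.asarray(t, float))
    if a_rise != 0.0 and rise == "plateau":
        out = out + a_rise * conv_rise_plateau(t, params.t0, params.tau_inst, s)
    elif a_rise != 0.0 and rise == "biexp":
        out = out + a_rise * conv_biexp_rise(
            t, params.t0, params.tau_rise1, params.tau_rise2,
            params.rise_weight, s,
        )
    elif rise not in ("plateau", "biexp"):
        raise ValueError(f"unknown rise model {rise!r}")
    if a_decay != 0.0:
        out = out + a_decay * conv_exp(t, params.t0, params.tau_decay, s)
    if a_osc != 0.0:
        out = out + a_osc * conv_damped_cos(
            t, params.t0, params.period, params.tau_damp, params.phase, s
        )
    return out


# ---------------------------------------------------------------------------
# Global fitting

_SHARED_DEFAULT = ("tau_decay", "period", "tau_damp", "t0")

_BOUNDS = {
    "tau_decay": (1e-3, 1e5),
    "period": (0.1, 1e3),
    "tau_damp": (1e-2, 1e4),
    "t0": (-0.3, 0.3),
    "phase": (-np.pi, np.pi),
    "tau_rise1": (1e-3, 1e4),
    "tau_rise2": (1e-3, 1e4),
    "rise_weight": (0.0, 1.0),
}


def global_fit(
    rsvs: list[tuple[np.ndarray, np.ndarray]],
    share: tuple[str, ...] = _SHARED_DEFAULT,
    init: KineticParams | None = None,
    max_nfev: int = 2000,
    rise: str = "plateau",
    baseline_delays=None,
) -> FitResult:
    """Fit several time traces with shared kinetic constants.

    Each trace in ``rsvs`` is ``(delays_ps, values)``.  The parameters named
    in ``share`` are optimized jointly across all traces; each trace gets its
    own ``(a_rise, a_decay, a_osc)`` amplitudes (see :func:`rsv_model`).  The
    IRF width and ``tau_inst`` stay fixed at their configured values.  With
    ``rise='biexp'`` the rising term is the hot-species biexponential and
    ``tau_rise1``/``tau_rise2``/``rise_weight`` may be added to ``share``.

    ``baseline_delays``: if given, the model's mean over these delays is
    subtracted from the model before comparing — matching data that were
    referenced to an average of (near-)negative delays, where IRF tails can
    leave a small pre-excitation offset.

    The amplitudes are eliminated by variable projection: at every trial
    value of the shared constants each trace's amplitudes are the linear
    least-squares solution, so the nonlinear optimizer only searches the
    low-dimensional space of time constants.

    Raises ``RuntimeError`` carrying the best-so-far parameters if the
    optimizer does not converge within ``max_nfev`` evaluations.
    """
    if not rsvs:
        raise ValueError("at least one trace is required")
    init = init or KineticParams()
    for name in share:
        if name not in _BOUNDS:
            raise ValueError(f"parameter {name!r} cannot be fitted")

    x0 = [getattr(init, name) for name in share]
    lo = [_BOUNDS[n][0] for n in share]
    hi = [_BOUNDS[n][1] for n in share]
    names = list(share)
    base = None if baseline_delays is None else np.asarray(baseline_delays, float)
    unit_amps = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def unpack(x):
        return replace(init, **dict(zip(share, x)))

    def trace_basis(t, p):
        basis = np.column_stack([rsv_model(t, p, a, rise) for a in unit_amps])
        if base is not None:
            basis = basis - np.array(
                [np.mean(rsv_model(base, p, a, rise)) for a in unit_amps]
            )
        return basis

    def solve_amps(p):
        amps, residuals = [], []
        for t, y in rsvs:
            basis = trace_basis(t, p)
            a, *_ = np.linalg.lstsq(basis, y, rcond=None)
            amps.append(tuple(float(v) for v in a))
            residuals.append(basis @ a - y)
        return amps, residuals

    def resid(x):
        _, residuals = solve_amps(unpack(x))
        return np.concatenate(residuals)

    res = optimize.least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
    )
    params = unpack(res.x)
    amps, residuals = solve_amps(params)
    curves = [
        np.asarray(trace_basis(t, params) @ np.array(a))
        for (t, y), a in zip(rsvs, amps)
    ]
    n_pts = sum(len(y) for _, y in rsvs)
    rms = float(np.sqrt(2.0 * res.cost / n_pts))
    cov, stderr = _covariance(res, n_pts, names)
    result = FitResult(
        params=params, amplitudes=amps, covariance=cov, param_names=names,
        stderr=stderr, residual_rms=rms, fitted_curves=curves,
        converged=res.status > 0,
    )
    if res.status <= 0:
        err = RuntimeError(f"global fit did not converge: {res.message}")
        err.result = result
        raise err
    return result


def _covariance(res, n_pts: int, names: list[str]):
    """Covariance from the Jacobian; zero matrix for a perfect fit."""
    j = res.jac
    dof = max(n_pts - len(res.x), 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj_inv = np.linalg.pinv(j.T @ j)
    except np.linalg.LinAlgError:
        jtj_inv = np.full((len(res.x), len(res.x)), np.nan)
    cov = s2 * jtj_inv
    stderr = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    return cov, stderr


def fit_biexp_rise(
    delays: np.ndarray,
    values: np.ndarray,
    init: KineticParams | None = None,
    fit_t0: bool = False,
    max_nfev: int = 2000,
) -> FitResult:
    """Fit a biexponential rise-to-plateau trace.

    Model: ``a * conv_biexp_rise(t; tau1, tau2, w)``.  Free parameters are
    ``tau_rise1``, ``tau_rise2``, ``rise_weight`` and the amplitude (plus
    ``t0`` when ``fit_t0``).  The two time constants are reported sorted so
    ``tau_rise1 <= tau_rise2``.
    """
    init = init or KineticParams()
    t = np.asarray(delays, float)
    y = np.asarray(values, float)
    free = ["tau_rise1", "tau_rise2", "rise_weight"] + (["t0"] if fit_t0 else [])
    x0 = [getattr(init, n) for n in free] + [float(np.max(np.abs(y))) or 1.0]
    lo = [_BOUNDS[n][0] for n in free] + [-np.inf]
    hi = [_BOUNDS[n][1] for n in free] + [np.inf]
    names = free + ["amplitude"]
    sigma = init.sigma

    def unpack(x):
        p = replace(init, **dict(zip(free, x[: len(free)])))
        return p, x[len(free)]

    def model(x):
        p, a = unpack(x)
        return a * conv_biexp_rise(
            t, p.t0, p.tau_rise1, p.tau_rise2, p.rise_weight, sigma
        )

    res = optimize.least_squares(
        lambda x: model(x) - y, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
    )
    params, amp = unpack(res.x)
    if params.tau_rise1 > params.tau_rise2:
        params = replace(
            params,
            tau_rise1=params.tau_rise2,
            tau_rise2=params.tau_rise1,
            rise_weight=1.0 - params.rise_weight,
        )
    rms = float(np.sqrt(2.0 * res.cost / len(y)))
    cov, stderr = _covariance(res, len(y), names)
    result = FitResult(
        params=params, amplitudes=[(float(amp),)], covariance=cov,
        param_names=names, stderr=stderr, residual_rms=rms,
        fitted_curves=[model(res.x)], converged=res.status > 0,
    )
    if res.status <= 0:
        err = RuntimeError(f"biexponential-rise fit did not converge: {res.message}")
        err.result = result
        raise err
    return result


def period_to_frequency(period_ps: float) -> tuple[float, float]:
    """Convert an oscillation period in ps to (THz, cm^-1)."""
    if period_ps <= 0:
        raise ValueError("period must be positive")
    thz = 1.0 / period_ps
    wavenumber = 1.0 / (_C_CM_PER_S * period_ps * 1e-12)
    return thz, wavenumber
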