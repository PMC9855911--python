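"""Maximum-entropy lifetime-distribution analysis (LDA).

A time trace y(t) is modelled as a quasi-continuous distribution of
exponential decays on a fixed logarithmic lifetime grid,

    y(t_j) = sum_k a_k exp(-t_j / tau_k) + c ,

an ill-posed discretized inverse Laplace transform.  The signed
amplitudes a_k (the only fitting parameters; the grid is fixed) are
regularized by the standard signed-MEM construction: a = p - n with
p, n >= 0 and the Shannon-Jaynes entropy relative to a flat prior m,

    S(p, n) = sum_k [p_k - m - p_k ln(p_k/m)] + [n_k - m - n_k ln(n_k/m)] ,

so each channel solves  min_{p,n>=0,c} 1/2 ||y - K(p-n) - c||^2 - lam*S.
The per-channel offset c absorbs components with lifetimes at or beyond
the experimental window.  The regularization weight is chosen once per
dataset (pooled over channels, so amplitudes stay comparable across the
map) by the L-curve criterion: the point of maximum curvature of the
log-log curve of total squared residual versus negentropy.

Numerics
--------
The entropy term acts as an interior barrier, so the optimum satisfies
the smooth stationarity conditions  p = m exp(g/lam), n = m exp(-g/lam)
with g = K^T r and r the fit residual.  Substituting back gives a small
nonlinear system in r (and c) only,

    r - y + K * 2m sinh(K^T r / lam) + c = 0 ,   sum(r) = 0 ,

solved by a damped Newton method, vectorized over channels (all channels
share the kernel) and warm-started along the descending lambda path.
This is exactly the KKT system of the convex primal problem, so the
Newton residual *is* the primal gradient; convergence is declared when
its norm drops below ``tol * ||y||``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    DatasetMeta,
    SpectralAxis,
    TimeGrid,
    TRDataset,
    ValidationError,
)

logger = logging.getLogger("flavidyn")

__all__ = [
    "LifetimeGrid",
    "AmplitudeMap",
    "RegularizationPath",
    "MEMFit",
    "build_lifetime_grid",
    "decay_kernel",
    "mem_fit_channel",
    "select_lambda_lcurve",
    "fit_lda",
    "reconstruct",
    "estimate_noise_sigma",
]

#: sinh/cosh argument clip; keeps intermediates finite at tiny lambda while
#: leaving the converged solution (|g/lam| ~ ln(|a|/m) ~ O(30)) untouched.
_UCLIP = 300.0

_DEFAULT_TOL = 1e-8
_DEFAULT_MAX_ITER = 10000


# ---------------------------------------------------------------------------
# Lifetime grid and kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifetimeGrid:
    """Fixed log-equidistant lifetime grid tau_k (seconds)."""

    taus: np.ndarray
    points_per_decade: int

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "taus", taus)
        if taus.ndim != 1 or taus.size < 2:
            raise ValidationError("lifetime grid needs at least 2 points")
        if np.any(taus <= 0):
            raise ValidationError("lifetimes must be > 0")
        ratios = taus[1:] / taus[:-1]
        if not np.allclose(ratios, ratios[0], rtol=1e-12):
            raise ValidationError("lifetime grid must be log-equidistant")

    @property
    def n_taus(self) -> int:
        return self.taus.size

    @property
    def log_step(self) -> float:
        """Grid step in log10(tau) units."""
        return float(np.log10(self.taus[1] / self.taus[0]))


def build_lifetime_grid(
    tau_min: float = 1e-13, tau_max: float = 1e-3, points_per_decade: int = 41
) -> LifetimeGrid:
    """Log grid tau_min * 10^(j/ppd) including both endpoints.

    When the decade span times ppd is not integral the point count is
    rounded up so the grid still ends exactly at ``tau_max``.
    """
    if not 0 < tau_min < tau_max:
        raise ValidationError("need 0 < tau_min < tau_max")
    if points_per_decade < 1:
        raise ValidationError("points_per_decade must be >= 1")
    decades = np.log10(tau_max / tau_min)
    steps_exact = decades * points_per_decade
    steps = int(round(steps_exact))
    if abs(steps_exact - steps) > 1e-9:
        steps = int(np.ceil(steps_exact))
    taus = np.geomspace(tau_min, tau_max, steps + 1)
    taus[0], taus[-1] = tau_min, tau_max
    return LifetimeGrid(taus, points_per_decade)


def decay_kernel(
    times: TimeGrid, grid: LifetimeGrid, with_offset: bool = True
) -> np.ndarray:
    """Discretized Laplace kernel K[j, k] = exp(-t_j / tau_k).

    With ``with_offset`` a final all-ones column represents the
    non-decaying component.
    """
    K = np.exp(-times.delays[:, None] / grid.taus[None, :])
    if with_offset:
        K = np.hstack([K, np.ones((times.n_delays, 1))])
    return K


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeMap:
    """Signed LDA amplitudes a[i, k] per channel i and lifetime tau_k."""

    amplitudes: np.ndarray  # (n_channels, n_taus)
    offsets: np.ndarray  # (n_channels,)
    grid: LifetimeGrid
    axis: SpectralAxis
    lambda_used: float
    converged: np.ndarray | None = None  # per-channel flags
    meta: DatasetMeta | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        off = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "offsets", off)
        if a.shape != (self.axis.n_channels, self.grid.n_taus):
            raise ValidationError(
                f"amplitude shape {a.shape} does not match "
                f"({self.axis.n_channels}, {self.grid.n_taus})"
            )
        if off.shape != (self.axis.n_channels,):
            raise ValidationError("need one offset per channel")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(off))):
            raise ValidationError("amplitude map contains non-finite values")


@dataclass(frozen=True)
class RegularizationPath:
    """Pooled chi^2 and negentropy along an ascending lambda path."""

    lambdas: np.ndarray
    chi2: np.ndarray
    negentropy: np.ndarray
    selected_index: int

    def __post_init__(self) -> None:
        lams = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lams)
        object.__setattr__(self, "chi2", np.asarray(self.chi2, dtype=float))
        object.__setattr__(self, "negentropy", np.asarray(self.negentropy, dtype=float))
        if np.any(lams <= 0) or not np.all(np.diff(lams) > 0):
            raise ValidationError("lambdas must be positive and ascending")
        if not 0 <= self.selected_index < lams.size:
            raise ValidationError("selected_index out of range")

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])


@dataclass(frozen=True)
class MEMFit:
    """Single-channel MEM fit result."""

    amplitudes: np.ndarray
    offset: float
    converged: bool
    n_iter: int
    chi2: float
    negentropy: float


# ---------------------------------------------------------------------------
# Batched damped-Newton MEM solver
# ---------------------------------------------------------------------------

def _mem_newton(
    Y: np.ndarray,
    K: np.ndarray,
    lam: float,
    m: float,
    with_offset: bool,
    tol: float,
    max_iter: int,
    R0: np.ndarray | None = None,
    o0: np.ndarray | None = None,
):
    """Solve the MEM stationarity system for all channels at one lambda.

    Y is (n_channels, n_delays); K is the pure decay kernel (n_delays,
    n_taus).  Returns (amplitudes, offsets, R, converged, n_iter).
    """
    n_c, n_t = Y.shape
    eye = np.eye(n_t)

    R = (Y - Y.mean(axis=1, keepdims=True)) if R0 is None else R0.copy()
    if with_offset:
        o = Y.mean(axis=1) if o0 is None else o0.copy()
    else:
        o = np.zeros(n_c)

    ynorm = np.linalg.norm(Y, axis=1)
    # absolute floor: channels carrying ~no signal relative to the dataset
    # converge to a tiny residual instead of chasing an unreachable 1e-8*||y||
    floor = 1e-3 * ynorm.max()
    ftol = tol * np.maximum(np.maximum(ynorm, floor), np.finfo(float).tiny)

    def residual(R, o, Yb=None):
        Yb = Y if Yb is None else Yb
        U = np.clip((R @ K) / lam, -_UCLIP, _UCLIP)
        a = 2.0 * m * np.sinh(U)
        Fr = R - Yb + a @ K.T + o[:, None]
        Fo = R.sum(axis=1)
        return U, a, Fr, Fo

    def merit(Fr, Fo):
        v = np.einsum("ct,ct->c", Fr, Fr)
        if with_offset:
            v = v + Fo**2
        return np.sqrt(v)

    U, a, Fr, Fo = residual(R, o)
    normF = merit(Fr, Fo)
    # channels whose line search cannot improve any further (limited by
    # conditioning at extreme lambda) are frozen at their best point
    frozen = np.zeros(n_c, dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        active = (normF > ftol) & ~frozen
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        w = (2.0 * m / lam) * np.cosh(U[idx])  # (na, n_k)
        Jrr = (K[None, :, :] * w[:, None, :]) @ K.T + eye  # (na, n_t, n_t)
        if with_offset:
            na = idx.size
            J = np.empty((na, n_t + 1, n_t + 1))
            J[:, :n_t, :n_t] = Jrr
            J[:, :n_t, n_t] = 1.0
            J[:, n_t, :n_t] = 1.0
            J[:, n_t, n_t] = 0.0
            F = np.concatenate([Fr[idx], Fo[idx, None]], axis=1)
        else:
            J = Jrr
            F = Fr[idx]
        try:
            delta = np.linalg.solve(J, -F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # Tikhonov-damped retry on (near-)singular Jacobians
            J = J + 1e-10 * np.trace(J, axis1=1, axis2=2)[:, None, None] * np.eye(
                J.shape[1]
            )
            delta = np.linalg.solve(J, -F[..., None])[..., 0]

        dR = delta[:, :n_t]
        do = delta[:, n_t] if with_offset else np.zeros(idx.size)

        # per-channel backtracking line search on the residual norm
        step = np.ones(idx.size)
        pending = np.ones(idx.size, dtype=bool)
        for _ in range(40):
            if not pending.any():
                break
            trialR = R[idx] + step[:, None] * dR
            trialo = o[idx] + step * do
            tU, ta, tFr, tFo = residual(trialR, trialo, Y[idx])
            tnorm = merit(tFr, tFo)
            ok = pending & (tnorm <= (1.0 - 1e-4 * step) * normF[idx])
            sel = np.nonzero(ok)[0]
            if sel.size:
                rows = idx[sel]
                R[rows] = trialR[sel]
                o[rows] = trialo[sel]
                U[rows], a[rows] = tU[sel], ta[sel]
                Fr[rows], Fo[rows] = tFr[sel], tFo[sel]
                normF[rows] = tnorm[sel]
                pending[sel] = False
            step[pending] *= 0.5
        if pending.any():
            # no improving step found: freeze these channels at their
            # current (best) point rather than accept a diverging update
            frozen[idx[pending]] = True

    converged = normF <= ftol
    # entropy and chi^2 at the implied primal point
    p = m * np.exp(U)
    n = m * np.exp(-U)
    negent = np.sum(p * U - p + m, axis=1) + np.sum(-n * U - n + m, axis=1)
    return a, o, R, converged, n_iter, negent


def _mem_solve(
    Y: np.ndarray,
    K: np.ndarray,
    lam: float,
    m: float,
    with_offset: bool,
    tol: float,
    max_iter: int,
    warm: tuple[np.ndarray, np.ndarray, float] | None = None,
):
    """Newton solve with lambda continuation.

    Cold starts descend from a heavily regularized lambda (where the
    solution is trivially the offset-only fit) to the target; warm starts
    rescale the previous residual by the lambda ratio (the residual
    scales with lambda near the solution, K^T r = lam * ln(p/m)).
    """
    if warm is not None:
        R0, o0, lam_prev = warm
        lam_path = [lam]
        R0 = R0 * (lam / lam_prev)
    else:
        R0 = o0 = None
        lam_big = max(lam, 10.0 * Y.shape[1] * max(float(np.max(Y**2)), m**2))
        n_steps = max(1, int(np.ceil(np.log10(lam_big / lam))))
        lam_path = np.geomspace(lam_big, lam, n_steps + 1)

    total_iter = 0
    lam_prev = None
    for lam_i in lam_path:
        if R0 is not None and lam_prev is not None:
            R0 = R0 * (lam_i / lam_prev)
        a, o, R, conv, it, negent = _mem_newton(
            Y, K, float(lam_i), m, with_offset, tol, max_iter, R0, o0
        )
        R0, o0, lam_prev = R, o, lam_i
        total_iter += it
    return a, o, R, conv, total_iter, negent


def mem_fit_channel(
    y: np.ndarray,
    K: np.ndarray,
    lam: float,
    prior_m: float,
    with_offset: bool = True,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> MEMFit:
    """Signed-MEM fit of one time trace on a fixed decay kernel.

    ``K`` is the pure decay kernel (no offset column); the offset is a
    separate unregularized parameter.  A cold start is stabilized by a
    short lambda continuation from a heavily regularized solution down to
    the requested ``lam``.  Non-convergence is reported via the
    ``converged`` flag and a log warning, never silently.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != K.shape[0]:
        raise ValidationError("trace length must match kernel rows")
    if lam <= 0:
        raise ValidationError("lambda must be > 0")
    if prior_m <= 0:
        raise ValidationError("prior_m must be > 0")
    Y = y[None, :]
    a, o, R, conv, total_iter, negent = _mem_solve(
        Y, K, float(lam), prior_m, with_offset, tol, max_iter
    )
    if not bool(conv[0]):
        logger.warning(
            "MEM channel fit did not reach tol=%g within %d iterations", tol, max_iter
        )
    resid = y - a[0] @ K.T - o[0]
    return MEMFit(
        amplitudes=a[0],
        offset=float(o[0]),
        converged=bool(conv[0]),
        n_iter=total_iter,
        chi2=float(resid @ resid),
        negentropy=float(negent[0]),
    )


# ---------------------------------------------------------------------------
# L-curve selection
# ---------------------------------------------------------------------------

def select_lambda_lcurve(path: RegularizationPath) -> float:
    """Corner of the (log10 chi^2, log10 negentropy) curve.

    The corner is the interior point of maximum discrete (Menger)
    curvature through each point and its two neighbours along the lambda
    path; ties go to the larger (more regularized) lambda.  Degenerate
    paths (all collinear) also fall back to the largest lambda.
    """
    lams = path.lambdas
    if lams.size < 3:
        raise ValidationError("L-curve selection needs at least 3 path points")
    floor = np.finfo(float).tiny
    x = np.log10(np.maximum(path.chi2, floor))
    y = np.log10(np.maximum(path.negentropy, floor))

    kappa = np.zeros(lams.size)
    for i in range(1, lams.size - 1):
        ax, ay = x[i] - x[i - 1], y[i] - y[i - 1]
        bx, by = x[i + 1] - x[i], y[i + 1] - y[i]
        cross = ax * by - ay * bx
        la = np.hypot(ax, ay)
        lb = np.hypot(bx, by)
        lc = np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1])
        denom = la * lb * lc
        kappa[i] = 2.0 * abs(cross) / denom if denom > 0 else 0.0

    kmax = kappa.max()
    if kmax <= 1e-12:
        return float(lams[-1])
    # ties to the larger lambda: scan from the large-lambda end
    for i in range(lams.size - 2, 0, -1):
        if kappa[i] >= kmax * (1.0 - 1e-9):
            return float(lams[i])
    return float(lams[int(np.argmax(kappa))])


# ---------------------------------------------------------------------------
# Dataset-level fit
# ---------------------------------------------------------------------------

def estimate_noise_sigma(signal: np.ndarray) -> float:
    """Robust noise scale from second differences along the time axis.

    The median absolute second difference is insensitive to the smooth
    kinetic signal (most delays sit on plateaus between events); the
    1.4826/sqrt(6) factor converts it to a Gaussian sigma.
    """
    if signal.shape[0] < 3:
        return float(np.std(signal)) or 1.0
    d2 = signal[:-2] - 2.0 * signal[1:-1] + signal[2:]
    sigma = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)
    if sigma <= 0:
        sigma = float(np.std(signal)) or 1.0
    return sigma


def default_lambda_path(
    ds_signal: np.ndarray, n_delays: int, n_lambdas: int = 24, decades: float = 6.0
) -> np.ndarray:
    """Log-spaced lambda path centered on lambda0 = n_delays * sigma^2."""
    sigma = estimate_noise_sigma(ds_signal)
    lam0 = n_delays * sigma**2
    half = decades / 2.0
    return np.geomspace(lam0 * 10**half, lam0 * 10**-half, n_lambdas)


def fit_lda(
    ds: TRDataset,
    grid: LifetimeGrid | None = None,
    lambdas: Sequence[float] | None = None,
    prior_scale: float = 1e-6,
    prior_m: float | None = None,
    with_offset: bool = True,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> tuple[AmplitudeMap, RegularizationPath]:
    """Fit every channel at every lambda; select one global lambda by L-curve.

    chi^2 and negentropy are pooled over channels per lambda; the returned
    amplitude map is the fit at the selected lambda.  The flat MEM prior
    defaults to ``prior_scale`` times the peak absolute signal.  ``seed``
    is accepted for interface uniformity; the fit is deterministic.
    """
    if grid is None:
        grid = build_lifetime_grid()
    if lambdas is None:
        lambdas = default_lambda_path(ds.signal, ds.n_delays)
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise ValidationError("lambda path must not be empty")
    if np.any(lambdas <= 0):
        raise ValidationError("lambdas must be > 0")
    if prior_m is None:
        prior_m = prior_scale * float(np.max(np.abs(ds.signal)))
        if prior_m <= 0:
            prior_m = prior_scale
    K = decay_kernel(ds.time, grid, with_offset=False)
    Y = ds.signal.T.copy()  # (n_channels, n_delays)

    order = np.argsort(lambdas)[::-1]  # descending, for warm starts
    lam_desc = lambdas[order]

    chi2s = np.empty(lam_desc.size)
    negents = np.empty(lam_desc.size)
    amps_all = np.empty((lam_desc.size, ds.n_channels, grid.n_taus))
    offs_all = np.empty((lam_desc.size, ds.n_channels))
    conv_all = np.empty((lam_desc.size, ds.n_channels), dtype=bool)

    warm = None
    for i, lam in enumerate(lam_desc):
        a, o, R, conv, _, negent = _mem_solve(
            Y, K, float(lam), prior_m, with_offset, tol, max_iter, warm
        )
        warm = (R, o, float(lam))
        resid = Y - a @ K.T - o[:, None]
        chi2s[i] = float(np.sum(resid**2))
        negents[i] = float(np.sum(negent))
        amps_all[i], offs_all[i], conv_all[i] = a, o, conv
        if not conv.all():
            logger.warning(
                "lambda=%.3g: %d/%d channels not converged",
                lam,
                int((~conv).sum()),
                ds.n_channels,
            )

    # re-sort ascending for the path object
    asc = np.argsort(lam_desc)
    path = RegularizationPath(
        lambdas=lam_desc[asc],
        chi2=chi2s[asc],
        negentropy=negents[asc],
        selected_index=0,
    )
    lam_star = select_lambda_lcurve(path)
    sel_asc = int(np.argmin(np.abs(path.lambdas - lam_star)))
    path = RegularizationPath(path.lambdas, path.chi2, path.negentropy, sel_asc)
    sel_desc = int(np.argmin(np.abs(lam_desc - lam_star)))
    logger.info("L-curve selected lambda* = %.4g", lam_star)

    amap = AmplitudeMap(
        amplitudes=amps_all[sel_desc],
        offsets=offs_all[sel_desc],
        grid=grid,
        axis=ds.axis,
        lambda_used=float(lam_star),
        converged=conv_all[sel_desc],
        meta=ds.meta,
    )
    return amap, path


def reconstruct(amap: AmplitudeMap, times: TimeGrid) -> np.ndarray:
    """Fitted matrix K(times) @ amplitudes^T + offsets, (n_delays, n_channels)."""
    K = decay_kernel(times, amap.grid, with_offset=False)
    return K @ amap.amplitudes.T + amap.offsets[None, :]
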