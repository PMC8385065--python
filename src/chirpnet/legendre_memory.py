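"""Legendre-polynomial memory: the mathematical core of the LMU.

A Legendre Memory Unit maintains a d-dimensional memory state ``m_t`` under
fixed linear dynamics ``m_t = Abar m_{t-1} + Bbar u_t``.  The continuous
system (A, B) is the classical delay-network construction: its state
approximates, at every instant, the coefficients of the least-squares
projection of the input's recent history (a sliding window of length theta)
onto Legendre polynomials.  This module provides

* the polynomials themselves (stable three-term recurrence, orthogonality
  check against the closed form 2/(2n+1));
* the *direct* projection oracle :func:`project_history` — numeric quadrature
  of the signal history against the shifted basis, the slow reference path
  that never touches the dynamical system;
* the state-space system, its discretization (zero-order hold / Euler), and
  :func:`run_recursive`, the fast recursion the LMU actually uses.

Basis orientation.  The history window ``[t - theta, t]`` is mapped onto the
polynomial domain [-1, 1] with the *most recent* sample at -1 and the oldest
at +1 (absolute time s maps to ``2(t-s)/theta - 1``).  This is the
orientation under which the delay-system state coincides with the projection
coefficients: the input enters through B with ``B_m ∝ P_m(-1) = (-1)^m``,
i.e. through the basis evaluated "now".  The mirrored map differs only by the
parity flip ``P_m(-x) = (-1)^m P_m(x)`` and would negate every odd channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.linalg import expm

from .synthetic_audio import ValidationError


# ---------------------------------------------------------------------------
# Legendre polynomials


def legendre_eval(m: int, x) -> np.ndarray | float:
    """P_m(x) on [-1, 1] via the Bonnet three-term recurrence."""
    if m < 0:
        raise ValidationError("degree must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValidationError("x outside [-1, 1]; extrapolation unsupported")
    vals = legendre_all(m + 1, np.atleast_1d(x))[m]
    return float(vals[0]) if x.ndim == 0 else vals


def legendre_all(d: int, x: np.ndarray) -> np.ndarray:
    """All degrees 0..d-1 at once: array (d, len(x))."""
    x = np.asarray(x, dtype=np.float64)
    P = np.zeros((d, x.size))
    P[0] = 1.0
    if d > 1:
        P[1] = x
    for m in range(1, d - 1):
        P[m + 1] = ((2 * m + 1) * x * P[m] - m * P[m - 1]) / (m + 1)
    return P


def orthogonality_check(max_degree: int, quadrature_order: int | None = None
                        ) -> float:
    """Max defect |<P_m, P_n> - delta_mn * 2/(2n+1)| over m, n < max_degree,
    with Gauss-Legendre quadrature (exact for the polynomial integrands when
    the order is sufficient for degree 2*max_degree)."""
    order = quadrature_order or (max_degree + 1)
    if 2 * order - 1 < 2 * (max_degree - 1):
        raise ValidationError("quadrature order insufficient for degree 2d")
    x, w = leggauss(order)
    P = legendre_all(max_degree, x)
    gram = (P * w) @ P.T
    n = np.arange(max_degree)
    expected = np.diag(2.0 / (2.0 * n + 1.0))
    return float(np.abs(gram - expected).max())


# ---------------------------------------------------------------------------
# direct projection oracle


@dataclass
class ProjectionCoeffs:
    """Per-time projection coefficients c_m(t): array (d, n_timepoints).
    Column t depends only on the signal history up to t (causal)."""

    coeffs: np.ndarray
    timepoints: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        self.timepoints = np.asarray(self.timepoints, dtype=np.float64)
        if self.coeffs.shape[1] != self.timepoints.size:
            raise ValidationError("one coefficient column per timepoint")


#: Gauss-Legendre nodes per unit step used by the quadrature oracle.
_QUAD_NODES = 8


def project_history(
    signal: np.ndarray,
    max_degree: int,
    dt: float = 1.0,
    window: float | None = None,
    literal: bool = False,
) -> ProjectionCoeffs:
    """Directly project the signal history onto Legendre polynomials.

    ``signal[j]`` is treated as the drive held constant over the interval
    ``[j*dt, (j+1)*dt)`` (the same zero-order-hold reading the recursion
    uses); the signal is zero before time 0.  At each timepoint
    ``t = (j+1)*dt`` the history over the window ``[t - theta_w, t]`` is
    mapped onto [-1, 1] (most recent sample at -1) and integrated against
    each basis polynomial by Gauss-Legendre quadrature; coefficients are
    least-squares (include the (2m+1)/theta_w normalization), so a constant
    signal filling the whole window yields exactly (c_0, 0, 0, ...).

    ``window=None`` projects the full history ``[0, t]`` at every t (the
    growing-window reading used for the simulated-pulse figures);
    ``window=theta`` uses a fixed trailing window, directly comparable to a
    recursion with that theta.

    ``literal=True`` instead evaluates the projection exactly as printed,
    ``c_m(t) = ∫_0^t f(x) P_m(x) dx`` with the raw time axis as the
    polynomial argument — only defined while ``t <= 1`` since the
    polynomials do not extrapolate beyond [-1, 1].
    """
    u = np.asarray(signal, dtype=np.float64)
    if u.ndim != 1 or u.size < 2:
        raise ValidationError("signal must be 1-D with >= 2 samples")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    n = u.size
    xg, wg = leggauss(_QUAD_NODES)
    # absolute quadrature nodes/weights per step, staircase-weighted
    j = np.arange(n)
    nodes = ((xg[None, :] + 1) / 2 + j[:, None]) * dt  # (n, q)
    wts = np.tile(wg * dt / 2, (n, 1)) * u[:, None]
    times = (j + 1) * dt
    coeffs = np.zeros((max_degree, n))
    scale_m = 2 * np.arange(max_degree) + 1.0
    for t_idx in range(n):
        tau = times[t_idx]
        s = nodes[: t_idx + 1].ravel()
        w = wts[: t_idx + 1].ravel()
        if literal:
            if tau > 1 + 1e-12:
                raise ValidationError(
                    "literal projection undefined for t > 1 (polynomial "
                    "argument would leave [-1, 1])"
                )
            P = legendre_all(max_degree, s)
            coeffs[:, t_idx] = P @ w
            continue
        theta_w = tau if window is None else float(window)
        if theta_w <= 0:
            raise ValidationError("degenerate history window")
        arg = 2 * (tau - s) / theta_w - 1
        inside = np.abs(arg) <= 1
        P = legendre_all(max_degree, arg[inside])
        coeffs[:, t_idx] = (scale_m / theta_w) * (P @ w[inside])
    return ProjectionCoeffs(coeffs=coeffs, timepoints=times)


# ---------------------------------------------------------------------------
# state-space system


@dataclass
class StateSpaceSystem:
    """Continuous delay system (A, B) with window length theta, optionally
    discretized to (Abar, Bbar) at step dt."""

    A: np.ndarray
    B: np.ndarray
    theta: float
    Abar: np.ndarray | None = None
    Bbar: np.ndarray | None = None
    dt: float | None = None
    method: str | None = None

    @property
    def d(self) -> int:
        return self.A.shape[0]

    @property
    def is_discretized(self) -> bool:
        return self.Abar is not None


def build_system(d: int, theta: float) -> StateSpaceSystem:
    """Continuous delay-network matrices:

    ``A[i,j] = (2i+1)/theta * (-1 if i<j else (-1)^(i-j+1))``,
    ``B[i]   = (2i+1) * (-1)^i / theta``.
    """
    if d < 1:
        raise ValidationError("memory size d must be >= 1")
    if theta <= 0:
        raise ValidationError("window length theta must be positive")
    i = np.arange(d)[:, None]
    j = np.arange(d)[None, :]
    A = np.where(i < j, -1.0, (-1.0) ** (i - j + 1)) * (2 * i + 1) / theta
    B = (2 * np.arange(d) + 1) * (-1.0) ** np.arange(d) / theta
    return StateSpaceSystem(A=A, B=B, theta=float(theta))


def discretize(system: StateSpaceSystem, dt: float,
               method: str = "zoh") -> StateSpaceSystem:
    """Discretize: zoh gives ``Abar = exp(A dt)``, ``Bbar = A^{-1}(Abar-I)B``
    (computed by one augmented matrix exponential, which is the series form
    and needs no explicit inverse); euler gives ``I + A dt``, ``B dt``."""
    if dt <= 0:
        raise ValidationError("dt must be positive")
    d = system.d
    if method == "zoh":
        M = np.zeros((d + 1, d + 1))
        M[:d, :d] = system.A * dt
        M[:d, d] = system.B * dt
        E = expm(M)
        Abar, Bbar = E[:d, :d], E[:d, d]
    elif method == "euler":
        Abar = np.eye(d) + system.A * dt
        Bbar = system.B * dt
    else:
        raise ValidationError(f"unknown discretization method {method!r}")
    return StateSpaceSystem(A=system.A, B=system.B, theta=system.theta,
                            Abar=Abar, Bbar=Bbar, dt=float(dt), method=method)


def spectral_radius(M: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(M)).max())


def run_recursive(system: StateSpaceSystem, drive: np.ndarray
                  ) -> ProjectionCoeffs:
    """Iterate ``m_t = Abar m_{t-1} + Bbar u_t`` from ``m_0 = 0``; column t of
    the output is the memory state after absorbing ``drive[t]``."""
    if not system.is_discretized:
        raise ValidationError("system must be discretized first")
    u = np.asarray(drive, dtype=np.float64)
    d = system.d
    out = np.zeros((d, u.size))
    m = np.zeros(d)
    for t in range(u.size):
        m = system.Abar @ m + system.Bbar * u[t]
        out[:, t] = m
    times = (np.arange(u.size) + 1) * (system.dt or 1.0)
    return ProjectionCoeffs(coeffs=out, timepoints=times)


def default_system(d: int = 64, n_steps: int = 26, dt: float = 1.0,
                   method: str = "zoh") -> StateSpaceSystem:
    """The memory system used throughout the package: window = the full
    sequence duration (memory persists across the whole clip), unit step."""
    return discretize(build_system(d, theta=n_steps * dt), dt, method)
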