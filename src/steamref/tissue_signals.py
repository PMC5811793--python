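"""Forward signal models for diffusion-weighted STEAM experiments.

Three tissue descriptions are provided:

* :class:`BiexponentialModel` — two freely diffusing pools (slow fraction
  ``f_s`` with coefficient ``D_s``, fast pool ``D_f``).  The attenuation is a
  function of the b-value only, so any apparent diffusion-time dependence
  measured on it is an artifact of the measurement design.
* :class:`GaussianTensorModel` — a single anisotropic Gaussian compartment,
  E = exp(-B:D) for a full b-matrix B.
* :class:`CylinderTwoCompartmentModel` — restricted diffusion inside
  impermeable parallel cylinders (narrow-pulse disk propagator, Bessel-root
  eigenfunction series) plus an isotropic hindered extracellular pool.

All attenuations are normalized to 1 at zero diffusion weighting.  The
narrow-pulse propagator is the package's own implementation; it is
validated against the independent Monte Carlo oracle in
:mod:`steamref.mc_validation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import special

from .sequence_models import BMatrix, SequenceTiming

__all__ = [
    "BiexponentialModel",
    "GaussianTensorModel",
    "CylinderTwoCompartmentModel",
    "RelaxationParams",
    "biexp_attenuation",
    "gaussian_attenuation",
    "cylinder_perp_attenuation",
    "two_compartment_attenuation",
    "steam_amplitude",
    "signal_attenuation",
    "SeriesConvergenceError",
]


class SeriesConvergenceError(RuntimeError):
    """Eigenfunction series failed to reach the requested tolerance."""


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiexponentialModel:
    """Two-pool free diffusion: E(b) = f_s e^{-b D_s} + (1-f_s) e^{-b D_f}."""

    f_s: float = 0.3  # slow-pool volume fraction
    D_s: float = 0.2  # um^2/ms
    D_f: float = 1.0  # um^2/ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_s <= 1.0:
            raise ValueError("f_s must lie in [0, 1]")
        if self.D_s <= 0:
            raise ValueError("D_s must be positive")
        if self.D_f < self.D_s:
            raise ValueError("D_f must be >= D_s")


@dataclass(frozen=True)
class GaussianTensorModel:
    """Single Gaussian compartment described by a 3x3 diffusion tensor (um^2/ms)."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.tensor, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("tensor must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(d).min() < -1e-12:
            raise ValueError("tensor must be positive semidefinite")
        object.__setattr__(self, "tensor", d)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class CylinderTwoCompartmentModel:
    """Impermeable parallel cylinders (intracellular) plus hindered extracellular pool.

    Intracellular water diffuses freely with ``D_i`` along the cylinder axis
    and is restricted in the transverse plane (radius ``r``); the
    extracellular pool is isotropic Gaussian with ``D_h``.
    """

    r: float = 5.0  # cylinder radius (um)
    D_i: float = 2.0  # intracellular coefficient (um^2/ms)
    f_i: float = 0.8  # intracellular volume fraction
    D_h: float = 2.0  # hindered extracellular coefficient (um^2/ms)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not 0.0 <= self.f_i <= 1.0:
            raise ValueError("f_i must lie in [0, 1]")
        if self.D_i <= 0 or self.D_h <= 0:
            raise ValueError("D_i and D_h must be positive")
        object.__setattr__(self, "axis", tuple(_unit(self.axis)))


@dataclass(frozen=True)
class RelaxationParams:
    """Relaxation and amplitude constants entering the STEAM signal equation."""

    T1: float = 600.0  # ms
    T2: float = 50.0  # ms
    S_base: float = 1.0

    def __post_init__(self) -> None:
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("T1 and T2 must be positive")


# ---------------------------------------------------------------------------
# attenuations
# ---------------------------------------------------------------------------


def biexp_attenuation(b: float | np.ndarray, model: BiexponentialModel):
    """Biexponential attenuation at b-value(s) b (ms*um^-2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    out = model.f_s * np.exp(-b * model.D_s) + (1.0 - model.f_s) * np.exp(-b * model.D_f)
    return float(out) if out.ndim == 0 else out


def gaussian_attenuation(B: BMatrix | np.ndarray, tensor: np.ndarray) -> float:
    """Gaussian attenuation exp(-B:D) for a full b-matrix and diffusion tensor."""
    m = B.matrix if isinstance(B, BMatrix) else np.asarray(B, dtype=float)
    d = np.asarray(tensor, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12) or np.linalg.eigvalsh(d).min() < -1e-12:
        raise ValueError("tensor must be symmetric positive semidefinite")
    return float(np.exp(-np.sum(m * d)))


@lru_cache(maxsize=4)
def _bessel_prime_roots(n_orders: int = 30, n_roots: int = 50) -> np.ndarray:
    """Table of positive roots of J_n'(x), shape (n_orders, n_roots).

    Order 0 excludes the trivial root x = 0 (the constant propagator mode is
    handled separately as the long-time disk form factor).
    """
    roots = np.empty((n_orders, n_roots))
    for n in range(n_orders):
        roots[n] = special.jnp_zeros(n, n_roots)
    return roots


def cylinder_perp_attenuation(
    q: float,
    Delta: float,
    r: float,
    D_i: float,
    tol: float = 1e-10,
    n_orders: int = 30,
    n_roots: int = 50,
) -> float:
    """Narrow-pulse attenuation perpendicular to an impermeable cylinder.

    Eigenfunction expansion of the reflecting-disk propagator:

        E(q, Delta) = [2 J1(qr)/(qr)]^2
                      + sum_{n>=0, k} c_n W_nk(qr) exp(-beta_nk^2 D_i Delta / r^2)

    with beta_nk the k-th positive root of J_n', c_0 = 1, c_n = 2 for n >= 1,
    and spectral weight

        W_nk = [2 qr J_n'(qr) / ((qr)^2 - beta_nk^2)]^2
               * beta_nk^2 / (beta_nk^2 - n^2).

    The leading term (the squared disk form factor) is the infinite-time
    limit; all decaying weights are positive, so E is monotone
    non-increasing in Delta.  Raises :class:`SeriesConvergenceError` when
    the truncated tail cannot be bounded below ``tol`` (very short
    normalized times D_i*Delta/r^2 or qr beyond the tabulated orders).
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if Delta <= 0 or r <= 0 or D_i <= 0:
        raise ValueError("Delta, r and D_i must be positive")
    if q == 0.0:
        return 1.0

    qa = q * r
    tnorm = D_i * Delta / r**2  # normalized diffusion time

    if qa > n_orders - 8:
        raise SeriesConvergenceError(
            f"qr = {qa:.2f} requires more angular orders than tabulated "
            f"({n_orders}); increase n_orders"
        )

    # infinite-time mode: squared form factor of the uniform disk
    E = (2.0 * special.j1(qa) / qa) ** 2

    roots = _bessel_prime_roots(n_orders, n_roots)
    ns = np.arange(n_orders)[:, None]  # (n_orders, 1)
    beta = roots  # (n_orders, n_roots)

    jp = special.jvp(ns, qa)  # J_n'(qa) per order, broadcast over roots below
    denom = qa**2 - beta**2
    # guard exact resonance qa == beta_nk (removable singularity; J_n'(qa) -> 0)
    tiny = np.abs(denom) < 1e-12 * beta**2
    denom = np.where(tiny, 1e-12 * beta**2, denom)
    weight = (2.0 * qa * jp / denom) ** 2 * beta**2 / (beta**2 - ns**2)
    mult = np.where(ns == 0, 1.0, 2.0)
    terms = mult * weight * np.exp(-(beta**2) * tnorm)
    E += float(terms.sum())

    # tail bound: next root is ~pi beyond the last tabulated one per order;
    # |J_n'| <= 1 and the geometric decay of exp(-beta^2 t) dominates.
    beta_next = beta[:, -1] + np.pi
    decay = np.exp(-(2.0 * beta_next * np.pi) * tnorm)
    with np.errstate(divide="ignore"):
        geo = np.where(decay < 1.0, 1.0 / (1.0 - decay), np.inf)
    tail = (
        2.0
        * (2.0 * qa / np.maximum(beta_next**2 - qa**2, 1e-300)) ** 2
        * np.exp(-(beta_next**2) * tnorm)
        * geo
    ).sum()
    if not np.isfinite(tail) or tail > tol:
        raise SeriesConvergenceError(
            f"series tail bound {tail:.2e} exceeds tol={tol:.1e} at "
            f"qr={qa:.3f}, D*Delta/r^2={tnorm:.3e}; the normalized diffusion "
            "time is too short for the tabulated root count"
        )
    return float(min(E, 1.0))


def two_compartment_attenuation(
    q: float,
    Delta: float,
    direction: Sequence[float],
    model: CylinderTwoCompartmentModel,
) -> float:
    """Two-compartment narrow-pulse attenuation along ``direction``.

    The gradient wave-vector q*direction is split into components parallel
    and perpendicular to the cylinder axis; the intracellular signal is the
    product of free Gaussian decay along the axis and the restricted disk
    propagator transversely, and the extracellular signal is isotropic
    Gaussian with D_h.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    d = _unit(direction)
    axis = np.asarray(model.axis)
    q_par = abs(q * float(d @ axis))
    q_perp = float(np.sqrt(max(q**2 - q_par**2, 0.0)))
    e_restricted = cylinder_perp_attenuation(q_perp, Delta, model.r, model.D_i) * np.exp(
        -(q_par**2) * model.D_i * Delta
    )
    e_hindered = np.exp(-(q**2) * model.D_h * Delta)
    return float(model.f_i * e_restricted + (1.0 - model.f_i) * e_hindered)


def steam_amplitude(
    E: float | np.ndarray,
    timing: SequenceTiming,
    relax: RelaxationParams,
):
    """STEAM signal: S = 0.5 S_base exp(-tau_m/T1) exp(-te/T2) E.

    The factor 0.5 is the intrinsic stimulated-echo loss; T1 acts during the
    mixing time only and T2 during the (fixed) echo time, so the ratio of a
    diffusion-weighted and reference signal at equal Delta is independent of
    T1, T2 and S_base.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0) or np.any(E > 1):
        raise ValueError("attenuation E must lie in [0, 1]")
    s = (
        0.5
        * relax.S_base
        * np.exp(-timing.tau_m / relax.T1)
        * np.exp(-timing.te / relax.T2)
        * E
    )
    return float(s) if s.ndim == 0 else s


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

TissueModel = BiexponentialModel | GaussianTensorModel | CylinderTwoCompartmentModel


def signal_attenuation(
    model: TissueModel,
    q_vec: Sequence[float],
    Delta: float,
    delta: float = 0.0,
) -> float:
    """Attenuation for an arbitrary gradient wave-vector (um^-1).

    Gaussian compartments use the exact pulsed-pair b-value
    b = |q|^2 (Delta - delta/3); the restricted propagator is evaluated at
    the same effective diffusion time Delta - delta/3, which reduces to the
    narrow-pulse time for delta -> 0 and keeps the Gaussian limit of the
    cylinder model consistent with the b-value convention used everywhere
    else in the package.
    """
    qv = np.asarray(q_vec, dtype=float)
    if qv.shape != (3,):
        raise ValueError("q_vec must be a 3-vector")
    t_eff = Delta - delta / 3.0
    if t_eff <= 0:
        raise ValueError("Delta - delta/3 must be positive")
    qmag = float(np.linalg.norm(qv))

    if isinstance(model, BiexponentialModel):
        return biexp_attenuation(qmag**2 * t_eff, model)
    if isinstance(model, GaussianTensorModel):
        B = t_eff * np.outer(qv, qv)
        return gaussian_attenuation(B, model.tensor)
    if isinstance(model, CylinderTwoCompartmentModel):
        if qmag == 0.0:
            return 1.0
        return two_compartment_attenuation(qmag, t_eff, qv / qmag, model)
    raise TypeError(f"unknown tissue model type {type(model).__name__}")
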