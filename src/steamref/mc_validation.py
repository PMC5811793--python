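"""Monte Carlo random-walk oracle for free and restricted diffusion.

An ensemble of independent Brownian walkers takes Gaussian steps of
variance 2*D*dt per dimension, with specular reflection at the wall of an
impermeable cylinder (simulated in its 2D cross-section).  The narrow-pulse
signal is the modulus of the ensemble-averaged phase factor
``|<exp(i q . dx)>|``, which is an estimator of the propagator's Fourier
transform and therefore an implementation-independent check on the
analytic eigenfunction series in :mod:`steamref.tissue_signals`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["WalkerEnsemble", "walk", "narrow_pulse_signal"]


@dataclass(frozen=True)
class WalkerEnsemble:
    """Configuration of one random-walk simulation.

    ``boundary="cylinder"`` confines walkers to a disk of radius ``r`` (the
    cylinder cross-section, ndim = 2); ``boundary="none"`` is free diffusion
    in ``ndim`` dimensions.  The stability condition dt <= r^2/(100 D) keeps
    the RMS step below ~0.14 r so that first-order specular reflection is
    accurate.
    """

    n_walkers: int = 100_000
    D: float = 2.0  # um^2/ms
    dt: float | None = None  # ms; default r^2/(200 D) when bounded, else 0.05
    boundary: Literal["none", "cylinder"] = "none"
    r: float = 5.0  # um, cylinder radius (used when bounded)
    ndim: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers <= 0:
            raise ValueError("n_walkers must be positive")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.boundary not in ("none", "cylinder"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.boundary == "cylinder":
            if self.r <= 0:
                raise ValueError("cylinder radius must be positive")
            if self.ndim != 2:
                raise ValueError("cylinder boundary is simulated in its 2D section")
        dt = self.dt if self.dt is not None else self.default_dt()
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.boundary == "cylinder" and dt > self.r**2 / (100.0 * self.D):
            raise ValueError(
                f"dt = {dt} ms violates the stability bound r^2/(100 D) = "
                f"{self.r**2 / (100.0 * self.D)} ms"
            )
        object.__setattr__(self, "dt", dt)

    def default_dt(self) -> float:
        if self.boundary == "cylinder":
            return self.r**2 / (200.0 * self.D)
        return 0.05


def _initial_positions(ens: WalkerEnsemble, rng: np.random.Generator) -> np.ndarray:
    if ens.boundary == "cylinder":
        # uniform in the disk via sqrt-radius sampling
        u = rng.random(ens.n_walkers)
        phi = rng.random(ens.n_walkers) * 2.0 * np.pi
        rad = ens.r * np.sqrt(u)
        return np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])
    return np.zeros((ens.n_walkers, ens.ndim))


def _reflect_into_disk(p0: np.ndarray, p1: np.ndarray, r: float) -> np.ndarray:
    """Specular reflection of steps p0 -> p1 at the circle of radius r.

    For each walker ending outside, the crossing point on the circle is
    solved exactly and the remaining path is mirrored across the local
    tangent; repeated up to a few times for the rare double crossing.
    """
    out = p1.copy()
    for _ in range(8):
        r2 = np.einsum("ij,ij->i", out, out)
        bad = r2 > r * r
        if not bad.any():
            return out
        a = p0[bad]
        b = out[bad]
        d = b - a
        dd = np.einsum("ij,ij->i", d, d)
        ad = np.einsum("ij,ij->i", a, d)
        aa = np.einsum("ij,ij->i", a, a)
        # |a + t d|^2 = r^2, take the root in (0, 1]
        disc = np.sqrt(np.maximum(ad**2 - dd * (aa - r * r), 0.0))
        t = (-ad + disc) / np.maximum(dd, 1e-300)
        t = np.clip(t, 0.0, 1.0)
        c = a + t[:, None] * d  # crossing point
        n = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-300)
        w = b - c  # remaining path
        w_ref = w - 2.0 * np.einsum("ij,ij->i", w, n)[:, None] * n
        out[bad] = c + w_ref
        p0 = p0.copy()
        p0[bad] = c
    # numerically stubborn stragglers: project just inside the wall
    r2 = np.einsum("ij,ij->i", out, out)
    bad = r2 > r * r
    if bad.any():
        out[bad] *= (r * (1.0 - 1e-12)) / np.sqrt(r2[bad])[:, None]
    return out


def walk(ens: WalkerEnsemble, Delta: float) -> np.ndarray:
    """Propagate the ensemble for a diffusion time Delta; return displacements.

    The number of steps is ``round(Delta / dt)`` with the step length
    adjusted so the total time is exactly Delta; at least 100 steps are
    required so that the discrete walk resolves the boundary interactions.
    """
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    n_steps = int(round(Delta / ens.dt))
    if n_steps < 100:
        raise ValueError(
            f"Delta/dt = {Delta / ens.dt:.1f} < 100 steps; reduce dt for this Delta"
        )
    dt_eff = Delta / n_steps
    sigma = np.sqrt(2.0 * ens.D * dt_eff)
    rng = np.random.default_rng(ens.seed)
    p = _initial_positions(ens, rng)
    start = p.copy()
    bounded = ens.boundary == "cylinder"
    for _ in range(n_steps):
        step = rng.normal(scale=sigma, size=p.shape)
        nxt = p + step
        if bounded:
            nxt = _reflect_into_disk(p, nxt, ens.r)
        p = nxt
    return p - start


def narrow_pulse_signal(
    displacements: np.ndarray,
    q_vec: Sequence[float] | float,
    n_batches: int = 20,
) -> tuple[float, float]:
    """Narrow-pulse signal estimate E = |<exp(i q . dx)>| with a batch-means SE.

    ``q_vec`` may be a vector matching the walk dimensionality or a scalar,
    interpreted as magnitude along the first axis.  At least 10^4 walkers
    and 20 batches are required for the standard error to be meaningful.
    """
    dx = np.asarray(displacements, dtype=float)
    if dx.ndim != 2:
        raise ValueError("displacements must be (n_walkers, ndim)")
    n = dx.shape[0]
    if n < 10_000:
        raise ValueError(f"need >= 10^4 walkers for a reliable estimate, got {n}")
    if n_batches < 20:
        raise ValueError("need >= 20 batches for the standard error")
    q = np.atleast_1d(np.asarray(q_vec, dtype=float))
    if q.size == 1 and dx.shape[1] > 1:
        q = np.concatenate([q, np.zeros(dx.shape[1] - 1)])
    if q.size != dx.shape[1]:
        raise ValueError("q_vec dimensionality does not match displacements")

    if not np.any(q):
        return 1.0, 0.0

    phase = dx @ q
    z = np.exp(1j * phase)
    E = float(np.abs(z.mean()))
    batches = np.array_split(z, n_batches)
    eb = np.array([np.abs(b.mean()) for b in batches])
    se = float(eb.std(ddof=1) / np.sqrt(n_batches))
    return E, se
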