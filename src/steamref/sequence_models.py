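"""Gradient and timing mathematics for diffusion-weighted stimulated echoes.

The stimulated-echo (STEAM) sequence stores magnetization longitudinally
during the mixing time ``tau_m`` between the second and third 90-degree
pulses, so very long diffusion times can be probed at the cost of a factor
of two in signal and T1 (rather than T2) decay during the mixing interval.

Unit conventions used throughout the package:

* gradient pulse area  ``q = gamma * delta * G``  in um^-1 (no 2*pi factor),
* diffusion weighting  ``b = q^2 * (Delta - delta/3)``  in ms*um^-2,
* times in ms, diffusivities in um^2/ms, gradient amplitudes in mT/m.

With these units the narrow-pulse b-value of a rectangular gradient pair is
dimensionally closed without any conversion constants, and the published
protocol numbers (q0 = 0.023 um^-1 on each of three crusher axes giving
b0 = 0.631 ms*um^-2 at Delta = 400 ms, delta = 2.22 ms) are mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "SequenceTiming",
    "ReferenceScheme",
    "GradientEvent",
    "EffectiveWaveform",
    "BMatrix",
    "AcquisitionProtocol",
    "narrow_pulse_b",
    "crusher_q_for_b0",
    "reference_schedule",
    "diffusion_gradient_strength",
    "build_steam_waveform",
    "b_matrix",
    "postmortem_protocol",
    "fibonacci_directions",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.6752218744e8

_AXES = {"x": 0, "y": 1, "z": 2}


class WaveformError(ValueError):
    """Raised for ill-formed effective waveforms (overlap, no refocusing)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceTiming:
    """Timing of one STEAM preparation.

    ``tau_m`` is derived as ``Delta - te/2``: the diffusion gradient sits in
    the first half-echo, its decoding twin after the third RF pulse, so the
    lobe separation Delta equals the mixing time plus half the echo time.
    """

    delta: float  # gradient lobe duration (ms)
    Delta: float  # diffusion time: lobe separation (ms)
    te: float = 16.0  # effective echo time (ms)
    gamma: float = GAMMA_PROTON  # rad s^-1 T^-1

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.Delta <= self.delta:
            raise ValueError(f"Delta ({self.Delta}) must exceed delta ({self.delta})")
        if self.te <= 0:
            raise ValueError(f"te must be > 0, got {self.te}")
        if self.tau_m < 0:
            raise ValueError(
                f"mixing time tau_m = Delta - te/2 = {self.tau_m} ms is negative"
            )

    @property
    def tau_m(self) -> float:
        """Mixing time (ms) during which magnetization is longitudinal."""
        return self.Delta - self.te / 2.0


@dataclass(frozen=True)
class ReferenceScheme:
    """Reference ("b0") acquisition design across diffusion times.

    ``fixed_q0`` keeps the crusher area constant, so the reference b-value
    grows linearly with (Delta - delta/3); ``fixed_b0`` keeps the reference
    b-value pinned at its value for the longest diffusion time by shrinking
    the crusher area as Delta grows.  The two schedules coincide at
    ``delta_max`` by construction.
    """

    mode: Literal["fixed_b0", "fixed_q0"]
    b0_at_delta_max: float  # reference b-value at Delta_max (ms um^-2)
    delta_max: float  # longest diffusion time (ms)
    n_axes: int = 3  # orthogonal crusher axes carrying equal area

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_b0", "fixed_q0"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.b0_at_delta_max < 0:
            raise ValueError("b0_at_delta_max must be >= 0")
        if self.n_axes not in (1, 2, 3):
            raise ValueError("n_axes must be 1, 2 or 3")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be positive")


@dataclass(frozen=True)
class GradientEvent:
    """One rectangular gradient lobe on a single axis.

    ``q_area`` is the signed physical area gamma*delta*G in um^-1;
    ``pathway_sign`` is the sign the stimulated-echo coherence pathway
    applies to it (+1 before storage, -1 after recall).
    """

    axis: Literal["x", "y", "z"]
    q_area: float  # signed area (um^-1)
    t_start: float  # onset (ms)
    duration: float  # (ms)
    pathway_sign: int = 1
    role: Literal["diffusion", "crusher", "slice_select"] = "diffusion"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if self.pathway_sign not in (-1, 1):
            raise ValueError("pathway_sign must be +1 or -1")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def effective_rate(self) -> float:
        """Effective gradient in q-units per ms (um^-1 ms^-1)."""
        return self.pathway_sign * self.q_area / self.duration


@dataclass(frozen=True)
class EffectiveWaveform:
    """Piecewise-constant effective gradient seen by the stored coherence.

    The effective gradient is zero during the mixing interval
    ``[te/2, te/2 + tau_m]`` (magnetization is longitudinal there); events
    are forbidden inside it.  The cumulative area per axis must return to
    zero at the echo for the waveform to refocus.
    """

    timing: SequenceTiming
    events: tuple[GradientEvent, ...]

    def __post_init__(self) -> None:
        t_mix0 = self.timing.te / 2.0
        t_mix1 = t_mix0 + self.timing.tau_m
        t_echo = self.timing.te + self.timing.tau_m
        by_axis: dict[str, list[GradientEvent]] = {"x": [], "y": [], "z": []}
        for ev in self.events:
            if ev.t_start < -1e-12 or ev.t_end > t_echo + 1e-9:
                raise WaveformError(
                    f"event on {ev.axis} at [{ev.t_start}, {ev.t_end}] ms falls "
                    f"outside the sequence window [0, {t_echo}] ms"
                )
            if ev.t_start < t_mix1 - 1e-12 and ev.t_end > t_mix0 + 1e-12:
                raise WaveformError(
                    f"event on {ev.axis} overlaps the mixing interval "
                    f"[{t_mix0}, {t_mix1}] ms where the coherence is longitudinal"
                )
            by_axis[ev.axis].append(ev)
        for axis, evs in by_axis.items():
            evs = sorted(evs, key=lambda e: e.t_start)
            for a, b in zip(evs, evs[1:]):
                if b.t_start < a.t_end - 1e-12:
                    raise WaveformError(
                        f"overlapping events on axis {axis} at {b.t_start} ms"
                    )

    @property
    def t_echo(self) -> float:
        return self.timing.te + self.timing.tau_m

    def net_area(self) -> np.ndarray:
        """Signed effective area per axis at the echo (um^-1); 0 if refocused."""
        area = np.zeros(3)
        for ev in self.events:
            area[_AXES[ev.axis]] += ev.pathway_sign * ev.q_area
        return area

    def is_refocused(self, atol: float = 1e-12) -> bool:
        scale = max((abs(ev.q_area) for ev in self.events), default=0.0)
        return bool(np.all(np.abs(self.net_area()) <= atol + 1e-9 * scale))

    def sample(self, dt: float = 0.01) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (time grid, (3, nt) effective gradient, pathway mask)."""
        t = np.arange(0.0, self.t_echo + dt, dt)
        g = np.zeros((3, t.size))
        for ev in self.events:
            sel = (t >= ev.t_start) & (t < ev.t_end)
            g[_AXES[ev.axis], sel] += ev.effective_rate
        t_mix0 = self.timing.te / 2.0
        mask = ~((t >= t_mix0) & (t < t_mix0 + self.timing.tau_m))
        return t, g, mask


@dataclass(frozen=True)
class BMatrix:
    """Symmetric 3x3 diffusion-weighting matrix in ms*um^-2."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("b-matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("b-matrix must be symmetric")
        evals = np.linalg.eigvalsh(m)
        if evals.min() < -1e-9 * max(1.0, evals.max()):
            raise ValueError("b-matrix must be positive semidefinite")
        object.__setattr__(self, "matrix", m)

    @property
    def b(self) -> float:
        """Scalar b-value (trace), ms*um^-2."""
        return float(np.trace(self.matrix))

    @property
    def direction(self) -> np.ndarray:
        """Principal eigenvector (unit norm)."""
        evals, evecs = np.linalg.eigh(self.matrix)
        v = evecs[:, -1]
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            v = -v
        return v


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One multi-diffusion-time DW-STEAM experiment."""

    Delta_list: tuple[float, ...]
    delta: float
    nominal_b: float  # ms um^-2
    directions: np.ndarray  # (n, 3) unit vectors
    reference: ReferenceScheme
    te: float = 16.0
    tr_list: tuple[float, ...] | None = None  # s, metadata only
    scheme_variant: Literal["conventional", "modified"] = "modified"

    def __post_init__(self) -> None:
        dl = tuple(float(d) for d in self.Delta_list)
        if any(b >= a for a, b in zip(dl[1:], dl)):
            raise ValueError("Delta_list must be strictly increasing")
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("directions must have unit norm")
        object.__setattr__(self, "Delta_list", dl)
        object.__setattr__(self, "directions", dirs)
        b0s, _ = reference_schedule(self.reference, dl, self.delta)
        if np.any(self.nominal_b <= b0s):
            raise ValueError("nominal_b must exceed the reference b0 at every Delta")

    def timing(self, Delta: float) -> SequenceTiming:
        return SequenceTiming(delta=self.delta, Delta=Delta, te=self.te)


# ---------------------------------------------------------------------------
# scalar b-value algebra
# ---------------------------------------------------------------------------


def narrow_pulse_b(
    q: float | np.ndarray,
    Delta: float,
    delta: float = 0.0,
    n_axes: int = 1,
) -> float | np.ndarray:
    """b-value of a rectangular gradient pair, b = n_axes * q^2 (Delta - delta/3).

    Parameters are in package units (q um^-1, times ms); ``n_axes`` counts
    orthogonal axes carrying the same per-axis area q, as for crusher
    gradients applied on all three axes simultaneously.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    eff = Delta - delta / 3.0
    if eff <= 0:
        raise ValueError(f"Delta - delta/3 = {eff} ms must be positive")
    out = n_axes * q**2 * eff
    return float(out) if out.ndim == 0 else out


def crusher_q_for_b0(
    b0: float | np.ndarray,
    Delta: float,
    delta: float = 0.0,
    n_axes: int = 1,
) -> float | np.ndarray:
    """Per-axis crusher area q (um^-1) whose n_axes-fold pair yields b-value b0."""
    b0 = np.asarray(b0, dtype=float)
    if np.any(b0 < 0):
        raise ValueError("b0 must be >= 0")
    eff = Delta - delta / 3.0
    if eff <= 0:
        raise ValueError(f"Delta - delta/3 = {eff} ms must be positive")
    out = np.sqrt(b0 / n_axes / eff)
    return float(out) if out.ndim == 0 else out


def reference_schedule(
    scheme: ReferenceScheme,
    Delta_list: Sequence[float],
    delta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-Delta reference (b0, per-axis q0) pairs for a reference design.

    Returns arrays aligned with ``Delta_list``.  For ``fixed_b0`` the b0
    column is constant and q0 shrinks as (Delta - delta/3)^(-1/2); for
    ``fixed_q0`` the q0 column is constant (its value fixed by b0 at
    delta_max) and b0 grows affinely in (Delta - delta/3).
    """
    Deltas = np.asarray(Delta_list, dtype=float)
    if np.any(Deltas <= delta):
        raise ValueError("every Delta must exceed delta")
    if np.any(Deltas > scheme.delta_max + 1e-9):
        raise ValueError(
            "schedule undefined beyond the calibration point delta_max "
            f"({scheme.delta_max} ms)"
        )
    if scheme.mode == "fixed_b0":
        b0 = np.full_like(Deltas, scheme.b0_at_delta_max)
        q0 = np.sqrt(scheme.b0_at_delta_max / scheme.n_axes / (Deltas - delta / 3.0))
    else:
        q0_max = crusher_q_for_b0(
            scheme.b0_at_delta_max, scheme.delta_max, delta, scheme.n_axes
        )
        q0 = np.full_like(Deltas, q0_max)
        b0 = scheme.n_axes * q0**2 * (Deltas - delta / 3.0)
    return b0, q0


def diffusion_gradient_strength(
    b: float,
    Delta: float,
    delta: float,
    gamma: float = GAMMA_PROTON,
) -> float:
    """Single-axis gradient amplitude G (mT/m) reaching b at (Delta, delta).

    Inverts b = gamma^2 delta^2 G^2 (Delta - delta/3) with b in ms*um^-2 and
    times in ms; the result is converted to mT/m.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    eff = Delta - delta / 3.0
    if eff <= 0:
        raise ValueError("Delta - delta/3 must be positive")
    # to SI: b [s m^-2] = b_pkg * 1e9 ; times to s
    q_si = np.sqrt(b * 1e9 / (eff * 1e-3))  # m^-1
    g_tesla_per_m = q_si / (gamma * delta * 1e-3)
    return float(g_tesla_per_m * 1e3)  # mT/m


# ---------------------------------------------------------------------------
# effective waveforms and b-matrix integration
# ---------------------------------------------------------------------------


def build_steam_waveform(
    timing: SequenceTiming,
    variant: Literal["conventional", "modified"] = "modified",
    q_diffusion: float = 0.0,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    q_crusher: float = 0.046,
    q_slice: float = 0.046,
    imaging_lobe: float = 0.5,
) -> EffectiveWaveform:
    """Assemble the effective STEAM waveform for one diffusion time.

    The conventional layout plays the crusher pair with the same polarity as
    the slice-select lobes, so a net area (q_crusher + q_slice) survives into
    the mixing interval and accrues diffusion weighting that grows with
    tau_m.  The modified layout flips the crushers so that each pairs with
    its adjacent slice-select lobe; the net area entering the mixing
    interval is q_slice - q_crusher (zero for equal areas), removing the
    diffusion-time dependence of the imaging-gradient b-value.

    The diffusion gradient pair (area ``q_diffusion`` along ``direction``)
    straddles the storage interval with lobe separation exactly
    ``timing.Delta``.
    """
    if variant not in ("conventional", "modified"):
        raise ValueError(f"unknown variant {variant!r}")
    te2 = timing.te / 2.0
    tau_m = timing.tau_m
    lob = imaging_lobe
    if te2 < 2 * lob + 2 * lob + 0.25 + timing.delta:
        raise WaveformError("echo time too short for the requested lobe layout")
    crusher_sign = 1.0 if variant == "conventional" else -1.0
    t_recall = te2 + tau_m  # third RF pulse

    events: list[GradientEvent] = []

    # slice-select pair of the first RF pulse (locally refocused)
    events.append(GradientEvent("z", +q_slice, 0.0, lob, 1, "slice_select"))
    events.append(GradientEvent("z", -q_slice, lob, lob, 1, "slice_select"))
    # crusher + storage-side slice-select half, just before the second RF pulse
    events.append(
        GradientEvent("z", crusher_sign * q_crusher, te2 - 2 * lob, lob, 1, "crusher")
    )
    events.append(GradientEvent("z", +q_slice, te2 - lob, lob, 1, "slice_select"))
    # recall-side slice-select half + crusher, just after the third RF pulse
    events.append(GradientEvent("z", +q_slice, t_recall, lob, -1, "slice_select"))
    events.append(
        GradientEvent("z", crusher_sign * q_crusher, t_recall + lob, lob, -1, "crusher")
    )

    if q_diffusion != 0.0:
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("direction must be nonzero")
        d = d / nrm
        t1 = 2 * lob + 0.25
        if t1 + timing.delta > te2 - 2 * lob:
            raise WaveformError("diffusion lobe does not fit in the first half-echo")
        for axis, comp in zip("xyz", d):
            if abs(comp) < 1e-15:
                continue
            area = q_diffusion * comp
            events.append(GradientEvent(axis, area, t1, timing.delta, 1, "diffusion"))
            events.append(
                GradientEvent(axis, area, t1 + timing.Delta, timing.delta, -1, "diffusion")
            )

    wf = EffectiveWaveform(timing=timing, events=tuple(events))
    if not wf.is_refocused():
        raise WaveformError(f"waveform does not refocus: net area {wf.net_area()}")
    return wf


def b_matrix(waveform: EffectiveWaveform, gamma: float = GAMMA_PROTON) -> BMatrix:
    """Exact b-matrix of a piecewise-constant effective waveform.

    B = int F(t) F(t)^T dt with F(t) the cumulative effective area (um^-1);
    integration is analytic over segments of constant gradient, so
    rectangular lobes incur no quadrature error.  ``gamma`` is accepted for
    interface symmetry; areas are already in q-units so it cancels.
    """
    if waveform.events and not waveform.is_refocused():
        raise WaveformError("cannot compute b-matrix of an unrefocused waveform")

    edges = {0.0, waveform.t_echo}
    for ev in waveform.events:
        edges.add(ev.t_start)
        edges.add(ev.t_end)
    ts = np.array(sorted(edges))

    B = np.zeros((3, 3))
    F = np.zeros(3)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        h = t1 - t0
        if h <= 0:
            continue
        g = np.zeros(3)
        tm = 0.5 * (t0 + t1)
        for ev in waveform.events:
            if ev.t_start - 1e-12 <= tm <= ev.t_end + 1e-12 and ev.t_start < t1 and ev.t_end > t0:
                g[_AXES[ev.axis]] += ev.effective_rate
        # int over [0,h] of (F + g t)(F + g t)^T dt
        B += (
            np.outer(F, F) * h
            + (np.outer(F, g) + np.outer(g, F)) * h**2 / 2.0
            + np.outer(g, g) * h**3 / 3.0
        )
        F = F + g * h
    return BMatrix(matrix=B)


def imaging_b(
    timing: SequenceTiming,
    variant: Literal["conventional", "modified"],
    q_crusher: float = 0.046,
    q_slice: float = 0.046,
) -> float:
    """Scalar b-value accrued by imaging gradients alone (no diffusion lobe)."""
    wf = build_steam_waveform(
        timing, variant, q_diffusion=0.0, q_crusher=q_crusher, q_slice=q_slice
    )
    return b_matrix(wf).b


# ---------------------------------------------------------------------------
# canonical protocol
# ---------------------------------------------------------------------------

POSTMORTEM_DELTAS = (70.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0)
POSTMORTEM_TRS = (2.4, 2.4, 2.4, 2.4, 2.4, 2.6, 3.6, 4.1)


def fibonacci_directions(n: int = 30) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (spherical Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def postmortem_protocol(
    mode: Literal["fixed_b0", "fixed_q0"] = "fixed_b0",
    n_directions: int = 30,
    scheme_variant: Literal["conventional", "modified"] = "modified",
) -> AcquisitionProtocol:
    """The postmortem acquisition: 8 diffusion times 70-400 ms, b = 3.5 ms*um^-2,
    delta = 2.22 ms, te = 16 ms, 3-axis reference with b0 = 0.631 ms*um^-2 at
    Delta_max."""
    scheme = ReferenceScheme(
        mode=mode, b0_at_delta_max=0.631, delta_max=400.0, n_axes=3
    )
    return AcquisitionProtocol(
        Delta_list=POSTMORTEM_DELTAS,
        delta=2.22,
        nominal_b=3.5,
        directions=fibonacci_directions(n_directions),
        reference=scheme,
        te=16.0,
        tr_list=POSTMORTEM_TRS,
        scheme_variant=scheme_variant,
    )
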