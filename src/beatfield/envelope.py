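"""Temporal-interference envelope amplitudes.

Two sinusoidal fields E1 sin(2 pi f1 t) and E2 sin(2 pi f2 t) with a small
frequency difference superpose to E(t) whose projection onto a unit vector u
is amplitude-modulated at the beat frequency |f2 - f1|.  The modulation depth
of the projection onto a direction at angle theta from E1 (in the plane the
two fields span, where the maximum lives) is

    2 * min(||E1|| |cos theta|, ||E2|| |cos(theta - phi)|),

phi being the angle between E1 and E2.  The per-node TI envelope amplitude A
is the maximum of this over theta in [0, 2 pi).

Three routes are provided: an exact closed form (the production path), a
brute-force theta grid, and a time-domain simulation with Hilbert-transform
envelope extraction; the latter two act as independent oracles.  The
single-frequency tACS amplitude (both pairs in phase at one frequency) is
the norm of the summed field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import ValidationError

__all__ = [
    "MontageConfig",
    "TIPattern",
    "ti_envelope",
    "ti_envelope_theta_grid",
    "ti_envelope_time_domain",
    "tacs_amplitude",
    "envelope_frequency",
]

#: Norms below this (V/m) are treated as a vanishing field.
NORM_EPS = 1e-14


@dataclass(frozen=True)
class MontageConfig:
    """Two electrode pairs with their currents and frequencies.

    ``pair1`` carries ``alpha_mA`` at ``f1_hz`` and ``pair2`` carries
    ``beta_mA`` at ``f2_hz``.  Defaults follow the 10 Hz beat produced by
    2 kHz and 2.01 kHz carriers.
    """

    pair1: tuple  # (anode_id, cathode_id)
    pair2: tuple
    alpha_mA: float = 1.0
    beta_mA: float = 1.0
    f1_hz: float = 2000.0
    f2_hz: float = 2010.0

    def __post_init__(self) -> None:
        ids = (*self.pair1, *self.pair2)
        if len(set(ids)) != 4:
            raise ValidationError("the four montage electrode ids must be distinct")
        if self.alpha_mA < 0 or self.beta_mA < 0:
            raise ValidationError("currents must be non-negative")

    @property
    def beat_frequency_hz(self) -> float:
        return abs(self.f2_hz - self.f1_hz)


@dataclass
class TIPattern:
    """Per-node maximal envelope amplitude with provenance."""

    amplitude: np.ndarray  # A per node, V/m
    envelope_frequency_hz: float
    montage: MontageConfig = None
    mesh_fingerprint: str = ""


def _norms_and_cos(E1, E2):
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    if E1.shape != E2.shape:
        raise ValidationError("E1 and E2 must have the same shape")
    n1 = np.linalg.norm(E1, axis=1)
    n2 = np.linalg.norm(E2, axis=1)
    dot = np.einsum("ij,ij->i", E1, E2)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(dot) / (n1 * n2)
    c = np.clip(np.where(np.isfinite(c), c, 0.0), 0.0, 1.0)
    return E1, E2, n1, n2, c


def envelope_from_norms(u, v, c, s=None) -> np.ndarray:
    """Closed-form A from field norms ``u``, ``v`` and ``|cos phi|`` ``c``
    (optionally ``sin phi`` ``s`` when it is known more accurately).

    The sign-flip invariance of the max-min expression folds phi into
    [0, pi/2], so only |cos phi| matters.  When the weaker field is within
    the stronger field's "cone" (v <= u c after ordering u >= v) the optimum
    is the collinear branch A = 2 min(u, v); otherwise the two projection
    amplitudes cross and A = 2 u v sin(phi) / ||E1 - E2||.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if s is None:
        s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    denom2 = np.clip(u * u + v * v - 2.0 * u * v * c, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        crossed = 2.0 * u * v * s / np.sqrt(np.maximum(denom2, 1e-300))
    # near the collinear limit the crossed expression cancels to rounding
    # noise; it never exceeds 2*min and tends to it at the boundary, so the
    # clamp recovers the collinear value there
    crossed = np.minimum(crossed, 2.0 * lo)
    # slack on the branch test: the branches agree to O(slack) at the
    # boundary, while rounding in c can misassign the exact-collinear case
    A = np.where(lo <= hi * c * (1.0 + 1e-12), 2.0 * lo, crossed)
    return np.where((u < NORM_EPS) | (v < NORM_EPS), 0.0, A)


def ti_envelope(E1, E2) -> np.ndarray:
    """Maximal TI envelope amplitude per node, V/m.

    ``E1`` and ``E2`` are (n, 3) field vectors already scaled by their
    injection currents.  Exact closed-form evaluation of the max-min
    definition (verified against :func:`ti_envelope_theta_grid`), arranged
    so every ingredient is computed stably from the vectors: the crossed
    branch is 2 ||E1 x E2|| / min(||E1 - E2||, ||E1 + E2||) and the branch
    test compares products rather than a rounded cosine.
    """
    E1, E2, n1, n2, _ = _norms_and_cos(E1, E2)
    adot = np.abs(np.einsum("ij,ij->i", E1, E2))
    cross = np.linalg.norm(np.cross(E1, E2), axis=1)
    lo = np.minimum(n1, n2)
    hi = np.maximum(n1, n2)
    # phi folded into [0, pi/2]: the relevant difference norm is the smaller
    # of ||E1 - E2|| and ||E1 + E2||, whose square is n1^2 + n2^2 - 2|dot|
    denom2 = np.minimum(
        np.einsum("ij,ij->i", E1 - E2, E1 - E2),
        np.einsum("ij,ij->i", E1 + E2, E1 + E2),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        crossed = 2.0 * cross / np.sqrt(np.maximum(denom2, 1e-300))
    crossed = np.minimum(crossed, 2.0 * lo)
    A = np.where(lo * n1 * n2 <= hi * adot * (1.0 + 1e-12), 2.0 * lo, crossed)
    return np.where((n1 < NORM_EPS) | (n2 < NORM_EPS), 0.0, A)


def ti_envelope_theta_grid(E1, E2, n_theta: int = 100_000) -> np.ndarray:
    """Brute-force maximization of the max-min expression on a uniform grid.

    A lower bound on the true amplitude, converging as ``n_theta`` grows;
    independent of the closed form.
    """
    if n_theta < 4:
        raise ValidationError("n_theta must be >= 4")
    _, _, n1, n2, c = _norms_and_cos(E1, E2)
    # fold phi into [0, pi/2]: |cos| symmetry makes the signed angle moot;
    # cos(theta - phi) expanded via the angle-addition identity
    s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
    best = np.zeros_like(n1)
    chunk = max(1, int(2e7) // max(1, n1.size))
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    for start in range(0, n_theta, chunk):
        th = theta[start : start + chunk]
        C, S = np.cos(th), np.sin(th)
        a = n1[:, None] * np.abs(C)[None, :]
        b = n2[:, None] * np.abs(C[None, :] * c[:, None] + S[None, :] * s[:, None])
        best = np.maximum(best, np.minimum(a, b).max(axis=1))
    return 2.0 * best


def _plane_directions(E1, E2, n_directions):
    """Orthonormal in-plane direction fans for each node pair."""
    u = E1 / np.maximum(np.linalg.norm(E1, axis=1, keepdims=True), NORM_EPS)
    w = E2 - (np.einsum("ij,ij->i", E2, u))[:, None] * u
    wn = np.linalg.norm(w, axis=1, keepdims=True)
    # collinear fallback: any direction in the plane works, keep u
    w = np.where(wn > NORM_EPS, w / np.maximum(wn, NORM_EPS), 0.0)
    psi = np.linspace(0.0, np.pi, n_directions, endpoint=False)
    return u, w, psi


def ti_envelope_time_domain(
    E1,
    E2,
    f1_hz: float = 2000.0,
    f2_hz: float = 2010.0,
    duration_s: float = 0.5,
    sampling_rate_hz: float = 100_000.0,
    n_directions: int = 181,
    measure: str = "depth",
) -> np.ndarray:
    """Simulate E(t), project onto in-plane directions, extract the envelope.

    For each node the superposed field is sampled in time, projected onto
    ``n_directions`` unit vectors spanning the (E1, E2) plane, and each
    projection's envelope is taken as the analytic-signal magnitude; 10% of
    the samples at each end are discarded against Hilbert edge artifacts.
    ``measure="depth"`` returns the peak-to-trough modulation depth (the TI
    amplitude A); ``measure="peak"`` returns the peak envelope magnitude
    (the single-frequency stimulation amplitude when f1 == f2).
    """
    if sampling_rate_hz < 20.0 * max(f1_hz, f2_hz):
        raise ValidationError("sampling_rate must be >= 20x the larger carrier frequency")
    df = abs(f2_hz - f1_hz)
    if df > 0 and duration_s < 3.0 / df:
        raise ValidationError("duration must cover at least 3 beat periods")
    if measure not in ("depth", "peak"):
        raise ValidationError("measure must be 'depth' or 'peak'")

    E1, E2, n1, n2, _ = _norms_and_cos(E1, E2)
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate_hz)
    s1 = np.sin(2.0 * np.pi * f1_hz * t)
    s2 = np.sin(2.0 * np.pi * f2_hz * t)
    u, w, psi = _plane_directions(E1, E2, n_directions)
    edge = int(0.1 * t.size)
    out = np.zeros(E1.shape[0])
    for i in range(E1.shape[0]):
        if n1[i] < NORM_EPS and n2[i] < NORM_EPS:
            continue
        dirs = np.outer(np.cos(psi), u[i]) + np.outer(np.sin(psi), w[i])  # (d, 3)
        a = dirs @ E1[i]  # (d,)
        b = dirs @ E2[i]
        proj = a[:, None] * s1[None, :] + b[:, None] * s2[None, :]
        env = np.abs(hilbert(proj, axis=1))[:, edge:-edge if edge else None]
        if measure == "depth":
            out[i] = np.max(env.max(axis=1) - env.min(axis=1))
        else:
            out[i] = np.max(env)
    return out


def tacs_amplitude(E1, E2, alpha_mA: float = 1.0, beta_mA: float = 1.0) -> np.ndarray:
    """Amplitude of the field when both pairs run in phase at one frequency.

    The total field then oscillates along the fixed vector
    ``alpha E1 + beta E2``; its amplitude is that vector's norm.  ``E1`` and
    ``E2`` are per-mA lead-field differences (unlike :func:`ti_envelope`,
    whose inputs are pre-scaled).
    """
    E1 = np.atleast_2d(np.asarray(E1, float))
    E2 = np.atleast_2d(np.asarray(E2, float))
    return np.linalg.norm(alpha_mA * E1 + beta_mA * E2, axis=1)


def envelope_frequency(
    E1_vec,
    E2_vec,
    f1_hz: float = 2000.0,
    f2_hz: float = 2010.0,
    duration_s: float = 1.0,
    sampling_rate_hz: float = 100_000.0,
) -> float:
    """Dominant oscillation frequency (Hz) of the projected field's envelope.

    Projects E(t) onto the direction of E1 at a single point, extracts the
    Hilbert envelope and returns the peak of its Fourier spectrum -- the
    measured beat frequency.
    """
    E1 = np.asarray(E1_vec, float).reshape(3)
    E2 = np.asarray(E2_vec, float).reshape(3)
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate_hz)
    u = E1 / np.linalg.norm(E1)
    p = (E1 @ u) * np.sin(2 * np.pi * f1_hz * t) + (E2 @ u) * np.sin(2 * np.pi * f2_hz * t)
    env = np.abs(hilbert(p))
    edge = int(0.1 * t.size)
    env = env[edge:-edge] - np.mean(env[edge:-edge])
    spec = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(env.size, 1.0 / sampling_rate_hz)
    return float(freqs[np.argmax(spec)])
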