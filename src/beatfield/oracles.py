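"""Analytic validation oracle: point electrodes on a homogeneous sphere.

For a current I injected at one surface point and withdrawn at another on a
homogeneous conducting sphere, the interior potential has the classical
Legendre-series form

    V(r) = I / (4 pi sigma R) * sum_{n>=1} (2n+1)/n * (r/R)^n
           * [P_n(cos g_src) - P_n(cos g_snk)]

with g the angle between the query point and the electrode.  The series is
evaluated by the Bonnet recurrence and used to cross-validate the FEM solver,
which models electrodes as finite discs; comparisons therefore exclude points
near the electrode footprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["SpherePointSourceProblem", "analytic_homogeneous_sphere_potential"]

MM = 1e-3


@dataclass(frozen=True)
class SpherePointSourceProblem:
    """Source/sink point-electrode pair on a homogeneous sphere.

    Radius in mm, conductivity in S/m, current in mA; ``source`` and ``sink``
    are positions on (or directions to) the sphere surface.
    """

    radius: float
    conductivity: float
    source: tuple
    sink: tuple
    current_mA: float = 1.0
    n_terms: int = 200

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.conductivity > 0 and self.current_mA > 0):
            raise ValidationError("radius, conductivity and current must be > 0")
        if self.n_terms < 1:
            raise ValidationError("n_terms must be >= 1")
        s = np.asarray(self.source, float)
        k = np.asarray(self.sink, float)
        if np.allclose(s / np.linalg.norm(s), k / np.linalg.norm(k)):
            raise ValidationError("source and sink must be distinct surface points")


def analytic_homogeneous_sphere_potential(
    problem: SpherePointSourceProblem, query_points, rel_increment: float = 1e-8
) -> np.ndarray:
    """Series potential (volts) at interior query points (mm).

    Converged when the last term's relative contribution drops below
    ``rel_increment`` at every query point; otherwise a truncation warning is
    issued with the last increment.
    """
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    R = problem.radius
    r = np.linalg.norm(q, axis=1)
    if np.any(r > R * (1 + 1e-12)):
        raise ValidationError("query points must lie inside the sphere")

    src = np.asarray(problem.source, float)
    snk = np.asarray(problem.sink, float)
    src = src / np.linalg.norm(src)
    snk = snk / np.linalg.norm(snk)

    with np.errstate(invalid="ignore"):
        qdir = np.where(r[:, None] > 0, q / np.maximum(r, 1e-300)[:, None], 0.0)
    ca = np.clip(qdir @ src, -1.0, 1.0)
    cb = np.clip(qdir @ snk, -1.0, 1.0)
    x = r / R

    # Bonnet recurrence for P_n(ca), P_n(cb)
    pa_prev, pa = np.ones_like(ca), ca.copy()
    pb_prev, pb = np.ones_like(cb), cb.copy()
    total = np.zeros_like(ca)
    xn = x.copy()
    last_inc = prev_inc = np.inf
    for n in range(1, problem.n_terms + 1):
        term = (2 * n + 1) / n * xn * (pa - pb)
        total += term
        scale = np.max(np.abs(total))
        prev_inc, last_inc = last_inc, (np.max(np.abs(term)) / scale if scale > 0 else 0.0)
        # symmetric layouts zero out alternate terms, so require two small
        # increments in a row before declaring convergence
        if max(last_inc, prev_inc) < rel_increment:
            break
        xn *= x
        pa_prev, pa = pa, ((2 * n + 1) * ca * pa - n * pa_prev) / (n + 1)
        pb_prev, pb = pb, ((2 * n + 1) * cb * pb - n * pb_prev) / (n + 1)
    else:
        warnings.warn(
            f"Legendre series not converged after {problem.n_terms} terms "
            f"(last relative increment {last_inc:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )

    I = problem.current_mA * 1e-3  # mA -> A
    return I / (4.0 * np.pi * problem.conductivity * R * MM) * total
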