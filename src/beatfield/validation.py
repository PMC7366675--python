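"""Built-in numerical QA studies.

Self-contained routines that quantify the solver's agreement with its
independent oracles: the FEM against the analytic sphere series across mesh
refinements, lead-field superposition against direct pair solves, and the
closed-form envelope against the theta-grid and time-domain routes.  The
test suite and the reproduction script both call these.
"""

from __future__ import annotations

import numpy as np

from .envelope import ti_envelope, ti_envelope_theta_grid, ti_envelope_time_domain
from .fem import assemble_system, solve_scaled_pair_field
from .leadfield import compute_leadfields, montage_field
from .mesh import ElectrodeSet, TissueLayer, attach_electrodes, build_layered_sphere_mesh
from .oracles import SpherePointSourceProblem, analytic_homogeneous_sphere_potential

__all__ = [
    "fem_vs_analytic_study",
    "superposition_study",
    "envelope_agreement_study",
]


def fem_vs_analytic_study(
    edge_lengths_mm=(14.0, 10.0, 7.0),
    radius_mm: float = 92.0,
    sigma: float = 0.33,
    electrode_diameter_mm: float = 10.0,
    seed: int = 3,
) -> dict:
    """FEM vs Legendre-series potentials on a homogeneous sphere.

    Two electrodes at the poles drive 1 mA; potentials are compared at mesh
    nodes with r < 0.55 R and more than 40 degrees from either electrode
    axis (where the finite-disc electrode model and the point-source oracle
    describe the same physics).  Both solutions are gauge-fixed to zero mean
    over the query set, since the Dirichlet drive pins the potential level
    through the (mesh-dependent) contact resistances while the series fixes
    it through a vanishing monopole moment.

    Returns per-level normalized L-infinity errors and whether they decrease
    monotonically with refinement.
    """
    errors = []
    for h in edge_lengths_mm:
        mesh = build_layered_sphere_mesh([TissueLayer("brain", radius_mm, sigma)], h, seed=seed)
        aug, elecs = attach_electrodes(
            mesh,
            np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
            ["A", "B"],
            diameter=electrode_diameter_mm,
        )
        system = assemble_system(aug)
        _, pot, _ = solve_scaled_pair_field(system, elecs[0], elecs[1])
        r = np.linalg.norm(mesh.nodes, axis=1)
        cos_pol = np.abs(mesh.nodes[:, 2]) / np.maximum(r, 1e-12)
        mask = (r < 0.55 * radius_mm) & (r > 5.0) & (cos_pol < np.cos(np.deg2rad(40.0)))
        pts = mesh.nodes[mask]
        problem = SpherePointSourceProblem(
            radius_mm, sigma, (0, 0, radius_mm), (0, 0, -radius_mm), 1.0
        )
        va = analytic_homogeneous_sphere_potential(problem, pts)
        vf = pot.potentials[: mesh.n_nodes][mask]
        va = va - va.mean()
        vf = vf - vf.mean()
        errors.append(float(np.max(np.abs(vf - va)) / np.max(np.abs(va))))
    return {
        "edge_lengths_mm": list(edge_lengths_mm),
        "errors": errors,
        "final_error": errors[-1],
        "monotone": all(a > b for a, b in zip(errors, errors[1:])),
    }


def superposition_study(
    edge_length_mm: float = 12.0,
    radius_mm: float = 92.0,
    sigma: float = 0.33,
    seed: int = 7,
) -> dict:
    """Lead-field superposition vs a direct two-electrode FEM solve.

    Three electrodes (two candidates plus a reference) on a homogeneous
    sphere; the candidate pair's field is synthesized from the two stored
    candidate-vs-reference solves and compared with a dedicated solve of
    that pair, on interior nodes (r < 0.8 R).  The two discretizations
    differ only in how the passive contact distributes current, so interior
    agreement is expected at the percent level.
    """
    mesh = build_layered_sphere_mesh([TissueLayer("brain", radius_mm, sigma)], edge_length_mm, seed=seed)
    th = np.deg2rad(70.0)
    dirs = np.array(
        [
            [np.sin(th), 0.0, np.cos(th)],
            [-np.sin(th), 0.0, np.cos(th)],
            [0.0, np.sin(th), -np.cos(th)],
        ]
    )
    aug, elecs = attach_electrodes(mesh, dirs, ["A", "B", "REF"])
    eset = ElectrodeSet(candidates=list(elecs[:2]), reference=elecs[2])
    lf = compute_leadfields(aug, eset)
    superposed = montage_field(lf, "A", "B", 1.0).node_values

    system = assemble_system(aug)
    direct, _, _ = solve_scaled_pair_field(system, elecs[0], elecs[1])
    r = np.linalg.norm(aug.nodes, axis=1)
    interior = r < 0.8 * radius_mm
    diff = np.linalg.norm(superposed[interior] - direct.node_values[interior], axis=1)
    scale = np.max(np.linalg.norm(direct.node_values[interior], axis=1))
    return {
        "n_interior_nodes": int(interior.sum()),
        "max_rel_error": float(diff.max() / scale),
    }


def envelope_agreement_study(
    n_pairs_grid: int = 1000,
    n_theta: int = 4_000_000,
    n_pairs_hilbert: int = 100,
    seed: int = 42,
) -> dict:
    """Three-way envelope agreement on random field-vector pairs.

    Closed form vs theta-grid (exact up to the grid's kink resolution
    ~pi/n_theta) and closed form vs time-domain Hilbert extraction at the
    default 2 kHz / 2.01 kHz carriers.
    """
    rng = np.random.default_rng(seed)
    E1 = rng.normal(size=(n_pairs_grid, 3))
    E2 = rng.normal(size=(n_pairs_grid, 3))
    A = ti_envelope(E1, E2)
    Ag = ti_envelope_theta_grid(E1, E2, n_theta=n_theta)
    grid_err = float(np.max(np.abs(A - Ag) / A))

    Eh1, Eh2 = E1[:n_pairs_hilbert], E2[:n_pairs_hilbert]
    Ah = ti_envelope_time_domain(Eh1, Eh2)
    hilbert_err = float(np.max(np.abs(Ah - A[:n_pairs_hilbert]) / A[:n_pairs_hilbert]))
    return {
        "n_pairs_grid": n_pairs_grid,
        "n_theta": n_theta,
        "grid_max_rel_error": grid_err,
        "n_pairs_hilbert": n_pairs_hilbert,
        "hilbert_max_rel_error": hilbert_err,
    }
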