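"""Exhaustive montage/current optimization of the peak-ratio objective.

The search space is every unordered 4-subset of the candidate electrodes,
each split into its 3 perfect matchings into two pairs, each pair assignment
evaluated over a grid of current splits (alpha, beta = total - alpha).  A
montage is scored by the peak TI envelope amplitude inside the deep target
(A_target) and over the cortical compartment (A_cortex); the primary
objective is the peak ratio PR = A_target / A_cortex subject to
A_target > 0.2 V/m, and the alternative objective maximizes A_target subject
to PR > 1.

Comparison conditions: unoptimized TI (1 mA + 1 mA montage chosen on a
conductivity-homogenized head for maximal A_target), single-frequency tACS
on the optimized montage, and constrained multi-electrode tACS (total
current 2 mA, per-electrode 1 mA) solved as a linear program over a fan of
target field directions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linprog

from .envelope import MontageConfig, TIPattern, envelope_from_norms, tacs_amplitude, ti_envelope
from .errors import ValidationError
from .leadfield import LeadFieldSet
from .mesh import ROISpec

__all__ = [
    "MontageCandidate",
    "SearchConfig",
    "OptimizationResult",
    "peak_ratio",
    "current_grid",
    "enumerate_montages",
    "evaluate_montage",
    "optimize_ti",
    "baseline_unoptimized_ti",
    "baseline_tacs",
    "optimized_tacs",
    "icosphere_directions",
]

logger = logging.getLogger(__name__)

#: Fixed pairing order for a sorted 4-tuple (a, b, c, d).
_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

#: Strictness tolerance for the "larger than" feasibility constraints.
CONSTRAINT_ATOL = 1e-12


@dataclass(frozen=True)
class MontageCandidate:
    """Four candidate electrodes split into two current-carrying pairs."""

    electrode_ids: tuple
    pairing: tuple  # ((anode1, cathode1), (anode2, cathode2))

    def __post_init__(self) -> None:
        ids = tuple(self.electrode_ids)
        if len(set(ids)) != 4:
            raise ValidationError("montage needs 4 distinct electrode ids")
        flat = tuple(e for pair in self.pairing for e in pair)
        if sorted(flat) != sorted(ids):
            raise ValidationError("pairing must cover the 4 electrode ids exactly once")


@dataclass(frozen=True)
class SearchConfig:
    """Current grid, feasibility constraint and objective mode."""

    alpha_min_mA: float = 0.5
    alpha_max_mA: float = 1.5
    alpha_step_mA: float = 0.05
    total_current_mA: float = 2.0
    constraint_threshold_V_per_m: float = 0.2
    objective_mode: str = "max_pr_with_amplitude_floor"
    pr_floor: float = 1.0
    f1_hz: float = 2000.0
    f2_hz: float = 2010.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_min_mA <= self.alpha_max_mA < self.total_current_mA):
            raise ValidationError("alpha grid must lie strictly inside (0, total_current)")
        if self.alpha_step_mA <= 0:
            raise ValidationError("alpha_step must be > 0")
        if self.alpha_max_mA > self.alpha_min_mA and self.alpha_step_mA > (
            self.alpha_max_mA - self.alpha_min_mA
        ):
            raise ValidationError("alpha_step larger than the alpha range")
        if self.constraint_threshold_V_per_m < 0:
            raise ValidationError("constraint threshold must be >= 0")
        if self.objective_mode not in (
            "max_pr_with_amplitude_floor",
            "max_amplitude_with_pr_floor",
        ):
            raise ValidationError(f"unknown objective mode {self.objective_mode!r}")


@dataclass
class OptimizationResult:
    """Winning montage with currents, peak amplitudes and diagnostics."""

    montage: MontageCandidate
    alpha_mA: float
    beta_mA: float
    A_target: float
    A_cortex: float
    PR: float
    feasible: bool
    objective_mode: str
    n_evaluations: int
    pattern: TIPattern = None

    def as_dict(self) -> dict:
        return {
            "electrodes": list(self.montage.electrode_ids),
            "pairing": [list(p) for p in self.montage.pairing],
            "alpha_mA": self.alpha_mA,
            "beta_mA": self.beta_mA,
            "A_target_V_per_m": self.A_target,
            "A_cortex_V_per_m": self.A_cortex,
            "PR": self.PR,
            "feasible": self.feasible,
            "objective_mode": self.objective_mode,
            "n_evaluations": self.n_evaluations,
        }


def peak_ratio(pattern: TIPattern, roi: ROISpec):
    """(A_target, A_cortex, PR): peak amplitudes over the two ROIs and their ratio."""
    A = np.asarray(pattern.amplitude)
    a_t = float(np.max(A[roi.target_nodes]))
    a_c = float(np.max(A[roi.cortex_nodes]))
    if a_c == 0.0:
        raise ValidationError("cortex peak amplitude is zero; peak ratio undefined")
    return a_t, a_c, a_t / a_c


def current_grid(config: SearchConfig = SearchConfig()):
    """Ordered (alpha, beta) pairs; built in integer hundredths of a mA so
    alpha + beta equals the total exactly."""
    lo = int(round(config.alpha_min_mA * 100))
    hi = int(round(config.alpha_max_mA * 100))
    step = int(round(config.alpha_step_mA * 100))
    if step == 0:
        raise ValidationError("alpha_step below 0.01 mA resolution")
    alphas = np.arange(lo, hi + 1, step) / 100.0
    betas = config.total_current_mA - alphas
    return list(zip(alphas.tolist(), betas.tolist()))


def enumerate_montages(n_candidates: int, ids=None):
    """Yield every 4-subset (lexicographic) in each of its 3 pairings.

    ``ids`` defaults to ``E00 .. E{n-1}`` labels; total count C(n, 4) * 3.
    """
    if n_candidates < 4:
        raise ValidationError("need at least 4 candidates to form a montage")
    if ids is None:
        ids = [f"E{i:02d}" for i in range(n_candidates)]
    if len(ids) != n_candidates:
        raise ValidationError("ids length must equal n_candidates")
    for four in itertools.combinations(range(n_candidates), 4):
        quad = tuple(ids[i] for i in four)
        for pairing in _PAIRINGS:
            yield MontageCandidate(
                electrode_ids=quad,
                pairing=(
                    (quad[pairing[0][0]], quad[pairing[0][1]]),
                    (quad[pairing[1][0]], quad[pairing[1][1]]),
                ),
            )


def evaluate_montage(
    leadfields: LeadFieldSet,
    montage: MontageCandidate,
    currents,
    roi: ROISpec = None,
    config: SearchConfig = SearchConfig(),
):
    """Score one montage at one current split.

    Returns an :class:`OptimizationResult` (without feasibility applied when
    ``roi`` is given; ``feasible`` reflects the config's constraint).  Node
    indices in ``roi`` refer to the lead-field set's own node numbering, so
    pass ROI-restricted lead fields with a matching re-indexed ROI or
    full-head lead fields with the mesh ROI.
    """
    alpha, beta = currents
    (a1, c1), (a2, c2) = montage.pairing
    E1 = alpha * (leadfields[a1] - leadfields[c1])
    E2 = beta * (leadfields[a2] - leadfields[c2])
    A = ti_envelope(E1, E2)
    pattern = TIPattern(
        amplitude=A,
        envelope_frequency_hz=abs(config.f2_hz - config.f1_hz),
        montage=MontageConfig(
            pair1=montage.pairing[0],
            pair2=montage.pairing[1],
            alpha_mA=alpha,
            beta_mA=beta,
            f1_hz=config.f1_hz,
            f2_hz=config.f2_hz,
        ),
        mesh_fingerprint=leadfields.mesh_fingerprint,
    )
    if roi is None:
        return pattern
    a_t, a_c, pr = peak_ratio(pattern, roi)
    feasible = _is_feasible(a_t, pr, config)
    return OptimizationResult(
        montage=montage,
        alpha_mA=alpha,
        beta_mA=beta,
        A_target=a_t,
        A_cortex=a_c,
        PR=pr,
        feasible=feasible,
        objective_mode=config.objective_mode,
        n_evaluations=1,
        pattern=pattern,
    )


def _is_feasible(a_target: float, pr: float, config: SearchConfig) -> bool:
    if config.objective_mode == "max_pr_with_amplitude_floor":
        return a_target > config.constraint_threshold_V_per_m + CONSTRAINT_ATOL
    return pr > config.pr_floor + CONSTRAINT_ATOL


def _objective(a_target: float, pr: float, config: SearchConfig) -> float:
    return pr if config.objective_mode == "max_pr_with_amplitude_floor" else a_target


def _roi_views(leadfields: LeadFieldSet, roi: ROISpec):
    """Restrict lead fields to target + cortex nodes; return views and local ROI."""
    if leadfields.node_subset is not None:
        return leadfields, roi  # caller already restricted consistently
    nodes = np.concatenate([roi.target_nodes, roi.cortex_nodes])
    local = ROISpec(
        target_nodes=np.arange(roi.target_nodes.size),
        cortex_nodes=np.arange(roi.target_nodes.size, nodes.size),
    )
    return leadfields.restrict(nodes), local


def optimize_ti(
    leadfields: LeadFieldSet,
    roi: ROISpec,
    config: SearchConfig = SearchConfig(),
    candidate_ids=None,
) -> OptimizationResult:
    """Exhaustive scan of all montages x pairings x current splits.

    Among feasible candidates the objective maximizer wins, ties broken by
    enumeration order (first wins); if nothing is feasible the unconstrained
    objective maximizer is returned flagged infeasible.  The search runs on
    ROI-restricted lead fields: per montage, per-node field norms and the
    angle between the two pair fields are computed once and the closed-form
    envelope is then evaluated for the whole current grid at once (identical,
    to tie-break order, to nested loops over :func:`evaluate_montage`).
    """
    ids = list(candidate_ids) if candidate_ids is not None else leadfields.candidate_ids
    if len(ids) < 4:
        raise ValidationError("need lead fields for at least 4 candidates")
    lf, local_roi = _roi_views(leadfields, roi)
    tgt, ctx = local_roi.target_nodes, local_roi.cortex_nodes

    pairs = {}
    for a, b in itertools.combinations(ids, 2):
        pairs[(a, b)] = lf[a] - lf[b]

    grid = current_grid(config)
    alphas = np.array([g[0] for g in grid])
    betas = np.array([g[1] for g in grid])

    best = None  # (objective, feasible) lexicographic with first-wins ties
    best_key = (-np.inf, False)
    n_eval = 0
    for montage in enumerate_montages(len(ids), ids=ids):
        (a1, c1), (a2, c2) = montage.pairing
        P1 = pairs[(a1, c1)] if (a1, c1) in pairs else -pairs[(c1, a1)]
        P2 = pairs[(a2, c2)] if (a2, c2) in pairs else -pairs[(c2, a2)]
        n1 = np.linalg.norm(P1, axis=1)
        n2 = np.linalg.norm(P2, axis=1)
        dot = np.einsum("ij,ij->i", P1, P2)
        cross = np.linalg.norm(np.cross(P1, P2), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = n1 * n2
            c = np.abs(dot) / nn
            s = cross / nn
        c = np.clip(np.where(np.isfinite(c), c, 0.0), 0.0, 1.0)
        s = np.clip(np.where(np.isfinite(s), s, 0.0), 0.0, 1.0)
        # (n_alpha, n_nodes) closed-form envelope for the whole current grid
        A = envelope_from_norms(
            alphas[:, None] * n1[None, :], betas[:, None] * n2[None, :], c[None, :], s[None, :]
        )
        a_t = A[:, tgt].max(axis=1)
        a_c = A[:, ctx].max(axis=1)
        n_eval += len(grid)
        for k in range(len(grid)):
            pr = a_t[k] / a_c[k] if a_c[k] > 0 else np.inf
            feas = _is_feasible(a_t[k], pr, config)
            key = (feas, _objective(a_t[k], pr, config))
            if key > best_key:
                best_key = key
                best = (montage, alphas[k], betas[k], a_t[k], a_c[k], pr, feas)

    montage, alpha, beta, a_t, a_c, pr, feas = best
    logger.info(
        "search done: %d evaluations, best %s alpha=%.2f PR=%.3f A_target=%.3f feasible=%s",
        n_eval, montage.electrode_ids, alpha, pr, a_t, feas,
    )
    return OptimizationResult(
        montage=montage,
        alpha_mA=float(alpha),
        beta_mA=float(beta),
        A_target=float(a_t),
        A_cortex=float(a_c),
        PR=float(pr),
        feasible=bool(feas),
        objective_mode=config.objective_mode,
        n_evaluations=n_eval,
    )


def baseline_unoptimized_ti(
    homogeneous_leadfields: LeadFieldSet,
    roi: ROISpec,
    config: SearchConfig = SearchConfig(),
    candidate_ids=None,
) -> OptimizationResult:
    """Fixed 1 mA + 1 mA exhaustive search maximizing A_target on a
    conductivity-homogenized head (no peak-ratio objective, no constraint).

    The caller re-evaluates the winning montage on the heterogeneous model
    (via :func:`evaluate_montage`) for the comparison table.
    """
    ids = list(candidate_ids) if candidate_ids is not None else homogeneous_leadfields.candidate_ids
    if len(ids) < 4:
        raise ValidationError("need lead fields for at least 4 candidates")
    lf, local_roi = _roi_views(homogeneous_leadfields, roi)
    tgt = local_roi.target_nodes
    pairs = {}
    for a, b in itertools.combinations(ids, 2):
        pairs[(a, b)] = lf[a] - lf[b]

    best = None
    best_a = -np.inf
    n_eval = 0
    for montage in enumerate_montages(len(ids), ids=ids):
        (a1, c1), (a2, c2) = montage.pairing
        P1 = pairs.get((a1, c1), None)
        P1 = P1 if P1 is not None else -pairs[(c1, a1)]
        P2 = pairs.get((a2, c2), None)
        P2 = P2 if P2 is not None else -pairs[(c2, a2)]
        A = ti_envelope(P1[tgt], P2[tgt])  # alpha = beta = 1 mA; target only
        a_t = float(A.max())
        n_eval += 1
        if a_t > best_a:
            best_a = a_t
            best = montage
    # score the winner on the full ROI for reporting
    res = evaluate_montage(lf, best, (1.0, 1.0), roi=local_roi, config=config)
    return replace(res, n_evaluations=n_eval, feasible=True, pattern=None)


def baseline_tacs(
    leadfields: LeadFieldSet,
    optimized: OptimizationResult,
    roi: ROISpec,
) -> dict:
    """Single-frequency stimulation through the optimized montage/currents.

    Both pairs run in phase at one low frequency, so the field amplitude is
    the norm of the summed pair fields; peaks and their ratio are reported
    over the same ROIs.
    """
    lf, local_roi = _roi_views(leadfields, roi)
    (a1, c1), (a2, c2) = optimized.montage.pairing
    E1 = lf[a1] - lf[c1]
    E2 = lf[a2] - lf[c2]
    amp = tacs_amplitude(E1, E2, optimized.alpha_mA, optimized.beta_mA)
    a_t = float(np.max(amp[local_roi.target_nodes]))
    a_c = float(np.max(amp[local_roi.cortex_nodes]))
    return {
        "montage": optimized.montage,
        "alpha_mA": optimized.alpha_mA,
        "beta_mA": optimized.beta_mA,
        "A_target": a_t,
        "A_cortex": a_c,
        "PR": a_t / a_c,
    }


def icosphere_directions(n_subdivisions: int = 2) -> np.ndarray:
    """Unit directions from a subdivided icosahedron (162 at 2 subdivisions)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v / np.linalg.norm(v)) for v in verts]
    index = {v: i for i, v in enumerate(verts)}

    def midpoint(a, b):
        m = (np.array(verts[a]) + np.array(verts[b])) / 2.0
        m = tuple(m / np.linalg.norm(m))
        if m not in index:
            index[m] = len(verts)
            verts.append(m)
        return index[m]

    for _ in range(n_subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts)


def optimized_tacs(
    leadfields: LeadFieldSet,
    roi: ROISpec,
    total_current_mA: float = 2.0,
    max_individual_mA: float = 1.0,
    n_directions: int = None,
    target_node: int = None,
) -> dict:
    """Constrained multi-electrode single-frequency optimization.

    Maximizes the field magnitude at the target (its centre-most ROI node by
    default) over per-electrode currents I (reference included, implied by
    current conservation), subject to sum(I) = 0, sum(|I|)/2 <= total and
    |I_i| <= max individual.  For each unit direction of an icosphere fan the
    directional field is a linear functional of I, so each direction is an
    LP; the best direction wins.

    Returns the winning currents (mA per electrode id), the achieved target
    amplitude, the full amplitude field over the lead-field nodes, and the
    peak ratio over the ROIs.
    """
    lf, local_roi = _roi_views(leadfields, roi)
    ids = lf.candidate_ids
    if target_node is None:
        target_node = int(local_roi.target_nodes[local_roi.target_nodes.size // 2])
    L = np.stack([lf[e][target_node] for e in ids])  # (n_cand, 3) V/m per mA
    dirs = icosphere_directions(2) if n_directions is None else icosphere_directions(n_directions)

    n = len(ids)
    # variables: I = p - q with p, q >= 0 (mA), plus t >= |sum(I)| (reference)
    # constraints: sum(p + q) + t <= 2 * total;  t >= +-sum(I);  t <= max_ind;
    #              |I_i| <= max_ind via p_i + q_i <= max_ind
    best = None
    for d in dirs:
        c_lin = L @ d  # objective coefficients for I
        c = np.concatenate([-c_lin, c_lin, [0.0]])  # maximize -> minimize negative
        A_ub = []
        b_ub = []
        row = np.concatenate([np.ones(n), np.ones(n), [1.0]])
        A_ub.append(row)
        b_ub.append(2.0 * total_current_mA)
        s_row = np.concatenate([np.ones(n), -np.ones(n), [-1.0]])
        A_ub.append(s_row)       # sum(I) - t <= 0
        b_ub.append(0.0)
        A_ub.append(-s_row - np.concatenate([np.zeros(2 * n), [2.0]]))  # -sum(I) - t <= 0
        b_ub.append(0.0)
        for i in range(n):
            r = np.zeros(2 * n + 1)
            r[i] = 1.0
            r[n + i] = 1.0
            A_ub.append(r)
            b_ub.append(max_individual_mA)
        bounds = [(0, None)] * (2 * n) + [(0, max_individual_mA)]
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
        if not res.success:
            raise ValidationError(f"tACS current LP infeasible: {res.message}")
        I = res.x[:n] - res.x[n : 2 * n]
        val = float(c_lin @ I)
        if best is None or val > best[0]:
            best = (val, I, d)

    _, I, d = best
    currents = {e: float(I[k]) for k, e in enumerate(ids)}
    currents[lf.reference_id] = float(-I.sum())
    field = np.tensordot(I, np.stack([lf[e] for e in ids]), axes=(0, 0))  # (n_nodes, 3)
    amp = np.linalg.norm(field, axis=1)
    a_t = float(np.max(amp[local_roi.target_nodes]))
    a_c = float(np.max(amp[local_roi.cortex_nodes]))
    return {
        "currents_mA": currents,
        "direction": d,
        "A_target": a_t,
        "A_cortex": a_c,
        "PR": a_t / a_c,
        "amplitude": amp,
    }
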