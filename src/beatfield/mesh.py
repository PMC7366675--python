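"""Layered-sphere head models: mesh generation, electrodes, ROIs, validation.

The package's geometric substrate is a concentric multi-shell ball standing in
for an MRI-derived head: scalp, skull, cerebrospinal fluid (CSF), gray matter
and white matter, each a spherical shell with its own isotropic conductivity,
plus a deep spherical target region (a hippocampus analogue) whose
conductivity equals gray matter.  Stimulation electrodes are thin conductive
cylinders extruded outward from the scalp surface.

All lengths are millimetres; conductivities are S/m.  Node and element indices
are 0-based.  The coordinate origin is the sphere centre with +z through the
vertex of the head.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .errors import PlacementError, ResolutionError, ValidationError

__all__ = [
    "TissueLayer",
    "HeadMesh",
    "Electrode",
    "ElectrodeSet",
    "ROISpec",
    "MeshValidationReport",
    "DEFAULT_LAYERS",
    "ELECTRODE_TISSUE",
    "build_layered_sphere_mesh",
    "attach_electrodes",
    "place_electrodes",
    "candidate_directions",
    "define_rois",
    "validate_mesh",
    "homogenize_conductivity",
]

#: Degeneracy threshold for tetrahedron volumes, mm^3.
VOLUME_EPSILON = 1e-12

#: Tissue name used for electrode elements.
ELECTRODE_TISSUE = "electrode"


@dataclass(frozen=True)
class TissueLayer:
    """One concentric tissue shell.

    Parameters
    ----------
    name : str
        Tissue label (``scalp``, ``skull``, ``csf``, ``gray``, ``white`` for
        the standard five-layer head, but arbitrary labels are accepted).
    outer_radius : float
        Outer radius of the shell in mm.  The shell extends inward to the
        next layer's outer radius (or to the centre for the innermost layer).
    conductivity : float
        Isotropic electrical conductivity in S/m.
    """

    name: str
    outer_radius: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (self.outer_radius > 0):
            raise ValidationError(f"layer {self.name!r}: outer_radius must be > 0")
        if not (self.conductivity > 0 and np.isfinite(self.conductivity)):
            raise ValidationError(f"layer {self.name!r}: conductivity must be positive and finite")


# Plausible adult-head shell radii with literature-style isotropic
# conductivities.  The deep target's conductivity equals gray matter by
# construction (it lives inside the gray/white compartments).
DEFAULT_LAYERS = (
    TissueLayer("scalp", 92.0, 0.465),
    TissueLayer("skull", 86.0, 0.010),
    TissueLayer("csf", 80.0, 1.654),
    TissueLayer("gray", 78.0, 0.276),
    TissueLayer("white", 70.0, 0.126),
)


@dataclass
class HeadMesh:
    """Labelled tetrahedral volume mesh with per-element conductivity.

    Attributes
    ----------
    nodes : (n, 3) float64
        Node positions, mm.
    tets : (m, 4) int32
        Tetrahedra as node-index 4-tuples, positively oriented.
    tissue : (m,) int16
        Per-element tissue code indexing into ``tissue_names``.
    sigma : (m,) float64
        Per-element conductivity, S/m.
    tissue_names : list of str
        Code -> label mapping.
    edge_length : float
        Target edge length the generator was asked for (mm); informational.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue: np.ndarray
    sigma: np.ndarray
    tissue_names: list
    edge_length: float = 0.0

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tets.shape[0])

    def tissue_code(self, name: str) -> int:
        try:
            return self.tissue_names.index(name)
        except ValueError:
            raise KeyError(f"no tissue named {name!r} in mesh") from None

    def element_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes, mm^3 (positive for a valid mesh)."""
        return _signed_volumes(self.nodes, self.tets)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def tissue_nodes(self, name: str) -> np.ndarray:
        """Sorted unique indices of nodes touched by elements of a tissue."""
        code = self.tissue_code(name)
        return np.unique(self.tets[self.tissue == code])

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces belonging to exactly one tetrahedron."""
        faces, counts, _ = _face_incidence(self.tets)
        return faces[counts == 1]

    def fingerprint(self) -> str:
        """Content hash binding derived artifacts (lead fields) to this mesh."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.tets, dtype=np.int32).tobytes())
        h.update(np.ascontiguousarray(self.sigma, dtype=np.float64).tobytes())
        return h.hexdigest()

    def copy(self) -> "HeadMesh":
        return HeadMesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            tissue=self.tissue.copy(),
            sigma=self.sigma.copy(),
            tissue_names=list(self.tissue_names),
            edge_length=self.edge_length,
        )


@dataclass(frozen=True)
class Electrode:
    """One cylindrical electrode attached to the scalp.

    ``top_nodes`` carry the Dirichlet boundary condition; ``bottom_faces``
    (scalp-surface triangles, node index triples) are where the injected
    current is integrated.
    """

    id: str
    center: np.ndarray  # on-scalp position, mm
    direction: np.ndarray  # outward unit axis
    diameter: float
    thickness: float
    conductivity: float
    top_nodes: np.ndarray
    bottom_faces: np.ndarray


@dataclass
class ElectrodeSet:
    candidates: list
    reference: Electrode

    def __post_init__(self) -> None:
        if len(self.candidates) < 1:
            raise ValidationError("need at least one candidate electrode")

    @property
    def candidate_ids(self) -> list:
        return [e.id for e in self.candidates]

    def get(self, electrode_id: str) -> Electrode:
        if electrode_id == self.reference.id:
            return self.reference
        for e in self.candidates:
            if e.id == electrode_id:
                return e
        raise KeyError(f"no electrode with id {electrode_id!r}")


@dataclass
class ROISpec:
    """Node sets over which envelope peaks are taken.

    ``target_nodes`` is the deep target ball (hippocampus-head analogue);
    ``cortex_nodes`` is the whole gray-matter compartment minus the target.
    """

    target_nodes: np.ndarray
    cortex_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.target_nodes = np.asarray(self.target_nodes, dtype=np.int64)
        self.cortex_nodes = np.asarray(self.cortex_nodes, dtype=np.int64)
        if self.target_nodes.size == 0 or self.cortex_nodes.size == 0:
            raise ValidationError("ROI node sets must be nonempty")
        if np.intersect1d(self.target_nodes, self.cortex_nodes).size:
            raise ValidationError("target and cortex node sets must be disjoint")


@dataclass(frozen=True)
class MeshValidationReport:
    n_isolated_nodes: int
    n_degenerate_elements: int
    n_out_of_range_indices: int
    n_nonfinite_conductivities: int

    @property
    def passed(self) -> bool:
        return (
            self.n_isolated_nodes == 0
            and self.n_degenerate_elements == 0
            and self.n_out_of_range_indices == 0
            and self.n_nonfinite_conductivities == 0
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _face_incidence(tets: np.ndarray):
    """All element faces as sorted node triples, with incidence counts.

    Returns (unique_faces, counts, owner) where ``owner`` maps each unique
    face to the index of one element containing it.
    """
    local = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    faces = tets[:, local].reshape(-1, 3)
    faces = np.sort(faces, axis=1)
    elem_of_face = np.repeat(np.arange(tets.shape[0]), 4)
    uniq, inv, counts = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    owner = np.zeros(uniq.shape[0], dtype=np.int64)
    owner[inv] = elem_of_face  # last writer wins; any owner is fine
    return uniq, counts, owner


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n deterministic, near-uniform points on a sphere of given radius."""
    i = np.arange(n, dtype=np.float64)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    th = golden * i
    return radius * np.column_stack([r * np.cos(th), r * np.sin(th), z])


def candidate_directions(n: int, max_polar_deg: float = 90.0) -> np.ndarray:
    """Deterministic near-uniform unit directions on the upper spherical cap.

    A golden-angle spiral over the cap ``polar angle <= max_polar_deg``:
    a fixed angular layout approximating the proportional coverage of the
    10-10 scalp electrode scheme for any candidate count.
    """
    i = np.arange(n, dtype=np.float64)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z_min = np.cos(np.deg2rad(max_polar_deg))
    z = 1.0 - (1.0 - z_min) * (2.0 * i + 1.0) / (2.0 * n)
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    th = golden * i
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


# ---------------------------------------------------------------------------
# mesh generation


def _prism_tets(tri_bottom, tri_top):
    """Split a triangular prism into 3 tetrahedra.

    ``tri_bottom``/``tri_top`` are matching vertex triples.  The staircase
    split keyed on sorted bottom indices picks, on every quad face, the
    diagonal from the higher-index bottom vertex to the lower-index top
    vertex, which makes adjacent prisms conform as long as top indices are
    ordered like bottom indices.
    """
    order = np.argsort(tri_bottom)
    b0, b1, b2 = (tri_bottom[k] for k in order)
    t0, t1, t2 = (tri_top[k] for k in order)
    return [[b0, b1, b2, t0], [b1, b2, t0, t1], [b2, t0, t1, t2]]


def build_layered_sphere_mesh(
    layers=DEFAULT_LAYERS,
    target_edge_length: float = 8.0,
    seed: int = 0,
) -> HeadMesh:
    """Generate a conforming tetrahedral mesh of nested spherical shells.

    One spherical surface triangulation (convex hull of a Fibonacci point
    set at roughly the requested edge length) is extruded radially through a
    ladder of radii that contains every shell interface, so elements conform
    to the interfaces exactly and labelling by centroid radius is exact.  The
    ball inside the innermost interface is filled with a Delaunay mesh over
    the shared interface points plus a jittered interior lattice (the hull
    facets of that Delaunay mesh are the same surface triangulation, so the
    two parts match).

    Deterministic for fixed ``layers``, ``target_edge_length`` and ``seed``
    (the seed only drives the interior lattice jitter).

    Raises
    ------
    ValidationError
        No layers, or radii not strictly nested.
    ResolutionError
        ``target_edge_length`` more than 5x the thinnest shell thickness
        (elements spanning such a shell would be too distorted), or a layer
        ends up without elements.
    """
    layers = list(layers)
    if len(layers) < 1:
        raise ValidationError("need at least 1 layer")
    radii = np.array([la.outer_radius for la in layers], dtype=float)
    if radii.size > 1 and not np.all(np.diff(radii) < 0):
        raise ValidationError(
            "layer radii must be strictly decreasing from outermost to innermost; got "
            + ", ".join(f"{r:g}" for r in radii)
        )
    h = float(target_edge_length)
    if not h > 0:
        raise ValidationError("target_edge_length must be > 0")
    thick = -np.diff(radii)
    if thick.size:
        k_min = int(np.argmin(thick))
        if h > 5.0 * thick[k_min]:
            raise ResolutionError(
                f"edge length {h:g} mm cannot resolve layer {layers[k_min].name!r} "
                f"({thick[k_min]:g} mm thick); use an edge length <= {5.0 * thick[k_min]:g} mm"
            )

    rng = np.random.default_rng(seed)
    R_out = radii[0]

    # shared angular triangulation at ~h spacing on the outer sphere
    n_dirs = max(14, int(round(4.0 * np.pi * R_out * R_out / (np.sqrt(3.0) / 2.0 * h * h))))
    dirs = _fibonacci_sphere(n_dirs, 1.0)
    hull = ConvexHull(dirs)
    surf_tris = np.asarray(hull.simplices, dtype=np.int64)

    # radial ladder: every interface plus intermediate rungs within thick shells
    rungs = [R_out]
    for k in range(1, len(radii)):
        t = radii[k - 1] - radii[k]
        n_sub = max(1, int(round(t / h)))
        for j in range(1, n_sub + 1):
            rungs.append(radii[k - 1] - t * j / n_sub)
    rungs = np.array(rungs)
    r_core = radii[-1]

    n_layers_of_nodes = len(rungs)
    nodes = np.vstack([r * dirs for r in rungs])
    tets, tissue_codes = [], []

    def layer_code(rc: float) -> int:
        for k in range(len(radii) - 1, -1, -1):
            if rc <= radii[k]:
                return k
        return 0

    for li in range(n_layers_of_nodes - 1):
        off_out, off_in = li * n_dirs, (li + 1) * n_dirs
        mid = 0.5 * (rungs[li] + rungs[li + 1])
        code = layer_code(mid)
        for tri in surf_tris:
            tets.extend(_prism_tets(tri + off_out, tri + off_in))
            tissue_codes.extend([code] * 3)

    # core ball inside the innermost interface
    inner_off = (n_layers_of_nodes - 1) * n_dirs
    core_code = len(radii) - 1
    if r_core > 1.5 * h:
        n_side = int(np.floor(2 * r_core / h)) + 1
        axis = (np.arange(n_side) - (n_side - 1) / 2.0) * h
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        lattice = lattice + rng.uniform(-0.12 * h, 0.12 * h, size=lattice.shape)
        lattice = lattice[np.linalg.norm(lattice, axis=1) < r_core - 0.45 * h]
    else:
        lattice = np.zeros((0, 3))
    if lattice.shape[0] == 0:
        # tiny core: fan all surface triangles to a centre node
        centre = nodes.shape[0]
        nodes = np.vstack([nodes, np.zeros((1, 3))])
        for tri in surf_tris:
            tets.append([tri[0] + inner_off, tri[1] + inner_off, tri[2] + inner_off, centre])
            tissue_codes.append(core_code)
    else:
        core_pts = np.vstack([r_core * dirs, lattice])
        dela = Delaunay(core_pts)
        core_tets = np.asarray(dela.simplices, dtype=np.int64)
        vols = _signed_volumes(core_pts, core_tets)
        core_tets = core_tets[np.abs(vols) > 1e-8 * h**3]
        # remap: sphere points are the innermost rung's nodes; lattice appended
        remap = np.concatenate(
            [np.arange(n_dirs) + inner_off, np.arange(lattice.shape[0]) + nodes.shape[0]]
        )
        nodes = np.vstack([nodes, lattice])
        tets.extend(remap[core_tets].tolist())
        tissue_codes.extend([core_code] * core_tets.shape[0])

    tets = np.asarray(tets, dtype=np.int64)
    vols = _signed_volumes(nodes, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    # compact node numbering (drops any lattice point qhull left unused)
    used, inverse = np.unique(tets.ravel(), return_inverse=True)
    nodes = nodes[used]
    tets = inverse.reshape(-1, 4).astype(np.int32)

    tissue = np.asarray(tissue_codes, dtype=np.int16)
    sigma = np.array([la.conductivity for la in layers], dtype=float)[tissue]

    for k, la in enumerate(layers):
        if not np.any(tissue == k):
            raise ResolutionError(
                f"edge length {h:g} mm is too coarse to resolve layer {la.name!r} "
                f"(outer radius {la.outer_radius:g} mm): no element falls in it"
            )

    return HeadMesh(
        nodes=nodes,
        tets=tets,
        tissue=tissue,
        sigma=sigma,
        tissue_names=[la.name for la in layers],
        edge_length=h,
    )


# ---------------------------------------------------------------------------
# electrodes


def attach_electrodes(
    mesh: HeadMesh,
    directions: np.ndarray,
    ids,
    diameter: float = 10.0,
    thickness: float = 2.5,
    conductivity: float = 1.0,
):
    """Attach cylindrical electrodes along the given outward unit directions.

    Each electrode claims the scalp-surface triangles whose centroid lies
    within ``max(diameter/2, 1.2 * edge_length)`` arc distance of its axis
    (the nearest triangle if that disc is empty at coarse resolution) and is
    extruded outward by ``thickness`` as a one-element-thick stack of prisms
    split into tetrahedra.  Bottom facets conform to the original scalp
    surface; the extruded copies of the footprint nodes form the electrode's
    top surface.

    Returns ``(augmented_mesh, electrodes)``; the input mesh is not modified.

    Raises
    ------
    PlacementError
        If two electrodes would claim overlapping scalp footprints.
    """
    directions = np.asarray(directions, dtype=float)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    if len(ids) != directions.shape[0]:
        raise ValidationError("ids and directions must have equal length")

    bfaces = mesh.boundary_faces()
    fc = mesh.nodes[bfaces].mean(axis=1)
    fc_dir = fc / np.linalg.norm(fc, axis=1, keepdims=True)
    scalp_r = np.linalg.norm(mesh.nodes[bfaces[0][0]])
    arc_radius = max(diameter / 2.0, 1.2 * mesh.edge_length) / scalp_r

    mesh = mesh.copy()
    if ELECTRODE_TISSUE in mesh.tissue_names:
        code = mesh.tissue_code(ELECTRODE_TISSUE)
    else:
        mesh.tissue_names.append(ELECTRODE_TISSUE)
        code = len(mesh.tissue_names) - 1

    claimed_nodes: dict = {}
    electrodes = []
    new_nodes = [mesh.nodes]
    next_node = mesh.n_nodes
    new_tets, new_tissue, new_sigma = [], [], []

    for eid, d in zip(ids, directions):
        ang = np.arccos(np.clip(fc_dir @ d, -1.0, 1.0))
        sel = np.flatnonzero(ang <= arc_radius)
        if sel.size == 0:
            sel = np.array([int(np.argmin(ang))])
        faces = bfaces[sel]
        foot_nodes = np.unique(faces)
        for n in foot_nodes:
            if n in claimed_nodes:
                raise PlacementError(
                    f"electrode {eid!r} collides with {claimed_nodes[n]!r} at scalp node {n}; "
                    "reduce the candidate count or the electrode diameter"
                )
        for n in foot_nodes:
            claimed_nodes[n] = eid

        # extruded top copies, radially outward
        base = mesh.nodes[foot_nodes]
        base_r = np.linalg.norm(base, axis=1, keepdims=True)
        top = base * (1.0 + thickness / base_r)
        top_index = {int(n): next_node + k for k, n in enumerate(foot_nodes)}
        next_node += foot_nodes.size
        new_nodes.append(top)

        for f in faces:
            b0, b1, b2 = sorted(int(v) for v in f)
            t0, t1, t2 = top_index[b0], top_index[b1], top_index[b2]
            # staircase prism split; conforming across shared quad faces
            # because vertex order follows global indices
            new_tets.extend([[b0, b1, b2, t0], [b1, b2, t0, t1], [b2, t0, t1, t2]])
            new_tissue.extend([code] * 3)
            new_sigma.extend([conductivity] * 3)

        electrodes.append(
            Electrode(
                id=str(eid),
                center=scalp_r * d,
                direction=d,
                diameter=diameter,
                thickness=thickness,
                conductivity=conductivity,
                top_nodes=np.array(sorted(top_index.values()), dtype=np.int64),
                bottom_faces=np.asarray(faces, dtype=np.int64),
            )
        )

    mesh.nodes = np.vstack(new_nodes)
    add = np.asarray(new_tets, dtype=np.int64)
    vols = _signed_volumes(mesh.nodes, add)
    add[vols < 0] = add[vols < 0][:, [0, 1, 3, 2]]
    mesh.tets = np.vstack([mesh.tets, add.astype(np.int32)])
    mesh.tissue = np.concatenate([mesh.tissue, np.asarray(new_tissue, dtype=np.int16)])
    mesh.sigma = np.concatenate([mesh.sigma, np.asarray(new_sigma, dtype=float)])
    return mesh, electrodes


def place_electrodes(
    mesh: HeadMesh,
    n_candidates: int,
    reference_polar_angle_deg: float = 115.0,
    diameter: float = 10.0,
    thickness: float = 2.5,
):
    """Place ``n_candidates`` candidate electrodes on the upper scalp plus a
    fixed low-lateral reference (left-mastoid analogue).

    Candidate centres follow the deterministic golden-angle cap layout of
    :func:`candidate_directions`; the reference sits at the given polar angle
    on the -x side of the head.

    Returns ``(augmented_mesh, ElectrodeSet)``.
    """
    if n_candidates < 4:
        raise ValidationError("need at least 4 electrode candidates")
    dirs = candidate_directions(n_candidates)
    th = np.deg2rad(reference_polar_angle_deg)
    ref_dir = np.array([[-np.sin(th), 0.0, np.cos(th)]])
    ids = [f"E{i:02d}" for i in range(n_candidates)] + ["REF"]
    aug, elecs = attach_electrodes(
        mesh, np.vstack([dirs, ref_dir]), ids, diameter=diameter, thickness=thickness
    )
    return aug, ElectrodeSet(candidates=elecs[:-1], reference=elecs[-1])


# ---------------------------------------------------------------------------
# ROIs, validation, homogenization


def define_rois(mesh: HeadMesh, target_center, target_radius: float) -> ROISpec:
    """Deep-target ball plus gray-matter cortical compartment.

    ``target_nodes`` are all mesh nodes within ``target_radius`` of
    ``target_center``; ``cortex_nodes`` are all nodes of the gray-matter
    compartment not in the target.  Peaks of the envelope objective are taken
    over these node sets (volumes, not surfaces).
    """
    center = np.asarray(target_center, dtype=float)
    d = np.linalg.norm(mesh.nodes - center, axis=1)
    target = np.flatnonzero(d <= target_radius)
    if target.size == 0:
        raise ValidationError(
            f"no mesh node within {target_radius:g} mm of {center.tolist()}; "
            "use a finer mesh or a larger target radius"
        )
    gray = mesh.tissue_nodes("gray")
    cortex = np.setdiff1d(gray, target)
    return ROISpec(target_nodes=target, cortex_nodes=cortex)


def validate_mesh(mesh: HeadMesh) -> MeshValidationReport:
    """Report isolated nodes, degenerate/inverted elements and bad indices."""
    in_range = (mesh.tets >= 0) & (mesh.tets < mesh.n_nodes)
    n_bad_idx = int(np.sum(~in_range))
    if n_bad_idx:
        return MeshValidationReport(0, 0, n_bad_idx, 0)
    referenced = np.zeros(mesh.n_nodes, dtype=bool)
    referenced[mesh.tets.ravel()] = True
    n_isolated = int(np.sum(~referenced))
    vols = mesh.element_volumes()
    n_degenerate = int(np.sum(vols <= VOLUME_EPSILON))
    n_bad_sigma = int(np.sum(~(np.isfinite(mesh.sigma) & (mesh.sigma > 0))))
    return MeshValidationReport(n_isolated, n_degenerate, n_bad_idx, n_bad_sigma)


def homogenize_conductivity(mesh: HeadMesh, sigma: float) -> HeadMesh:
    """Copy of the mesh with one conductivity for all tissue compartments.

    Electrode elements keep their own conductivity; tissue labels are kept so
    ROI definitions still apply.
    """
    if not sigma > 0:
        raise ValidationError("homogeneous conductivity must be > 0")
    out = mesh.copy()
    if ELECTRODE_TISSUE in out.tissue_names:
        is_tissue = out.tissue != out.tissue_code(ELECTRODE_TISSUE)
    else:
        is_tissue = np.ones(out.n_elements, dtype=bool)
    out.sigma = np.where(is_tissue, sigma, out.sigma)
    return out
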