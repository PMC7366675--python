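"""Lead-field computation, storage, and montage-field superposition.

One FEM solve per candidate electrode (against the fixed reference) is
stored as the node-averaged electric field per 1 mA injected.  Because the
problem is linear, the field of any candidate pair (a, b) carrying I mA with
no current in the reference is the superposition

    E_ab = I * (L_a - L_b),

which turns the exhaustive montage search into pure array arithmetic.
Lead-field sets are persisted in an HDF5 container bound to their mesh by a
content hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import BeatfieldError, FingerprintMismatchError, ValidationError
from .fem import FieldDistribution, assemble_system, solve_scaled_pair_field
from .mesh import ElectrodeSet, HeadMesh

__all__ = ["LeadFieldSet", "compute_leadfields", "montage_field", "save_leadfields", "load_leadfields"]

logger = logging.getLogger(__name__)


@dataclass
class LeadFieldSet:
    """Per-candidate unit-current (1 mA) field distributions.

    ``fields[eid]`` is an (n_nodes, 3) array of V/m per mA for the pair
    (candidate ``eid``, reference).  ``node_subset`` is None for full-head
    sets, or the original node indices of an ROI-restricted view.
    """

    fields: dict
    reference_id: str
    mesh_fingerprint: str
    raw_currents_mA: dict = field(default_factory=dict)
    node_subset: np.ndarray = None

    @property
    def candidate_ids(self) -> list:
        return list(self.fields.keys())

    @property
    def n_nodes(self) -> int:
        return next(iter(self.fields.values())).shape[0]

    def __getitem__(self, eid: str) -> np.ndarray:
        try:
            return self.fields[eid]
        except KeyError:
            raise KeyError(
                f"no lead field for electrode {eid!r}; have {self.candidate_ids}"
            ) from None

    def restrict(self, node_indices) -> "LeadFieldSet":
        """ROI-restricted view so search loops touch only the nodes they score."""
        idx = np.asarray(node_indices, dtype=np.int64)
        return LeadFieldSet(
            fields={k: v[idx] for k, v in self.fields.items()},
            reference_id=self.reference_id,
            mesh_fingerprint=self.mesh_fingerprint,
            raw_currents_mA=dict(self.raw_currents_mA),
            node_subset=idx,
        )


def compute_leadfields(
    mesh: HeadMesh,
    electrodes: ElectrodeSet,
    tolerance: float = 1e-10,
    current_mA: float = 1.0,
) -> LeadFieldSet:
    """Solve every candidate against the reference and store 1 mA fields.

    Deterministic; a failure in any single solve aborts with the electrode id.
    """
    system = assemble_system(mesh)
    fp = mesh.fingerprint()
    fields, raw = {}, {}
    for k, cand in enumerate(electrodes.candidates):
        try:
            fdist, _, computed = solve_scaled_pair_field(
                system, cand, electrodes.reference, current_mA, tolerance
            )
        except BeatfieldError as exc:
            raise type(exc)(f"lead-field solve failed for electrode {cand.id!r}: {exc}") from exc
        fields[cand.id] = fdist.node_values
        raw[cand.id] = computed
        logger.info("lead field %d/%d (%s): raw current %.3f mA",
                    k + 1, len(electrodes.candidates), cand.id, computed)
    return LeadFieldSet(fields=fields, reference_id=electrodes.reference.id,
                        mesh_fingerprint=fp, raw_currents_mA=raw)


def montage_field(
    leadfields: LeadFieldSet, anode: str, cathode: str, current_mA: float = 1.0
) -> FieldDistribution:
    """Field of the (anode, cathode) pair carrying ``current_mA``.

    Superposition of the stored unit fields; the reference carries no net
    current because its two unit-solve contributions cancel.
    """
    if anode == cathode:
        raise ValidationError("anode and cathode must differ")
    vals = current_mA * (leadfields[anode] - leadfields[cathode])
    return FieldDistribution(
        node_values=vals,
        element_values=None,
        pair=(anode, cathode),
        current_mA=current_mA,
    )


def save_leadfields(leadfields: LeadFieldSet, path) -> None:
    """Write the set to an HDF5 container (datasets ``/leadfield/<id>``)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("leadfield")
        for eid, arr in leadfields.fields.items():
            d = grp.create_dataset(eid, data=np.asarray(arr, dtype=np.float64))
            d.attrs["raw_current_mA"] = leadfields.raw_currents_mA.get(eid, float("nan"))
        f.attrs["mesh_sha256"] = leadfields.mesh_fingerprint
        f.attrs["reference_id"] = leadfields.reference_id
        f.attrs["units"] = "V/m per mA"


def load_leadfields(path, mesh: HeadMesh = None) -> LeadFieldSet:
    """Load a saved set; verifies the mesh hash when a mesh is given."""
    with h5py.File(path, "r") as f:
        fp = f.attrs["mesh_sha256"]
        if mesh is not None and fp != mesh.fingerprint():
            raise FingerprintMismatchError(
                f"lead fields in {path} were computed on a different mesh "
                f"(stored hash {fp[:12]}..., mesh hash {mesh.fingerprint()[:12]}...)"
            )
        fields, raw = {}, {}
        for eid, d in f["leadfield"].items():
            fields[eid] = d[()]
            raw[eid] = float(d.attrs.get("raw_current_mA", float("nan")))
        return LeadFieldSet(
            fields=fields,
            reference_id=str(f.attrs["reference_id"]),
            mesh_fingerprint=str(fp),
            raw_currents_mA=raw,
        )
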