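"""Ligand-residue to transmembrane-helix contact mapping of docked poses.

A ligand residue contacts a helix when the minimum distance over all
atom/bead pairs between the residue and the helix's residues falls below a
cutoff.  Defaults: 0.45 nm for all-atom heavy-atom models, 0.8 nm for
one-bead-per-residue coarse models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .conformers import Conformer
from .exceptions import AnnotationError
from .screening import Receptor

__all__ = ["CUTOFF_ALL_ATOM_NM", "CUTOFF_COARSE_NM", "residue_helix_contacts",
           "contacts_to_frame"]

CUTOFF_ALL_ATOM_NM = 0.45
CUTOFF_COARSE_NM = 0.8


def residue_helix_contacts(ligand_pose: Conformer, receptor: Receptor,
                           cutoff: float = CUTOFF_COARSE_NM
                           ) -> dict[int, dict[int, float]]:
    """Map each ligand residue to the helices it contacts, with min distances.

    Returns ``{ligand_res_id: {helix_id: min_distance_nm}}`` keeping only
    helices whose minimum pair distance is strictly below ``cutoff``.
    Residues without any contact are omitted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not receptor.tmh_annotation:
        raise AnnotationError("receptor carries no helix annotation")
    rec = receptor.structure
    helix_masks = {}
    for hid, (s, e) in receptor.tmh_annotation.items():
        mask = (rec.res_ids >= s) & (rec.res_ids <= e)
        if not mask.any():
            raise AnnotationError(f"helix {hid} range {s}-{e} matches no receptor residue")
        helix_masks[hid] = mask
    contact_map: dict[int, dict[int, float]] = {}
    for res_id in np.unique(ligand_pose.res_ids):
        lig_coords = ligand_pose.coords[ligand_pose.res_ids == res_id]
        hits = {}
        for hid, mask in helix_masks.items():
            d = float(cdist(lig_coords, rec.coords[mask]).min())
            if d < cutoff:
                hits[hid] = d
        if hits:
            contact_map[int(res_id)] = hits
    return contact_map


def contacts_to_frame(contact_map: dict[int, dict[int, float]],
                      pose_id: int | None = None) -> pd.DataFrame:
    """Flatten a contact map to a tidy table (ligand_res, helix_id, min_dist_nm)."""
    rows = [
        {"ligand_res": res, "helix_id": hid, "min_dist_nm": d}
        for res, hits in sorted(contact_map.items())
        for hid, d in sorted(hits.items())
    ]
    df = pd.DataFrame(rows, columns=["ligand_res", "helix_id", "min_dist_nm"])
    if pose_id is not None:
        df["pose_id"] = pose_id
    return df
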