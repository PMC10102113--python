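"""Rule-based ablation lesion sets on the idealized left-atrial shell.

Five component lesions are supported: pulmonary vein isolation (PVI,
closed bands encircling each ostium), mitral isthmus line (MIL, annulus
to left inferior PV), anterior line (AL, annulus to roof), roof line
(RL, joining the superior PV ostia) and posterior box lesion (BL, the RL
plus an inferior posterior line closing the box, hence BL contains RL).
Lesion paths are great-circle geodesics between landmark directions on
the shell midsurface, dilated to the requested average width; all lesions
are transmural by construction (selection acts on whole transmural
columns).  Masks live on the EP mesh and are mapped to the mechanics mesh
by volume-majority vote over the nested refinement children.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (LabeledMesh, REGIONS, _LANDMARK_DIRS, _OSTIUM_ANGLE,
                   PV_NAMES, direction_of)

COMPONENT_LESIONS = ("PVI", "MIL", "AL", "RL", "BL")

#: the ten studied configurations
CASES = (
    "Control", "PVI", "PVI+BL", "PVI+AL", "PVI+AL+BL", "PVI+AL+RL",
    "PVI+MIL", "PVI+MIL+BL", "PVI+MIL+RL", "PVI+RL",
)

# geodesic endpoints (landmark directions) of the line lesions
_PATHS = {
    "MIL": ("lateral_annulus", "lipv"),
    "AL": ("anterior_annulus", "roof"),
    "RL": ("lspv", "rspv"),
    "_BL_BOTTOM": ("lipv", "ripv"),
}


@dataclass
class LesionSet:
    """A named ablation pattern realized as EP and mechanics element masks."""

    name: str
    component_lesions: tuple[str, ...]
    ep_mask: np.ndarray
    mech_mask: np.ndarray
    width: float = 5.0  # mm

    def ablated_volume(self, mesh: LabeledMesh) -> float:
        return float(np.abs(mesh.element_volumes())[self.mech_mask].sum())


def _column_directions(mesh: LabeledMesh) -> tuple[np.ndarray, np.ndarray]:
    """Mean unit direction per transmural column (and the column array)."""
    if mesh.column is None:
        raise ValueError("mesh has no transmural column bookkeeping")
    dirs = direction_of(mesh.centroids())
    ncol = mesh.column.max() + 1
    acc = np.zeros((ncol, 3))
    np.add.at(acc, mesh.column, dirs)
    acc /= np.linalg.norm(acc, axis=1, keepdims=True)
    return acc, mesh.column


def _arc_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angular distance of unit directions `p` to the geodesic segment a-b."""
    nrm = np.cross(a, b)
    nrm = nrm / np.linalg.norm(nrm)
    # distance to the full great circle
    d_circ = np.abs(np.arcsin(np.clip(p @ nrm, -1.0, 1.0)))
    # inside the segment? project onto the circle plane and check the wedge
    t = p - np.outer(p @ nrm, nrm)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    ang_ab = np.arccos(np.clip(a @ b, -1, 1))
    ang_a = np.arccos(np.clip(t @ a, -1, 1))
    ang_b = np.arccos(np.clip(t @ b, -1, 1))
    inside = np.abs(ang_a + ang_b - ang_ab) < 1e-6
    d_a = np.arccos(np.clip(p @ a, -1, 1))
    d_b = np.arccos(np.clip(p @ b, -1, 1))
    return np.where(inside, d_circ, np.minimum(d_a, d_b))


def _mean_radius(mesh: LabeledMesh) -> float:
    return float(np.linalg.norm(mesh.vertices, axis=1).mean())


def _resolution_estimate(mesh: LabeledMesh) -> float:
    vols = np.abs(mesh.element_volumes())
    return float((6.0 * np.median(vols)) ** (1.0 / 3.0))


def build_lesion(mesh: LabeledMesh, lesion: str, width: float = 5.0,
                 width_scale: dict[str, float] | None = None) -> np.ndarray:
    """Element mask of one component lesion on `mesh` (EP or mechanics).

    `width_scale` is the per-lesion calibration knob multiplying the
    nominal width.
    """
    if lesion not in COMPONENT_LESIONS:
        raise ValueError(f"unknown lesion {lesion!r}")
    if width <= 0:
        raise ValueError("lesion width must be positive")
    res = _resolution_estimate(mesh)
    if width < 0.8 * res:
        raise ValueError(f"width {width} mm below mesh resolution ~{res:.2f} mm")
    w = width * (width_scale or {}).get(lesion, 1.0)
    R = _mean_radius(mesh)
    half_ang = 0.5 * w / R

    col_dir, col = _column_directions(mesh)
    sel_cols = np.zeros(len(col_dir), dtype=bool)

    if lesion == "PVI":
        for name in PV_NAMES:
            c = _LANDMARK_DIRS[name]
            ang = np.arccos(np.clip(col_dir @ c, -1, 1))
            sel_cols |= (ang >= _OSTIUM_ANGLE - 1e-9) & \
                        (ang <= _OSTIUM_ANGLE + 2 * half_ang)
    elif lesion in ("MIL", "AL", "RL"):
        a, b = (_LANDMARK_DIRS[k] for k in _PATHS[lesion])
        sel_cols |= _arc_distance(col_dir, a, b) <= half_ang
    elif lesion == "BL":
        a, b = (_LANDMARK_DIRS[k] for k in _PATHS["RL"])
        sel_cols |= _arc_distance(col_dir, a, b) <= half_ang
        a, b = (_LANDMARK_DIRS[k] for k in _PATHS["_BL_BOTTOM"])
        sel_cols |= _arc_distance(col_dir, a, b) <= half_ang
    mask = sel_cols[col]
    if not mask.any():
        raise ValueError(f"lesion {lesion} produced an empty mask")
    return mask


def map_to_mech(ep_mask: np.ndarray, ep: LabeledMesh,
                mech: LabeledMesh) -> np.ndarray:
    """EP -> mechanics mask by volume-majority vote over refinement children."""
    if ep.ep_to_mech is None:
        raise ValueError("EP mesh lacks a parent map")
    vols = np.abs(ep.element_volumes())
    in_vol = np.zeros(mech.n_elements)
    tot_vol = np.zeros(mech.n_elements)
    np.add.at(in_vol, ep.ep_to_mech, vols * ep_mask)
    np.add.at(tot_vol, ep.ep_to_mech, vols)
    return in_vol > 0.5 * tot_vol


def combine(mesh: LabeledMesh, case_name: str, width: float = 5.0,
            width_scale: dict[str, float] | None = None) -> LesionSet:
    """Realize one of the ten studied cases on a shell with a nested EP mesh."""
    key = case_name.replace(" ", "")
    if key not in {c.replace(" ", "") for c in CASES}:
        raise ValueError(f"unknown case {case_name!r}")
    if mesh.ep is None:
        raise ValueError("mesh has no nested EP mesh")
    ep = mesh.ep
    components = tuple(p for p in key.split("+") if p != "Control")
    ep_mask = np.zeros(ep.n_elements, dtype=bool)
    for comp in components:
        ep_mask |= build_lesion(ep, comp, width, width_scale)
    mech_mask = map_to_mech(ep_mask, ep, mesh)
    return LesionSet(name=case_name, component_lesions=components,
                     ep_mask=ep_mask, mech_mask=mech_mask, width=width)


def ablated_fraction(mesh: LabeledMesh, lesions: LesionSet) -> float:
    """Percentage of LA myocardial volume covered by the lesion set."""
    vols = np.abs(mesh.element_volumes())
    myo = (mesh.region == REGIONS["LA"]) | (mesh.region == REGIONS["scar"])
    denom = vols[myo].sum()
    if denom == 0:
        raise ValueError("zero myocardial volume")
    return float(100.0 * vols[myo & lesions.mech_mask].sum() / denom)


def apply_to_mesh(mesh: LabeledMesh, lesions: LesionSet) -> LabeledMesh:
    """Tag lesioned elements as scar on both meshes (in place, returns mesh)."""
    mesh.region = mesh.region.copy()
    mesh.region[lesions.mech_mask] = REGIONS["scar"]
    if mesh.ep is not None:
        mesh.ep.region = mesh.ep.region.copy()
        mesh.ep.region[lesions.ep_mask] = REGIONS["scar"]
    return mesh


def is_transmural(mesh: LabeledMesh, mask: np.ndarray) -> bool:
    """True if the mask selects whole transmural columns only."""
    if mesh.column is None:
        return False
    for ci in np.unique(mesh.column[mask]):
        sel = mesh.column == ci
        if not mask[sel].all():
            return False
    return True


def pvi_rings_closed(mesh: LabeledMesh, mask: np.ndarray) -> bool:
    """Check each PV ostium is fully encircled: the band of masked columns
    around each ostium blocks every great-circle ray leaving the ostium."""
    col_dir, col = _column_directions(mesh)
    masked_cols = np.unique(col[mask])
    mdirs = col_dir[masked_cols]
    # a ray "hits" the band if it passes within one lattice spacing of a
    # masked column; the spacing is measured from the columns themselves
    gram = np.clip(mdirs @ mdirs.T, -1.0, 1.0)
    np.fill_diagonal(gram, -1.0)
    nn = np.arccos(gram.max(axis=1))
    tol = 1.2 * float(np.median(nn))
    for name in PV_NAMES:
        c = _LANDMARK_DIRS[name]
        # sweep rays in the tangent plane of the ostium center
        t1 = np.cross(c, [0.0, 0.0, 1.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(c, t1)
        for phi in np.linspace(0, 2 * np.pi, 72, endpoint=False):
            ray = np.cos(phi) * t1 + np.sin(phi) * t2
            # points along the outward geodesic from the ostium rim
            hit = False
            for ang in np.linspace(_OSTIUM_ANGLE, _OSTIUM_ANGLE + 0.35, 24):
                p = np.cos(ang) * c + np.sin(ang) * ray
                d = np.arccos(np.clip(mdirs @ p, -1, 1))
                if d.min() < tol:
                    hit = True
                    break
            if not hit:
                return False
    return True
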