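"""Bidirectional penalty contact between SPH particles and solid surfaces.

A point that penetrates a surface by depth delta receives the normal penalty
force F = kc * delta * n (n = outward-from-solid unit normal); the exact
negative is distributed to the surface element's nodes with the element's
linear interpolation weights at the contact point, so Newton's third law holds
to machine precision by construction.  The same machinery serves fluid-solid
coupling and (in the unprotected scenario) direct solid-solid node-to-surface
contact.

Surfaces are polylines of mesh boundary segments evaluated in the *deformed*
configuration.  Segment orientation convention: the outward normal is the
segment direction rotated -90 degrees, i.e. n = (t_y, -t_x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ContactSpec",
    "DeepPenetrationError",
    "segment_normals",
    "closest_on_segments",
    "contact_force",
    "surface_contact",
]


class DeepPenetrationError(RuntimeError):
    """Penetration exceeded the configured cap — kc/dt misconfiguration."""


@dataclass(frozen=True)
class ContactSpec:
    """Penalty-contact parameters for one particle-set/surface pairing.

    ``contact_stiffness`` has units N/m per metre of penetration in 2-D
    (force per unit depth).  ``engagement_offset`` is the contact radius of
    the query points: an SPH particle represents fluid out to half a lattice
    spacing from its centre, so the penalty engages once the centre comes
    within that distance of the surface (offset 0 for bare solid nodes).
    ``max_penetration`` aborts the run when exceeded.
    """

    contact_stiffness: float
    engagement_offset: float = 0.0
    max_penetration: float = np.inf

    def __post_init__(self) -> None:
        if self.contact_stiffness <= 0:
            raise ValueError("contact_stiffness must be > 0")


def segment_normals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unit outward normals for segments a->b (direction rotated -90 deg)."""
    t = b - a
    length = np.linalg.norm(t, axis=-1, keepdims=True)
    if np.any(length <= 0):
        raise ValueError("zero-length surface segment")
    t = t / length
    return np.stack([t[..., 1], -t[..., 0]], axis=-1)


def closest_on_segments(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                        k_candidates: int = 4):
    """Nearest surface segment per query point.

    Returns (segment index, closest point, barycentric weight of node b,
    distance).  Candidate segments are pre-selected with a k-d tree on segment
    midpoints, then resolved exactly by point-to-segment projection.
    """
    points = np.atleast_2d(points)
    ns = len(a)
    ab = b - a          # (ns, 2)
    ab2 = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
    if len(points) * ns <= 500_000:
        # small problem: exact dense scan beats building a tree
        pa = points[:, None, :] - a[None, :, :]          # (np, ns, 2)
        t = np.clip(np.einsum("psj,sj->ps", pa, ab) / ab2, 0.0, 1.0)
        closest = a[None] + t[..., None] * ab[None]
        diff = points[:, None, :] - closest
        d = np.sqrt(np.einsum("psj,psj->ps", diff, diff))
        best = np.argmin(d, axis=1)
        rows = np.arange(len(points))
        return best, closest[rows, best], t[rows, best], d[rows, best]
    k = min(k_candidates, ns)
    tree = cKDTree(0.5 * (a + b))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand.reshape(len(points), k))
    pa = points[:, None, :] - a[cand]            # (np, k, 2)
    t = np.einsum("pkj,pkj->pk", pa, ab[cand]) / ab2[cand]
    t = np.clip(t, 0.0, 1.0)
    closest = a[cand] + t[..., None] * ab[cand]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    best = np.argmin(d, axis=1)
    rows = np.arange(len(points))
    seg = cand[rows, best]
    return seg, closest[rows, best], t[rows, best], d[rows, best]


def candidate_segments(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                       k: int = 8) -> np.ndarray:
    """Indices of the k nearest segments (by midpoint) per query point.

    Used by the time loop to cache the contact search: particles move a tiny
    fraction of a segment length per step, so the candidate set stays valid
    for many steps between refreshes.
    """
    ns = len(a)
    k = min(k, ns)
    tree = cKDTree(0.5 * (a + b))
    _, cand = tree.query(points, k=k)
    return np.atleast_2d(cand.reshape(len(points), k))


def closest_on_candidates(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                          cand: np.ndarray):
    """Exact point-to-segment resolution restricted to cached candidates."""
    ab = b - a
    ab2 = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
    pa = points[:, None, :] - a[cand]
    t = np.clip(np.einsum("pkj,pkj->pk", pa, ab[cand]) / ab2[cand], 0.0, 1.0)
    closest = a[cand] + t[..., None] * ab[cand]
    diff = points[:, None, :] - closest
    d = np.sqrt(np.einsum("pkj,pkj->pk", diff, diff))
    best = np.argmin(d, axis=1)
    rows = np.arange(len(points))
    seg = cand[rows, best]
    return seg, closest[rows, best], t[rows, best], d[rows, best]


def contact_force(point: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray,
                  spec: ContactSpec):
    """Penalty force on a single point against one surface segment.

    Returns (force on the point, penetration depth, nodal reaction weights
    (w_a, w_b)).  Penetration is measured along the segment's outward normal;
    a point on the outward side gets zero force.
    """
    point = np.asarray(point, dtype=float)
    seg_a = np.asarray(seg_a, dtype=float)
    seg_b = np.asarray(seg_b, dtype=float)
    ab = seg_b - seg_a
    t = float(np.dot(point - seg_a, ab) / max(np.dot(ab, ab), 1e-300))
    t = min(max(t, 0.0), 1.0)
    closest = seg_a + t * ab
    n = segment_normals(seg_a[None], seg_b[None])[0]
    depth = max(0.0, spec.engagement_offset - float(np.dot(point - closest, n)))
    force = spec.contact_stiffness * depth * n
    return force, depth, (1.0 - t, t)


def surface_contact(points: np.ndarray, segments: np.ndarray,
                    node_positions: np.ndarray, spec: ContactSpec,
                    cand: np.ndarray = None):
    """Vectorised penalty contact of many points against one deformed surface.

    Parameters
    ----------
    points : (np, 2) query positions (fluid particles or opposing solid nodes).
    segments : (ns, 2) node-id pairs into ``node_positions``, oriented so the
        outward-from-solid normal is the direction rotated -90 degrees.
    node_positions : (n, 2) current (deformed) positions of the surface mesh.
    spec : penalty parameters.

    Returns
    -------
    point_forces : (np, 2) penalty force on each query point.
    nodal_forces : (n, 2) reaction forces scattered to the surface nodes
        (exact negative of the point forces by construction).
    max_depth : float, deepest penetration encountered.
    """
    nodal = np.zeros_like(node_positions)
    pf = np.zeros((len(points), 2))
    if len(points) == 0 or len(segments) == 0:
        return pf, nodal, 0.0
    a = node_positions[segments[:, 0]]
    b = node_positions[segments[:, 1]]
    if cand is not None:
        seg, closest, t, _ = closest_on_candidates(points, a, b, cand)
    else:
        seg, closest, t, _ = closest_on_segments(points, a, b)
    n = segment_normals(a[seg], b[seg])
    depth = spec.engagement_offset - np.einsum("ij,ij->i", points - closest, n)
    depth = np.maximum(depth, 0.0)
    max_depth = float(depth.max()) if len(depth) else 0.0
    if max_depth > spec.max_penetration:
        raise DeepPenetrationError(
            f"penetration {max_depth:.3e} m exceeds cap "
            f"{spec.max_penetration:.3e} m (check contact stiffness / dt)")
    hit = depth > 0.0
    if np.any(hit):
        f = (spec.contact_stiffness * depth[hit])[:, None] * n[hit]
        pf[hit] = f
        w_b = t[hit]
        np.add.at(nodal, segments[seg[hit], 0], -(1.0 - w_b)[:, None] * f)
        np.add.at(nodal, segments[seg[hit], 1], -w_b[:, None] * f)
    return pf, nodal, max_depth
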