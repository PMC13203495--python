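"""Parametric nested anatomy: concentric elliptical uterus / amniotic gap /
fetal body / skull / CSF gap / brain, with fluid particle fills and an
anatomical landmark registry.

The anatomy is a desk-scale stand-in that preserves the nested-layer topology
the analysis measures: a viscoelastic uterine wall annulus enclosing an
amniotic-fluid gap, a fetal-body annulus rigidly merged with an embedded skull
annulus, a cerebrospinal-fluid gap, and a soft brain.  All dimensions are
configurable; the defaults are placeholders of mid-gestation order, not
patient measurements.

Landmarks sit at fixed parametric angles on the fetal-body and brain surfaces
so that baseline gaps at the axis-aligned ones equal the configured gap widths
in closed form (concentric ellipses, vertex-nearest condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

from .coupling import closest_on_segments, segment_normals
from .solid import SolidMesh, ViscoelasticMaterial
from .sph import FluidMaterial, KernelSpec, ParticleSet

__all__ = [
    "GeometryError",
    "NestedModelConfig",
    "MaterialSet",
    "LandmarkRegistry",
    "NestedModel",
    "AnnularRegion",
    "ellipse_ring_mesh",
    "ellipse_disk_mesh",
    "seed_fluid_particles",
    "build_nested_model",
]

OUTER_LANDMARKS = ("FL", "OL", "P", "LB")
INNER_LANDMARKS = ("LFL", "RFL", "LOL", "ROL", "LH", "RH")

# parametric angles (rad) of landmark points on the fetal-body / brain surface
_OUTER_ANGLES = {"FL": 0.0, "OL": math.pi, "P": 3.0 * math.pi / 4.0,
                 "LB": -math.pi / 2.0}
_INNER_ANGLES = {"LFL": math.radians(25.0), "RFL": math.radians(-25.0),
                 "LOL": math.radians(155.0), "ROL": math.radians(-155.0),
                 "LH": math.pi / 2.0, "RH": -math.pi / 2.0}


class GeometryError(ValueError):
    """Configuration describes an infeasible nested geometry."""


@dataclass(frozen=True)
class NestedModelConfig:
    """Geometric configuration of the nested model (all lengths in metres).

    Semi-axes are (a, b) pairs; ``uterus_semi_axes`` is the *cavity* (inner
    wall surface), ``skull_semi_axes`` the outer skull surface.  The gap
    fields state the required minimum clearances and are validated against
    the semi-axes.  Defaults are documented placeholders: the anatomy is
    parametric, not patient-derived.
    """

    spatial_dimension: int = 2
    uterus_semi_axes: tuple = (0.110, 0.085)
    uterine_wall_thickness: float = 0.012
    amniotic_gap: float = 0.025
    fetal_body_semi_axes: tuple = (0.085, 0.060)
    skull_semi_axes: tuple = (0.052, 0.040)
    skull_thickness: float = 0.005
    csf_gap: float = 0.010
    brain_semi_axes: tuple = (0.037, 0.025)
    particle_spacing_amniotic: float = 0.005
    particle_spacing_csf: float = 0.0025
    mesh_edge_length: float = 0.006
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_dimension != 2:
            raise NotImplementedError(
                "only the 2-D plane-strain geometry generator is implemented")
        lengths = [*self.uterus_semi_axes, self.uterine_wall_thickness,
                   self.amniotic_gap, *self.fetal_body_semi_axes,
                   *self.skull_semi_axes, self.skull_thickness, self.csf_gap,
                   *self.brain_semi_axes, self.particle_spacing_amniotic,
                   self.particle_spacing_csf, self.mesh_edge_length]
        if any(v <= 0 for v in lengths):
            raise GeometryError("all lengths must be > 0")
        ua, ub = self.uterus_semi_axes
        fa, fb = self.fetal_body_semi_axes
        sa, sb = self.skull_semi_axes
        ba, bb = self.brain_semi_axes
        sia, sib = self.skull_inner_semi_axes
        tol = 1e-9
        if min(ua - fa, ub - fb) < self.amniotic_gap - tol:
            raise GeometryError(
                "amniotic gap violated: fetal body does not fit inside the "
                f"uterus with clearance {self.amniotic_gap} m")
        if sa >= fa or sb >= fb:
            raise GeometryError("skull does not fit inside the fetal body")
        if sia <= 0 or sib <= 0:
            raise GeometryError("skull thickness exceeds skull semi-axes")
        if min(sia - ba, sib - bb) < self.csf_gap - tol:
            raise GeometryError(
                "csf gap violated: brain does not fit inside the skull with "
                f"clearance {self.csf_gap} m")
        if self.particle_spacing_csf >= self.csf_gap:
            raise GeometryError("csf particle spacing must be < csf gap")
        if self.particle_spacing_amniotic >= self.amniotic_gap:
            raise GeometryError("amniotic particle spacing must be < amniotic gap")

    @property
    def skull_inner_semi_axes(self) -> tuple:
        return (self.skull_semi_axes[0] - self.skull_thickness,
                self.skull_semi_axes[1] - self.skull_thickness)

    @property
    def uterus_outer_semi_axes(self) -> tuple:
        return (self.uterus_semi_axes[0] + self.uterine_wall_thickness,
                self.uterus_semi_axes[1] + self.uterine_wall_thickness)


@dataclass(frozen=True)
class MaterialSet:
    """Per-component materials.  Solid moduli are documented placeholders:
    fetal brain roughly an order softer than adult-brain-order values, skull
    far softer than adult bone (incomplete ossification), both fluids
    water-like."""

    amniotic: FluidMaterial = field(
        default_factory=lambda: FluidMaterial(1000.0, 15.0, 1.0e-3))
    csf: FluidMaterial = field(
        default_factory=lambda: FluidMaterial(1000.0, 15.0, 1.0e-3))
    uterus: ViscoelasticMaterial = field(default_factory=lambda: ViscoelasticMaterial(
        long_term_shear_modulus=3.0e4, mode_moduli=(2.0e4,),
        relaxation_times=(0.2,), density=1050.0, bulk_modulus=2.0e5))
    fetal_body: ViscoelasticMaterial = field(default_factory=lambda: ViscoelasticMaterial(
        long_term_shear_modulus=1.0e4, mode_moduli=(5.0e3,),
        relaxation_times=(0.1,), density=1000.0, bulk_modulus=2.0e5))
    skull: ViscoelasticMaterial = field(default_factory=lambda: ViscoelasticMaterial(
        long_term_shear_modulus=3.0e5, mode_moduli=(),
        relaxation_times=(), density=1500.0, bulk_modulus=7.0e5))
    brain: ViscoelasticMaterial = field(default_factory=lambda: ViscoelasticMaterial(
        long_term_shear_modulus=8.0e2, mode_moduli=(6.0e2,),
        relaxation_times=(0.05,), density=1040.0, bulk_modulus=5.0e4))


@dataclass
class LandmarkRegistry:
    """Landmark points and opposing surfaces for the cushioning metrics.

    ``outer_pairs``: fetal-body surface landmarks tracked against the uterine
    cavity wall (4 by default).  ``inner_pairs``: brain surface landmarks
    tracked against the inner skull surface (6 by default).  Each entry maps
    landmark id -> (mesh name, node id, opposing mesh name, opposing surface).
    """

    outer_pairs: dict
    inner_pairs: dict
    baseline_distances: dict

    def __post_init__(self) -> None:
        for lm, d in self.baseline_distances.items():
            if d <= 0:
                raise GeometryError(f"baseline distance for {lm} must be > 0")

    @property
    def all_pairs(self) -> dict:
        return {**self.outer_pairs, **self.inner_pairs}

    def level(self, landmark: str) -> str:
        return "outer" if landmark in self.outer_pairs else "inner"


@dataclass
class NestedModel:
    """The assembled nested anatomy: four solid meshes, two fluid domains,
    the landmark registry, and the fetal-body/skull interface tie."""

    uterus: SolidMesh
    fetal_body: SolidMesh
    skull: SolidMesh
    brain: SolidMesh
    amniotic_fluid: ParticleSet
    csf: ParticleSet
    landmarks: LandmarkRegistry
    config: NestedModelConfig
    materials: MaterialSet
    # node-id arrays of equal length: fetal_body inner ring <-> skull outer ring
    tie_fetal_inner: np.ndarray = None
    tie_skull_outer: np.ndarray = None
    # brainstem anchor: brain boundary nodes paired with the nearest inner
    # skull nodes at the foramen-magnum region (inferior-posterior pole)
    tether_brain_nodes: np.ndarray = None
    tether_skull_nodes: np.ndarray = None

    @property
    def solids(self) -> dict:
        return {"uterus": self.uterus, "fetal_body": self.fetal_body,
                "skull": self.skull, "brain": self.brain}

    @property
    def fluids(self) -> dict:
        return {"amniotic": self.amniotic_fluid, "csf": self.csf}


def _ellipse_points(a: float, b: float, n_theta: int, phase: float = 0.0):
    phi = phase + 2.0 * np.pi * np.arange(n_theta) / n_theta
    return np.stack([a * np.cos(phi), b * np.sin(phi)], axis=1)


def _ring_count(a: float, b: float, edge: float) -> int:
    # Ramanujan perimeter approximation
    h = ((a - b) / (a + b)) ** 2
    per = math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))
    return max(12, int(round(per / edge)))


def ellipse_ring_mesh(inner_semi_axes, outer_semi_axes, n_theta: int,
                      n_radial: int, material: ViscoelasticMaterial,
                      name: str = "ring",
                      damping_coefficient: float = 0.0) -> SolidMesh:
    """Structured triangle mesh of an elliptical annulus.

    Rings share the parametric angle grid so radially adjacent nodes align.
    Boundary surfaces: ``inner`` (cavity-facing, normals toward the centre)
    and ``outer`` (normals away from the centre), both following the
    outward-from-solid orientation convention.
    """
    ai, bi = inner_semi_axes
    ao, bo = outer_semi_axes
    if ai >= ao or bi >= bo:
        raise GeometryError(f"{name}: inner semi-axes must be < outer")
    nodes = []
    for ir in range(n_radial + 1):
        f = ir / n_radial
        nodes.append(_ellipse_points(ai + (ao - ai) * f, bi + (bo - bi) * f, n_theta))
    nodes = np.concatenate(nodes, axis=0)

    tris = []
    for ir in range(n_radial):
        base0, base1 = ir * n_theta, (ir + 1) * n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            p00, p01 = base0 + k, base0 + k1
            p10, p11 = base1 + k, base1 + k1
            tris.append((p00, p11, p01))
            tris.append((p00, p10, p11))
    tris = np.asarray(tris, dtype=np.intp)

    ks = np.arange(n_theta)
    k1s = (ks + 1) % n_theta
    outer_base = n_radial * n_theta
    boundary = {
        # inner ring traversed clockwise so the outward-from-solid normal
        # points into the cavity
        "inner": np.stack([k1s, ks], axis=1),
        "outer": np.stack([outer_base + ks, outer_base + k1s], axis=1),
    }
    return SolidMesh(nodes=nodes, elements=tris, material=material,
                     boundary_segments=boundary, name=name,
                     damping_coefficient=damping_coefficient)


def ellipse_disk_mesh(semi_axes, edge: float, material: ViscoelasticMaterial,
                      name: str = "disk",
                      damping_coefficient: float = 0.0) -> SolidMesh:
    """Unstructured triangle mesh of a solid ellipse.

    Boundary ring at the target edge length plus an interior hexagonal
    lattice, Delaunay-triangulated (valid for the convex domain).  Surface
    ``outer`` has outward normals.
    """
    a, b = semi_axes
    n_theta = _ring_count(a, b, edge)
    ring = _ellipse_points(a, b, n_theta)
    margin = 0.75 * edge
    if a - margin <= 0 or b - margin <= 0:
        raise GeometryError(f"{name}: edge length too large for the ellipse")
    # hexagonal interior lattice clipped with a margin from the boundary
    dy = edge * math.sqrt(3.0) / 2.0
    ys = np.arange(-b, b + dy, dy)
    pts = []
    for row, y in enumerate(ys):
        xs = np.arange(-a, a + edge, edge) + (0.5 * edge if row % 2 else 0.0)
        pts.append(np.stack([xs, np.full_like(xs, y)], axis=1))
    interior = np.concatenate(pts, axis=0)
    keep = ((interior[:, 0] / (a - margin)) ** 2
            + (interior[:, 1] / (b - margin)) ** 2) <= 1.0
    nodes = np.concatenate([ring, interior[keep]], axis=0)
    tri = Delaunay(nodes)
    elements = tri.simplices.astype(np.intp)
    # enforce CCW orientation
    p = nodes[elements]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = area2 < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    ks = np.arange(n_theta)
    boundary = {"outer": np.stack([ks, (ks + 1) % n_theta], axis=1)}
    return SolidMesh(nodes=nodes, elements=elements, material=material,
                     boundary_segments=boundary, name=name,
                     damping_coefficient=damping_coefficient)


@dataclass(frozen=True)
class AnnularRegion:
    """Fluid region bounded by two solid surface polylines (deformed node
    positions + oriented segments, outward-from-solid normals)."""

    inner_positions: np.ndarray
    inner_segments: np.ndarray
    outer_positions: np.ndarray
    outer_segments: np.ndarray

    @classmethod
    def between(cls, inner_mesh: SolidMesh, inner_surface: str,
                outer_mesh: SolidMesh, outer_surface: str) -> "AnnularRegion":
        return cls(inner_mesh.nodes, inner_mesh.boundary_segments[inner_surface],
                   outer_mesh.nodes, outer_mesh.boundary_segments[outer_surface])


def _signed_clearance(points, positions, segments):
    """Signed distance of points from a surface along its outward normal
    (positive on the fluid side)."""
    a = positions[segments[:, 0]]
    b = positions[segments[:, 1]]
    seg, closest, _, _ = closest_on_segments(points, a, b)
    n = segment_normals(a[seg], b[seg])
    return np.einsum("ij,ij->i", points - closest, n)


def seed_fluid_particles(region: AnnularRegion, spacing: float,
                         material: FluidMaterial,
                         smoothing_ratio: float = 1.3,
                         clearance_factor: float = 0.5) -> ParticleSet:
    """Fill an annular region with fluid particles on a regular lattice.

    Particles keep a clearance of ``clearance_factor * spacing`` from both
    bounding surfaces so the initial state is penetration-free.  Mass per
    particle is rho0 * spacing^d; densities start at rho0, pressures at zero
    and velocities at rest (stress-free quiescent initial state).
    """
    if spacing <= 0:
        raise GeometryError("spacing must be > 0")
    lo = region.outer_positions.min(axis=0)
    hi = region.outer_positions.max(axis=0)
    nx = np.arange(lo[0] + 0.5 * spacing, hi[0], spacing)
    ny = np.arange(lo[1] + 0.5 * spacing, hi[1], spacing)
    xx, yy = np.meshgrid(nx, ny, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    clear = clearance_factor * spacing
    keep = (_signed_clearance(pts, region.inner_positions,
                              region.inner_segments) >= clear)
    pts = pts[keep]
    if len(pts):
        keep = (_signed_clearance(pts, region.outer_positions,
                                  region.outer_segments) >= clear)
        pts = pts[keep]
    if len(pts) == 0:
        raise GeometryError("empty fluid region: no lattice point fits with "
                            "the required clearance")
    n = len(pts)
    rho0 = material.reference_density
    kernel = KernelSpec(smoothing_length=smoothing_ratio * spacing, dimension=2)
    return ParticleSet(
        positions=pts,
        velocities=np.zeros((n, 2)),
        masses=np.full(n, rho0 * spacing**2),
        densities=np.full(n, rho0),
        pressures=np.zeros(n),
        material=material,
        kernel=kernel,
        spacing=spacing,
    )


def _nearest_boundary_node(mesh: SolidMesh, surface: str, point) -> int:
    ids = mesh.surface_nodes(surface)
    d = np.linalg.norm(mesh.nodes[ids] - np.asarray(point), axis=1)
    return int(ids[np.argmin(d)])


def _min_dist_to_surface(point, mesh: SolidMesh, surface: str) -> float:
    seg = mesh.boundary_segments[surface]
    a, b = mesh.nodes[seg[:, 0]], mesh.nodes[seg[:, 1]]
    _, _, _, d = closest_on_segments(np.atleast_2d(point), a, b,
                                     k_candidates=len(seg))
    return float(d[0])


def _empty_particles(material: FluidMaterial, spacing: float) -> ParticleSet:
    return ParticleSet(
        positions=np.zeros((0, 2)), velocities=np.zeros((0, 2)),
        masses=np.zeros(0), densities=np.zeros(0), pressures=np.zeros(0),
        material=material,
        kernel=KernelSpec(smoothing_length=1.3 * spacing, dimension=2),
        spacing=spacing)


def build_nested_model(config: NestedModelConfig,
                       materials: MaterialSet = None,
                       damping_coefficient: float = 2.0,
                       include_fluids: bool = True) -> NestedModel:
    """Build the full nested model in its stress-free quiescent initial state.

    The fetal-body annulus and the skull annulus share the interface angle
    grid so their interface nodes coincide; the returned tie arrays let the
    simulation assembler merge those degrees of freedom (the skull is rigidly
    embedded in the fetal body).  Deterministic for a fixed config.
    """
    if materials is None:
        materials = MaterialSet()
    cfg = config
    edge = cfg.mesh_edge_length

    n_theta_ut = _ring_count(*cfg.uterus_semi_axes, edge)
    n_r_ut = max(1, int(round(cfg.uterine_wall_thickness / edge)))
    uterus = ellipse_ring_mesh(cfg.uterus_semi_axes, cfg.uterus_outer_semi_axes,
                               n_theta_ut, n_r_ut, materials.uterus, "uterus",
                               damping_coefficient)

    n_theta_f = _ring_count(*cfg.skull_semi_axes, edge)
    thick_f = max(cfg.fetal_body_semi_axes[0] - cfg.skull_semi_axes[0],
                  cfg.fetal_body_semi_axes[1] - cfg.skull_semi_axes[1])
    n_r_f = max(1, int(round(thick_f / (1.5 * edge))))
    fetal = ellipse_ring_mesh(cfg.skull_semi_axes, cfg.fetal_body_semi_axes,
                              n_theta_f, n_r_f, materials.fetal_body,
                              "fetal_body", damping_coefficient)

    n_r_s = max(1, int(round(cfg.skull_thickness / edge)))
    skull = ellipse_ring_mesh(cfg.skull_inner_semi_axes, cfg.skull_semi_axes,
                              n_theta_f, n_r_s, materials.skull, "skull",
                              damping_coefficient)

    brain = ellipse_disk_mesh(cfg.brain_semi_axes, edge, materials.brain,
                              "brain", damping_coefficient)

    if include_fluids:
        amniotic = seed_fluid_particles(
            AnnularRegion.between(fetal, "outer", uterus, "inner"),
            cfg.particle_spacing_amniotic, materials.amniotic)
        csf = seed_fluid_particles(
            AnnularRegion.between(brain, "outer", skull, "inner"),
            cfg.particle_spacing_csf, materials.csf)
    else:
        amniotic = _empty_particles(materials.amniotic, cfg.particle_spacing_amniotic)
        csf = _empty_particles(materials.csf, cfg.particle_spacing_csf)

    # interface tie: fetal inner ring (ids 0..n_theta-1) <-> skull outer ring
    tie_fetal = np.arange(n_theta_f, dtype=np.intp)
    tie_skull = n_r_s * n_theta_f + np.arange(n_theta_f, dtype=np.intp)
    if not np.allclose(fetal.nodes[tie_fetal], skull.nodes[tie_skull]):
        raise GeometryError("fetal-body/skull interface nodes do not coincide")

    outer_pairs, inner_pairs, baselines = {}, {}, {}
    fa, fb = cfg.fetal_body_semi_axes
    for lm, ang in _OUTER_ANGLES.items():
        pt = (fa * math.cos(ang), fb * math.sin(ang))
        nid = _nearest_boundary_node(fetal, "outer", pt)
        outer_pairs[lm] = ("fetal_body", nid, "uterus", "inner")
        baselines[lm] = _min_dist_to_surface(fetal.nodes[nid], uterus, "inner")
    ba, bb = cfg.brain_semi_axes
    for lm, ang in _INNER_ANGLES.items():
        pt = (ba * math.cos(ang), bb * math.sin(ang))
        nid = _nearest_boundary_node(brain, "outer", pt)
        inner_pairs[lm] = ("brain", nid, "skull", "inner")
        baselines[lm] = _min_dist_to_surface(brain.nodes[nid], skull, "inner")

    landmarks = LandmarkRegistry(outer_pairs=outer_pairs,
                                 inner_pairs=inner_pairs,
                                 baseline_distances=baselines)

    # distributed brain-skull restraint (brainstem, dural septa, arachnoid
    # trabeculae): a submerged neutrally buoyant body has no static centring
    # or rotational stiffness in a closed fluid cavity under frictionless
    # normal contact, so like the anatomy the brain is elastically tied to
    # the skull all around its surface; the tangential arms of the web are
    # what restrain relative rotation, while CSF still carries the dynamic
    # normal load
    tether_brain = brain.surface_nodes("outer")
    skull_ring = skull.surface_nodes("inner")
    tether_skull = np.array([
        skull_ring[np.argmin(np.linalg.norm(
            skull.nodes[skull_ring] - brain.nodes[b], axis=1))]
        for b in tether_brain], dtype=np.intp)

    return NestedModel(uterus=uterus, fetal_body=fetal, skull=skull,
                       brain=brain, amniotic_fluid=amniotic, csf=csf,
                       landmarks=landmarks, config=cfg, materials=materials,
                       tie_fetal_inner=tie_fetal, tie_skull_outer=tie_skull,
                       tether_brain_nodes=tether_brain,
                       tether_skull_nodes=tether_skull)


def unprotected_config(config: NestedModelConfig,
                       clearance: float = 1.0e-3) -> NestedModelConfig:
    """Geometry for the unprotected counterfactual: both fluid gaps collapsed
    to a small clearance so motion transmits by direct penalty contact.

    The fetal body outer surface and the brain are unchanged; the uterine
    cavity shrinks onto the fetal body and the skull shrinks onto the brain,
    keeping the stressed component (the brain) identical across scenarios.
    """
    fa, fb = config.fetal_body_semi_axes
    ba, bb = config.brain_semi_axes
    return replace(
        config,
        uterus_semi_axes=(fa + clearance, fb + clearance),
        amniotic_gap=clearance * 0.999,
        skull_semi_axes=(ba + clearance + config.skull_thickness,
                         bb + clearance + config.skull_thickness),
        csf_gap=clearance * 0.999,
        particle_spacing_amniotic=clearance * 0.5,
        particle_spacing_csf=clearance * 0.5,
    )
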