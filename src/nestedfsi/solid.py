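"""Explicit transient dynamics of deformable solids with generalized-Maxwell
viscoelasticity.

Small-strain linear kinematics on linear triangles (2-D, plane strain) or
tetrahedra (3-D), lumped mass, mass-proportional damping and central-difference
time stepping:

    M u'' + C u' + f_int(u, history) = F_ext + F_FSI

The constitutive split is volumetric-elastic / deviatoric-viscoelastic: the
pressure responds with the bulk modulus K while the deviatoric stress carries
an equilibrium spring plus N Maxwell modes,

    G(t) = G_inf + sum_k G_k exp(-t / tau_k),

integrated with the standard midpoint exponential internal-variable recurrence
(exact for the exponential kernel within each step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViscoelasticMaterial",
    "SolidMesh",
    "SolidState",
    "StressState",
    "SolidInstabilityError",
    "relaxation_modulus",
    "update_viscoelastic_stress",
    "element_strains",
    "internal_force",
    "solid_step",
]


class SolidInstabilityError(RuntimeError):
    """Raised when the explicit integration produces non-finite state."""


@dataclass(frozen=True)
class ViscoelasticMaterial:
    """Generalized Maxwell solid: equilibrium shear spring G_inf, Maxwell
    modes (G_k, tau_k), linear-elastic bulk modulus, mass density."""

    long_term_shear_modulus: float       # G_inf, Pa
    mode_moduli: tuple = ()              # G_k, Pa
    relaxation_times: tuple = ()         # tau_k, s
    density: float = 1000.0              # kg/m^3
    bulk_modulus: float = 1.0e5          # K, Pa

    def __post_init__(self) -> None:
        if self.long_term_shear_modulus <= 0:
            raise ValueError("long_term_shear_modulus must be > 0")
        if len(self.mode_moduli) != len(self.relaxation_times):
            raise ValueError("mode_moduli and relaxation_times must be congruent")
        if any(g < 0 for g in self.mode_moduli):
            raise ValueError("mode_moduli must be >= 0")
        if any(t <= 0 for t in self.relaxation_times):
            raise ValueError("relaxation_times must be > 0")
        if self.density <= 0 or self.bulk_modulus <= 0:
            raise ValueError("density and bulk_modulus must be > 0")

    @property
    def instantaneous_shear_modulus(self) -> float:
        return self.long_term_shear_modulus + sum(self.mode_moduli)

    @property
    def dilatational_wave_speed(self) -> float:
        g = self.instantaneous_shear_modulus
        return np.sqrt((self.bulk_modulus + 4.0 * g / 3.0) / self.density)


def relaxation_modulus(t, material: ViscoelasticMaterial):
    """Shear relaxation modulus G(t) = G_inf + sum_k G_k exp(-t/tau_k)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    g = np.full_like(t, material.long_term_shear_modulus, dtype=float)
    for gk, tauk in zip(material.mode_moduli, material.relaxation_times):
        g = g + gk * np.exp(-t / tauk)
    return g


# Stress/strain carried as 4-component tensors [xx, yy, zz, xy] with TENSOR
# shear (e_xy, not the engineering gamma).  Plane strain fixes e_zz = 0 but
# sigma_zz is tracked so all three principal stresses are available.
_NCOMP = 4


@dataclass
class StressState:
    """Viscoelastic stress state with Maxwell internal variables.

    Arrays have shape (..., 4) in [xx, yy, zz, xy] order; the leading shape is
    arbitrary (a single point or a whole element array).
    """

    equilibrium: np.ndarray          # sigma_eq (volumetric + long-term dev)
    maxwell: np.ndarray              # (n_modes, ..., 4) per-mode dev stresses
    deviatoric_strain: np.ndarray    # previous deviatoric strain, (..., 4)

    @classmethod
    def zeros(cls, leading_shape, n_modes: int) -> "StressState":
        shape = tuple(np.atleast_1d(leading_shape)) + (_NCOMP,)
        return cls(
            equilibrium=np.zeros(shape),
            maxwell=np.zeros((n_modes,) + shape),
            deviatoric_strain=np.zeros(shape),
        )

    @property
    def total(self) -> np.ndarray:
        """sigma = sigma_eq + sum_k sigma_k."""
        return self.equilibrium + self.maxwell.sum(axis=0)


def _deviatoric(strain: np.ndarray) -> np.ndarray:
    tr = strain[..., 0] + strain[..., 1] + strain[..., 2]
    dev = strain.copy()
    dev[..., :3] -= (tr / 3.0)[..., None]
    return dev


def update_viscoelastic_stress(strain: np.ndarray, dt: float,
                               state: StressState,
                               material: ViscoelasticMaterial) -> StressState:
    """Advance the generalized-Maxwell stress one step.

    ``strain`` is the current total small-strain tensor (..., 4).  The
    equilibrium part responds elastically to the total strain (bulk + G_inf
    deviatoric); each Maxwell mode follows the exponential recurrence

        s_k^{n+1} = exp(-dt/tau_k) s_k^n + 2 G_k exp(-dt/(2 tau_k)) d(e_dev),

    which converges to the hereditary integral of G(t) as dt -> 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    strain = np.asarray(strain, dtype=float)
    tr = strain[..., 0] + strain[..., 1] + strain[..., 2]
    dev = _deviatoric(strain)
    d_dev = dev - state.deviatoric_strain

    eq = 2.0 * material.long_term_shear_modulus * dev
    eq[..., :3] += (material.bulk_modulus * tr)[..., None]

    maxwell = np.empty_like(state.maxwell)
    for k, (gk, tauk) in enumerate(
            zip(material.mode_moduli, material.relaxation_times)):
        decay = np.exp(-dt / tauk)
        maxwell[k] = decay * state.maxwell[k] + \
            2.0 * gk * np.exp(-dt / (2.0 * tauk)) * d_dev

    return StressState(equilibrium=eq, maxwell=maxwell, deviatoric_strain=dev)


@dataclass
class SolidMesh:
    """Linear-triangle mesh of one deformable component (2-D plane strain).

    ``boundary_segments`` maps a surface name to an (s, 2) array of node-id
    pairs ordered so the outward-from-solid normal is the edge direction
    rotated -90 degrees.  ``fixed`` and ``prescribed`` are per-node masks;
    prescribed nodes are driven kinematically by the caller.
    """

    nodes: np.ndarray                 # (n, 2) reference positions
    elements: np.ndarray              # (m, 3) connectivity, CCW
    material: ViscoelasticMaterial
    boundary_segments: dict = field(default_factory=dict)
    fixed: np.ndarray = None          # (n,) bool
    prescribed: np.ndarray = None     # (n,) bool
    damping_coefficient: float = 0.0  # mass-proportional Rayleigh c, 1/s
    name: str = "solid"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.intp)
        n = len(self.nodes)
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        if self.prescribed is None:
            self.prescribed = np.zeros(n, dtype=bool)
        self._precompute()

    def _precompute(self) -> None:
        tri = self.nodes[self.elements]  # (m, 3, 2)
        x, y = tri[..., 0], tri[..., 1]
        # signed areas; CCW orientation required
        self.areas = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                            - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
        bad = np.nonzero(self.areas <= 0.0)[0]
        if len(bad):
            raise ValueError(
                f"mesh '{self.name}': element {bad[0]} is degenerate or "
                f"negatively oriented (signed area {self.areas[bad[0]]:.3e})")
        # shape-function gradients: b_i = y_j - y_k, c_i = x_k - x_j
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        self.dNdx = b / (2.0 * self.areas[:, None])   # (m, 3)
        self.dNdy = c / (2.0 * self.areas[:, None])
        # lumped nodal masses: rho * A / 3 to each vertex
        self.node_mass = np.zeros(len(self.nodes))
        np.add.at(self.node_mass, self.elements.ravel(),
                  np.repeat(self.material.density * self.areas / 3.0, 3))
        if np.any(self.node_mass[np.unique(self.elements)] <= 0):
            raise ValueError(f"mesh '{self.name}': non-positive lumped mass")
        edges = np.concatenate([
            tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]])
        self.min_edge = float(np.min(np.linalg.norm(edges, axis=1)))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def stable_dt(self) -> float:
        """Element CFL limit: min edge / dilatational wave speed."""
        return self.min_edge / self.material.dilatational_wave_speed

    def surface_nodes(self, surface: str) -> np.ndarray:
        return np.unique(self.boundary_segments[surface])


@dataclass
class SolidState:
    """Kinematic + constitutive state of one SolidMesh."""

    displacements: np.ndarray     # u, (n, 2)
    velocities: np.ndarray        # u', (n, 2)
    accelerations: np.ndarray     # u'', (n, 2)
    f_external: np.ndarray        # (n, 2)
    f_fsi: np.ndarray             # (n, 2)
    stress: StressState           # per-element, (m, 4) arrays

    @classmethod
    def zeros(cls, mesh: SolidMesh) -> "SolidState":
        n = mesh.n_nodes
        return cls(
            displacements=np.zeros((n, 2)),
            velocities=np.zeros((n, 2)),
            accelerations=np.zeros((n, 2)),
            f_external=np.zeros((n, 2)),
            f_fsi=np.zeros((n, 2)),
            stress=StressState.zeros(mesh.n_elements,
                                     len(mesh.material.mode_moduli)),
        )


def element_strains(mesh: SolidMesh, displacements: np.ndarray) -> np.ndarray:
    """Small-strain tensor per element, (m, 4) in [xx, yy, zz, xy]; plane
    strain (e_zz = 0), tensor shear e_xy."""
    u = displacements[mesh.elements]          # (m, 3, 2)
    exx = np.einsum("mi,mi->m", mesh.dNdx, u[..., 0])
    eyy = np.einsum("mi,mi->m", mesh.dNdy, u[..., 1])
    gxy = np.einsum("mi,mi->m", mesh.dNdy, u[..., 0]) + \
        np.einsum("mi,mi->m", mesh.dNdx, u[..., 1])
    out = np.zeros((mesh.n_elements, _NCOMP))
    out[:, 0], out[:, 1], out[:, 3] = exx, eyy, 0.5 * gxy
    return out


def _assemble(mesh: SolidMesh, stress: np.ndarray) -> np.ndarray:
    """Nodal internal forces from element stresses: f = sum_e A_e B^T sigma."""
    sxx, syy, sxy = stress[:, 0], stress[:, 1], stress[:, 3]
    a = mesh.areas[:, None]
    fx = a * (mesh.dNdx * sxx[:, None] + mesh.dNdy * sxy[:, None])  # (m, 3)
    fy = a * (mesh.dNdy * syy[:, None] + mesh.dNdx * sxy[:, None])
    f = np.empty((mesh.n_nodes, 2))
    idx = mesh.elements.ravel()
    f[:, 0] = np.bincount(idx, weights=fx.ravel(), minlength=mesh.n_nodes)
    f[:, 1] = np.bincount(idx, weights=fy.ravel(), minlength=mesh.n_nodes)
    return f


def internal_force(mesh: SolidMesh, state: SolidState,
                   stress: np.ndarray = None) -> np.ndarray:
    """Assembled nodal internal forces.

    With ``stress`` omitted the equilibrium (long-term) elastic stress for the
    current displacement field is used — the quasi-static stiffness action.
    During time stepping the caller passes the viscoelastically updated total
    stress instead.
    """
    if stress is None:
        eps = element_strains(mesh, state.displacements)
        tr = eps[:, 0] + eps[:, 1] + eps[:, 2]
        dev = _deviatoric(eps)
        stress = 2.0 * mesh.material.long_term_shear_modulus * dev
        stress[:, :3] += (mesh.material.bulk_modulus * tr)[:, None]
    return _assemble(mesh, stress)


def solid_step(mesh: SolidMesh, state: SolidState, dt: float,
               check_finite: bool = True, step: int = -1) -> SolidState:
    """One central-difference step (semi-implicit Euler: kick then drift).

    Updates the viscoelastic stress from the current displacement field,
    assembles internal forces, applies mass-proportional damping and advances
    free nodes.  Fixed nodes do not move; prescribed nodes are expected to be
    overwritten by the caller's trajectory after the step.
    """
    eps = element_strains(mesh, state.displacements)
    state.stress = update_viscoelastic_stress(eps, dt, state.stress, mesh.material)
    f_int = _assemble(mesh, state.stress.total)
    m = mesh.node_mass[:, None]
    f_damp = mesh.damping_coefficient * m * state.velocities
    acc = np.zeros_like(state.displacements)
    active = mesh.node_mass > 0
    acc[active] = ((state.f_external + state.f_fsi - f_int - f_damp)[active]
                   / m[active])
    hold = mesh.fixed | mesh.prescribed
    acc[hold] = 0.0
    state.accelerations = acc
    state.velocities = state.velocities + dt * acc
    state.velocities[mesh.fixed] = 0.0
    state.displacements = state.displacements + dt * state.velocities
    if check_finite and not np.all(np.isfinite(state.displacements)):
        raise SolidInstabilityError(
            f"mesh '{mesh.name}': non-finite displacement at step {step}")
    return state
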