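"""Weakly compressible smoothed particle hydrodynamics (WCSPH) core.

Field values are kernel-weighted sums over neighbouring particles,

    A(r) = sum_j (m_j / rho_j) A_j W(|r - r_j|, h),

with density evolved through the SPH continuity equation, pressure closed by
the linear equation of state p = c0^2 (rho - rho0), and momentum driven by the
symmetric pressure-gradient form with Monaghan artificial viscosity.  The
formulation is dimension-agnostic (2-D plane-strain by default, 3-D optional);
in 2-D all extensive quantities are per unit out-of-plane depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FluidMaterial",
    "KernelSpec",
    "SPHParams",
    "ParticleSet",
    "kernel_value",
    "kernel_gradient_magnitude",
    "neighbor_pairs",
    "interpolate",
    "continuity_rate",
    "eos_pressure",
    "momentum_rate",
    "fluid_step",
    "shepard_density",
]

# Cubic-spline normalisation constants sigma_d / h^d for d = 1, 2, 3
_SIGMA = {1: 2.0 / 3.0, 2: 10.0 / (7.0 * np.pi), 3: 1.0 / np.pi}


@dataclass(frozen=True)
class FluidMaterial:
    """Weakly compressible fluid parameters.

    ``sound_speed`` is a numerical sound speed chosen >= 10x the fastest
    expected material velocity (weak-compressibility rule), not the physical
    acoustic speed.  ``dynamic_viscosity`` is recorded for reporting; momentum
    dissipation is carried by the artificial-viscosity term.
    """

    reference_density: float  # rho0, kg/m^3
    sound_speed: float        # c0, m/s
    dynamic_viscosity: float = 1.0e-3  # mu, Pa s

    def __post_init__(self) -> None:
        if self.reference_density <= 0:
            raise ValueError("reference_density must be > 0")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be > 0")
        if self.dynamic_viscosity < 0:
            raise ValueError("dynamic_viscosity must be >= 0")


@dataclass(frozen=True)
class KernelSpec:
    """Cubic B-spline smoothing kernel with compact support 2h."""

    smoothing_length: float  # h, m
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.smoothing_length <= 0:
            raise ValueError("smoothing_length must be > 0")
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2 or 3")

    @property
    def support_radius(self) -> float:
        return 2.0 * self.smoothing_length


@dataclass(frozen=True)
class SPHParams:
    """Global SPH parameters: artificial viscosity, gravity, regularisation."""

    alpha: float = 1.0          # linear artificial-viscosity coefficient
    beta: float = 2.0           # quadratic artificial-viscosity coefficient
    gravity: tuple = (0.0, 0.0)
    epsilon: float = 0.01       # denominator regulariser in Pi_ij

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("artificial-viscosity coefficients must be >= 0")


@dataclass
class ParticleSet:
    """State of one SPH fluid domain.

    Arrays are congruent along the particle axis: positions/velocities are
    (n, d); masses, densities and pressures are (n,).
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    densities: np.ndarray
    pressures: np.ndarray
    material: FluidMaterial
    kernel: KernelSpec
    spacing: float = 0.0  # initial lattice spacing, informational

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("velocities", "masses", "densities", "pressures"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n}")
        if n and np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")
        if n and np.any(self.densities <= 0):
            raise ValueError("densities must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "ParticleSet":
        return ParticleSet(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            self.densities.copy(), self.pressures.copy(),
            self.material, self.kernel, self.spacing,
        )


def kernel_value(separation, spec: KernelSpec):
    """Cubic-spline kernel W(|r|, h); zero at and beyond the 2h support."""
    q = np.asarray(separation, dtype=float) / spec.smoothing_length
    if np.any(q < 0):
        raise ValueError("separation must be >= 0")
    sigma = _SIGMA[spec.dimension] / spec.smoothing_length**spec.dimension
    w = np.where(
        q < 1.0,
        1.0 - 1.5 * q**2 + 0.75 * q**3,
        np.where(q < 2.0, 0.25 * (2.0 - q) ** 3, 0.0),
    )
    return sigma * w


def kernel_gradient_magnitude(separation, spec: KernelSpec):
    """dW/dr for the cubic spline (<= 0 everywhere inside the support)."""
    q = np.asarray(separation, dtype=float) / spec.smoothing_length
    sigma = _SIGMA[spec.dimension] / spec.smoothing_length**spec.dimension
    dw = np.where(
        q < 1.0,
        -3.0 * q + 2.25 * q**2,
        np.where(q < 2.0, -0.75 * (2.0 - q) ** 2, 0.0),
    )
    return sigma * dw / spec.smoothing_length


def neighbor_pairs(particles: ParticleSet) -> np.ndarray:
    """Unique interacting pairs (i < j) within the kernel support.

    Uses a k-d tree on current positions; rebuilt each call so the list is
    always current for the configuration passed in.
    """
    if len(particles) < 2:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(particles.positions)
    pairs = tree.query_pairs(particles.kernel.support_radius, output_type="ndarray")
    return pairs


def _pair_geometry(particles: ParticleSet, pairs: np.ndarray):
    """Separation vectors, distances and kernel gradient vectors per pair."""
    i, j = pairs[:, 0], pairs[:, 1]
    rij = particles.positions[i] - particles.positions[j]
    dist = np.sqrt(np.einsum("ij,ij->i", rij, rij))
    dist = np.maximum(dist, 1e-300)  # coincident particles contribute nothing
    dwdr = kernel_gradient_magnitude(dist, particles.kernel)
    grad = (dwdr / dist)[:, None] * rij  # grad_i W_ij
    return i, j, rij, dist, grad


def interpolate(values: np.ndarray, query: np.ndarray,
                particles: ParticleSet, shepard: bool = False):
    """SPH interpolation of per-particle ``values`` at ``query`` points.

    Returns ``(estimate, has_support)``.  Where no particle lies within the
    kernel support the estimate is 0 and ``has_support`` is False.  With
    ``shepard=True`` the raw sum is divided by the partition-of-unity sum,
    which reproduces constants exactly on any particle distribution.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    values = np.asarray(values, dtype=float)
    tree = cKDTree(particles.positions)
    neighbors = tree.query_ball_point(query, particles.kernel.support_radius)
    out = np.zeros(len(query))
    flag = np.zeros(len(query), dtype=bool)
    vol = particles.masses / particles.densities
    for k, idx in enumerate(neighbors):
        if not idx:
            continue
        idx = np.asarray(idx, dtype=np.intp)
        d = np.linalg.norm(particles.positions[idx] - query[k], axis=1)
        w = kernel_value(d, particles.kernel)
        denom = np.sum(vol[idx] * w)
        if denom <= 0.0:
            continue
        flag[k] = True
        s = np.sum(vol[idx] * values[idx] * w)
        out[k] = s / denom if shepard else s
    return out, flag


def continuity_rate(particles: ParticleSet, pairs: np.ndarray) -> np.ndarray:
    """Density rate D(rho_i)/Dt = sum_j m_j (v_i - v_j) . grad_i W_ij."""
    drho = np.zeros(len(particles))
    if len(pairs) == 0:
        return drho
    i, j, _, _, grad = _pair_geometry(particles, pairs)
    vij = particles.velocities[i] - particles.velocities[j]
    proj = np.einsum("ij,ij->i", vij, grad)
    np.add.at(drho, i, particles.masses[j] * proj)
    np.add.at(drho, j, particles.masses[i] * proj)
    return drho


def eos_pressure(density, material: FluidMaterial):
    """Linear weakly compressible equation of state p = c0^2 (rho - rho0)."""
    density = np.asarray(density, dtype=float)
    if np.any(density <= 0):
        raise ValueError("density must be > 0")
    return material.sound_speed**2 * (density - material.reference_density)


def momentum_rate(particles: ParticleSet, params: SPHParams,
                  pairs: np.ndarray) -> np.ndarray:
    """Acceleration from the symmetric pressure gradient, Monaghan artificial
    viscosity (active only for approaching pairs) and gravity."""
    d = particles.dimension
    acc = np.zeros((len(particles), d))
    g = np.asarray(params.gravity, dtype=float)[:d]
    if len(pairs):
        i, j, rij, dist, grad = _pair_geometry(particles, pairs)
        rho_i, rho_j = particles.densities[i], particles.densities[j]
        term = (particles.pressures[i] / rho_i**2
                + particles.pressures[j] / rho_j**2)
        vij = particles.velocities[i] - particles.velocities[j]
        vdotr = np.einsum("ij,ij->i", vij, rij)
        if params.alpha > 0.0 or params.beta > 0.0:
            h = particles.kernel.smoothing_length
            approaching = vdotr < 0.0
            mu = h * vdotr / (dist**2 + params.epsilon * h**2)
            mu = np.where(approaching, mu, 0.0)
            cbar = particles.material.sound_speed
            rho_bar = 0.5 * (rho_i + rho_j)
            term = term + (-params.alpha * cbar * mu + params.beta * mu**2) / rho_bar
        contrib = term[:, None] * grad
        np.add.at(acc, i, -particles.masses[j][:, None] * contrib)
        np.add.at(acc, j, particles.masses[i][:, None] * contrib)
    return acc + g


def fluid_step(particles: ParticleSet, params: SPHParams, dt: float,
               external_accel: np.ndarray = None,
               reinit_density: bool = False) -> None:
    """Advance one WCSPH step in place, kick -> density -> drift order:

      1. accelerations from the momentum equation (+ external, e.g. contact)
      2. velocity kick
      3. continuity with the *kicked* velocities, then EOS pressures
      4. position drift

    Updating density from the post-kick velocities makes the acoustic
    density-velocity coupling semi-implicit, which keeps short-wavelength
    lattice modes neutrally stable where the fully explicit ordering slowly
    amplifies them.
    """
    n = len(particles)
    if n == 0:
        return
    d = particles.dimension
    g = np.asarray(params.gravity, dtype=float)[:d]
    pairs = neighbor_pairs(particles)
    acc = np.tile(g, (n, 1))
    if len(pairs):
        i, j, rij, dist, grad = _pair_geometry(particles, pairs)
        mi, mj = particles.masses[i], particles.masses[j]
        rho_i, rho_j = particles.densities[i], particles.densities[j]
        term = (particles.pressures[i] / rho_i**2
                + particles.pressures[j] / rho_j**2)
        if params.alpha > 0.0 or params.beta > 0.0:
            vij = particles.velocities[i] - particles.velocities[j]
            vdotr = np.einsum("ij,ij->i", vij, rij)
            h = particles.kernel.smoothing_length
            mu = np.where(vdotr < 0.0,
                          h * vdotr / (dist**2 + params.epsilon * h**2), 0.0)
            term = term + ((-params.alpha * particles.material.sound_speed * mu
                            + params.beta * mu**2) / (0.5 * (rho_i + rho_j)))
        for c in range(d):
            fc = term * grad[:, c]
            acc[:, c] -= np.bincount(i, weights=mj * fc, minlength=n)
            acc[:, c] += np.bincount(j, weights=mi * fc, minlength=n)
    if external_accel is not None:
        acc = acc + external_accel
    particles.velocities = particles.velocities + dt * acc
    if len(pairs):
        vij = particles.velocities[i] - particles.velocities[j]
        proj = np.einsum("ij,ij->i", vij, grad)
        drho = np.bincount(i, weights=mj * proj, minlength=n) \
            + np.bincount(j, weights=mi * proj, minlength=n)
        particles.densities = particles.densities + dt * drho
    if reinit_density:
        particles.densities = shepard_density(particles, pairs)
    particles.pressures = eos_pressure(particles.densities, particles.material)
    particles.positions = particles.positions + dt * particles.velocities


def shepard_density(particles: ParticleSet, pairs: np.ndarray = None) -> np.ndarray:
    """Shepard-normalised density summation (includes the self term).

    rho_i = sum_j m_j W_ij / sum_j (m_j / rho_j) W_ij.  Used periodically to
    re-anchor the integrated density field; the normalisation removes the
    free-surface/boundary kernel-deficiency bias of the plain summation.
    """
    if pairs is None:
        pairs = neighbor_pairs(particles)
    w0 = kernel_value(0.0, particles.kernel)
    num = particles.masses * w0
    den = particles.masses / particles.densities * w0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dist = np.linalg.norm(particles.positions[i] - particles.positions[j], axis=1)
        w = kernel_value(dist, particles.kernel)
        np.add.at(num, i, particles.masses[j] * w)
        np.add.at(num, j, particles.masses[i] * w)
        np.add.at(den, i, particles.masses[j] / particles.densities[j] * w)
        np.add.at(den, j, particles.masses[i] / particles.densities[i] * w)
    return num / den
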