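"""Simulation driver: scenario assembly, time-step control, the coupled
SPH-FEM time loop, metrics sampling and output.

Each step advances, in order: prescribed uterine-wall motion, penalty-contact
force exchange (fluid <-> solid, or solid <-> solid in the unprotected
scenario), both SPH domains (continuity -> equation of state -> momentum,
kick-drift), and all solid bodies (viscoelastic stress update -> internal
forces -> central-difference update), with the fetal-body/skull interface
nodes merged into shared degrees of freedom.  Landmark separations and brain
stress invariants are sampled at a fixed output cadence.

Scenarios
---------
``nested``     the full protected configuration with both fluid layers.
``no_fluids``  the unprotected counterfactual: fluids removed and both
               protective gaps collapsed to a small clearance so uterine-wall
               motion reaches the fetal body, and skull motion the brain,
               through direct penalty contact.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupling import ContactSpec, candidate_segments, surface_contact
from .geometry import (MaterialSet, NestedModel, NestedModelConfig,
                       build_nested_model, unprotected_config)
from .kinematics import (KinematicsTrace, SeizureParams, generate_seizure_roll,
                         prescribe_uterine_motion)
from .metrics import (DistanceSeries, mean_abs_deviation, min_distance,
                      principal_stresses, von_mises)
from .solid import (SolidInstabilityError, SolidState, element_strains,
                    internal_force, update_viscoelastic_stress)
from .sph import SPHParams, fluid_step
from .vtkio import write_model, write_point_cloud, write_unstructured_grid

__all__ = [
    "SimulationConfig",
    "RunResult",
    "stable_timestep",
    "run_simulation",
    "run_comparison",
    "simulate_hydrostatic_column",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Aggregated inputs for one simulation run."""

    model: NestedModelConfig = field(default_factory=NestedModelConfig)
    materials: MaterialSet = field(default_factory=MaterialSet)
    seizure: SeizureParams = field(default_factory=SeizureParams)
    sph: SPHParams = field(default_factory=SPHParams)
    contact_stiffness_fluid: float = 1.0e5    # N/m per m penetration (2-D)
    contact_stiffness_solid: float = 1.0e6
    total_time: float = 6.0                   # s (>= 3 cycles at 0.5 Hz)
    output_interval: float = 0.005            # s
    cfl: float = 0.4
    scenario: str = "nested"                  # "nested" | "no_fluids"
    seed: int = 0
    shepard_interval: int = 30                # density reinitialisation cadence
    max_penetration: float = 0.02             # abort threshold, m
    damping_coefficient: float = 0.5          # mass-proportional, 1/s
    tether_stiffness: float = 1.2e4           # brain-skull web, N/m per m
    tether_damping: float = 250.0             # brain-skull web, N s/m per m
    check_balance: bool = False               # assert global force balance
    snapshot_interval: float = 0.0            # s; 0 disables VTK snapshots

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if not 0.0 < self.cfl <= 1.0:
            raise ValueError("cfl must lie in (0, 1]")
        if self.scenario not in ("nested", "no_fluids"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_to_plain(dataclasses.asdict(self)), f,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        from .geometry import MaterialSet as MS
        from .sph import FluidMaterial
        from .solid import ViscoelasticMaterial
        kwargs = dict(raw)
        if "model" in kwargs:
            kwargs["model"] = NestedModelConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in kwargs["model"].items()})
        if "materials" in kwargs:
            mats = {}
            for name, m in kwargs["materials"].items():
                m = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in m.items()}
                mats[name] = (FluidMaterial(**m) if "reference_density" in m
                              else ViscoelasticMaterial(**m))
            kwargs["materials"] = MS(**mats)
        if "seizure" in kwargs:
            kwargs["seizure"] = SeizureParams(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in kwargs["seizure"].items()})
        if "sph" in kwargs:
            s = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in kwargs["sph"].items()}
            kwargs["sph"] = SPHParams(**s)
        return cls(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def stable_timestep(model: NestedModel, config: SimulationConfig) -> float:
    """dt = CFL factor x min(fluid acoustic limits h/c0, solid element
    limits, penalty-contact oscillator limits)."""
    limits = {}
    for name, ps in model.fluids.items():
        if len(ps):
            limits[f"fluid:{name}"] = (ps.kernel.smoothing_length
                                       / ps.material.sound_speed)
            m_min = float(ps.masses.min())
            limits[f"contact:{name}"] = 2.0 * np.sqrt(
                m_min / config.contact_stiffness_fluid)
    for name, mesh in model.solids.items():
        limits[f"solid:{name}"] = mesh.stable_dt()
    if config.scenario == "no_fluids":
        m_min = min(float(mesh.node_mass[mesh.node_mass > 0].min())
                    for mesh in model.solids.values())
        limits["contact:solid"] = 2.0 * np.sqrt(
            m_min / config.contact_stiffness_solid)
    bad = [k for k, v in limits.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive stability limit for {bad[0]}")
    return config.cfl * min(limits.values())


@dataclass
class RunResult:
    """Time series and summaries of one run."""

    config: SimulationConfig
    dt: float
    n_steps: int
    times: np.ndarray
    distances: dict               # landmark -> DistanceSeries
    brain_max_vm: np.ndarray      # Pa, per output step
    brain_principals_at_max: np.ndarray   # (n_out, 3) Pa
    rel_disp_brain_skull: np.ndarray      # m
    seizure_realized: dict
    wall_clock_s: float
    particle_counts: dict

    @property
    def inner_mad(self) -> float:
        return mean_abs_deviation(
            [s for s in self.distances.values() if s.level == "inner"])

    @property
    def outer_mad(self) -> float:
        return mean_abs_deviation(
            [s for s in self.distances.values() if s.level == "outer"])

    @property
    def peak_brain_vm(self) -> float:
        return float(self.brain_max_vm.max())

    @property
    def peak_rel_disp(self) -> float:
        return float(self.rel_disp_brain_skull.max())

    def summary(self) -> dict:
        inner = {lm: s for lm, s in self.distances.items() if s.level == "inner"}
        outer = {lm: s for lm, s in self.distances.items() if s.level == "outer"}
        return {
            "scenario": self.config.scenario,
            "dt_s": self.dt,
            "n_steps": self.n_steps,
            "simulated_time_s": float(self.times[-1]) if len(self.times) else 0.0,
            "particle_counts": self.particle_counts,
            "peak_brain_von_mises_pa": self.peak_brain_vm,
            "peak_brain_skull_rel_disp_m": self.peak_rel_disp,
            "inner_mean_abs_deviation": self.inner_mad,
            "outer_mean_abs_deviation": self.outer_mad,
            "outer_to_inner_deviation_ratio": (
                self.outer_mad / self.inner_mad if self.inner_mad > 0
                else float("inf")),
            "inner_max_abs_deviation": max(
                float(np.abs(s.normalized - 1.0).max()) for s in inner.values()),
            "outer_normalized_range": [
                min(float(s.normalized.min()) for s in outer.values()),
                max(float(s.normalized.max()) for s in outer.values())],
            "seizure_realized": self.seizure_realized,
            "wall_clock_s": self.wall_clock_s,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for lm, s in self.distances.items():
            rows.append(pd.DataFrame({
                "time_s": s.times, "landmark": lm, "level": s.level,
                "raw_m": s.raw, "normalized": s.normalized}))
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "distances.csv", index=False, float_format="%.12g")
        pd.DataFrame({
            "time_s": self.times,
            "brain_max_von_mises_pa": self.brain_max_vm,
            "sigma1_pa": self.brain_principals_at_max[:, 0],
            "sigma2_pa": self.brain_principals_at_max[:, 1],
            "sigma3_pa": self.brain_principals_at_max[:, 2],
            "brain_skull_rel_disp_m": self.rel_disp_brain_skull,
        }).to_csv(outdir / "stress.csv", index=False, float_format="%.12g")
        with open(outdir / "summary.json", "w") as f:
            json.dump(_to_plain(self.summary()), f, indent=2)


class _Simulation:
    """Internal stepping engine for one assembled scenario."""

    def __init__(self, config: SimulationConfig,
                 trace: KinematicsTrace = None):
        self.config = config
        model_cfg = config.model
        if config.scenario == "no_fluids":
            model_cfg = unprotected_config(model_cfg)
        self.model = build_nested_model(
            model_cfg, config.materials,
            damping_coefficient=config.damping_coefficient,
            include_fluids=(config.scenario == "nested"))
        if trace is None:
            seiz = replace(config.seizure, seed=config.seed)
            if seiz.duration < config.total_time:
                seiz = replace(seiz, duration=config.total_time)
            trace = generate_seizure_roll(seiz)
        elif trace.duration < config.total_time - 1e-9:
            raise ValueError(
                f"kinematics trace ({trace.duration:.3f} s) shorter than the "
                f"simulation ({config.total_time:.3f} s)")
        self.trace = trace
        self.states = {name: SolidState.zeros(mesh)
                       for name, mesh in self.model.solids.items()}
        self.motion = prescribe_uterine_motion(
            self.trace, self.model.uterus, center=(0.0, 0.0), surface="outer")
        self.dt = stable_timestep(self.model, config)
        self.n_steps = int(np.ceil(config.total_time / self.dt))
        # fluid particles carry a contact radius of half a lattice spacing
        self.fluid_specs = {
            name: ContactSpec(config.contact_stiffness_fluid,
                              engagement_offset=0.5 * ps.spacing,
                              max_penetration=config.max_penetration)
            for name, ps in self.model.fluids.items()}
        self.solid_spec = ContactSpec(config.contact_stiffness_solid,
                                      max_penetration=config.max_penetration)
        # contact pairs: (point source, surface mesh name, surface name, spec)
        if config.scenario == "nested":
            self.fluid_contacts = {
                "amniotic": [("uterus", "inner"), ("fetal_body", "outer")],
                "csf": [("skull", "inner"), ("brain", "outer")],
            }
            self.solid_contacts = []
        else:
            self.fluid_contacts = {"amniotic": [], "csf": []}
            self.solid_contacts = [
                ("fetal_body", "outer", "uterus", "inner"),
                ("brain", "outer", "skull", "inner"),
            ]
        self.max_depth = 0.0
        self._cand = {}
        self._cand_refresh = 10  # steps between contact candidate refreshes

    def _deformed(self, name: str) -> np.ndarray:
        return self.model.solids[name].nodes + self.states[name].displacements

    def _candidates(self, key, step, points, segments, positions):
        """Cached k-nearest candidate segments, refreshed periodically;
        particles move a tiny fraction of a segment length per step."""
        if key not in self._cand or step % self._cand_refresh == 1:
            self._cand[key] = candidate_segments(
                points, positions[segments[:, 0]], positions[segments[:, 1]])
        return self._cand[key]

    def _contact_phase(self, step: int = 0):
        """Exchange penalty forces; returns per-fluid particle force arrays."""
        model, states = self.model, self.states
        for st in states.values():
            st.f_fsi[:] = 0.0
        fluid_forces = {}
        balance = np.zeros(2)
        for fname, pairs in self.fluid_contacts.items():
            ps = model.fluids[fname]
            pf_total = np.zeros((len(ps), 2))
            for mesh_name, surf in pairs:
                mesh = model.solids[mesh_name]
                segs = mesh.boundary_segments[surf]
                pos = self._deformed(mesh_name)
                cand = self._candidates((fname, mesh_name, surf), step,
                                        ps.positions, segs, pos)
                pf, nodal, depth = surface_contact(
                    ps.positions, segs, pos, self.fluid_specs[fname],
                    cand=cand)
                pf_total += pf
                states[mesh_name].f_fsi += nodal
                self.max_depth = max(self.max_depth, depth)
            fluid_forces[fname] = pf_total
            balance += pf_total.sum(axis=0)
        for src_name, src_surf, dst_name, dst_surf in self.solid_contacts:
            src_mesh = model.solids[src_name]
            ids = src_mesh.surface_nodes(src_surf)
            pts = self._deformed(src_name)[ids]
            dst_mesh = model.solids[dst_name]
            segs = dst_mesh.boundary_segments[dst_surf]
            pos = self._deformed(dst_name)
            cand = self._candidates((src_name, dst_name, dst_surf), step,
                                    pts, segs, pos)
            pf, nodal, depth = surface_contact(
                pts, segs, pos, self.solid_spec, cand=cand)
            np.add.at(self.states[src_name].f_fsi, ids, pf)
            self.states[dst_name].f_fsi += nodal
            self.max_depth = max(self.max_depth, depth)
        if self.config.check_balance:
            for st in states.values():
                balance += st.f_fsi.sum(axis=0)
            if not np.all(np.abs(balance) < 1e-9 * max(1.0, self.max_depth
                          * self.config.contact_stiffness_fluid)):
                raise AssertionError(
                    f"global fluid-solid force balance violated: {balance}")
        return fluid_forces

    def _fluid_phase(self, fluid_forces, step: int):
        dt = self.dt
        params = self.config.sph
        for fname, ps in self.model.fluids.items():
            if len(ps) == 0:
                continue
            reinit = (self.config.shepard_interval > 0
                      and step % self.config.shepard_interval == 0)
            fluid_step(ps, params, dt,
                       external_accel=fluid_forces[fname] / ps.masses[:, None],
                       reinit_density=reinit)

    def _solid_phase(self, t_next: float, step: int):
        dt = self.dt
        model, states = self.model, self.states
        nets, masses = {}, {}
        for name, mesh in model.solids.items():
            st = states[name]
            eps = element_strains(mesh, st.displacements)
            st.stress = update_viscoelastic_stress(eps, dt, st.stress,
                                                   mesh.material)
            f_int = internal_force(mesh, st, st.stress.total)
            m = mesh.node_mass[:, None]
            nets[name] = (st.f_external + st.f_fsi - f_int
                          - mesh.damping_coefficient * m * st.velocities)
            masses[name] = mesh.node_mass
        # brain-skull restraint web: damped springs on relative displacement
        # between the paired brain-surface and inner-skull nodes
        bm, sn = model.tether_brain_nodes, model.tether_skull_nodes
        if bm is not None and len(bm):
            k = self.config.tether_stiffness / len(bm)
            c = self.config.tether_damping / len(bm)
            rel_u = (states["skull"].displacements[sn]
                     - states["brain"].displacements[bm])
            rel_v = (states["skull"].velocities[sn]
                     - states["brain"].velocities[bm])
            f = k * rel_u + c * rel_v
            np.add.at(nets["brain"], bm, f)
            np.add.at(nets["skull"], sn, -f)
        # merge the fetal-body/skull interface degrees of freedom
        fi, sj = model.tie_fetal_inner, model.tie_skull_outer
        f_shared = nets["fetal_body"][fi] + nets["skull"][sj]
        m_shared = (masses["fetal_body"][fi] + masses["skull"][sj])[:, None]
        for name, mesh in model.solids.items():
            st = states[name]
            m = masses[name][:, None]
            acc = np.zeros_like(st.displacements)
            active = masses[name] > 0
            acc[active] = nets[name][active] / m[active]
            if name == "fetal_body":
                acc[fi] = f_shared / m_shared
            elif name == "skull":
                acc[sj] = f_shared / m_shared
            hold = mesh.fixed | mesh.prescribed
            acc[hold] = 0.0
            st.accelerations = acc
            st.velocities = st.velocities + dt * acc
            st.velocities[mesh.fixed] = 0.0
            st.displacements = st.displacements + dt * st.velocities
        # keep tied nodes bit-identical
        states["skull"].displacements[sj] = states["fetal_body"].displacements[fi]
        states["skull"].velocities[sj] = states["fetal_body"].velocities[fi]
        # prescribed uterine-wall trajectory, tracked exactly
        ids = self.motion.node_ids
        ut = states["uterus"]
        ut.displacements[ids] = (self.motion.positions(t_next)
                                 - model.uterus.nodes[ids])
        ut.velocities[ids] = self.motion.velocities(t_next)
        if step % 200 == 0:
            for name, st in states.items():
                if not np.all(np.isfinite(st.displacements)):
                    raise SolidInstabilityError(
                        f"mesh '{name}': non-finite displacement at step {step}")

    def _sample_metrics(self):
        model, states = self.model, self.states
        dvals = {}
        for lm, (mname, nid, oname, osurf) in model.landmarks.all_pairs.items():
            pt = self._deformed(mname)[nid]
            segs = model.solids[oname].boundary_segments[osurf]
            dvals[lm] = min_distance(pt, self._deformed(oname), segs)
        stress = states["brain"].stress.total
        trio = principal_stresses(stress)
        vm = von_mises(trio[:, 0], trio[:, 1], trio[:, 2])
        k = int(np.argmax(vm))
        rel = np.linalg.norm(states["brain"].displacements.mean(axis=0)
                             - states["skull"].displacements.mean(axis=0))
        return dvals, float(vm[k]), trio[k], float(rel)

    def run(self, outdir=None, progress=False) -> RunResult:
        t0 = _time.perf_counter()
        cfg = self.config
        out_every = max(1, int(round(cfg.output_interval / self.dt)))
        snap_every = (int(round(cfg.snapshot_interval / self.dt))
                      if cfg.snapshot_interval > 0 else 0)
        times, vm_series, trio_series, rel_series = [], [], [], []
        dist_series = {lm: [] for lm in self.model.landmarks.all_pairs}

        def sample(t):
            dvals, vm, trio, rel = self._sample_metrics()
            times.append(t)
            vm_series.append(vm)
            trio_series.append(trio)
            rel_series.append(rel)
            for lm, v in dvals.items():
                dist_series[lm].append(v)

        sample(0.0)
        if outdir is not None and snap_every:
            self._snapshot(outdir, 0)
        for step in range(1, self.n_steps + 1):
            t_next = min(step * self.dt, cfg.total_time)
            fluid_forces = self._contact_phase(step)
            self._fluid_phase(fluid_forces, step)
            self._solid_phase(t_next, step)
            if step % out_every == 0 or step == self.n_steps:
                sample(t_next)
                if progress and (len(times) % 100 == 0):
                    print(f"  t={t_next:7.3f}s step={step}/{self.n_steps} "
                          f"max_vm={vm_series[-1]:.3e} Pa "
                          f"max_depth={self.max_depth:.2e} m", flush=True)
            if snap_every and outdir is not None and step % snap_every == 0:
                self._snapshot(outdir, step)

        baselines = self.model.landmarks.baseline_distances
        distances = {}
        for lm, vals in dist_series.items():
            distances[lm] = DistanceSeries(
                landmark=lm, level=self.model.landmarks.level(lm),
                times=np.asarray(times), raw=np.asarray(vals),
                baseline=baselines[lm])
        result = RunResult(
            config=cfg, dt=self.dt, n_steps=self.n_steps,
            times=np.asarray(times), distances=distances,
            brain_max_vm=np.asarray(vm_series),
            brain_principals_at_max=np.asarray(trio_series),
            rel_disp_brain_skull=np.asarray(rel_series),
            seizure_realized=self.trace.realized,
            wall_clock_s=_time.perf_counter() - t0,
            particle_counts={k: len(v) for k, v in self.model.fluids.items()})
        if outdir is not None:
            result.write(outdir)
        return result

    def _snapshot(self, outdir, step: int):
        snapdir = Path(outdir) / "snapshots"
        snapdir.mkdir(parents=True, exist_ok=True)
        for name, mesh in self.model.solids.items():
            st = self.states[name]
            trio = principal_stresses(st.stress.total)
            vm = von_mises(trio[:, 0], trio[:, 1], trio[:, 2])
            write_unstructured_grid(
                snapdir / f"{name}_{step:08d}.vtk",
                mesh.nodes + st.displacements, mesh.elements,
                point_data={"displacement": st.displacements,
                            "velocity": st.velocities},
                cell_data={"von_mises": vm})
        for name, ps in self.model.fluids.items():
            if len(ps):
                write_point_cloud(
                    snapdir / f"{name}_{step:08d}.vtk", ps.positions,
                    {"density": ps.densities, "pressure": ps.pressures,
                     "velocity": ps.velocities})


def run_simulation(config: SimulationConfig, outdir=None,
                   progress: bool = False,
                   trace: KinematicsTrace = None) -> RunResult:
    """Build the configured scenario and integrate it to ``total_time``.

    Deterministic for a fixed config+seed.  ``trace`` overrides the
    synthesised seizure kinematics (e.g. a recorded/processed IMU trace).
    Writes distances.csv, stress.csv and summary.json (plus optional VTK
    snapshots) when ``outdir`` is given.
    """
    sim = _Simulation(config, trace=trace)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        write_model(sim.model, Path(outdir) / "model")
        config.to_yaml(Path(outdir) / "config.yaml")
    return sim.run(outdir=outdir, progress=progress)


def run_comparison(config: SimulationConfig, outdir=None,
                   progress: bool = False) -> dict:
    """Protected (nested) vs unprotected (no_fluids) comparison.

    Runs both scenarios at the same scale and reports peak brain von Mises
    stress and peak brain-skull relative displacement for each, with the
    percent attenuation achieved by the nested fluid architecture.
    """
    from .metrics import attenuation_percent
    nested = run_simulation(replace(config, scenario="nested"),
                            outdir=None if outdir is None
                            else Path(outdir) / "nested", progress=progress)
    bare = run_simulation(replace(config, scenario="no_fluids"),
                          outdir=None if outdir is None
                          else Path(outdir) / "no_fluids", progress=progress)
    report = {
        "nested_peak_brain_von_mises_pa": nested.peak_brain_vm,
        "unprotected_peak_brain_von_mises_pa": bare.peak_brain_vm,
        "stress_attenuation_percent": attenuation_percent(
            nested.peak_brain_vm, bare.peak_brain_vm),
        "nested_peak_rel_disp_m": nested.peak_rel_disp,
        "unprotected_peak_rel_disp_m": bare.peak_rel_disp,
        "rel_disp_attenuation_percent": attenuation_percent(
            nested.peak_rel_disp, bare.peak_rel_disp),
        "nested_summary": nested.summary(),
        "unprotected_summary": bare.summary(),
    }
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        with open(Path(outdir) / "comparison.json", "w") as f:
            json.dump(_to_plain(report), f, indent=2)
    return report


def simulate_hydrostatic_column(width: float = 0.06, height: float = 0.09,
                                spacing: float = 0.003, g: float = 9.81,
                                sound_speed: float = 12.0,
                                settle_time: float = 1.5,
                                contact_stiffness: float = 2.0e5,
                                settle_drag: float = 4.0):
    """Still-fluid column in a fixed rigid box under gravity — the classic
    hydrostatic verification: after damped transients the pressure profile
    should approach p = rho0 g (H - y).

    Returns (particles, depth array, pressure array) after settling.  Uses
    strong artificial viscosity to damp the start-up transient quickly.
    """
    from .sph import FluidMaterial

    mat = FluidMaterial(1000.0, sound_speed, 1.0e-3)
    # fixed box walls: left, bottom, right (open top); outward-from-solid
    # normals must point INTO the fluid
    # traversed right-top -> bottom -> left-top so the outward-from-solid
    # normals (direction rotated -90 deg) point into the fluid
    wall = np.array([
        [width / 2 + spacing, height + 10 * spacing],
        [width / 2 + spacing, -spacing],
        [-width / 2 - spacing, -spacing],
        [-width / 2 - spacing, height + 10 * spacing]])
    # densify the walls so contact is smooth
    pts = [wall[0]]
    for a, b in zip(wall[:-1], wall[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / spacing)))
        for i in range(1, n + 1):
            pts.append(a + (b - a) * i / n)
    wall_pts = np.asarray(pts)
    segs = np.stack([np.arange(len(wall_pts) - 1),
                     np.arange(1, len(wall_pts))], axis=1)
    # lattice fill of the column
    xs = np.arange(-width / 2 + 0.5 * spacing, width / 2, spacing)
    ys = np.arange(0.5 * spacing, height, spacing)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.stack([xx.ravel(), yy.ravel()], axis=1)
    n = len(pos)
    from .sph import KernelSpec, ParticleSet
    ps = ParticleSet(pos, np.zeros((n, 2)), np.full(n, 1000.0 * spacing**2),
                     np.full(n, 1000.0), np.zeros(n), mat,
                     KernelSpec(1.3 * spacing, 2), spacing)
    params = SPHParams(alpha=2.0, beta=2.0, gravity=(0.0, -g))
    spec = ContactSpec(contact_stiffness, engagement_offset=0.5 * spacing,
                       max_penetration=5 * spacing)
    dt = 0.35 * min(ps.kernel.smoothing_length / sound_speed,
                    2.0 * np.sqrt(ps.masses.min() / contact_stiffness))
    steps = int(settle_time / dt)
    for step in range(1, steps + 1):
        pf, _, _ = surface_contact(ps.positions, segs, wall_pts, spec)
        # relaxation drag kills acoustic ringing; it vanishes at rest so the
        # converged equilibrium is unbiased
        ext = pf / ps.masses[:, None] - settle_drag * ps.velocities
        fluid_step(ps, params, dt, external_accel=ext,
                   reinit_density=(step % 30 == 0))
    # depth below the realized free surface (half a spacing above the top
    # particle centres)
    surface = ps.positions[:, 1].max() + 0.5 * spacing
    depth = surface - ps.positions[:, 1]
    return ps, depth, ps.pressures
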