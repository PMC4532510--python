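"""Langevin dynamics, replica management and constant-velocity pulling.

The equation of motion is the standard underdamped Langevin equation

    m_i dv_i/dt = F_i - m_i gamma_i v_i + xi_i(t),

with Gaussian white noise obeying the fluctuation-dissipation relation
<xi_i(t) xi_j(t')> = 2 m_i gamma_i k_B T delta_ij delta(t - t'). It is
integrated with the BAOAB splitting (velocity half-kick, half-drift, exact
Ornstein-Uhlenbeck velocity update, half-drift, half-kick), which reduces
exactly to velocity Verlet when gamma = 0 and noise is disabled.

Units: time in t0 = sqrt(g/mol A^2 / (kcal/mol)) (~48.9 fs), so with the
default friction gamma = 0.02 / t0 the dynamics is strongly underdamped, as
appropriate for a low-friction coarse-grained model. Defaults follow the
nucleosome study conditions: dt = 0.1 t0, T = 300 K, pulling speed
1e-4 A/t0 with dt = 0.05 t0.

Mechanical unwrapping attaches one virtual particle to each duplex end
(the 5' terminal bead of one strand and the 3' terminal bead of the other)
through harmonic springs; the two virtual particles move apart at constant
speed and the spring extensions report the force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .forcefield import ForceField
from .params import KB, KCAL_PER_MOL_PER_A_IN_PN, ForceFieldParameters
from .topology import CGTopology, SUGAR


class IntegrationError(RuntimeError):
    """Raised when coordinates become non-finite; carries the last frame."""

    def __init__(self, message: str, frame: np.ndarray | None = None):
        super().__init__(message)
        self.frame = frame


@dataclass
class SimulationParams:
    """Run-control parameters (the force-field lives elsewhere)."""

    dt: float = 0.1                 # t0
    gamma: float = 0.02             # 1/t0
    temperature: float = 300.0      # K
    n_steps: int = 100_000
    snapshot_every: int = 1_000
    seed: int = 0
    replica: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0 or self.snapshot_every <= 0:
            raise ValueError("invalid step counts")


@dataclass
class PullingApparatus:
    """Two virtual particles pulling the duplex ends apart.

    Each virtual particle is linked to its terminal beads by harmonic
    springs whose rest vectors equal the initial bead offsets, so the
    apparatus exerts no force at t = 0. The particles move in exactly
    opposite directions along ``axis`` at ``speed`` (A/t0); ``k_link`` is
    the spring constant of each link (kcal/mol/A^2). The recorded force is
    the spring force component along the pulling axis (mean over beads and
    ends); for a frozen bead it grows exactly as k_link x speed x t.
    """

    left_beads: tuple[int, ...]
    right_beads: tuple[int, ...]
    left_pos: np.ndarray                 # virtual particle positions
    right_pos: np.ndarray
    offsets: dict[int, np.ndarray]       # bead -> rest vector from its VP
    axis: np.ndarray
    speed: float = 1e-4
    k_link: float = 0.5
    _d0: float = 0.0

    @classmethod
    def from_topology(cls, topology: CGTopology, coords: np.ndarray,
                      speed: float = 1e-4, k_link: float = 0.5
                      ) -> "PullingApparatus":
        left, right = dna_terminal_beads(topology)
        lp = coords[list(left)].mean(axis=0)
        rp = coords[list(right)].mean(axis=0)
        axis = rp - lp
        n = np.linalg.norm(axis)
        if n < 1e-9:
            raise ValueError("degenerate pulling axis")
        offsets = {int(b): coords[b] - lp for b in left}
        offsets.update({int(b): coords[b] - rp for b in right})
        return cls(left, right, lp.copy(), rp.copy(), offsets, axis / n,
                   speed, k_link, _d0=float(n))

    def advance(self, dt: float) -> None:
        self.left_pos = self.left_pos - self.axis * self.speed * dt
        self.right_pos = self.right_pos + self.axis * self.speed * dt

    def forces(self, coords: np.ndarray) -> tuple[np.ndarray, float, float]:
        """Spring forces on the linked beads plus per-end mean axial
        extension (positive when the springs pull outward)."""
        f = np.zeros_like(coords)
        ext_l, ext_r = [], []
        for beads, anchor, outward, ext in (
                (self.left_beads, self.left_pos, -self.axis, ext_l),
                (self.right_beads, self.right_pos, self.axis, ext_r)):
            for b in beads:
                dr = anchor + self.offsets[b] - coords[b]
                f[b] += self.k_link * dr
                ext.append(float(np.dot(dr, outward)))
        return f, float(np.mean(ext_l)), float(np.mean(ext_r))

    def separation(self) -> float:
        """Pulling coordinate d: distance between the two virtual particles
        along the pulling axis."""
        return float(np.dot(self.right_pos - self.left_pos, self.axis))


def dna_terminal_beads(topology: CGTopology) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Terminal sugar beads at each duplex end.

    The left end (base pair 1) couples the 5' terminus of strand 1 with the
    3' terminus of strand 2; the right end is the mirror pair.
    """
    if not len(topology.basepairs):
        raise ValueError("topology has no base pairs")
    sugars = np.nonzero(topology.kind == SUGAR)[0]

    def sugar_of(base_bead: int) -> int:
        # the sugar of the same nucleotide (same chain and residue)
        m = (topology.chain_id[sugars] == topology.chain_id[base_bead]) & \
            (topology.residue_index[sugars] == topology.residue_index[base_bead])
        return int(sugars[np.nonzero(m)[0][0]])

    left_pair = topology.basepairs[0]
    right_pair = topology.basepairs[-1]
    left = tuple(sugar_of(int(b)) for b in left_pair)
    right = tuple(sugar_of(int(b)) for b in right_pair)
    return left, right


@dataclass
class Trajectory:
    """Time-ordered snapshots plus per-frame observables and metadata."""

    times: np.ndarray
    coords: np.ndarray                    # (n_frames, n_beads, 3)
    observables: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def save(self, path: str | Path) -> None:
        obs = {f"obs_{k}": v for k, v in self.observables.items()}
        np.savez_compressed(path, times=self.times, coords=self.coords,
                            metadata=np.array([repr(self.metadata)]), **obs)

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        import ast
        data = np.load(path, allow_pickle=False)
        obs = {k[4:]: data[k] for k in data.files if k.startswith("obs_")}
        meta = ast.literal_eval(str(data["metadata"][0]))
        return cls(data["times"], data["coords"], obs, meta)

    def to_dcd(self, path: str | Path) -> None:
        """Export to DCD, readable by common MD analysis tools."""
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path), "w") as f:
            f.write(np.asarray(self.coords, np.float32))

    def observables_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.times, **self.observables})


class LangevinIntegrator:
    """BAOAB Langevin integrator over a compiled force field."""

    def __init__(self, forcefield: ForceField, sim: SimulationParams,
                 apparatus: PullingApparatus | None = None):
        self.ff = forcefield
        self.sim = sim
        self.apparatus = apparatus
        self.masses = forcefield.topology.mass.astype(float)
        self.rng = np.random.default_rng(sim.seed)
        kbt = KB * sim.temperature
        self._c1 = float(np.exp(-sim.gamma * sim.dt))
        self._c2 = np.sqrt(kbt * (1.0 - self._c1 ** 2) / self.masses)[:, None]
        self._sigma_v = np.sqrt(kbt / self.masses)[:, None]

    def initial_velocities(self) -> np.ndarray:
        """Maxwell-Boltzmann draw at the target temperature."""
        return self.rng.standard_normal((len(self.masses), 3)) * self._sigma_v

    def _forces(self, coords: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
        f = self.ff.forces(coords)
        ext = (0.0, 0.0)
        if self.apparatus is not None:
            fa, ext_l, ext_r = self.apparatus.forces(coords)
            f = f + fa
            ext = (ext_l, ext_r)
        return f, ext

    def run(self, coords: np.ndarray, velocities: np.ndarray | None = None,
            n_steps: int | None = None, record: bool = True,
            extra_observables=None) -> tuple[Trajectory, np.ndarray, np.ndarray]:
        """Integrate ``n_steps``; returns (trajectory, coords, velocities).

        ``extra_observables`` is an optional callable(frame_coords) -> dict
        evaluated at snapshot times.
        """
        sim = self.sim
        n_steps = sim.n_steps if n_steps is None else n_steps
        x = np.array(coords, float)
        v = self.initial_velocities() if velocities is None else np.array(velocities)
        m = self.masses[:, None]
        dt = sim.dt
        f, ext = self._forces(x)

        times, frames = [], []
        obs: dict[str, list] = {"kinetic_temperature": [], "potential": [],
                                "pull_force_pN": [], "pull_distance": []}
        extra_keys: list[str] = []

        def snapshot(step: int) -> None:
            if not record:
                return
            times.append((step + 1) * dt)
            frames.append(x.copy())
            ke = 0.5 * float(np.sum(self.masses[:, None] * v * v))
            ndof = 3 * len(self.masses)
            obs["kinetic_temperature"].append(2.0 * ke / (ndof * KB))
            obs["potential"].append(self.ff.energy(x))
            if self.apparatus is not None:
                mean_ext = 0.5 * (ext[0] + ext[1])
                obs["pull_force_pN"].append(self.apparatus.k_link * mean_ext
                                            * KCAL_PER_MOL_PER_A_IN_PN)
                obs["pull_distance"].append(self.apparatus.separation())
            if extra_observables is not None:
                for k, val in extra_observables(x).items():
                    if k not in obs:
                        obs[k] = []
                        extra_keys.append(k)
                    obs[k].append(val)

        noisy = sim.gamma > 0
        for step in range(n_steps):
            v = v + (0.5 * dt) * f / m                     # B
            x = x + (0.5 * dt) * v                          # A
            if noisy:                                       # O (exact OU)
                v = self._c1 * v + self._c2 * self.rng.standard_normal(v.shape)
            x = x + (0.5 * dt) * v                          # A
            if self.apparatus is not None:
                self.apparatus.advance(dt)
            try:
                f, ext = self._forces(x)
            except FloatingPointError as exc:
                raise IntegrationError(
                    f"step {step}: {exc}", frame=x) from exc
            v = v + (0.5 * dt) * f / m                     # B
            if (step + 1) % sim.snapshot_every == 0:
                snapshot(step)

        frame_array = (np.asarray(frames).reshape(len(times), -1, 3)
                       if times else np.empty((0, len(self.masses), 3)))
        traj = Trajectory(
            np.asarray(times), frame_array,
            {k: np.asarray(v_) for k, v_ in obs.items()
             if v_ or k in ("kinetic_temperature",)},
            metadata={"dt": dt, "gamma": sim.gamma, "T": sim.temperature,
                      "seed": sim.seed, "replica": sim.replica,
                      "n_steps": n_steps, "integrator": "BAOAB",
                      "topology_hash": self.ff.topology.content_hash(),
                      "salt_mM": self.ff.params.salt_mM,
                      "go_scaling": self.ff.params.go_scaling},
        )
        return traj, x, v


def run_equilibrium(topology: CGTopology, params: ForceFieldParameters,
                    sim: SimulationParams, n_replicas: int = 1,
                    coords: np.ndarray | None = None,
                    extra_observables=None) -> list[Trajectory]:
    """Independent equilibrium replicas with per-replica derived seeds.

    Replica r uses seed ``sim.seed + r`` (distinct noise streams); replica
    failures abort only the affected replica.
    """
    if coords is None:
        coords = topology.ref_coords
    ff = ForceField(topology, params)
    out: list[Trajectory] = []
    for r in range(n_replicas):
        rsim = replace(sim, seed=sim.seed + r, replica=r)
        integ = LangevinIntegrator(ff, rsim)
        try:
            traj, _, _ = integ.run(coords, extra_observables=extra_observables)
        except IntegrationError as exc:
            import logging
            logging.getLogger("nucleomd").warning(
                "replica %d (seed %d) aborted: %s", r, rsim.seed, exc)
            traj = Trajectory(np.empty(0), np.empty((0, topology.n_beads, 3)),
                              metadata={"replica": r, "failed": str(exc)})
        out.append(traj)
    return out


def run_pulling(topology: CGTopology, params: ForceFieldParameters,
                sim: SimulationParams, speed: float = 1e-4,
                k_link: float = 0.5, coords: np.ndarray | None = None
                ) -> Trajectory:
    """Constant-velocity mechanical unwrapping of the duplex ends."""
    if coords is None:
        coords = topology.ref_coords
    ff = ForceField(topology, params)
    apparatus = PullingApparatus.from_topology(topology, coords,
                                               speed=speed, k_link=k_link)
    integ = LangevinIntegrator(ff, sim, apparatus=apparatus)
    traj, _, _ = integ.run(coords)
    traj.metadata["pull_speed"] = speed
    traj.metadata["k_link"] = k_link
    return traj


def measure_pulling_force(extension: float, k_link: float) -> float:
    """Spring force in pN from the harmonic-link extension in A."""
    return k_link * extension * KCAL_PER_MOL_PER_A_IN_PN
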