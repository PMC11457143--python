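"""Integration of the equations of motion under periodic boundaries.

Provides steepest-descent energy minimization, NVT dynamics (BAOAB Langevin
by default, deterministic Nose-Hoover behind a config switch), and NPT with
an isotropic Berendsen barostat driven by the pairwise virial pressure.  The
velocity-Verlet core uses a 20 fs default time step.  All stochastic terms
draw from a single seeded generator, so identical (seed, config, inputs)
give bitwise-identical trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from cgdroplet.forcefield import (
    BAR_PER_KJ_NM3,
    KB,
    ForceFieldParams,
    SystemTopology,
    total_energy_and_forces,
)

logger = logging.getLogger("cgdroplet.engine")

#: abort threshold for the potential energy guard rail (kJ/mol per bead)
ENERGY_GUARD_PER_BEAD = 1.0e6


class SimulationAborted(RuntimeError):
    """Energy blow-up, box collapse, or another guard-rail violation."""


@dataclass
class SimulationState:
    """Positions/velocities (nm, nm/ps), orthorhombic box (nm), time (ps)."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(), self.velocities.copy(), self.box.copy(), self.time
        )

    def wrapped_positions(self) -> np.ndarray:
        w = np.mod(self.positions, self.box)
        # guard against w == box from floating-point roundoff
        w[w >= self.box] = 0.0
        return w


@dataclass
class IntegratorConfig:
    """Time step, thermostat/barostat couplings and the RNG seed.

    ``friction`` (ps^-1) defaults to 1/tau_t, mapping the stated thermostat
    coupling time onto the Langevin collision rate.  ``thermostat`` may be
    "langevin", "nose-hoover" or "none" (NVE).
    """

    dt_fs: float = 20.0
    temperature: float = 300.0
    tau_t: float = 100.0  # ps
    tau_p: float = 10.0  # ps
    ref_pressure: float = 1.0  # bar
    compressibility: float = 4.5e-5  # bar^-1
    friction: float | None = None  # ps^-1
    thermostat: str = "langevin"
    seed: int = 0
    min_box_edge: float = 1.0  # nm; NPT abort threshold
    neighbor_skin: float = 0.3  # nm

    def __post_init__(self) -> None:
        if self.dt_fs <= 0 or self.tau_t <= 0 or self.tau_p <= 0:
            raise ValueError("dt, tau_t and tau_p must be positive")
        if self.thermostat not in ("langevin", "nose-hoover", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")

    @property
    def dt(self) -> float:
        """Time step in ps."""
        return self.dt_fs * 1e-3

    @property
    def gamma(self) -> float:
        return self.friction if self.friction is not None else 1.0 / self.tau_t


@dataclass
class Trajectory:
    """Sampled frames plus run metadata."""

    frames: list[np.ndarray] = field(default_factory=list)
    boxes: list[np.ndarray] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    final_state: SimulationState | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def add_frame(self, state: SimulationState) -> None:
        self.frames.append(state.positions.copy())
        self.boxes.append(state.box.copy())
        self.times.append(state.time)

    def positions_array(self) -> np.ndarray:
        return np.stack(self.frames)

    def save_xyz(self, path, names: list[str] | None = None) -> None:
        """Plain-text XYZ snapshots (one block per frame)."""
        n = self.frames[0].shape[0]
        names = names or ["C"] * n
        with open(path, "w") as fh:
            for pos, t in zip(self.frames, self.times):
                fh.write(f"{n}\nt={t:.3f} ps\n")
                for nm, (x, y, z) in zip(names, pos):
                    fh.write(f"{nm} {10*x:.4f} {10*y:.4f} {10*z:.4f}\n")

    def save_dcd(self, path) -> None:
        """Binary DCD trajectory (Angstrom convention) via mdtraj."""
        import mdtraj.formats

        with mdtraj.formats.DCDTrajectoryFile(str(path), "w") as fh:
            for pos, box in zip(self.frames, self.boxes):
                fh.write(
                    10.0 * pos[None, :, :],
                    cell_lengths=10.0 * box[None, :],
                    cell_angles=np.array([[90.0, 90.0, 90.0]]),
                )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            frames=self.positions_array(),
            boxes=np.stack(self.boxes),
            times=np.array(self.times),
        )


# ---------------------------------------------------------------------------
# neighbor list
# ---------------------------------------------------------------------------

@dataclass
class NeighborList:
    pairs: np.ndarray  # (n, 2) int64, i < j
    cutoff: float
    skin: float
    _ref_positions: np.ndarray = None
    _box: np.ndarray = None

    def needs_rebuild(self, state: SimulationState) -> bool:
        if self._ref_positions is None:
            return True
        # box drift (NPT): rebuild well before pairs can cross the skin
        if np.max(np.abs(self._box - state.box)) > 0.2 * self.skin:
            return True
        disp = state.positions - self._ref_positions
        disp -= state.box * np.round(disp / state.box)
        return bool(np.max(np.abs(disp)) > 0.45 * self.skin)


from numba import njit as _njit


@_njit(cache=True)
def _cell_list_pairs(wrapped, box, reach, buf):
    """Periodic cell-list pair search; returns the number of pairs written
    into ``buf`` (or -1 on buffer overflow)."""
    n = wrapped.shape[0]
    ncx = max(1, int(box[0] / reach))
    ncy = max(1, int(box[1] / reach))
    ncz = max(1, int(box[2] / reach))
    ncells = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        cx = int(wrapped[i, 0] / box[0] * ncx)
        cy = int(wrapped[i, 1] / box[1] * ncy)
        cz = int(wrapped[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    reach2 = reach * reach
    npairs = 0
    cap = buf.shape[0]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0, a1 = count[c], count[c + 1]
                # half the neighbor stencil (13 cells) + the cell itself
                for off in range(14):
                    if off == 0:
                        dxc, dyc, dzc = 0, 0, 0
                    elif off == 1:
                        dxc, dyc, dzc = 1, 0, 0
                    elif off == 2:
                        dxc, dyc, dzc = 1, 1, 0
                    elif off == 3:
                        dxc, dyc, dzc = 0, 1, 0
                    elif off == 4:
                        dxc, dyc, dzc = -1, 1, 0
                    elif off == 5:
                        dxc, dyc, dzc = 0, 0, 1
                    elif off == 6:
                        dxc, dyc, dzc = 1, 0, 1
                    elif off == 7:
                        dxc, dyc, dzc = 1, 1, 1
                    elif off == 8:
                        dxc, dyc, dzc = 0, 1, 1
                    elif off == 9:
                        dxc, dyc, dzc = -1, 1, 1
                    elif off == 10:
                        dxc, dyc, dzc = -1, 0, 1
                    elif off == 11:
                        dxc, dyc, dzc = -1, -1, 1
                    elif off == 12:
                        dxc, dyc, dzc = 0, -1, 1
                    else:
                        dxc, dyc, dzc = 1, -1, 1
                    nx = (cx + dxc) % ncx
                    ny = (cy + dyc) % ncy
                    nz = (cz + dzc) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    if off > 0 and c2 == c:
                        continue  # small grids: neighbor wraps onto self
                    b0, b1 = count[c2], count[c2 + 1]
                    for ai in range(a0, a1):
                        i = order[ai]
                        start = ai + 1 if off == 0 else b0
                        for bi in range(start, b1):
                            j = order[bi]
                            dx = wrapped[i, 0] - wrapped[j, 0]
                            dy = wrapped[i, 1] - wrapped[j, 1]
                            dz = wrapped[i, 2] - wrapped[j, 2]
                            dx -= box[0] * round(dx / box[0])
                            dy -= box[1] * round(dy / box[1])
                            dz -= box[2] * round(dz / box[2])
                            if dx * dx + dy * dy + dz * dz <= reach2:
                                if npairs >= cap:
                                    return -1
                                if i < j:
                                    buf[npairs, 0] = i
                                    buf[npairs, 1] = j
                                else:
                                    buf[npairs, 0] = j
                                    buf[npairs, 1] = i
                                npairs += 1
    return npairs


def neighbor_list(
    state: SimulationState, cutoff: float, skin: float = 0.3
) -> NeighborList:
    """All bead pairs within ``cutoff + skin`` under periodic minimum image.

    A superset of the true in-range pair set (the kernel re-tests distances).
    Requires ``cutoff + skin < min(box)/2`` so the minimum image is unique.
    Uses a periodic cell list when the box holds at least 3 cells per
    dimension, otherwise a periodic KD-tree.
    """
    reach = cutoff + skin
    if reach >= 0.5 * float(np.min(state.box)):
        raise ValueError(
            f"cutoff+skin={reach} nm violates minimum image for box "
            f"{state.box} (must be < half the smallest edge)"
        )
    if state.n_beads == 0:
        return NeighborList(np.zeros((0, 2), dtype=np.int64), cutoff, skin,
                            state.positions.copy(), state.box.copy())
    wrapped = state.wrapped_positions()
    if np.all(state.box / reach >= 3.0):
        cap = max(4096, state.n_beads * 160)
        while True:
            buf = np.empty((cap, 2), dtype=np.int64)
            n_found = _cell_list_pairs(wrapped, state.box, reach, buf)
            if n_found >= 0:
                pairs = buf[:n_found].copy()
                break
            cap *= 2
    else:
        tree = cKDTree(wrapped, boxsize=state.box)
        pairs = tree.query_pairs(reach, output_type="ndarray").astype(np.int64)
    return NeighborList(
        pairs, cutoff, skin, state.positions.copy(), state.box.copy()
    )


class _ForceEvaluator:
    """Caches the neighbor list (bonded pairs pre-excluded) between calls."""

    def __init__(self, topo: SystemTopology, params: ForceFieldParams,
                 skin: float = 0.6):
        from cgdroplet.forcefield import (
            _exclude_bonded, _prepare_pair_tables,
        )

        self.topo = topo
        self.params = params
        self.skin = skin
        self.nlist: NeighborList | None = None
        self._pairs: np.ndarray | None = None
        self._exclude_bonded = _exclude_bonded
        self._prepare_pair_tables = _prepare_pair_tables
        self._total = total_energy_and_forces

    def __call__(self, state: SimulationState, return_virial: bool = False):
        _exclude_bonded = self._exclude_bonded
        _prepare_pair_tables = self._prepare_pair_tables
        if self.nlist is None or self.nlist.needs_rebuild(state):
            self.nlist = neighbor_list(state, self.params.cutoff, self.skin)
            pairs = _exclude_bonded(self.nlist.pairs, self.topo)
            # sort for cache locality in the force kernel
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
            pi = np.ascontiguousarray(pairs[:, 0])
            pj = np.ascontiguousarray(pairs[:, 1])
            self._pairs = (
                pi, pj, _prepare_pair_tables(pi, pj, self.topo, self.params)
            )
        return self._total(
            state, self.topo, self.params,
            pairs=self._pairs, return_virial=return_virial,
            pairs_prepared=True,
        )


# ---------------------------------------------------------------------------
# energy minimization
# ---------------------------------------------------------------------------

def minimize_energy(
    state: SimulationState,
    topo: SystemTopology,
    params: ForceFieldParams,
    tolerance: float = 1.0,
    max_iterations: int = 2000,
) -> SimulationState:
    """Relax a configuration until max |F_i| <= tolerance (kJ/mol/nm).

    A short steepest-descent pre-phase removes any hard overlaps, then
    L-BFGS refines to the force tolerance.  The energy is non-increasing
    across accepted steps; hitting the iteration cap is reported, not
    raised.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    st = state.copy()
    ev = _ForceEvaluator(topo, params)
    energy, forces = ev(st)
    if not math.isfinite(energy):
        raise ValueError("non-finite energy at start of minimization")

    # steepest-descent pre-phase with adaptive step (robust to overlaps)
    h = 0.01
    for _ in range(50):
        fmax = float(np.max(np.abs(forces)))
        if fmax <= tolerance:
            return st
        trial = st.copy()
        trial.positions = st.positions + forces * (h / fmax)
        e_new, f_new = ev(trial)
        if e_new < energy:
            st, energy, forces = trial, e_new, f_new
            h = min(h * 1.5, 0.1)
        else:
            h *= 0.3

    from scipy.optimize import minimize as scipy_minimize

    shape = st.positions.shape
    probe = st.copy()

    def fun(x):
        probe.positions = x.reshape(shape)
        e, f = ev(probe)
        return e, -f.ravel()

    res = scipy_minimize(
        fun,
        st.positions.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "gtol": 0.5 * tolerance,
                 "ftol": 1e-14},
    )
    cand = st.copy()
    cand.positions = res.x.reshape(shape)
    e_cand, f_cand = ev(cand)
    if e_cand <= energy:
        st, energy, forces = cand, e_cand, f_cand
    fmax = float(np.max(np.abs(forces)))
    if fmax > tolerance:
        logger.warning(
            "minimization stopped before reaching tolerance "
            "(max|F|=%.3g > %.3g kJ/mol/nm)", fmax, tolerance,
        )
    return st


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(
    topo: SystemTopology, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw velocities (nm/ps) from the Maxwell-Boltzmann distribution."""
    sd = np.sqrt(KB * temperature / topo.mass)[:, None]
    return rng.standard_normal((topo.n_beads, 3)) * sd


def kinetic_energy(state: SimulationState, topo: SystemTopology) -> float:
    return 0.5 * float(np.sum(topo.mass[:, None] * state.velocities**2))


def instantaneous_temperature(state: SimulationState, topo: SystemTopology) -> float:
    return 2.0 * kinetic_energy(state, topo) / (3.0 * topo.n_beads * KB)


def instantaneous_pressure(
    state: SimulationState, topo: SystemTopology, virial: float
) -> float:
    """Virial pressure in bar: P = (2 KE + W) / (3 V)."""
    vol = float(np.prod(state.box))
    p_kj_nm3 = (2.0 * kinetic_energy(state, topo) + virial) / (3.0 * vol)
    return p_kj_nm3 * BAR_PER_KJ_NM3


def _run_md(
    state: SimulationState,
    topo: SystemTopology,
    params: ForceFieldParams,
    config: IntegratorConfig,
    n_steps: int,
    *,
    barostat: bool,
    sample_every: int,
    callback: Callable | None = None,
) -> Trajectory:
    st = state.copy()
    ev = _ForceEvaluator(topo, params, skin=config.neighbor_skin)
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    dt = config.dt
    m = topo.mass[:, None]
    kT = KB * config.temperature

    traj = Trajectory(metadata={
        "ensemble": "npt" if barostat else "nvt",
        "thermostat": config.thermostat,
        "dt_fs": config.dt_fs,
        "temperature": config.temperature,
        "seed": config.seed,
        "n_steps": n_steps,
        "sample_every": sample_every,
    })
    traj.add_frame(st)
    if n_steps == 0:
        traj.final_state = st
        return traj

    need_virial = barostat
    out = ev(st, return_virial=need_virial)
    energy, forces = out[0], out[1]
    virial = out[2] if need_virial else 0.0

    # Langevin OU coefficients (BAOAB splitting)
    if config.thermostat == "langevin":
        c1 = math.exp(-config.gamma * dt)
        c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
        sigma_v = np.sqrt(kT / topo.mass)[:, None]
    zeta = 0.0  # Nose-Hoover friction variable
    q_nh = 3.0 * topo.n_beads * kT * config.tau_t**2

    guard = ENERGY_GUARD_PER_BEAD * topo.n_beads
    for step in range(1, n_steps + 1):
        if config.thermostat == "nose-hoover":
            # half-kick with thermostat friction folded in
            st.velocities = (
                st.velocities * (1.0 - 0.5 * dt * zeta)
                + 0.5 * dt * forces / m
            )
            st.positions = st.positions + dt * st.velocities
        elif config.thermostat == "langevin":
            # BAOAB: B (half kick), A (half drift), O, A, then B after forces
            st.velocities = st.velocities + 0.5 * dt * forces / m
            st.positions = st.positions + 0.5 * dt * st.velocities
            noise = rng.standard_normal(st.velocities.shape)
            st.velocities = c1 * st.velocities + c2 * sigma_v * noise
            st.positions = st.positions + 0.5 * dt * st.velocities
        else:  # NVE
            st.velocities = st.velocities + 0.5 * dt * forces / m
            st.positions = st.positions + dt * st.velocities

        out = ev(st, return_virial=need_virial)
        energy, forces = out[0], out[1]
        if need_virial:
            virial = out[2]

        if config.thermostat == "nose-hoover":
            ke = kinetic_energy(st, topo)
            zeta = zeta + dt * (2.0 * ke - 3.0 * topo.n_beads * kT) / q_nh
            st.velocities = (st.velocities + 0.5 * dt * forces / m) / (
                1.0 + 0.5 * dt * zeta
            )
        else:
            st.velocities = st.velocities + 0.5 * dt * forces / m

        if barostat:
            pressure = instantaneous_pressure(st, topo, virial)
            factor = 1.0 - (config.compressibility * dt / config.tau_p) * (
                config.ref_pressure - pressure
            )
            mu = factor ** (1.0 / 3.0)
            st.box = st.box * mu
            st.positions = st.positions * mu
            if float(np.min(st.box)) < config.min_box_edge:
                raise SimulationAborted(
                    f"box collapsed below {config.min_box_edge} nm at step "
                    f"{step} (box={st.box})"
                )

        st.time += dt
        if not math.isfinite(energy) or abs(energy) > guard:
            raise SimulationAborted(
                f"energy blow-up at step {step}: U={energy:.3g} kJ/mol "
                f"(T={instantaneous_temperature(st, topo):.1f} K)"
            )
        if step % sample_every == 0:
            traj.add_frame(st)
        if callback is not None:
            callback(step, st, energy)

    traj.final_state = st
    return traj


def run_nvt(
    state: SimulationState,
    topo: SystemTopology,
    params: ForceFieldParams,
    config: IntegratorConfig,
    n_steps: int,
    sample_every: int = 1000,
    callback: Callable | None = None,
) -> Trajectory:
    """Fixed-box dynamics with the configured thermostat."""
    return _run_md(
        state, topo, params, config, n_steps,
        barostat=False, sample_every=sample_every, callback=callback,
    )


def run_npt(
    state: SimulationState,
    topo: SystemTopology,
    params: ForceFieldParams,
    config: IntegratorConfig,
    n_steps: int,
    sample_every: int = 1000,
    callback: Callable | None = None,
) -> Trajectory:
    """Thermostatted dynamics with isotropic Berendsen pressure coupling.

    Each step the box and positions are rescaled by
    ``mu = [1 - kappa dt/tau_p (P0 - P)]^(1/3)`` with P the instantaneous
    virial pressure, so a system above the reference pressure expands.
    """
    return _run_md(
        state, topo, params, config, n_steps,
        barostat=True, sample_every=sample_every, callback=callback,
    )
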