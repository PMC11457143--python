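"""The droplet-formation pipeline and ternary composition bookkeeping.

A droplet run places randomly coiled chains with their centers of mass on a
regular grid, relaxes them (energy minimization), equilibrates at fixed
volume and then at 1 bar (Berendsen), re-inserts the condensed system into a
cubic box sized to the target particle density (80 000 uM by default) after
unwrapping and recentering, minimizes again, and finally collects a
production NVT trajectory sampled at a fixed stride.  Ternary compositions
are expressed as percentages of the reference amounts 120 RBP / 267 RNA /
267 DPR molecules.

Full-scale runs (3 us, 120 FUS equivalents) are cluster-sized; the
``desk`` preset scales molecule counts and stage durations down so the same
pipeline runs on one CPU in minutes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from cgdroplet.engine import (
    IntegratorConfig,
    SimulationState,
    Trajectory,
    minimize_energy,
    run_npt,
    run_nvt,
)
from cgdroplet.forcefield import (
    ForceFieldParams,
    N_AVOGADRO,
    SystemTopology,
    build_topology,
    default_forcefield,
)
from cgdroplet.sequences import (
    DPRSpec,
    Molecule,
    ProteinSequence,
    RNASequence,
    build_dpr_sequence,
    build_rna_sequence,
    get_rbp_sequence,
)

logger = logging.getLogger("cgdroplet.protocol")

#: reference molecule numbers the composition percentages scale
REFERENCE_COUNTS = (120, 267, 267)  # RBP, RNA, DPR


class StageError(RuntimeError):
    """A protocol stage failed; the message names the stage."""


@dataclass
class PhaseComposition:
    """Ternary composition in percent (RBP, RNA, DPR), summing to 100.

    Molecule counts are the reference amounts scaled by percentage/100 and
    rounded to the nearest integer (ties up).  Note the bead-count parity of
    the reference species: 120 x 267-residue RBP chains, 267 x 120-bead
    U_40 chains and 267 x 120-residue DPR_60 chains all give 32 040 beads.
    """

    percent_rbp: float
    percent_rna: float
    percent_dpr: float
    reference: tuple[int, int, int] = REFERENCE_COUNTS

    def __post_init__(self) -> None:
        for p in (self.percent_rbp, self.percent_rna, self.percent_dpr):
            if p < 0:
                raise ValueError("percentages must be >= 0")
        total = self.percent_rbp + self.percent_rna + self.percent_dpr
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"percentages sum to {total}, expected 100 +- 0.1")

    def resolved_counts(self, scale: float = 1.0) -> tuple[int, int, int]:
        """Molecule counts; ``scale`` shrinks the reference amounts for desk
        presets (rounding documented: nearest integer, ties up)."""
        def round_half_up(x: float) -> int:
            return int(math.floor(x + 0.5))

        return (
            round_half_up(self.percent_rbp / 100.0 * self.reference[0] * scale),
            round_half_up(self.percent_rna / 100.0 * self.reference[1] * scale),
            round_half_up(self.percent_dpr / 100.0 * self.reference[2] * scale),
        )


@dataclass
class ProtocolConfig:
    """Stage lengths, density target and sampling for a droplet run.

    Full-scale defaults follow the published protocol (50 ns NVT, 500 ns
    NPT, 3 us production, 5 ns sampling stride, 80 000 uM, 300 K, 150 mM);
    ``ProtocolConfig.desk()`` returns a scaled-down preset.
    """

    nvt1_ns: float = 50.0
    npt_ns: float = 500.0
    production_ns: float = 3000.0
    sampling_stride_ns: float = 5.0
    target_density_uM: float = 80000.0
    # the droplet is pre-formed: chains start packed at condensed-phase
    # density (a few molar in beads, ~25x the final box density) so the
    # grid-placed coils overlap into one droplet before equilibration
    initial_density_uM: float = 2.0e6
    temperature: float = 300.0
    ionic_strength_mM: float = 150.0
    em_tolerance: float = 1.0  # kJ/mol/nm
    em_max_iterations: int = 2000
    count_scale: float = 1.0  # scales the reference molecule amounts
    density_counts_all_beads: bool = True  # False: amino-acid beads only
    seed: int = 0
    dt_fs: float = 20.0
    tau_t: float = 100.0
    tau_p: float = 10.0

    def __post_init__(self) -> None:
        if min(self.nvt1_ns, self.npt_ns, self.production_ns) < 0:
            raise ValueError("stage durations must be >= 0")
        if self.target_density_uM <= 0:
            raise ValueError("density must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "ProtocolConfig":
        """Desk-scale preset: molecule counts / 24, sub-ns stages."""
        kw = dict(
            nvt1_ns=0.04,
            npt_ns=0.06,
            production_ns=0.4,
            sampling_stride_ns=0.05,
            count_scale=1.0 / 24.0,
            em_max_iterations=300,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def integrator(self, seed_offset: int = 0, thermostat: str = "langevin") -> IntegratorConfig:
        return IntegratorConfig(
            dt_fs=self.dt_fs,
            temperature=self.temperature,
            tau_t=self.tau_t,
            tau_p=self.tau_p,
            thermostat=thermostat,
            seed=self.seed + seed_offset,
        )


def compose_system(
    comp: PhaseComposition,
    *,
    rbp: ProteinSequence | str = "FUS_PLD_RGG1",
    rna: RNASequence | None = None,
    dpr: ProteinSequence | DPRSpec | None = None,
    count_scale: float = 1.0,
) -> list[tuple[Molecule, int]]:
    """Resolve a ternary composition into concrete (molecule, count) pairs.

    Zero-count species are dropped from the returned list.
    """
    if isinstance(rbp, str):
        rbp = get_rbp_sequence(rbp)
    if rna is None:
        rna = build_rna_sequence(40, "U")
    if dpr is None:
        dpr = DPRSpec("PR", 60)
    if isinstance(dpr, DPRSpec):
        dpr = build_dpr_sequence(dpr)
    n_rbp, n_rna, n_dpr = comp.resolved_counts(count_scale)
    out: list[tuple[Molecule, int]] = []
    if n_rbp:
        out.append((rbp, n_rbp))
    if n_rna:
        out.append((rna, n_rna))
    if n_dpr:
        out.append((dpr, n_dpr))
    if not out:
        raise ValueError("composition resolves to an empty system")
    return out


ROLES_BY_POSITION = ("rbp", "rna", "dpr")


def species_roles(species_counts: list[tuple[Molecule, int]]) -> dict[str, str]:
    """Map species names to protocol roles (rbp / rna / dpr) by kind."""
    roles: dict[str, str] = {}
    for mol, _ in species_counts:
        if isinstance(mol, RNASequence):
            roles[mol.name] = "rna"
        elif set(mol.residues) <= set("PRGA") and len(set(mol.residues)) <= 2:
            roles[mol.name] = "dpr"
        else:
            roles[mol.name] = "rbp"
    return roles


# ---------------------------------------------------------------------------
# initial placement
# ---------------------------------------------------------------------------

def _random_coil(
    mol: Molecule, params: ForceFieldParams, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk coil honoring the parameter file's bond lengths."""
    from cgdroplet.forcefield import _molecule_bonds

    bonds = _molecule_bonds(mol, params)
    n = len(mol.bead_codes)
    pos = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    placed[0] = True
    # bonds are emitted parent-before-child for linear/branched chains
    for i, j, r0 in bonds:
        parent, child = (i, j) if placed[i] else (j, i)
        if placed[child]:
            continue
        step = rng.standard_normal(3)
        step *= r0 / np.linalg.norm(step)
        pos[child] = pos[parent] + step
        placed[child] = True
    return pos - pos.mean(axis=0)


def place_on_grid(
    species_counts: list[tuple[Molecule, int]],
    box: np.ndarray | float,
    params: ForceFieldParams | None = None,
    seed: int = 0,
    min_separation: float = 0.2,
) -> tuple[SimulationState, SystemTopology]:
    """Place each molecule as a random coil with its COM on a regular grid.

    A single molecule sits at the box center.  Raises if the grid spacing
    would be smaller than twice the largest coil extent cap (box too small).
    A coil landing within ``min_separation`` of already-placed beads is
    re-drawn (hard-core overlap guard, best effort over a few attempts).
    """
    params = params or default_forcefield()
    box = np.asarray(box, dtype=float) * np.ones(3)
    topo = build_topology(species_counts, params)
    n_mol = topo.n_molecules
    n_grid = max(1, math.ceil(n_mol ** (1.0 / 3.0)))
    spacing = box / n_grid
    if np.any(spacing <= 0):
        raise ValueError("box too small for grid placement")
    rng = np.random.default_rng(np.random.PCG64(seed))

    nodes = []
    for a in range(n_grid):
        for b in range(n_grid):
            for c in range(n_grid):
                nodes.append((np.array([a, b, c]) + 0.5) * spacing)
    if n_mol == 1:
        nodes = [box / 2.0]

    positions = np.zeros((topo.n_beads, 3))
    start = 0
    from scipy.spatial import cKDTree

    for mol_idx in range(n_mol):
        info = topo.species_of_molecule(mol_idx)
        nb = info.n_beads_per_molecule
        # redraw the coil a few times if it lands on already-placed beads
        for _attempt in range(8):
            coil = _random_coil(info.molecule, params, rng) + nodes[mol_idx]
            if start == 0:
                break
            tree = cKDTree(np.mod(positions[:start], box), boxsize=box)
            if not tree.query_ball_point(
                np.mod(coil, box), min_separation, return_length=True
            ).any():
                break
        positions[start : start + nb] = coil
        start += nb
    state = SimulationState(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=box,
    )
    return state, topo


# ---------------------------------------------------------------------------
# unwrap / recenter / resize
# ---------------------------------------------------------------------------

def unwrap_molecules(state: SimulationState, topo: SystemTopology) -> np.ndarray:
    """Make every chain whole across periodic boundaries.

    Walks each molecule's bond graph, shifting every bead so bonded
    neighbors obey the minimum image relative to their parent.
    """
    pos = state.positions.copy()
    box = state.box
    n = topo.n_beads
    # adjacency from bonds
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in topo.bonds:
        adj[i].append(j)
        adj[j].append(i)
    visited = np.zeros(n, dtype=bool)
    for root in range(n):
        if visited[root]:
            continue
        visited[root] = True
        stack = [root]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if visited[j]:
                    continue
                d = pos[j] - pos[i]
                pos[j] = pos[i] + d - box * np.round(d / box)
                visited[j] = True
                stack.append(j)
    return pos


def density_to_volume(n_particles: int, density_uM: float) -> float:
    """V (nm^3) holding ``n_particles`` beads at a molar particle density."""
    number_density = density_uM * 1e-6 * N_AVOGADRO * 1e-24  # beads per nm^3
    return n_particles / number_density


def resize_box_to_density(
    state: SimulationState,
    topo: SystemTopology,
    target_density_uM: float,
    *,
    count_all_beads: bool = True,
) -> SimulationState:
    """New cubic box with V = N / (N_A c); contents unwrapped and recentered.

    ``count_all_beads=False`` restricts the density bookkeeping to
    amino-acid beads (the RNA beads then ride along without contributing
    to N).
    """
    if topo.n_beads == 0:
        raise ValueError("empty system")
    if count_all_beads:
        n = topo.n_beads
    else:
        protein_species = [s.name for s in topo.species if s.kind == "protein"]
        n = sum(len(topo.beads_of(nm)) for nm in protein_species)
        if n == 0:
            raise ValueError("no amino-acid beads to count")
    volume = density_to_volume(n, target_density_uM)
    edge = volume ** (1.0 / 3.0)
    pos = unwrap_molecules(state, topo)
    com = np.average(pos, axis=0, weights=topo.mass)
    new_box = np.full(3, edge)
    pos = pos - com + new_box / 2.0
    return SimulationState(
        positions=pos,
        velocities=state.velocities.copy(),
        box=new_box,
        time=state.time,
    )


# ---------------------------------------------------------------------------
# the droplet pipeline
# ---------------------------------------------------------------------------

STAGES = ("em1", "nvt1", "npt", "resize", "em2", "production")


@dataclass
class DropletRun:
    trajectory: Trajectory
    topology: SystemTopology
    final_state: SimulationState
    provenance: dict
    workdir: Path | None = None


def _ns_to_steps(ns: float, dt_fs: float) -> int:
    return int(round(ns * 1e6 / dt_fs))


def run_droplet_protocol(
    species_counts: list[tuple[Molecule, int]] | PhaseComposition,
    config: ProtocolConfig | None = None,
    params: ForceFieldParams | None = None,
    workdir: str | Path | None = None,
    resume: bool = False,
) -> DropletRun:
    """Run the six-stage droplet pipeline; returns the sampled production
    trajectory plus a provenance record.

    Stages: EM -> NVT -> NPT -> recenter/unwrap/resize-to-density -> EM ->
    NVT production.  Each stage's end state is persisted to ``workdir`` (if
    given) and reloaded when ``resume`` is set, making the pipeline
    restartable per stage.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    config = config or ProtocolConfig()
    params = params or default_forcefield()
    if isinstance(species_counts, PhaseComposition):
        species_counts = compose_system(
            species_counts, count_scale=config.count_scale
        )
    roles = species_roles(species_counts)

    wd = Path(workdir) if workdir is not None else None
    if wd is not None:
        wd.mkdir(parents=True, exist_ok=True)

    def stage_file(name: str) -> Path | None:
        return None if wd is None else wd / f"stage_{name}.npz"

    def save_state(name: str, st: SimulationState) -> None:
        f = stage_file(name)
        if f is not None:
            np.savez_compressed(
                f, positions=st.positions, velocities=st.velocities,
                box=st.box, time=st.time,
            )

    def load_state(name: str) -> SimulationState | None:
        f = stage_file(name)
        if resume and f is not None and f.exists():
            d = np.load(f)
            return SimulationState(
                d["positions"], d["velocities"], d["box"], float(d["time"])
            )
        return None

    provenance = {
        "config": asdict(config),
        "species": [
            {"name": m.name, "count": c, "role": roles[m.name]}
            for m, c in species_counts
        ],
        "stages": [],
    }

    # initial placement
    topo = build_topology(species_counts, params, roles=roles)
    n_density = topo.n_beads
    init_volume = density_to_volume(n_density, config.initial_density_uM)
    init_edge = init_volume ** (1.0 / 3.0)
    state, topo = place_on_grid(
        species_counts, init_edge, params, seed=config.seed
    )

    def run_stage(name, fn):
        cached = load_state(name)
        if cached is not None:
            provenance["stages"].append({"name": name, "resumed": True})
            return cached, None
        try:
            result = fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        st, extra = result if isinstance(result, tuple) else (result, None)
        save_state(name, st)
        provenance["stages"].append({"name": name, "resumed": False})
        return st, extra

    state, _ = run_stage(
        "em1", lambda: minimize_energy(state, topo, params, config.em_tolerance,
                                max_iterations=config.em_max_iterations)
    )

    def _nvt1():
        st = state.copy()
        rng = np.random.default_rng(np.random.PCG64(config.seed + 1))
        from cgdroplet.engine import maxwell_boltzmann_velocities

        st.velocities = maxwell_boltzmann_velocities(topo, config.temperature, rng)
        steps = _ns_to_steps(config.nvt1_ns, config.dt_fs)
        traj = run_nvt(st, topo, params, config.integrator(2), steps,
                       sample_every=max(1, steps))
        return traj.final_state

    state, _ = run_stage("nvt1", _nvt1)

    def _npt():
        steps = _ns_to_steps(config.npt_ns, config.dt_fs)
        traj = run_npt(state, topo, params, config.integrator(3), steps,
                       sample_every=max(1, steps))
        return traj.final_state

    state, _ = run_stage("npt", _npt)

    def _resize():
        return resize_box_to_density(
            state, topo, config.target_density_uM,
            count_all_beads=config.density_counts_all_beads,
        )

    state, _ = run_stage("resize", _resize)

    state, _ = run_stage(
        "em2", lambda: minimize_energy(state, topo, params, config.em_tolerance,
                                max_iterations=config.em_max_iterations)
    )

    prod_traj_holder: dict = {}

    def _production():
        steps = _ns_to_steps(config.production_ns, config.dt_fs)
        stride = max(1, _ns_to_steps(config.sampling_stride_ns, config.dt_fs))
        traj = run_nvt(state, topo, params, config.integrator(4), steps,
                       sample_every=stride)
        prod_traj_holder["traj"] = traj
        return traj.final_state

    final_state, _ = run_stage("production", _production)
    traj = prod_traj_holder.get("traj")
    if traj is None:
        # production resumed from disk: reload sampled frames if persisted
        f = wd / "production_traj.npz" if wd is not None else None
        traj = Trajectory()
        if f is not None and f.exists():
            d = np.load(f)
            for fr, bx, t in zip(d["frames"], d["boxes"], d["times"]):
                traj.frames.append(fr)
                traj.boxes.append(bx)
                traj.times.append(float(t))
        else:
            traj.add_frame(final_state)
        traj.final_state = final_state
    elif wd is not None:
        traj.save_npz(wd / "production_traj.npz")

    if wd is not None:
        with open(wd / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)

    return DropletRun(
        trajectory=traj,
        topology=topo,
        final_state=final_state,
        provenance=provenance,
        workdir=wd,
    )
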