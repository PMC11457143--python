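"""Synthetic configurations with known ground truth.

Every analysis and engine contract can be exercised without running any
dynamics: the generators here place molecules in exactly known geometries
(ideal gas, uniform sphere, core-shell, two blobs, marbled, lattice pairs)
and return the configuration together with a ground-truth record (true
cluster labels, true contact pairs, true radial extents).  Fixtures are
geometric, not thermodynamic: they are seed-deterministic and make no
claim of force-field realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cgdroplet.engine import SimulationState
from cgdroplet.forcefield import (
    ForceFieldParams,
    SystemTopology,
    build_topology,
    default_forcefield,
)
from cgdroplet.sequences import Molecule, build_dpr_sequence, DPRSpec

FIXTURE_KINDS = (
    "ideal_gas",
    "uniform_sphere",
    "core_shell",
    "two_blob",
    "marbled",
    "lattice_pairs",
)


@dataclass
class FixtureSpec:
    kind: str
    species_counts: Sequence[tuple[Molecule, int]] | None = None
    box: float = 60.0  # nm
    seed: int = 0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; allowed: {FIXTURE_KINDS}"
            )


@dataclass
class Fixture:
    state: SimulationState
    topology: SystemTopology
    ground_truth: dict


def _default_species(n: int) -> list[tuple[Molecule, int]]:
    return [(build_dpr_sequence(DPRSpec("GA", 5)), n)]


def _compact_molecule(nb: int, radius: float, rng) -> np.ndarray:
    """Beads of one chain packed inside a small ball (bonds not honored;
    geometric fixtures only)."""
    pts = rng.standard_normal((nb, 3))
    pts *= radius * rng.random((nb, 1)) ** (1 / 3) / np.linalg.norm(
        pts, axis=1, keepdims=True
    )
    return pts


def _place_molecules(topo, centers, mol_radius, rng):
    pos = np.zeros((topo.n_beads, 3))
    for m in range(topo.n_molecules):
        beads = np.where(topo.molecule_id == m)[0]
        pos[beads] = centers[m] + _compact_molecule(len(beads), mol_radius, rng)
    return pos


def make_fixture(spec: FixtureSpec, params: ForceFieldParams | None = None) -> Fixture:
    """Generate a configuration plus its ground-truth sidecar."""
    params = params or default_forcefield()
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    box = np.full(3, float(spec.box))
    g = dict(spec.geometry)

    if spec.kind == "ideal_gas":
        counts = spec.species_counts or _default_species(g.get("n", 100))
        topo = build_topology(counts, params)
        n_mol = topo.n_molecules
        # molecules on a sparse grid: guaranteed far apart
        n_grid = math.ceil(n_mol ** (1 / 3))
        spacing = box[0] / n_grid
        min_gap = g.get("min_gap", 4.0)
        if spacing < min_gap:
            raise ValueError(
                f"box {spec.box} too small for {n_mol} isolated molecules"
            )
        centers = []
        for a in range(n_grid):
            for b in range(n_grid):
                for c in range(n_grid):
                    centers.append((np.array([a, b, c]) + 0.5) * spacing)
        centers = np.array(centers[:n_mol])
        pos = _place_molecules(topo, centers, g.get("mol_radius", 0.5), rng)
        truth = {
            "cluster_labels": np.arange(n_mol),
            "n_clusters": n_mol,
            "phase_label": "no_LLPS",
        }

    elif spec.kind == "uniform_sphere":
        counts = spec.species_counts or _default_species(g.get("n", 300))
        topo = build_topology(counts, params)
        radius = g.get("radius", 6.0)
        centers = _uniform_ball(topo.n_molecules, radius, rng) + box / 2
        pos = _place_molecules(topo, centers, g.get("mol_radius", 0.5), rng)
        truth = {
            "cluster_labels": np.zeros(topo.n_molecules, dtype=int),
            "n_clusters": 1,
            "radius": radius,
            "center": box / 2,
            "phase_label": "full_LLPS",
        }

    elif spec.kind == "core_shell":
        core_counts = spec.species_counts or None
        if core_counts is None:
            core = _default_species(g.get("n_core", 150))[0]
            shell_mol = build_dpr_sequence(DPRSpec("GP", 5))
            shell = (shell_mol, g.get("n_shell", 400))
            counts = [core, shell]
        else:
            counts = list(spec.species_counts)
            if len(counts) != 2:
                raise ValueError("core_shell needs exactly two species")
        r_core = g.get("r_core", 5.0)
        r_inner = g.get("r_inner", 6.0)
        r_outer = g.get("r_outer", 8.5)
        if not (r_core < r_inner < r_outer):
            raise ValueError("impossible shell geometry: need r_core < r_inner < r_outer")
        topo = build_topology(counts, params)
        mols_core = topo.molecules_of(counts[0][0].name)
        mols_shell = topo.molecules_of(counts[1][0].name)
        centers = np.zeros((topo.n_molecules, 3))
        centers[mols_core] = _uniform_ball(len(mols_core), r_core, rng) + box / 2
        centers[mols_shell] = _uniform_shell(len(mols_shell), r_inner, r_outer, rng) + box / 2
        pos = _place_molecules(topo, centers, g.get("mol_radius", 0.5), rng)
        truth = {
            "core_species": counts[0][0].name,
            "shell_species": counts[1][0].name,
            "r_core": r_core,
            "r_outer": r_outer,
            "center": box / 2,
            "morphology": "core_shell",
        }

    elif spec.kind == "two_blob":
        if spec.species_counts and len(spec.species_counts) == 2:
            counts = list(spec.species_counts)
        else:
            a = _default_species(g.get("n_a", 120))[0]
            b = (build_dpr_sequence(DPRSpec("GP", 5)), g.get("n_b", 120))
            counts = [a, b]
        radius = g.get("radius", 4.0)
        gap = g.get("gap", 2.0 * radius + 6.0)  # well separated by default
        topo = build_topology(counts, params)
        mols_a = topo.molecules_of(counts[0][0].name)
        mols_b = topo.molecules_of(counts[1][0].name)
        c_a = box / 2 - np.array([gap / 2, 0, 0])
        c_b = box / 2 + np.array([gap / 2, 0, 0])
        centers = np.zeros((topo.n_molecules, 3))
        centers[mols_a] = _uniform_ball(len(mols_a), radius, rng) + c_a
        centers[mols_b] = _uniform_ball(len(mols_b), radius, rng) + c_b
        pos = _place_molecules(topo, centers, g.get("mol_radius", 0.4), rng)
        labels = np.zeros(topo.n_molecules, dtype=int)
        labels[mols_b] = 1
        truth = {
            "cluster_labels": labels,
            "n_clusters": 2,
            "centers": (c_a, c_b),
            "morphology": "separate",
        }

    elif spec.kind == "marbled":
        if spec.species_counts and len(spec.species_counts) == 2:
            counts = list(spec.species_counts)
        else:
            a = _default_species(g.get("n_a", 150))[0]
            b = (build_dpr_sequence(DPRSpec("GP", 5)), g.get("n_b", 150))
            counts = [a, b]
        radius = g.get("radius", 6.0)
        topo = build_topology(counts, params)
        # both species uniformly interleaved in one ball
        centers = _uniform_ball(topo.n_molecules, radius, rng) + box / 2
        pos = _place_molecules(topo, centers, g.get("mol_radius", 0.5), rng)
        truth = {
            "n_clusters": 1,
            "radius": radius,
            "center": box / 2,
            "morphology": "marbled",
        }

    elif spec.kind == "lattice_pairs":
        counts = spec.species_counts or _default_species(g.get("n", 16))
        topo = build_topology(counts, params)
        n_mol = topo.n_molecules
        if n_mol % 2:
            raise ValueError("lattice_pairs needs an even molecule count")
        k = n_mol // 2
        pair_dist = g.get("pair_distance", 0.8)
        n_grid = math.ceil(k ** (1 / 3))
        spacing = box[0] / n_grid
        stack = 1.2
        max_beads = max(
            s.n_beads_per_molecule for s in build_topology(counts, params).species
        )
        if spacing < 2.0 * stack * max_beads + 2.0:
            raise ValueError("box too small to isolate the lattice pairs")
        pos = np.zeros((topo.n_beads, 3))
        node = 0
        contact_pairs = []
        for a in range(n_grid):
            for b in range(n_grid):
                for c in range(n_grid):
                    if node >= k:
                        break
                    base = (np.array([a, b, c]) + 0.5) * spacing
                    m1, m2 = 2 * node, 2 * node + 1
                    b1 = np.where(topo.molecule_id == m1)[0]
                    b2 = np.where(topo.molecule_id == m2)[0]
                    # stack each chain's beads far apart; only bead 0 of each
                    # molecule forms the designed contact
                    for rank, bead in enumerate(b1):
                        pos[bead] = base + np.array([0.0, 0.0, stack * rank])
                    for rank, bead in enumerate(b2):
                        pos[bead] = base + np.array(
                            [pair_dist, 0.0, -stack * rank]
                        )
                    contact_pairs.append((int(b1[0]), int(b2[0])))
                    node += 1
        truth = {
            "n_contact_pairs": k,
            "contact_pairs": contact_pairs,
            "pair_distance": pair_dist,
            "cluster_labels": np.repeat(np.arange(k), 2),
        }

    else:  # pragma: no cover
        raise AssertionError

    state = SimulationState(
        positions=pos, velocities=np.zeros_like(pos), box=box
    )
    return Fixture(state=state, topology=topo, ground_truth=truth)


def _uniform_ball(n: int, radius: float, rng) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius * rng.random((n, 1)) ** (1 / 3)


def _uniform_shell(n: int, r_inner: float, r_outer: float, rng) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random((n, 1))
    r = (r_inner**3 + u * (r_outer**3 - r_inner**3)) ** (1 / 3)
    return v * r
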