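"""Bead chemistry, hydrophobicity calibration, and all energy/force terms.

The model is strictly parameter-file driven: a YAML file declares the bead
table (mass, charge, hydrophobicity epsilon on the [0, 1] scale, size, and
sticker category), the bonded constants, and the nonbonded constants.  The
packaged default file encodes the calibrated defaults used throughout the
test-suite and protocol presets.

Nonbonded interactions between beads i and j at distance r (nm):

* hydrophobic / excluded volume — Ashbaugh-Hatch scaling of a 12-6
  Lennard-Jones well: with ``u(r) = 4 e_hp [(s/r)^12 - (s/r)^6]``,
  ``s = (s_i + s_j)/2`` and ``lam = (eps_i + eps_j)/2``,

      U_hp(r) = u(r) + (1 - lam) e_hp      for r <= 2^(1/6) s
              = lam u(r)                   otherwise

  so a fully hydrophobic pair (lam = 1) sees the full well while a fully
  hydrophilic pair (lam = 0) sees only the repulsive core;
* cation-pi — an extra 12-6 well of depth ``e_cp`` between cationic (R, K)
  and aromatic (Y, F, W) beads, representing the sticker interaction that
  generic hydrophobic contacts do not capture;
* electrostatics — Debye-Hueckel screened Coulomb,
  ``U_el(r) = f q_i q_j exp(-r / lambda_D) / (eps_r r)`` with
  ``f = 138.935458 kJ mol^-1 nm e^-2``.

Every term is shifted so it vanishes continuously at the single nonbonded
cutoff.  Bonds are harmonic; angle/torsion terms are schema-supported but
disabled in the packaged defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from numba import njit

from cgdroplet.sequences import Molecule, ProteinSequence, RNASequence

# --- physical constants (GROMACS-style units: kJ/mol, nm, ps, amu, e) ---
KB = 0.008314462618  # kJ mol^-1 K^-1
F_COULOMB = 138.935458  # kJ mol^-1 nm e^-2
N_AVOGADRO = 6.02214076e23  # mol^-1
BAR_PER_KJ_NM3 = 16.6054  # 1 kJ mol^-1 nm^-3 in bar

CATEGORIES = (
    "aromatic",
    "aliphatic",
    "cationic",
    "anionic",
    "hydrophilic",
    "backbone-RNA",
    "base-RNA",
)

_CATEGORY_BY_CODE = {
    "Y": "aromatic", "F": "aromatic", "W": "aromatic",
    "R": "cationic", "K": "cationic",
    "D": "anionic", "E": "anionic",
}


class ForceFieldError(ValueError):
    pass


@dataclass(frozen=True)
class BeadType:
    """Per-bead chemistry: one amino acid or one RNA interaction site."""

    code: str
    mass: float  # amu
    charge: float  # e
    epsilon: float  # dimensionless hydrophobicity in [0, 1]
    sigma: float  # nm
    category: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ForceFieldError(
                f"bead {self.code}: epsilon {self.epsilon} outside [0, 1]"
            )
        if self.category not in CATEGORIES:
            raise ForceFieldError(
                f"bead {self.code}: unknown category {self.category!r}"
            )
        expected = _CATEGORY_BY_CODE.get(self.code)
        if expected is not None and self.category != expected:
            raise ForceFieldError(
                f"bead {self.code}: category must be {expected!r}"
            )


@dataclass(frozen=True)
class HydrophobicityCalibration:
    """Linear map from Kapcha-Rossky bead hydrophobicity to the [0, 1] scale."""

    slope: float
    intercept: float
    kr_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ForceFieldError("calibration slope must be nonzero")


@dataclass
class ForceFieldParams:
    bead_types: dict[str, BeadType]
    # bonded
    bond_force_constant: float
    protein_bond_length: float
    rna_bond_lengths: dict[str, float]
    angles_enabled: bool
    # nonbonded
    hydrophobic_strength: float
    cation_pi_strength: float
    relative_permittivity: float
    ionic_strength_mM: float
    temperature_K: float
    cutoff: float
    min_distance: float
    calibration: HydrophobicityCalibration | None = None

    @property
    def debye_length_nm(self) -> float:
        return debye_length(
            self.ionic_strength_mM, self.temperature_K, self.relative_permittivity
        )

    def require_bead(self, code: str) -> BeadType:
        try:
            return self.bead_types[code]
        except KeyError:
            raise ForceFieldError(f"unknown bead code {code!r}") from None


def load_forcefield(path) -> ForceFieldParams:
    """Load and validate a YAML parameter file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    beads = {
        code: BeadType(code=code, **entry) for code, entry in raw["beads"].items()
    }
    nb = raw["nonbonded"]
    bd = raw["bonded"]
    calib_raw = raw.get("hydrophobicity_calibration")
    calib = None
    if calib_raw is not None:
        calib = HydrophobicityCalibration(
            slope=calib_raw["slope"],
            intercept=calib_raw["intercept"],
            kr_values=dict(calib_raw.get("kr_values", {})),
        )
    params = ForceFieldParams(
        bead_types=beads,
        bond_force_constant=bd["bond_force_constant"],
        protein_bond_length=bd["protein_bond_length"],
        rna_bond_lengths=dict(bd["rna_bonds"]),
        angles_enabled=bool(bd.get("angles_enabled", False)),
        hydrophobic_strength=nb["hydrophobic_strength"],
        cation_pi_strength=nb["cation_pi_strength"],
        relative_permittivity=nb["relative_permittivity"],
        ionic_strength_mM=nb["ionic_strength_mM"],
        temperature_K=nb["temperature_K"],
        cutoff=nb["cutoff_nm"],
        min_distance=nb["min_distance_nm"],
        calibration=calib,
    )
    if params.cutoff <= 0:
        raise ForceFieldError("cutoff must be positive")
    # the packaged calibration must reproduce the packaged RNA bead epsilons
    if calib is not None:
        mapped = map_hydrophobicity(calib.kr_values, calib)
        for code, eps in mapped.items():
            if code in beads and abs(eps - beads[code].epsilon) > 1e-9:
                raise ForceFieldError(
                    f"calibration maps {code} to {eps}, bead table says "
                    f"{beads[code].epsilon}"
                )
    return params


_DEFAULT_CACHE: ForceFieldParams | None = None


def default_forcefield() -> ForceFieldParams:
    """The packaged default parameter file (loaded once, then cached)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        path = Path(resources.files("cgdroplet") / "data" / "forcefield.yaml")
        _DEFAULT_CACHE = load_forcefield(path)
    return _DEFAULT_CACHE


def map_hydrophobicity(
    kr_values: Mapping[str, float] | Sequence[float],
    calib: HydrophobicityCalibration,
    *,
    tolerance: float = 1e-9,
) -> dict[str, float] | list[float]:
    """Apply the linear Kapcha-Rossky -> [0, 1] hydrophobicity map.

    Mapped values must land in [0, 1] (within ``tolerance``, then clipped);
    anything further outside is rejected with the offending bead named.
    """
    def _map_one(name, v):
        e = calib.slope * v + calib.intercept
        if e < -tolerance or e > 1.0 + tolerance:
            raise ForceFieldError(
                f"mapped hydrophobicity for {name} is {e:.4f}, outside [0, 1]"
            )
        return min(max(e, 0.0), 1.0)

    if isinstance(kr_values, Mapping):
        return {k: _map_one(k, v) for k, v in kr_values.items()}
    return [_map_one(i, v) for i, v in enumerate(kr_values)]


def debye_length(
    ionic_strength_mM: float,
    temperature: float = 300.0,
    relative_permittivity: float = 80.0,
) -> float:
    """Debye screening length (nm) for a 1:1 electrolyte.

    lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I)); at 150 mM, 300 K and
    eps_r = 80 this is ~0.78 nm.
    """
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive")
    # in these units: lambda_D^2 = eps_r kB T / (8 pi f I_nm)  with
    # I_nm the ion number density in nm^-3 and f the Coulomb constant.
    i_nm3 = ionic_strength_mM * 1e-3 * N_AVOGADRO * 1e-24  # ions per nm^3
    lam2 = relative_permittivity * KB * temperature / (
        8.0 * math.pi * F_COULOMB * i_nm3
    )
    return math.sqrt(lam2)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class SpeciesInfo:
    name: str
    kind: str  # "protein" | "rna"
    n_molecules: int
    n_beads_per_molecule: int
    role: str | None = None  # "rbp" | "rna" | "dpr" (protocol bookkeeping)
    molecule: Molecule | None = None


@dataclass
class SystemTopology:
    """Chains, bonds and per-bead parameters for a composed mixture."""

    bead_codes: list[str]
    epsilon: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    sticker: np.ndarray  # int8: 0 other, 1 aromatic, 2 cationic
    bonds: np.ndarray  # (n_bonds, 2) int64
    bond_r0: np.ndarray
    bond_k: np.ndarray
    molecule_id: np.ndarray  # int64 per bead
    residue_index: np.ndarray  # bead position within its chain
    species_index: np.ndarray  # per molecule -> index into species
    species: list[SpeciesInfo]

    @property
    def n_beads(self) -> int:
        return len(self.bead_codes)

    @property
    def n_molecules(self) -> int:
        return len(self.species_index)

    def molecules_of(self, species_name: str) -> np.ndarray:
        """Molecule ids belonging to a named species."""
        idx = [i for i, s in enumerate(self.species) if s.name == species_name]
        if not idx:
            raise KeyError(f"species {species_name!r} not in topology")
        return np.where(np.isin(self.species_index, idx))[0]

    def beads_of(self, species_name: str) -> np.ndarray:
        mols = self.molecules_of(species_name)
        return np.where(np.isin(self.molecule_id, mols))[0]

    def species_of_molecule(self, mol: int) -> SpeciesInfo:
        return self.species[self.species_index[mol]]


def _molecule_bonds(mol: Molecule, params: ForceFieldParams) -> list[tuple[int, int, float]]:
    """Local bond list (i, j, r0) for one chain starting at bead 0."""
    out: list[tuple[int, int, float]] = []
    if isinstance(mol, ProteinSequence):
        r0 = params.protein_bond_length
        for i in range(len(mol.residues) - 1):
            out.append((i, i + 1, r0))
    elif isinstance(mol, RNASequence):
        pr = params.rna_bond_lengths["phosphate_ribose"]
        rb = params.rna_bond_lengths["ribose_base"]
        rp = params.rna_bond_lengths["ribose_phosphate"]
        n = len(mol.nucleotides)
        for k in range(n):
            p, r, b = 3 * k, 3 * k + 1, 3 * k + 2
            out.append((p, r, pr))
            out.append((r, b, rb))
            if k + 1 < n:
                out.append((r, 3 * (k + 1), rp))  # backbone link via phosphate
    else:  # pragma: no cover
        raise TypeError(f"unsupported molecule type {type(mol)!r}")
    return out


def build_topology(
    species_counts: Sequence[tuple[Molecule, int]],
    params: ForceFieldParams,
    *,
    roles: Mapping[str, str] | None = None,
) -> SystemTopology:
    """Compose a mixture into a bead-level topology.

    ``species_counts`` is an ordered list of ``(molecule, count)`` pairs;
    molecules of one species are laid out contiguously.  Every bead code must
    resolve in the parameter file's bead table.
    """
    roles = dict(roles or {})
    total = sum(c for _, c in species_counts)
    if total < 1:
        raise ValueError("empty system: at least one molecule required")

    codes: list[str] = []
    bonds: list[tuple[int, int]] = []
    bond_r0: list[float] = []
    mol_id: list[int] = []
    res_idx: list[int] = []
    species: list[SpeciesInfo] = []
    species_index: list[int] = []

    offset = 0
    mol_counter = 0
    for s_i, (mol, count) in enumerate(species_counts):
        if count < 0:
            raise ValueError("species counts must be >= 0")
        bead_codes = mol.bead_codes
        for code in bead_codes:
            params.require_bead(code)
        local_bonds = _molecule_bonds(mol, params)
        kind = "rna" if isinstance(mol, RNASequence) else "protein"
        species.append(
            SpeciesInfo(
                name=mol.name,
                kind=kind,
                n_molecules=count,
                n_beads_per_molecule=len(bead_codes),
                role=roles.get(mol.name),
                molecule=mol,
            )
        )
        for _ in range(count):
            codes.extend(bead_codes)
            for i, j, r0 in local_bonds:
                bonds.append((offset + i, offset + j))
                bond_r0.append(r0)
            mol_id.extend([mol_counter] * len(bead_codes))
            res_idx.extend(range(len(bead_codes)))
            species_index.append(s_i)
            mol_counter += 1
            offset += len(bead_codes)

    table = params.bead_types
    eps = np.array([table[c].epsilon for c in codes])
    sig = np.array([table[c].sigma for c in codes])
    q = np.array([table[c].charge for c in codes])
    m = np.array([table[c].mass for c in codes])
    sticker = np.zeros(len(codes), dtype=np.int8)
    for i, c in enumerate(codes):
        cat = table[c].category
        if cat == "aromatic":
            sticker[i] = 1
        elif cat == "cationic":
            sticker[i] = 2
    bonds_arr = (
        np.array(bonds, dtype=np.int64)
        if bonds
        else np.zeros((0, 2), dtype=np.int64)
    )
    return SystemTopology(
        bead_codes=codes,
        epsilon=eps,
        sigma=sig,
        charge=q,
        mass=m,
        sticker=sticker,
        bonds=bonds_arr,
        bond_r0=np.array(bond_r0),
        bond_k=np.full(len(bond_r0), params.bond_force_constant),
        molecule_id=np.array(mol_id, dtype=np.int64),
        residue_index=np.array(res_idx, dtype=np.int64),
        species_index=np.array(species_index, dtype=np.int64),
        species=species,
    )


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _nonbonded_kernel(
    pos, box, pi, pj, s2, c_in, c_out, u0_in, shift, qqc,
    lam_d, rc2, cap2, forces,
):
    """Accumulate nonbonded forces from per-pair coefficient tables.

    The Ashbaugh-Hatch + cation-pi terms are folded into two 12-6
    coefficients per pair (inside/outside the LJ minimum); ``shift``
    carries the total cutoff shift including the screened-Coulomb part.
    Returns (energy, virial, min squared distance seen).
    """
    energy = 0.0
    virial = 0.0
    r2min_seen = 1e30
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < r2min_seen:
            r2min_seen = r2
        if r2 < cap2:
            r2 = cap2  # evaluation floor; true overlaps reported by caller
        sr2 = s2[k] / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        # branch at the LJ minimum: r <= 2^(1/6) s  <=>  r2 <= 2^(1/3) s2
        if r2 <= 1.2599210498948732 * s2[k]:
            u = c_in[k] * (sr12 - sr6) + u0_in[k] - shift[k]
            f_r = 6.0 * c_in[k] * (2.0 * sr12 - sr6)  # = -r dU/dr
        else:
            u = c_out[k] * (sr12 - sr6) - shift[k]
            f_r = 6.0 * c_out[k] * (2.0 * sr12 - sr6)
        qq = qqc[k]
        if qq != 0.0:
            r = math.sqrt(r2)
            ue = qq * math.exp(-r / lam_d) / r
            u += ue  # cutoff shift already folded into shift[k]
            f_r += ue * (1.0 + r / lam_d)
        energy += u
        fscale = f_r / r2  # f_vec = fscale * r_vec
        fx = fscale * dx
        fy = fscale * dy
        fz = fscale * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial += f_r  # sum of (-dU/dr) * r = f . r
    return energy, virial, r2min_seen


def _prepare_pair_tables(pi, pj, topo: SystemTopology, params: ForceFieldParams):
    """Vectorized per-pair coefficient tables for the nonbonded kernel."""
    e_hp = params.hydrophobic_strength
    e_cp = params.cation_pi_strength
    rc = params.cutoff
    lam_d = params.debye_length_nm
    s = 0.5 * (topo.sigma[pi] + topo.sigma[pj])
    s2 = s * s
    lam = 0.5 * (topo.epsilon[pi] + topo.epsilon[pj])
    sticker_sum = topo.sticker[pi].astype(np.int64) + topo.sticker[pj]
    catpi = (sticker_sum == 3) & (topo.sticker[pi] != topo.sticker[pj])
    ecp = np.where(catpi, e_cp, 0.0)
    c_in = 4.0 * (e_hp + ecp)
    c_out = 4.0 * (lam * e_hp + ecp)
    u0_in = (1.0 - lam) * e_hp
    src6 = (s2 / (rc * rc)) ** 3
    qqc = (F_COULOMB / params.relative_permittivity) * (
        topo.charge[pi] * topo.charge[pj]
    )
    shift = c_out * (src6 * src6 - src6) + qqc * math.exp(-rc / lam_d) / rc
    return s2, c_in, c_out, u0_in, shift, qqc


@njit(cache=True)
def _bond_kernel(pos, box, bonds, r0, kbond, forces):
    energy = 0.0
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        delta = r - r0[b]
        energy += 0.5 * kbond[b] * delta * delta
        f_over_r = -kbond[b] * delta / r
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial += -kbond[b] * delta * r
    return energy, virial


def pair_energy(
    type_i: str | BeadType,
    type_j: str | BeadType,
    r: float,
    params: ForceFieldParams,
) -> float:
    """Nonbonded pair energy (kJ/mol) between two bead types at distance r.

    Uses exactly the shifted-at-cutoff forms the engine integrates, so the
    value is zero at and beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    bi = params.require_bead(type_i) if isinstance(type_i, str) else type_i
    bj = params.require_bead(type_j) if isinstance(type_j, str) else type_j
    rc = params.cutoff
    if r >= rc:
        return 0.0
    e_hp = params.hydrophobic_strength
    s = 0.5 * (bi.sigma + bj.sigma)
    lam = 0.5 * (bi.epsilon + bj.epsilon)
    sr6 = (s / r) ** 6
    src6 = (s / rc) ** 6
    ulj = 4 * e_hp * (sr6**2 - sr6)
    uljc = 4 * e_hp * (src6**2 - src6)
    if r <= 2 ** (1 / 6) * s:
        u = ulj + (1 - lam) * e_hp - lam * uljc
    else:
        u = lam * (ulj - uljc)
    cats = {bi.category, bj.category}
    if cats == {"aromatic", "cationic"}:
        e_cp = params.cation_pi_strength
        u += 4 * e_cp * (sr6**2 - sr6) - 4 * e_cp * (src6**2 - src6)
    qq = bi.charge * bj.charge
    if qq != 0:
        lam_d = params.debye_length_nm
        pref = F_COULOMB * qq / params.relative_permittivity
        u += pref * math.exp(-r / lam_d) / r - pref * math.exp(-rc / lam_d) / rc
    return u


class OverlapError(RuntimeError):
    """Two beads closer than the parameter file's minimum distance."""


def total_energy_and_forces(
    state,
    topo: SystemTopology,
    params: ForceFieldParams,
    *,
    pairs=None,
    return_virial: bool = False,
    pairs_prepared: bool = False,
):
    """Total potential energy and per-bead forces for a simulation state.

    ``pairs`` may carry a precomputed candidate pair array (n, 2); otherwise
    all pairs within the cutoff are found with a periodic KD-tree.  Bonded
    (1-2) pairs are excluded from the nonbonded sum.  Forces are -grad U
    under the minimum-image convention.
    """
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    box = np.asarray(state.box, dtype=np.float64)
    if not np.all(np.isfinite(pos)):
        bad = np.where(~np.isfinite(pos).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates for bead(s) {bad[:5]}")
    if pairs_prepared:
        pi, pj, tables = pairs
    else:
        if pairs is None:
            from cgdroplet.engine import neighbor_list

            pairs = neighbor_list(state, params.cutoff, 0.0).pairs
        pairs = _exclude_bonded(pairs, topo)
        pi = np.ascontiguousarray(pairs[:, 0])
        pj = np.ascontiguousarray(pairs[:, 1])
        tables = _prepare_pair_tables(pi, pj, topo, params)

    forces = np.zeros_like(pos)
    cap = max(params.min_distance, 0.1)  # evaluation floor against overflow
    e_nb, w_nb, r2min = _nonbonded_kernel(
        pos,
        box,
        pi,
        pj,
        *tables,
        params.debye_length_nm,
        params.cutoff**2,
        cap * cap,
        forces,
    )
    if r2min < params.min_distance**2:
        raise OverlapError(
            f"bead pair at r={math.sqrt(r2min):.2e} nm < min_distance="
            f"{params.min_distance} nm"
        )
    e_b, w_b = _bond_kernel(
        pos, box, topo.bonds, topo.bond_r0, topo.bond_k, forces
    )
    if return_virial:
        return e_nb + e_b, forces, w_nb + w_b
    return e_nb + e_b, forces


def _exclude_bonded(pairs: np.ndarray, topo: SystemTopology) -> np.ndarray:
    """Drop 1-2 bonded pairs from a candidate pair array."""
    if len(topo.bonds) == 0 or len(pairs) == 0:
        return pairs
    n = topo.n_beads
    cache = getattr(topo, "_bonded_keys_sorted", None)
    if cache is None:
        blo = np.minimum(topo.bonds[:, 0], topo.bonds[:, 1])
        bhi = np.maximum(topo.bonds[:, 0], topo.bonds[:, 1])
        cache = np.sort(blo * n + bhi)
        topo._bonded_keys_sorted = cache
    lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    keys = lo * n + hi
    idx = np.searchsorted(cache, keys)
    idx[idx == len(cache)] = len(cache) - 1
    mask = cache[idx] != keys
    return pairs[mask]
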