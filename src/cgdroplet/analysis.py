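"""Condensate observables: contact maps, interaction fractions, phase
classification, radial profiles, charge ratios and droplet morphology.

Conventions (all config-exposed and echoed in every output record):

* a *contact* is an inter-molecular bead pair within ``cutoff`` (default
  1.0 nm) under the minimum image;
* contact maps are averaged over frames and normalized by the number of
  molecules of the row species;
* molecules are clustered by single linkage: two molecules join a cluster
  when any inter-molecular bead pair is within ``cluster_cutoff``;
* a system phase-separates when the largest cluster holds at least half of
  all beads; a species has a significant dilute phase when at least 10% of
  its molecules sit outside the largest cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from cgdroplet.engine import SimulationState, Trajectory
from cgdroplet.forcefield import ForceFieldParams, SystemTopology, default_forcefield
from cgdroplet.sequences import sequence_statistics

DEFAULT_CONTACT_CUTOFF = 1.0  # nm
DEFAULT_CLUSTER_CUTOFF = 1.5  # nm

#: interaction classes in reporting order
INTERACTION_CLASSES = (
    "aromatic",
    "cation-pi",
    "electrostatic",
    "aliphatic",
    "aromatic-aliphatic",
    "hydrophilic-other",
)


class AnalysisError(ValueError):
    pass


def _frames_of(traj_or_state) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(traj_or_state, Trajectory):
        return list(zip(traj_or_state.frames, traj_or_state.boxes))
    if isinstance(traj_or_state, SimulationState):
        return [(traj_or_state.positions, traj_or_state.box)]
    raise TypeError("expected Trajectory or SimulationState")


def _wrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    w = np.mod(pos, box)
    w[w >= box] = 0.0
    return w


def _pairs_within(pos, box, cutoff) -> np.ndarray:
    tree = cKDTree(_wrap(pos, box), boxsize=box)
    return tree.query_pairs(cutoff, output_type="ndarray").astype(np.int64)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Time-averaged, molecule-normalized intermolecular contact matrix.

    ``matrix[a, b]`` counts contacts between position/type ``a`` of species
    A and position/type ``b`` of species B, averaged over frames and
    divided by the number of A molecules.  ``row_labels``/``col_labels``
    are residue indices (by-index map) or bead type codes (by-type map).
    """

    species_a: str
    species_b: str
    matrix: np.ndarray
    row_labels: list
    col_labels: list
    cutoff: float
    n_frames: int
    normalization: str = "per molecule of row species"

    def profile(self, axis: int = 0) -> np.ndarray:
        """1D contact profile N_contact: summation of the 2D map."""
        return self.matrix.sum(axis=1 - axis)

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def transpose(self) -> "ContactMap":
        return ContactMap(
            species_a=self.species_b,
            species_b=self.species_a,
            matrix=self.matrix.T.copy(),
            row_labels=list(self.col_labels),
            col_labels=list(self.row_labels),
            cutoff=self.cutoff,
            n_frames=self.n_frames,
            normalization=self.normalization,
        )


def contact_map(
    traj,
    topo: SystemTopology,
    species_a: str,
    species_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactMap:
    """Intermolecular contact map by residue (bead-position) index.

    Only pairs of beads on *different* molecules are counted; the raw count
    is averaged over frames and normalized by the number of molecules of
    ``species_a``.  For ``species_a == species_b`` each unordered bead pair
    contributes to both (i, j) and (j, i), making the map symmetric.
    """
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    beads_a = topo.beads_of(species_a)  # raises if absent
    beads_b = topo.beads_of(species_b)
    info_a = next(s for s in topo.species if s.name == species_a)
    info_b = next(s for s in topo.species if s.name == species_b)
    na, nb = info_a.n_beads_per_molecule, info_b.n_beads_per_molecule

    in_a = np.zeros(topo.n_beads, dtype=bool)
    in_a[beads_a] = True
    in_b = np.zeros(topo.n_beads, dtype=bool)
    in_b[beads_b] = True

    frames = _frames_of(traj)
    matrix = np.zeros((na, nb))
    for pos, box in frames:
        pairs = _pairs_within(pos, box, cutoff)
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        inter = topo.molecule_id[i] != topo.molecule_id[j]
        for ii, jj in ((i, j), (j, i)):
            sel = inter & in_a[ii] & in_b[jj]
            if not np.any(sel):
                continue
            np.add.at(
                matrix,
                (topo.residue_index[ii[sel]], topo.residue_index[jj[sel]]),
                1.0,
            )
    matrix /= len(frames) * info_a.n_molecules
    return ContactMap(
        species_a=species_a,
        species_b=species_b,
        matrix=matrix,
        row_labels=list(range(na)),
        col_labels=list(range(nb)),
        cutoff=cutoff,
        n_frames=len(frames),
    )


def aggregate_by_type(
    cm: ContactMap,
    row_types: Sequence[str],
    col_types: Sequence[str] | None = None,
) -> ContactMap:
    """Sum-aggregate a by-index map over a residue-type partition.

    ``row_types[i]`` is the type label of row index i (the partition must
    cover every index).  Totals are conserved exactly.
    """
    col_types = row_types if col_types is None else col_types
    if len(row_types) != cm.matrix.shape[0] or len(col_types) != cm.matrix.shape[1]:
        raise AnalysisError(
            "type partition does not cover the contact-map indices"
        )
    row_labels = sorted(set(row_types))
    col_labels = sorted(set(col_types))
    out = np.zeros((len(row_labels), len(col_labels)))
    r_idx = {t: k for k, t in enumerate(row_labels)}
    c_idx = {t: k for k, t in enumerate(col_labels)}
    for i, ti in enumerate(row_types):
        for j, tj in enumerate(col_types):
            out[r_idx[ti], c_idx[tj]] += cm.matrix[i, j]
    return ContactMap(
        species_a=cm.species_a,
        species_b=cm.species_b,
        matrix=out,
        row_labels=row_labels,
        col_labels=col_labels,
        cutoff=cm.cutoff,
        n_frames=cm.n_frames,
        normalization=cm.normalization + " (aggregated by type)",
    )


# ---------------------------------------------------------------------------
# interaction-type fractions
# ---------------------------------------------------------------------------

@dataclass
class InteractionSummary:
    """F_int per interaction class; fractions sum to 1."""

    fractions: dict[str, float]
    total_contacts: float
    cutoff: float

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]


def classify_pair(cat_i: str, cat_j: str, charge_i: float, charge_j: float) -> str:
    """Interaction class of an (unordered) bead-type pair.

    cation-pi covers {R, K} x {Y, F, W}; electrostatic covers opposite-charge
    pairs (including the RNA phosphate); aromatic and aliphatic denote
    aromatic-aromatic and aliphatic-aliphatic contacts respectively.
    """
    cats = {cat_i, cat_j}
    if cats == {"aromatic"}:
        return "aromatic"
    if cats == {"aromatic", "cationic"}:
        return "cation-pi"
    if charge_i * charge_j < 0:
        return "electrostatic"
    if cats == {"aliphatic"}:
        return "aliphatic"
    if cats == {"aromatic", "aliphatic"}:
        return "aromatic-aliphatic"
    return "hydrophilic-other"


def interaction_fractions(
    cm_by_type: ContactMap,
    params: ForceFieldParams | None = None,
    class_rules=classify_pair,
) -> InteractionSummary:
    """Aggregate a by-type contact map into interaction-class fractions.

    Raises on a zero-contact map (no silent zeros).
    """
    params = params or default_forcefield()
    total = cm_by_type.total
    if total <= 0:
        raise AnalysisError("contact map has zero total contacts")
    sums = {c: 0.0 for c in INTERACTION_CLASSES}
    for i, ti in enumerate(cm_by_type.row_labels):
        bi = params.require_bead(ti)
        for j, tj in enumerate(cm_by_type.col_labels):
            bj = params.require_bead(tj)
            cls = class_rules(bi.category, bj.category, bi.charge, bj.charge)
            sums.setdefault(cls, 0.0)
            sums[cls] += cm_by_type.matrix[i, j]
    fractions = {c: v / total for c, v in sums.items()}
    return InteractionSummary(
        fractions=fractions, total_contacts=total, cutoff=cm_by_type.cutoff
    )


# ---------------------------------------------------------------------------
# clustering and phase classification
# ---------------------------------------------------------------------------

def detect_clusters(
    frame: SimulationState | tuple[np.ndarray, np.ndarray],
    topo: SystemTopology,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> np.ndarray:
    """Single-linkage cluster label per molecule.

    Molecules are linked when any inter-molecular bead pair is within
    ``cluster_cutoff`` (minimum image respected).  Labels are 0-based and
    ordered by first molecule id.
    """
    if isinstance(frame, SimulationState):
        pos, box = frame.positions, frame.box
    else:
        pos, box = frame
    pairs = _pairs_within(pos, box, cluster_cutoff)
    n_mol = topo.n_molecules
    parent = np.arange(n_mol)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if len(pairs):
        mi = topo.molecule_id[pairs[:, 0]]
        mj = topo.molecule_id[pairs[:, 1]]
        for a, b in zip(mi, mj):
            if a == b:
                continue
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(m) for m in range(n_mol)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


@dataclass
class PhaseRegion:
    """Four-region phase label plus the fractions that produced it."""

    label: str  # no_LLPS | full_LLPS | dilute_RNA | dilute_DPR
    largest_cluster_fraction: float
    dilute_fraction: dict[str, float]  # per species name
    thresholds: dict = field(default_factory=dict)


def largest_cluster_info(
    frame, topo: SystemTopology, cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
):
    """(labels, id of largest cluster by bead count, bead fraction in it)."""
    labels = detect_clusters(frame, topo, cluster_cutoff)
    beads_per_mol = np.bincount(topo.molecule_id)
    sizes = np.bincount(labels, weights=beads_per_mol)
    big = int(np.argmax(sizes))
    frac = float(sizes[big] / topo.n_beads)
    return labels, big, frac


def classify_phase(
    traj,
    topo: SystemTopology,
    *,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    llps_threshold: float = 0.5,
    dilute_threshold: float = 0.10,
    equilibration_fraction: float = 1.0 / 3.0,
    min_frames: int = 1,
) -> PhaseRegion:
    """Assign one of the four phase-diagram regions from a trajectory.

    The first ``equilibration_fraction`` of the frames is discarded; the
    remaining frames are averaged.  LLPS requires the largest cluster to
    hold at least ``llps_threshold`` of all beads; a species is "in the
    dilute phase" when at least ``dilute_threshold`` of its molecules fall
    outside the largest cluster.  Roles (rna / dpr) come from the topology's
    species records.
    """
    frames = _frames_of(traj)
    start = int(len(frames) * equilibration_fraction)
    use = frames[start:] if len(frames) > 1 else frames
    if len(use) < min_frames:
        raise AnalysisError(
            f"too few frames after equilibration window ({len(use)} < {min_frames})"
        )
    cluster_fracs = []
    dilute: dict[str, list[float]] = {s.name: [] for s in topo.species}
    for pos, box in use:
        labels, big, frac = largest_cluster_info(
            SimulationState(pos, np.zeros_like(pos), box), topo, cluster_cutoff
        )
        cluster_fracs.append(frac)
        for s in topo.species:
            mols = topo.molecules_of(s.name)
            outside = np.mean(labels[mols] != big)
            dilute[s.name].append(float(outside))
    mean_frac = float(np.mean(cluster_fracs))
    mean_dilute = {k: float(np.mean(v)) for k, v in dilute.items()}

    role_dilute = {"rna": 0.0, "dpr": 0.0}
    for s in topo.species:
        if s.role in role_dilute:
            role_dilute[s.role] = max(role_dilute[s.role], mean_dilute[s.name])

    if mean_frac < llps_threshold:
        label = "no_LLPS"
    elif (
        role_dilute["rna"] >= dilute_threshold
        and role_dilute["rna"] >= role_dilute["dpr"]
    ):
        label = "dilute_RNA"
    elif role_dilute["dpr"] >= dilute_threshold:
        label = "dilute_DPR"
    else:
        label = "full_LLPS"
    return PhaseRegion(
        label=label,
        largest_cluster_fraction=mean_frac,
        dilute_fraction=mean_dilute,
        thresholds={
            "cluster_cutoff": cluster_cutoff,
            "llps_threshold": llps_threshold,
            "dilute_threshold": dilute_threshold,
            "equilibration_fraction": equilibration_fraction,
        },
    )


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    r: np.ndarray  # bin centers, nm
    density: dict[str, np.ndarray]  # species -> beads / nm^3
    bin_width: float
    center: np.ndarray
    about_cluster: bool
    flags: list[str] = field(default_factory=list)

    def integrated_counts(self, species: str) -> float:
        shell = 4.0 * np.pi * self.r**2 * self.bin_width
        return float(np.sum(self.density[species] * shell))


def _cluster_center(pos, box, topo, cluster_cutoff) -> tuple[np.ndarray, bool]:
    state = SimulationState(pos, np.zeros_like(pos), box)
    labels, big, frac = largest_cluster_info(state, topo, cluster_cutoff)
    mols_in = np.where(labels == big)[0]
    sel = np.isin(topo.molecule_id, mols_in)
    if frac <= 0 or not np.any(sel):
        return box / 2.0, False
    # center via circular mean per axis (PBC-safe)
    center = np.empty(3)
    for ax in range(3):
        theta = 2.0 * np.pi * np.mod(pos[sel, ax], box[ax]) / box[ax]
        w = topo.mass[sel]
        c = np.average(np.cos(theta), weights=w)
        s = np.average(np.sin(theta), weights=w)
        center[ax] = (math.atan2(s, c) % (2.0 * np.pi)) * box[ax] / (2.0 * np.pi)
    return center, True


def radial_density_profile(
    traj,
    topo: SystemTopology,
    species: Sequence[str] | None = None,
    bin_width: float = 0.5,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> RadialProfile:
    """Per-species bead density rho(r) about the condensate center of mass.

    The center is the periodic (circular-mean) center of mass of the largest
    cluster; if no cluster exists the box center is used and the profile is
    flagged.  Densities are shell-volume normalized so that
    ``sum 4 pi r^2 rho(r) dr`` recovers each species' bead count up to
    binning error.
    """
    species = list(species) if species is not None else [s.name for s in topo.species]
    frames = _frames_of(traj)
    flags: list[str] = []
    box0 = frames[0][1]
    r_max = 0.5 * float(np.min(box0)) * math.sqrt(3.0)
    n_bins = max(1, int(math.ceil(r_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = {sp: np.zeros(n_bins) for sp in species}
    center_used = None
    for pos, box in frames:
        center, ok = _cluster_center(pos, box, topo, cluster_cutoff)
        center_used = center
        if not ok and "no_cluster:box_center_used" not in flags:
            flags.append("no_cluster:box_center_used")
        d = pos - center
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        for sp in species:
            beads = topo.beads_of(sp)
            if len(beads) == 0:
                flags.append(f"empty_species:{sp}")
                continue
            hist, _ = np.histogram(r[beads], bins=edges)
            acc[sp] += hist
    shell = 4.0 * np.pi * centers**2 * bin_width
    shell[shell == 0] = np.inf
    density = {sp: acc[sp] / (len(frames) * shell) for sp in species}
    return RadialProfile(
        r=centers,
        density=density,
        bin_width=bin_width,
        center=center_used,
        about_cluster="no_cluster:box_center_used" not in flags,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# charge ratios
# ---------------------------------------------------------------------------

@dataclass
class ChargeRatioReport:
    """Totals and stability ratios for a composed mixture.

    ``ratio_pi = (q_- + N_pi) / q_+`` augments the bare charge ratio with
    the aromatic sticker count; the empirical condensate stability band is
    1 <= ratio <= 5.
    """

    q_minus: float
    q_plus: float
    n_pi: int
    ratio_basic: float
    ratio_pi: float
    in_stability_band: bool
    stability_band: tuple[float, float] = (1.0, 5.0)


def charge_ratio(
    species_counts,
    params: ForceFieldParams | None = None,
    *,
    count_rna_aromatics: bool = False,
) -> ChargeRatioReport:
    """Charge-ratio stability metric for (molecule, count) pairs.

    N_pi counts protein aromatic residues over the whole system by default
    (RNA bases excluded); a zero q_+ yields infinite ratios, flagged rather
    than raised.
    """
    params = params or default_forcefield()
    if not species_counts:
        raise AnalysisError("empty system")
    q_plus = q_minus = 0.0
    n_pi = 0
    total_molecules = 0
    for mol, count in species_counts:
        if count == 0:
            continue
        stats = sequence_statistics(
            mol, params=params, count_rna_aromatics=count_rna_aromatics
        )
        q_plus += count * stats.q_plus
        q_minus += count * stats.q_minus
        n_pi += count * stats.n_pi
        total_molecules += count
    if total_molecules == 0:
        raise AnalysisError("empty system")
    if q_plus > 0:
        basic = q_minus / q_plus
        rpi = (q_minus + n_pi) / q_plus
    else:
        basic = math.inf if q_minus > 0 else 0.0
        rpi = math.inf if (q_minus + n_pi) > 0 else 0.0
    lo, hi = 1.0, 5.0
    return ChargeRatioReport(
        q_minus=q_minus,
        q_plus=q_plus,
        n_pi=n_pi,
        ratio_basic=basic,
        ratio_pi=rpi,
        in_stability_band=(lo <= rpi <= hi),
    )


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class MorphologyReport:
    label: str  # core_shell | marbled | mixed | separate
    core_species: str | None
    shell_species: str | None
    mean_radius: dict[str, float]
    rules: dict


def morphology_descriptor(
    traj,
    topo: SystemTopology,
    species_list: Sequence[str] | None = None,
    *,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    radial_separation_threshold: float = 0.25,
    separate_fraction: float = 0.30,
) -> MorphologyReport:
    """Classify condensate architecture from radial composition dominance.

    Rules (thresholds echoed in the output):

    * ``separate`` — the two largest clusters each hold >= ``separate_fraction``
      of all beads and are dominated by different species (bimodal droplets);
    * ``core_shell`` — within the largest cluster the gap between the
      innermost and outermost species' mean radial positions exceeds
      ``radial_separation_threshold`` x the cluster radius;
    * ``marbled`` — multiple species share the cluster without radial
      ordering;
    * ``mixed`` — a single-species condensate.

    Raises when no condensate is present (see ``classify_phase``).
    """
    species_list = (
        list(species_list) if species_list is not None
        else [s.name for s in topo.species]
    )
    frames = _frames_of(traj)
    pos, box = frames[-1]
    state = SimulationState(pos, np.zeros_like(pos), box)
    labels, big, frac = largest_cluster_info(state, topo, cluster_cutoff)
    if frac < 0.2:
        raise AnalysisError(
            "no condensate present; run classify_phase for the dilute case"
        )
    rules = {
        "cluster_cutoff": cluster_cutoff,
        "radial_separation_threshold": radial_separation_threshold,
        "separate_fraction": separate_fraction,
    }

    beads_per_mol = np.bincount(topo.molecule_id)
    sizes = np.bincount(labels, weights=beads_per_mol)
    order = np.argsort(sizes)[::-1]
    n_beads_tot = topo.n_beads

    def dominant_species(cluster_id) -> str:
        mols = np.where(labels == cluster_id)[0]
        counts: dict[str, int] = {}
        for m in mols:
            s = topo.species_of_molecule(m)
            counts[s.name] = counts.get(s.name, 0) + s.n_beads_per_molecule
        return max(counts, key=counts.get)

    if (
        len(order) >= 2
        and sizes[order[0]] >= separate_fraction * n_beads_tot
        and sizes[order[1]] >= separate_fraction * n_beads_tot
        and dominant_species(order[0]) != dominant_species(order[1])
    ):
        return MorphologyReport(
            label="separate",
            core_species=None,
            shell_species=None,
            mean_radius={},
            rules=rules,
        )

    center, _ = _cluster_center(pos, box, topo, cluster_cutoff)
    mols_in = np.where(labels == big)[0]
    sel_cluster = np.isin(topo.molecule_id, mols_in)
    d = pos - center
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    cluster_radius = float(np.quantile(r[sel_cluster], 0.90))

    mean_radius: dict[str, float] = {}
    for sp in species_list:
        beads = np.intersect1d(topo.beads_of(sp), np.where(sel_cluster)[0])
        if len(beads):
            mean_radius[sp] = float(np.mean(r[beads]))
    present = list(mean_radius)
    if len(present) <= 1:
        return MorphologyReport(
            label="mixed",
            core_species=present[0] if present else None,
            shell_species=None,
            mean_radius=mean_radius,
            rules=rules,
        )
    inner = min(present, key=lambda s: mean_radius[s])
    outer = max(present, key=lambda s: mean_radius[s])
    gap = (mean_radius[outer] - mean_radius[inner]) / max(cluster_radius, 1e-9)
    if gap > radial_separation_threshold:
        return MorphologyReport(
            label="core_shell",
            core_species=inner,
            shell_species=outer,
            mean_radius=mean_radius,
            rules=rules,
        )
    return MorphologyReport(
        label="marbled",
        core_species=None,
        shell_species=None,
        mean_radius=mean_radius,
        rules=rules,
    )


# ---------------------------------------------------------------------------
# helpers for the scaled-down directional checks
# ---------------------------------------------------------------------------

def species_core_fraction(
    traj,
    topo: SystemTopology,
    species: str,
    reference_species: str,
    *,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    edge_quantile: float = 0.90,
) -> float:
    """Fraction of ``species`` beads lying inside the condensate formed by
    ``reference_species`` (radius = ``edge_quantile`` of the reference
    beads' radial distribution about the cluster center), averaged over
    frames.  Low values mean the species stays outside / at the surface.
    """
    frames = _frames_of(traj)
    fracs = []
    ref_beads = topo.beads_of(reference_species)
    sp_beads = topo.beads_of(species)
    for pos, box in frames:
        center, ok = _cluster_center(pos, box, topo, cluster_cutoff)
        d = pos - center
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        edge = np.quantile(r[ref_beads], edge_quantile)
        fracs.append(float(np.mean(r[sp_beads] <= edge)))
    return float(np.mean(fracs))
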