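"""Condensate observables against constructed fixtures and brute-force
oracles."""

import math

import numpy as np
import pytest

from cgdroplet.analysis import (
    AnalysisError,
    aggregate_by_type,
    charge_ratio,
    classify_phase,
    contact_map,
    detect_clusters,
    interaction_fractions,
    morphology_descriptor,
    radial_density_profile,
    species_core_fraction,
)
from cgdroplet.engine import SimulationState, Trajectory
from cgdroplet.fixtures import FixtureSpec, make_fixture
from cgdroplet.forcefield import build_topology
from cgdroplet.sequences import (
    DPRSpec,
    ProteinSequence,
    build_dpr_sequence,
    build_rna_sequence,
)


def _two_molecule_fixture(ff, d=0.8):
    """Two GA dimers with exactly one inter-molecular bead pair within 1 nm."""
    mol = build_dpr_sequence(DPRSpec("GA", 1))
    topo = build_topology([(mol, 2)], ff)
    pos = np.array([
        [5.0, 5.0, 5.0],   # mol 0, bead 0 (G)
        [5.0, 5.0, 8.0],   # mol 0, bead 1 (A)  far from everything else
        [5.0 + d, 5.0, 5.0],  # mol 1, bead 0 (G): the designed contact
        [5.0 + d, 5.0, 2.0],  # mol 1, bead 1 (A)
    ])
    state = SimulationState(pos, np.zeros_like(pos), np.full(3, 20.0))
    return state, topo


class TestContactMap:
    def test_hand_countable_fixture(self, ff):
        state, topo = _two_molecule_fixture(ff)
        cm = contact_map(state, topo, "GA_1", "GA_1", cutoff=1.0)
        # one unordered contact counted from both sides, over 2 molecules:
        # matrix[0,0] = 2 / (1 frame * 2 molecules) = 1
        assert cm.matrix[0, 0] == pytest.approx(1.0)
        assert cm.total == pytest.approx(1.0)

    def test_single_copy_species_has_no_intermolecular_contacts(self, ff):
        mol = build_dpr_sequence(DPRSpec("PR", 4))
        topo = build_topology([(mol, 1)], ff)
        pos = np.cumsum(np.full((8, 3), 0.2), axis=0) + 5.0
        state = SimulationState(pos, np.zeros_like(pos), np.full(3, 20.0))
        cm = contact_map(state, topo, "PR_4", "PR_4", cutoff=1.0)
        assert cm.total == 0.0

    def test_heterotypic_transpose_consistency(self, ff):
        rna = build_rna_sequence(3, "U")
        pr = build_dpr_sequence(DPRSpec("PR", 2))
        topo = build_topology([(rna, 2), (pr, 2)], ff)
        rng = np.random.default_rng(7)
        pos = rng.random((topo.n_beads, 3)) * 6.0 + 2.0
        state = SimulationState(pos, np.zeros_like(pos), np.full(3, 12.0))
        ab = contact_map(state, topo, "U_3", "PR_2", cutoff=1.2)
        ba = contact_map(state, topo, "PR_2", "U_3", cutoff=1.2)
        # maps are normalized per molecule of the row species; undo that to
        # compare the raw transposed counts
        raw_ab = ab.matrix * 2
        raw_ba = ba.matrix * 2
        assert np.allclose(raw_ab, raw_ba.T)

    def test_brute_force_oracle(self, ff):
        # naive O(N^2) recount on a random 2-species system
        rna = build_rna_sequence(5, "U")
        ga = build_dpr_sequence(DPRSpec("GA", 5))
        topo = build_topology([(rna, 3), (ga, 3)], ff)
        rng = np.random.default_rng(11)
        box = np.full(3, 9.0)
        pos = rng.random((topo.n_beads, 3)) * box
        state = SimulationState(pos, np.zeros_like(pos), box)
        cutoff = 1.0
        cm = contact_map(state, topo, "U_5", "GA_5", cutoff=cutoff)

        n_a_mol = 3
        na, nb = 15, 10
        ref = np.zeros((na, nb))
        beads_a = topo.beads_of("U_5")
        beads_b = topo.beads_of("GA_5")
        for i in beads_a:
            for j in beads_b:
                if topo.molecule_id[i] == topo.molecule_id[j]:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) <= cutoff:
                    ref[topo.residue_index[i], topo.residue_index[j]] += 1
        assert np.allclose(cm.matrix, ref / n_a_mol)

    def test_absent_species_rejected(self, ff):
        state, topo = _two_molecule_fixture(ff)
        with pytest.raises(KeyError):
            contact_map(state, topo, "GA_1", "U_40")


class TestAggregation:
    def test_identity_partition_unchanged(self, ff):
        state, topo = _two_molecule_fixture(ff)
        cm = contact_map(state, topo, "GA_1", "GA_1", cutoff=1.0)
        agg = aggregate_by_type(cm, ["t0", "t1"])
        assert agg.matrix.sum() == pytest.approx(cm.total)

    def test_totals_conserved(self, ff):
        rna = build_rna_sequence(4, "U")
        pr = build_dpr_sequence(DPRSpec("PR", 3))
        topo = build_topology([(rna, 2), (pr, 2)], ff)
        rng = np.random.default_rng(13)
        pos = rng.random((topo.n_beads, 3)) * 7.0
        state = SimulationState(pos, np.zeros_like(pos), np.full(3, 14.0))
        cm = contact_map(state, topo, "U_4", "PR_3", cutoff=1.5)
        row_types = [topo.bead_codes[b] for b in topo.beads_of("U_4")[:12]]
        col_types = [topo.bead_codes[b] for b in topo.beads_of("PR_3")[:6]]
        agg = aggregate_by_type(cm, row_types, col_types)
        assert agg.total == pytest.approx(cm.total)

    def test_row_sums_match_index_rows(self, ff):
        # a Y-row in the by-type map equals the sum of the Y-index rows
        toy = ProteinSequence("toy", "GYGGYG")
        topo = build_topology([(toy, 2)], ff)
        rng = np.random.default_rng(17)
        pos = rng.random((topo.n_beads, 3)) * 4.0 + 1.0
        state = SimulationState(pos, np.zeros_like(pos), np.full(3, 10.0))
        cm = contact_map(state, topo, "toy", "toy", cutoff=1.2)
        agg = aggregate_by_type(cm, list("GYGGYG"))
        y_rows = [i for i, t in enumerate("GYGGYG") if t == "Y"]
        assert agg.matrix[agg.row_labels.index("Y")].sum() == pytest.approx(
            cm.matrix[y_rows].sum()
        )

    def test_partition_must_cover_indices(self, ff):
        state, topo = _two_molecule_fixture(ff)
        cm = contact_map(state, topo, "GA_1", "GA_1", cutoff=1.0)
        with pytest.raises(AnalysisError):
            aggregate_by_type(cm, ["G"])  # wrong length


class TestInteractionFractions:
    def _toy_by_type_map(self, ff, pairs):
        """Build a by-type ContactMap with the given {(ti, tj): weight}."""
        from cgdroplet.analysis import ContactMap

        labels = sorted({t for p in pairs for t in p})
        m = np.zeros((len(labels), len(labels)))
        for (ti, tj), w in pairs.items():
            m[labels.index(ti), labels.index(tj)] += w
        return ContactMap(
            species_a="A", species_b="B", matrix=m,
            row_labels=labels, col_labels=labels, cutoff=1.0, n_frames=1,
        )

    def test_enumerated_fractions(self, ff):
        cm = self._toy_by_type_map(ff, {("Y", "Y"): 1.0, ("Y", "R"): 1.0})
        s = interaction_fractions(cm, ff)
        assert s["aromatic"] == pytest.approx(0.5)
        assert s["cation-pi"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, ff):
        cm = self._toy_by_type_map(
            ff,
            {("Y", "Y"): 2.0, ("R", "PHO"): 1.0, ("A", "A"): 0.5,
             ("G", "S"): 3.0, ("Y", "L"): 1.5, ("K", "E"): 1.0},
        )
        s = interaction_fractions(cm, ff)
        assert sum(s.fractions.values()) == pytest.approx(1.0)
        assert s["electrostatic"] == pytest.approx(2.0 / 9.0)
        assert s["aromatic-aliphatic"] == pytest.approx(1.5 / 9.0)

    def test_phosphate_counts_as_electrostatic_with_cations(self, ff):
        cm = self._toy_by_type_map(ff, {("R", "PHO"): 1.0})
        assert interaction_fractions(cm, ff)["electrostatic"] == 1.0

    def test_zero_contacts_is_an_error(self, ff):
        cm = self._toy_by_type_map(ff, {("Y", "Y"): 0.0})
        with pytest.raises(AnalysisError):
            interaction_fractions(cm, ff)


class TestClusters:
    def test_two_separated_blobs(self, ff):
        fx = make_fixture(FixtureSpec(kind="two_blob", seed=3), ff)
        labels = detect_clusters(fx.state, fx.topology)
        assert len(np.unique(labels)) == 2
        # agreement with the constructed ground truth up to relabeling
        truth = fx.ground_truth["cluster_labels"]
        assert (labels == labels[0]).sum() == (truth == truth[0]).sum()

    def test_ideal_gas_one_cluster_per_molecule(self, ff):
        fx = make_fixture(FixtureSpec(kind="ideal_gas", seed=4), ff)
        labels = detect_clusters(fx.state, fx.topology)
        assert len(np.unique(labels)) == fx.topology.n_molecules

    def test_all_overlapping_is_one_cluster(self, ff):
        mol = build_dpr_sequence(DPRSpec("GA", 2))
        topo = build_topology([(mol, 6)], ff)
        rng = np.random.default_rng(5)
        pos = rng.random((topo.n_beads, 3)) * 1.5 + 9.0
        state = SimulationState(pos, np.zeros_like(pos), np.full(3, 20.0))
        assert len(np.unique(detect_clusters(state, topo))) == 1

    def test_brute_force_oracle(self, ff):
        # naive O(N^2) single-linkage on a random configuration
        mol = build_dpr_sequence(DPRSpec("GA", 4))
        topo = build_topology([(mol, 20)], ff)
        rng = np.random.default_rng(6)
        box = np.full(3, 16.0)
        pos = rng.random((topo.n_beads, 3)) * box
        state = SimulationState(pos, np.zeros_like(pos), box)
        cutoff = 1.5
        labels = detect_clusters(state, topo, cutoff)

        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(topo.n_molecules))
        for i in range(topo.n_beads):
            for j in range(i + 1, topo.n_beads):
                mi, mj = topo.molecule_id[i], topo.molecule_id[j]
                if mi == mj:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) <= cutoff:
                    g.add_edge(mi, mj)
        comps = list(nx.connected_components(g))
        assert len(np.unique(labels)) == len(comps)
        for comp in comps:
            comp = sorted(comp)
            assert len(set(labels[comp])) == 1


class TestClassifyPhase:
    def _traj_of(self, state, n=3):
        t = Trajectory()
        for _ in range(n):
            t.add_frame(state)
        return t

    def test_single_full_cluster_is_full_llps(self, ff):
        fx = make_fixture(FixtureSpec(kind="uniform_sphere", seed=7), ff)
        region = classify_phase(self._traj_of(fx.state), fx.topology)
        assert region.label == "full_LLPS"
        assert region.largest_cluster_fraction == 1.0

    def test_ideal_gas_is_no_llps(self, ff):
        fx = make_fixture(FixtureSpec(kind="ideal_gas", seed=8), ff)
        region = classify_phase(self._traj_of(fx.state), fx.topology)
        assert region.label == "no_LLPS"

    def test_dilute_rna_region(self, ff):
        # cluster holds all protein; 40% of RNA molecules isolated
        rna = build_rna_sequence(4, "U")
        pr = build_dpr_sequence(DPRSpec("PR", 5))
        topo = build_topology([(rna, 5), (pr, 10)], ff,
                              roles={"U_4": "rna", "PR_5": "dpr"})
        rng = np.random.default_rng(9)
        box = np.full(3, 40.0)
        pos = np.zeros((topo.n_beads, 3))
        # protein blob + 3 RNA at center, 2 RNA far away
        blob_mols = list(topo.molecules_of("PR_5")) + list(
            topo.molecules_of("U_4")[:3]
        )
        for m in range(topo.n_molecules):
            beads = np.where(topo.molecule_id == m)[0]
            if m in blob_mols:
                center = box / 2
            else:
                center = np.array([5.0, 5.0, 5.0]) + 8.0 * (m % 2)
            pos[beads] = center + rng.normal(0, 0.6, (len(beads), 3))
        state = SimulationState(pos, np.zeros_like(pos), box)
        region = classify_phase(self._traj_of(state), topo)
        assert region.label == "dilute_RNA"
        assert region.dilute_fraction["U_4"] == pytest.approx(0.4)

    def test_invariance_under_rigid_translation(self, ff):
        fx = make_fixture(FixtureSpec(kind="two_blob", seed=10), ff)
        r1 = classify_phase(self._traj_of(fx.state), fx.topology)
        moved = fx.state.copy()
        moved.positions = moved.positions + np.array([13.1, -7.7, 21.9])
        r2 = classify_phase(self._traj_of(moved), fx.topology)
        assert r1.label == r2.label
        assert r1.largest_cluster_fraction == pytest.approx(
            r2.largest_cluster_fraction
        )

    def test_too_few_frames_rejected(self, ff):
        fx = make_fixture(FixtureSpec(kind="ideal_gas", seed=11), ff)
        with pytest.raises(AnalysisError):
            classify_phase(self._traj_of(fx.state, n=1), fx.topology,
                           min_frames=5)


class TestRadialProfile:
    def test_uniform_sphere_flat_interior(self, ff):
        fx = make_fixture(
            FixtureSpec(kind="uniform_sphere", seed=12,
                        geometry={"n": 600, "radius": 8.0}),
            ff,
        )
        prof = radial_density_profile(fx.state, fx.topology, bin_width=1.0)
        name = fx.topology.species[0].name
        rho = prof.density[name]
        interior = rho[1:6]  # 1-6 nm, inside the 8 nm sphere
        assert interior.std() / interior.mean() < 0.35
        # density beyond the sphere is ~zero
        assert rho[11:].max() < 0.05 * interior.mean()

    def test_bead_count_conservation(self, ff):
        fx = make_fixture(FixtureSpec(kind="uniform_sphere", seed=13), ff)
        prof = radial_density_profile(fx.state, fx.topology, bin_width=0.5)
        name = fx.topology.species[0].name
        n_true = len(fx.topology.beads_of(name))
        assert prof.integrated_counts(name) == pytest.approx(n_true, rel=0.02)

    def test_core_shell_species_separation(self, ff):
        fx = make_fixture(FixtureSpec(kind="core_shell", seed=14), ff)
        prof = radial_density_profile(fx.state, fx.topology, bin_width=0.5)
        core = fx.ground_truth["core_species"]
        shell = fx.ground_truth["shell_species"]
        r_core = fx.ground_truth["r_core"]
        # core species vanishes well beyond its radius
        sel_out = prof.r > r_core + 1.5
        assert prof.density[core][sel_out].max() <= 0.02 * prof.density[core].max()
        # shell species dominates outside
        sel_shell = (prof.r > 7.5) & (prof.r < 9.5)
        assert prof.density[shell][sel_shell].sum() > prof.density[core][sel_shell].sum()


class TestChargeRatio:
    def test_pure_pr60_ratio_zero(self, ff):
        pr = build_dpr_sequence(DPRSpec("PR", 60))
        rep = charge_ratio([(pr, 10)], ff)
        assert rep.ratio_basic == 0.0
        assert rep.q_plus == 600

    def test_u40_pr60_two_thirds(self, ff):
        rep = charge_ratio(
            [(build_rna_sequence(40), 1),
             (build_dpr_sequence(DPRSpec("PR", 60)), 1)],
            ff,
        )
        assert rep.ratio_basic == pytest.approx(2.0 / 3.0)
        assert rep.ratio_pi == pytest.approx(2.0 / 3.0)  # no aromatics

    def test_ratio_pi_adds_aromatics(self, ff):
        from cgdroplet.sequences import get_rbp_sequence

        fus = get_rbp_sequence("FUS_PLD_RGG1")
        rep = charge_ratio(
            [(fus, 1), (build_dpr_sequence(DPRSpec("PR", 10)), 1)], ff
        )
        assert rep.ratio_pi > rep.ratio_basic
        assert rep.n_pi > 0

    def test_no_positive_charge_flagged_infinite(self, ff):
        rep = charge_ratio([(build_rna_sequence(10), 2)], ff)
        assert math.isinf(rep.ratio_basic)

    def test_empty_system_rejected(self, ff):
        with pytest.raises(AnalysisError):
            charge_ratio([], ff)


class TestMorphology:
    def test_core_shell_fixture(self, ff):
        fx = make_fixture(FixtureSpec(kind="core_shell", seed=15), ff)
        rep = morphology_descriptor(fx.state, fx.topology)
        assert rep.label == "core_shell"
        assert rep.core_species == fx.ground_truth["core_species"]
        assert rep.shell_species == fx.ground_truth["shell_species"]

    def test_single_species_droplet_is_mixed(self, ff):
        fx = make_fixture(FixtureSpec(kind="uniform_sphere", seed=16), ff)
        rep = morphology_descriptor(fx.state, fx.topology)
        assert rep.label == "mixed"

    def test_tangent_droplets_are_separate(self, ff):
        fx = make_fixture(
            FixtureSpec(kind="two_blob", seed=17, geometry={"gap": 11.0}), ff
        )
        rep = morphology_descriptor(fx.state, fx.topology)
        assert rep.label == "separate"

    def test_marbled_fixture(self, ff):
        fx = make_fixture(FixtureSpec(kind="marbled", seed=18), ff)
        rep = morphology_descriptor(fx.state, fx.topology)
        assert rep.label == "marbled"

    def test_no_condensate_rejected(self, ff):
        fx = make_fixture(FixtureSpec(kind="ideal_gas", seed=19), ff)
        with pytest.raises(AnalysisError, match="classify_phase"):
            morphology_descriptor(fx.state, fx.topology)
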