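"""Contact detection, residence-time filtering, profiles, ranking, ion
pairs, and RDFs, checked against brute-force oracles and planted truth."""
import numpy as np
import pytest

from synbind import binding, synth
from synbind.core import Atom, ChargedGroup, Ensemble, Replica, Residue, Topology
from conftest import random_system


def brute_force_contacts(top, xyz, cutoff):
    """Independent all-pairs double-loop contact oracle."""
    lig = [i for i, a in enumerate(top.ligand_atoms, start=len(top.atoms)) if not a.is_hydrogen]
    out = np.zeros((top.n_residues, xyz.shape[0]), dtype=bool)
    for f in range(xyz.shape[0]):
        for r in range(top.n_residues):
            best = np.inf
            for i, a in enumerate(top.atoms):
                if a.residue_index == r + 1 and not a.is_hydrogen:
                    for j in lig:
                        best = min(best, float(np.linalg.norm(xyz[f, i] - xyz[f, j])))
            out[r, f] = best < cutoff
    return out


class TestMinHeavyDistance:
    def test_simple_minimum(self):
        frame = np.array([[0.0, 0, 0], [0.3, 0, 0], [1.0, 0, 0]])
        d = binding.min_heavy_distance(frame, np.array([0]), np.array([1, 2]))
        assert d == pytest.approx(0.3)

    def test_coincident_points(self):
        frame = np.zeros((2, 3))
        assert binding.min_heavy_distance(frame, np.array([0]), np.array([1])) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(size=(50, 3))
        a, b = np.arange(20), np.arange(20, 50)
        expected = min(
            float(np.linalg.norm(frame[i] - frame[j])) for i in a for j in b
        )
        assert binding.min_heavy_distance(frame, a, b) == expected

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            binding.min_heavy_distance(np.zeros((3, 3)), np.array([], dtype=int), np.array([0]))


def _two_residue_ensemble(ligand_distance_nm):
    """One frame, two 1-heavy-atom residues 1 nm apart, ligand at a chosen
    distance from residue 1."""
    residues = [Residue(1, "UNK", "X"), Residue(2, "UNK", "X")]
    atoms = [Atom(1, 1, "A0", "C", False, False), Atom(2, 2, "A0", "C", False, False)]
    lig = [Atom(3, 0, "L0", "C", False, False)]
    top = Topology(residues, atoms, lig)
    xyz = np.array([[[0.0, 0, 0], [1.0, 0, 0], [ligand_distance_nm, 0, 0]]])
    return Ensemble([Replica(0, xyz)], 1.0, top)


class TestDetectContacts:
    @pytest.mark.parametrize(
        "distance,expected", [(0.349, True), (0.350, False), (0.351, False)]
    )
    def test_strict_cutoff_boundary(self, distance, expected):
        ens = _two_residue_ensemble(distance)
        contacts = binding.detect_contacts(ens, cutoff_nm=0.35)
        assert bool(contacts.series[0][0, 0]) is expected

    def test_matches_planted_truth_exactly(self, small_planted):
        _, ensemble, truth = small_planted
        contacts = binding.detect_contacts(
            ensemble, cutoff_nm=0.35
        )
        detected = {
            (rid, r + 1, f)
            for rid, mat in zip(contacts.replica_ids, contacts.series)
            for r, f in zip(*np.nonzero(mat))
        }
        assert detected == truth.contact_cells()

    def test_oracle_equivalence_random_systems(self):
        rng = np.random.default_rng(100)
        for _ in range(5):
            top, xyz = random_system(rng, n_frames=4, n_atoms_total=30)
            ens = Ensemble([Replica(0, xyz)], 1.0, top)
            got = binding.detect_contacts(ens, cutoff_nm=0.5).series[0]
            np.testing.assert_array_equal(got, brute_force_contacts(top, xyz, 0.5))

    def test_distant_ligand_all_false(self):
        ens = _two_residue_ensemble(50.0)
        assert not binding.detect_contacts(ens).series[0].any()


def _series_from_rows(rows, spacing=1.0):
    mat = np.asarray(rows, dtype=bool)
    return binding.ContactSeries([mat], spacing)


class TestEventsAndProfile:
    def test_run_length_decomposition(self):
        contacts = _series_from_rows([[True, True, True, False, True, True]])
        events = binding.extract_events(contacts)
        assert [(e.start_frame, e.end_frame, e.duration_ns) for e in events] == [
            (0, 2, 3.0),
            (4, 5, 2.0),
        ]

    def test_all_false_gives_no_events(self):
        contacts = _series_from_rows([[False] * 6])
        assert binding.extract_events(contacts) == []

    def test_event_count_matches_planted_episodes(self):
        cfg = synth.SynthConfig(
            n_residues=30, n_replicas=2, n_frames=400,
            binding=synth.BindingConfig(target_residues=(10, 20), decoy_rate=0.0),
            seed=31,
        )
        ensemble, truth = synth.generate_ensemble(cfg)
        events = binding.extract_events(binding.detect_contacts(ensemble))
        assert len(events) == len(truth.episodes)

    def test_profile_counts_by_definition(self):
        contacts = _series_from_rows([[True, True, True, False, True, True]])
        prof = binding.binding_profile(contacts, thresholds_ns=[3.0])
        assert prof.total_frames[0] == 5
        assert prof.stable_frames[3.0][0] == 3
        assert prof.n_events[3.0][0] == 1
        assert prof.n_replicas_stable[3.0][0] == 1

    def test_threshold_monotonicity(self, small_planted):
        _, ensemble, _ = small_planted
        prof = binding.binding_profile(binding.detect_contacts(ensemble))
        assert np.all(prof.n_events[3.0] >= prof.n_events[5.0])
        assert np.all(prof.n_events[5.0] >= prof.n_events[15.0])
        assert np.all(prof.stable_frames[3.0] >= prof.stable_frames[15.0])
        assert np.all(prof.stable_frames[3.0] <= prof.total_frames)

    def test_event_partition_at_unit_threshold(self, small_planted):
        _, ensemble, _ = small_planted
        contacts = binding.detect_contacts(ensemble)
        prof = binding.binding_profile(contacts, thresholds_ns=[1.0])
        np.testing.assert_array_equal(prof.stable_frames[1.0], prof.total_frames)

    def test_invalid_threshold_rejected(self):
        contacts = _series_from_rows([[True, False]])
        with pytest.raises(ValueError, match="threshold"):
            binding.binding_profile(contacts, thresholds_ns=[0.5])
        with pytest.raises(ValueError, match="multiple"):
            binding.binding_profile(contacts, thresholds_ns=[2.5])


class TestRanking:
    def _profile(self, scores):
        contacts = _series_from_rows(
            [[True] * s + [False] * (max(scores) + 1 - s) for s in scores]
        )
        return binding.binding_profile(contacts, thresholds_ns=[1.0])

    def test_descending_with_index_tiebreak(self):
        prof = self._profile([2, 5, 5, 1])
        ranked = binding.rank_binding_site(prof, "stable_frames", 1.0, top_k=3)
        assert ranked == [(2, 5.0), (3, 5.0), (1, 2.0)]

    def test_all_zero_profile_warns_and_is_empty(self):
        prof = self._profile([0, 0])
        with pytest.warns(UserWarning, match="all-zero"):
            assert binding.rank_binding_site(prof, "stable_frames", 1.0) == []

    def test_bad_top_k(self):
        prof = self._profile([1])
        with pytest.raises(ValueError, match="top_k"):
            binding.rank_binding_site(prof, top_k=0)

    def test_planted_targets_recovered(self, small_planted):
        cfg, ensemble, _ = small_planted
        prof = binding.binding_profile(binding.detect_contacts(ensemble))
        ranked = binding.rank_binding_site(prof, "stable_frames", 3.0, top_k=5)
        assert {r for r, _ in ranked} == set(cfg.binding.target_residues)


class TestBoundFraction:
    def test_simple_values(self):
        assert binding.bound_fraction(_series_from_rows([[False] * 4])) == 0.0
        assert binding.bound_fraction(
            _series_from_rows([[True, False, True, True], [False, False, False, True]])
        ) == 0.75

    def test_matches_planted_stationary_law(self, small_planted):
        cfg, ensemble, _ = small_planted
        bf = binding.bound_fraction(binding.detect_contacts(ensemble))
        b = cfg.binding
        p = b.mean_residence_ns / (b.mean_residence_ns + b.mean_unbound_ns)
        expected = p + (1 - p) * b.decoy_rate
        assert abs(bf - expected) < 0.1


class TestIonPairs:
    def _system(self, positions_protein, positions_ligand):
        n_p, n_l = len(positions_protein), len(positions_ligand)
        residues = [Residue(i + 1, "UNK", "X") for i in range(n_p)]
        atoms = [Atom(i + 1, i + 1, "A0", "O", False, False) for i in range(n_p)]
        lig = [Atom(n_p + j + 1, 0, f"L{j}", "N", False, False) for j in range(n_l)]
        groups = [
            ChargedGroup(f"carb_{i}", (i + 1,), -1, "protein") for i in range(n_p)
        ] + [ChargedGroup(f"am_{j}", (n_p + j + 1,), +1, "ligand") for j in range(n_l)]
        top = Topology(residues, atoms, lig, groups)
        xyz = np.array([list(positions_protein) + list(positions_ligand)])
        return Ensemble([Replica(0, xyz)], 1.0, top)

    def test_constructed_counts(self):
        # 3 carboxylates within cutoff of some amine, 1 far away
        ens = self._system(
            [(0, 0, 0), (0.3, 0, 0), (0, 0.3, 0), (5, 5, 5)],
            [(0.1, 0.1, 0), (2, 2, 2), (3, 3, 3), (4, 4, 4)],
        )
        per_rep, hist = binding.count_ion_pairs(ens, cutoff_nm=0.45)
        assert per_rep[0][0] == 3
        assert hist[3] == 1

    def test_no_pairs_in_range(self):
        ens = self._system([(0, 0, 0)], [(5, 5, 5)])
        per_rep, _ = binding.count_ion_pairs(ens, cutoff_nm=0.45)
        assert per_rep[0][0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        prot = rng.uniform(0, 1, size=(6, 3))
        lig = rng.uniform(0, 1, size=(4, 3))
        ens = self._system(prot, lig)
        per_rep, _ = binding.count_ion_pairs(ens, cutoff_nm=0.45)
        expected = sum(
            1
            for p in prot
            for l in lig
            if np.linalg.norm(np.asarray(p) - np.asarray(l)) < 0.45
        )
        assert per_rep[0][0] == expected

    def test_empty_groups_rejected(self, coil_small):
        with pytest.raises(ValueError, match="charged group"):
            binding.count_ion_pairs(coil_small)


class TestRDF:
    def _sphere_ensemble(self, rng, n_frames=400, n_around=1000, radius=2.0):
        residues = [Residue(1, "UNK", "X")]
        atoms = [Atom(1, 1, "A0", "C", False, False)]
        lig = [Atom(i + 2, 0, f"L{i}", "C", False, False) for i in range(n_around)]
        top = Topology(residues, atoms, lig)
        # around-atoms uniform in the sphere centred on the single center atom
        pts = rng.normal(size=(n_frames, n_around, 3))
        pts /= np.linalg.norm(pts, axis=-1, keepdims=True)
        r = radius * rng.random((n_frames, n_around, 1)) ** (1 / 3)
        xyz = np.concatenate([np.zeros((n_frames, 1, 3)), pts * r], axis=1)
        return Ensemble([Replica(0, xyz)], 1.0, top)

    def test_uniform_placement_gives_unit_g(self):
        rng = np.random.default_rng(12)
        ens = self._sphere_ensemble(rng)
        prof = binding.rdf(
            ens, np.array([0]), np.arange(1, 1001), bin_width_nm=0.1, r_max_nm=2.0
        )
        far = prof.bin_centers_nm > 0.5  # beyond r_max / 4
        np.testing.assert_allclose(prof.g[far], 1.0, atol=0.05)

    def test_single_distance_occupies_one_bin(self):
        residues = [Residue(1, "UNK", "X")]
        atoms = [Atom(1, 1, "A0", "C", False, False)]
        lig = [Atom(2, 0, "L0", "C", False, False)]
        top = Topology(residues, atoms, lig)
        xyz = np.array([[[0.0, 0, 0], [0.73, 0, 0]]])
        ens = Ensemble([Replica(0, xyz)], 1.0, top)
        prof = binding.rdf(ens, np.array([0]), np.array([1]), 0.1, 2.0)
        occupied = np.flatnonzero(prof.g > 0)
        assert len(occupied) == 1
        assert prof.bin_centers_nm[occupied[0]] == pytest.approx(0.75)

    def test_bad_binning_rejected(self, coil_small):
        with pytest.raises(ValueError, match="bin_width"):
            binding.rdf(coil_small, np.array([0]), np.array([1]), 0.0, 2.0)
        with pytest.raises(ValueError, match="bin_width"):
            binding.rdf(coil_small, np.array([0]), np.array([1]), 3.0, 2.0)
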