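"""Entropy, clustering, distance matrices, mutation profiling, salt bridges,
spatial clusters, and the activity formula."""

import math

import numpy as np
import pytest

from deepevo import analysis
from deepevo.analysis import (MutationSet, activity_units, cluster_sequences,
                              distance_matrix, mutation_profile,
                              positional_entropy, salt_bridges,
                              spatial_mutation_clusters)
from deepevo.seqio import (AMINO_ACIDS, SequenceRecord, StructureModel,
                           read_structure)

from .oracles import brute_force_components, brute_force_salt_bridges


# ---------------------------------------------------------------------------
# Positional entropy
# ---------------------------------------------------------------------------

class TestPositionalEntropy:
    def test_closed_forms(self):
        conserved = ["A"] * 10
        uniform = list(AMINO_ACIDS)
        half = ["A"] * 10 + ["V"] * 10
        assert positional_entropy(conserved)[0] == 0.0
        assert positional_entropy(uniform)[0] == \
            pytest.approx(math.log2(20), abs=1e-12)
        assert positional_entropy(half)[0] == pytest.approx(1.0, abs=1e-12)

    def test_bounds_and_zero_iff_constant(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=12))
                for _ in range(30)]
        ent = positional_entropy(seqs)
        assert ((ent >= 0) & (ent <= math.log2(20) + 1e-12)).all()
        for col, value in enumerate(ent):
            constant = len({s[col] for s in seqs}) == 1
            assert (value == 0.0) == constant

    def test_gaps_excluded_and_all_gap_is_nan(self):
        ent = positional_entropy(["A-", "A-", "V-"])
        assert ent[0] == pytest.approx(-(2 / 3) * math.log2(2 / 3)
                                       - (1 / 3) * math.log2(1 / 3))
        assert np.isnan(ent[1])

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            positional_entropy(["AC", "ACD"])

    def test_motif_columns_of_family_have_zero_entropy(self, family_records):
        from deepevo.synthdata import FamilyConfig

        ent = positional_entropy([r.residues for r in family_records])
        for pos in FamilyConfig().motif_positions:
            assert ent[pos - 1] == 0.0


# ---------------------------------------------------------------------------
# Clustering and distances
# ---------------------------------------------------------------------------

class TestClustering:
    def test_identical_records_single_cluster(self):
        records = [SequenceRecord(f"r{i}", "ACDEFGHIKL" * 3)
                   for i in range(5)]
        clusters = cluster_sequences(records)
        assert len(clusters) == 1
        assert clusters[0].size == 5

    def test_mutually_distant_records_singletons(self, rng):
        records = [SequenceRecord(f"r{i}",
                                  "".join(rng.choice(list(AMINO_ACIDS), 40)))
                   for i in range(6)]
        clusters = cluster_sequences(records, min_identity=80.0)
        assert len(clusters) == 6

    def test_members_within_identity_of_representative(self, family_records):
        from deepevo.candidate_selection import percent_identity

        clusters = cluster_sequences(family_records[:50], min_identity=80.0)
        assert sum(c.size for c in clusters) == 50
        for cluster in clusters:
            for member in cluster.members:
                assert percent_identity(
                    member.residues,
                    cluster.representative.residues) >= 80.0

    def test_distance_matrix_properties(self, family_records):
        reps = family_records[:8]
        dist, ids = distance_matrix(reps)
        assert ids == [r.id for r in reps]
        np.testing.assert_allclose(dist, dist.T)
        np.testing.assert_allclose(np.diag(dist), 0.0)
        assert ((dist >= 0) & (dist <= 1)).all()

    def test_distance_extremes(self):
        same = [SequenceRecord("a", "ACDEFGHIKL"),
                SequenceRecord("b", "ACDEFGHIKL")]
        dist, _ = distance_matrix(same)
        assert dist[0, 1] == 0.0
        far = [SequenceRecord("a", "AAAAAAAAAA"),
               SequenceRecord("b", "TTTTTTTTTT")]
        dist, _ = distance_matrix(far)
        assert dist[0, 1] == 1.0

    def test_tsne_embed_shapes(self, family_records):
        reps = family_records[:10]
        dist, _ = distance_matrix(reps)
        coords = analysis.tsne_embed(dist, sizes=[1] * 10, seed=0)
        assert coords.shape == (10, 2)


# ---------------------------------------------------------------------------
# Mutation profiling
# ---------------------------------------------------------------------------

class TestMutationProfile:
    def test_identical_pair_empty(self):
        rec = SequenceRecord("a", "ACDEFGHIKL")
        mset, summary = mutation_profile(rec, SequenceRecord("b", rec.residues))
        assert mset.substitutions == []
        assert summary.total == 0

    def test_single_ala_to_ser(self):
        ref = SequenceRecord("ref", "MKVLAAGHIW")
        var = SequenceRecord("var", "MKVLSAGHIW")
        mset, summary = mutation_profile(var, ref)
        assert mset.substitutions == [(5, "A", "S")]
        assert summary.ala_to_ser == 1
        assert summary.charged_introduced == 0
        assert summary.same_class == 0  # A hydrophobic, S polar

    def test_charged_introduction_counting(self):
        ref = SequenceRecord("ref", "MKVLAAGHIW")
        var = SequenceRecord("var", "MKVLEAGHIW")  # A5E
        _, summary = mutation_profile(var, ref)
        assert summary.charged_introduced == 1
        assert summary.charged_removed == 0

    def test_counts_agree_with_columnwise_brute_force(self, rng):
        aa = list(AMINO_ACIDS)
        for _ in range(100):
            ref_seq = "".join(rng.choice(aa, size=30))
            var_seq = list(ref_seq)
            # interior substitutions only: a substitution at a terminal
            # residue can make a staggered free-end-gap alignment optimal
            for pos in rng.choice(np.arange(3, 27),
                                  size=rng.integers(0, 8), replace=False):
                var_seq[pos] = aa[rng.integers(20)]
            var_seq = "".join(var_seq)
            mset, summary = mutation_profile(SequenceRecord("v", var_seq),
                                             SequenceRecord("r", ref_seq))
            expected = [(i + 1, r, v) for i, (r, v)
                        in enumerate(zip(ref_seq, var_seq)) if r != v]
            assert mset.substitutions == expected
            assert summary.total == len(expected)

    def test_mutation_set_invariants(self):
        with pytest.raises(ValueError):
            MutationSet("r", "v", [(5, "A", "A")])
        with pytest.raises(ValueError):
            MutationSet("r", "v", [(5, "A", "S"), (3, "G", "W")])


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

class TestSaltBridges:
    def test_lys_glu_within_cutoff(self, three_residue_pdb):
        structure = read_structure(three_residue_pdb, "A")
        result = salt_bridges(structure, cutoff=4.0)
        assert result.count == 1
        bridge = result.pairs[0]
        assert (bridge.acidic_residue, bridge.basic_residue) == (2, 1)
        assert bridge.atom_pair == ("OE1", "NZ")
        assert bridge.distance == pytest.approx(3.5)

    def test_same_pair_beyond_cutoff(self, three_residue_pdb):
        structure = read_structure(three_residue_pdb, "A")
        assert salt_bridges(structure, cutoff=3.0).count == 0

    def test_matches_all_pairs_brute_force_on_random_structure(self, rng):
        structure = _random_charged_structure(rng, n=30)
        result = salt_bridges(structure, cutoff=4.0)
        assert result.count == brute_force_salt_bridges(structure, 4.0)
        no_his = salt_bridges(structure, cutoff=4.0, include_his=False)
        assert no_his.count == brute_force_salt_bridges(structure, 4.0,
                                                        include_his=False)

    def test_invariant_under_rigid_motion(self, rng):
        structure = _random_charged_structure(rng, n=20)
        baseline = salt_bridges(structure, cutoff=4.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 2.0])
        moved = StructureModel(
            structure.chain_id, structure.residue_numbers,
            structure.residue_names, structure.ca_coords @ rot.T + shift,
            [(n, r, a, xyz @ rot.T + shift)
             for n, r, a, xyz in structure.charged_atoms])
        result = salt_bridges(moved, cutoff=4.0)
        assert result.count == baseline.count
        for a, b in zip(result.pairs, baseline.pairs):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)


def _random_charged_structure(rng, n=30) -> StructureModel:
    from deepevo.seqio import CHARGED_SIDECHAIN_ATOMS

    names = rng.choice(["ASP", "GLU", "LYS", "ARG", "HIS", "ALA"], size=n)
    ca = rng.uniform(0, 25, size=(n, 3))
    charged = []
    for i, name in enumerate(names):
        for atom in CHARGED_SIDECHAIN_ATOMS.get(str(name), ()):
            charged.append((i + 1, str(name), atom,
                            ca[i] + rng.normal(0, 2.0, size=3)))
    return StructureModel("A", np.arange(1, n + 1), [str(x) for x in names],
                          ca, charged)


# ---------------------------------------------------------------------------
# Spatial mutation clusters
# ---------------------------------------------------------------------------

class TestSpatialClusters:
    def _structure(self, coords):
        n = len(coords)
        return StructureModel("A", np.arange(1, n + 1), ["ALA"] * n,
                              np.asarray(coords, dtype=float), [])

    def _mutations(self, positions):
        return MutationSet("r", "v", [(p, "A", "S") for p in positions])

    def test_hand_geometry(self):
        structure = self._structure([[0, 0, 0], [5, 0, 0], [20, 0, 0]])
        result = spatial_mutation_clusters(self._mutations([1, 2, 3]),
                                           structure, cutoff=8.0)
        assert result.clusters == [{1, 2}]
        assert result.singles == {3}
        assert result.clustered_fraction == pytest.approx(2 / 3)

    def test_no_mutations_empty_partition(self):
        structure = self._structure([[0, 0, 0]])
        result = spatial_mutation_clusters(self._mutations([]), structure)
        assert result.clusters == [] and result.singles == set()
        assert result.clustered_fraction == 0.0

    def test_missing_ca_raises_with_position(self):
        structure = self._structure([[0, 0, 0], [5, 0, 0]])
        with pytest.raises(KeyError, match="9"):
            spatial_mutation_clusters(self._mutations([1, 9]), structure)

    def test_components_match_union_find_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 15))
            coords = rng.uniform(0, 30, size=(n, 3))
            structure = self._structure(coords)
            positions = list(range(1, n + 1))
            result = spatial_mutation_clusters(self._mutations(positions),
                                               structure, cutoff=8.0)
            coord_map = {p: coords[p - 1] for p in positions}
            clusters, singles = brute_force_components(positions, coord_map,
                                                       cutoff=8.0)
            assert result.clusters == clusters
            assert result.singles == singles
            covered = set().union(*result.clusters) | result.singles \
                if result.clusters else result.singles
            assert covered == set(positions)


# ---------------------------------------------------------------------------
# Activity units
# ---------------------------------------------------------------------------

class TestActivityUnits:
    def test_constants_cancel(self):
        assert activity_units(6.22, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_zero_absorbance_change(self):
        assert activity_units(0.0, 1.0, 0.5, 600.0) == 0.0

    def test_linearity(self, rng):
        for _ in range(20):
            d, v, c, t = rng.uniform(0.1, 5, size=4)
            assert activity_units(2 * d, v, c, t) == \
                pytest.approx(2 * activity_units(d, v, c, t))

    @pytest.mark.parametrize("conc, t", [(0.0, 1.0), (-1.0, 1.0),
                                         (1.0, 0.0), (1.0, -5.0)])
    def test_invalid_denominators(self, conc, t):
        with pytest.raises(ValueError):
            activity_units(1.0, 1.0, conc, t)
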