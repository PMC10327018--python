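import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from crossconn import consensus_typing as ct
from crossconn import crossmatch as cm
from crossconn import morphology as mo
from crossconn import synthetic_data as sd

from conftest import cohort_distances
from oracles import extraction_oracle, ward_lance_williams


def dist_matrix(values, ids):
    return mo.ScoreMatrix(np.asarray(values, float), ids, ids, "mean")


def planted_blobs(rng, centers, per_blob, spread=0.3):
    pts, labels = [], []
    for k, c in enumerate(centers):
        pts.append(np.asarray(c) + rng.normal(0, spread, (per_blob, 3)))
        labels += [k] * per_blob
    return np.vstack(pts), labels


class TestWardLinkage:
    def test_two_leaves_single_merge(self):
        D = dist_matrix([[0, 2.0], [2.0, 0]], ["a", "b"])
        dend = ct.ward_linkage(D, {"a": "h1", "b": "h2"})
        assert dend.Z.shape == (1, 4)
        assert dend.Z[0, 2] == pytest.approx(2.0)

    def test_planted_two_blob_root_split(self, rng):
        pts, labels = planted_blobs(rng, [(0, 0, 0), (20, 0, 0)], 4)
        ids = [f"n{i}" for i in range(8)]
        D = dist_matrix(squareform(pdist(pts)), ids)
        dend = ct.ward_linkage(D, {i: "h" for i in ids})
        sets = dend.node_leaves()
        # the children of the root are exactly the two blobs
        root_children_sizes = sorted(len(sets[int(k)]) for k in dend.Z[-1, :2])
        assert root_children_sizes == [4, 4]
        child = sets[int(dend.Z[-1, 0])]
        assert len({labels[i] for i in child}) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lance_williams_oracle_on_eight_leaves(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (8, 3))
        D = squareform(pdist(pts))
        ids = [f"n{i}" for i in range(8)]
        dend = ct.ward_linkage(dist_matrix(D, ids), {i: "h" for i in ids})
        heights, merged_sets = ward_lance_williams(D)
        np.testing.assert_allclose(sorted(dend.Z[:, 2]), heights, atol=1e-9)
        from oracles import linkage_leaf_sets

        got = set(linkage_leaf_sets(dend.Z, 8)[8:])
        assert got == merged_sets

    def test_nan_distances_rejected(self):
        V = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            ct.ward_linkage(dist_matrix(V, ["a", "b"]), {"a": "h", "b": "h"})


class TestExtractConsensusClusters:
    def triplet_cohort(self, rng, n_groups=2, sep=20.0):
        """One leaf per hemisphere per group, well separated groups."""
        ids, tags, pts = [], {}, []
        for g in range(n_groups):
            for h in ("h1", "h2", "h3"):
                nid = f"g{g}_{h}"
                ids.append(nid)
                tags[nid] = h
                pts.append(np.array([g * sep, 0.0, 0.0]) + rng.normal(0, 0.3, 3))
        D = dist_matrix(squareform(pdist(np.vstack(pts))), ids)
        return D, tags

    def test_two_planted_triplets(self, rng):
        D, tags = self.triplet_cohort(rng)
        part = ct.extract_consensus_clusters(ct.ward_linkage(D, tags))
        sizes = sorted(
            sum(len(v) for v in c["members"].values()) for c in part.clusters
        )
        assert sizes == [3, 3] and not part.unassigned

    def test_connectivity_splits_what_morphology_cannot(self, rng):
        """Twelve neurons, four per hemisphere: one morphological blob but two
        balanced connectivity groups -> two clusters of six on connectivity
        distances, one cluster of twelve on morphology distances."""
        hemis = ["hb", "fw_l", "fw_r"]
        ids, tags, sub = [], {}, {}
        for h in hemis:
            for i in range(4):
                nid = f"{h}_{i}"
                ids.append(nid)
                tags[nid] = h
                sub[nid] = i % 2
        X = np.zeros((12, 4))
        for k, nid in enumerate(ids):
            g = sub[nid]
            X[k, g] = 100 + rng.normal(0, 10)
            X[k, 2 + g] = 50 + rng.normal(0, 8)
            X[k, 2 + (1 - g)] = 10 + rng.normal(0, 3)
        Dc = cm.cosine_distances(
            cm.ConnectivityProfile(X, ids, [tags[i] for i in ids], ["X", "Y"])
        )
        pc = ct.extract_consensus_clusters(ct.ward_linkage(Dc, tags))
        assert sorted(
            sum(len(v) for v in c["members"].values()) for c in pc.clusters
        ) == [6, 6]
        # same neurons, one shared morphology
        proto = sd._random_tree(np.random.default_rng(1), np.array([50.0] * 3), 120)
        dps = [
            mo.make_dotprops(
                proto.xyz + np.random.default_rng(100 + k).normal(0, 0.5, proto.xyz.shape),
                neuron_id=nid,
            )
            for k, nid in enumerate(ids)
        ]
        Dm = mo.scores_to_distance(mo.mean_scores(mo.nblast_matrix(dps)))
        pm = ct.extract_consensus_clusters(ct.ward_linkage(Dm, tags))
        assert [
            sum(len(v) for v in c["members"].values()) for c in pm.clusters
        ] == [12]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_enumeration_oracle_on_small_trees(self, seed):
        """Bare deepest-admissible-ancestor semantics vs leaf-set enumeration."""
        rng = np.random.default_rng(seed)
        n = 9
        ids = [f"n{i}" for i in range(n)]
        tag_list = [("h1", "h2", "h3")[i % 3] for i in range(n)]
        tags = dict(zip(ids, tag_list))
        pts = rng.uniform(0, 10, (n, 3))
        D = dist_matrix(squareform(pdist(pts)), ids)
        dend = ct.ward_linkage(D, tags)
        part = ct.extract_consensus_clusters(
            dend, definition_check=False, split_gap=None
        )
        oracle = extraction_oracle(dend.Z, tag_list)
        got = {}
        for c in part.clusters:
            for ids_ in c["members"].values():
                for nid in ids_:
                    got[nid] = c["label"]
        for nid in part.unassigned:
            got[nid] = None
        # same partition up to relabelling
        by_oracle = {}
        for leaf, node in oracle.items():
            by_oracle.setdefault(node, set()).add(ids[leaf])
        oracle_sets = {frozenset(v) for k, v in by_oracle.items() if k is not None}
        got_sets = {
            frozenset(
                nid for nid, lab in got.items() if lab == c["label"]
            )
            for c in part.clusters
        }
        assert got_sets == oracle_sets
        assert {ids[l] for l, v in oracle.items() if v is None} == set(part.unassigned)

    def test_partition_covers_every_leaf_exactly_once(self, small_cohort_distances):
        D, tags, _ = small_cohort_distances
        part = ct.extract_consensus_clusters(ct.ward_linkage(D, tags))
        seen = list(part.unassigned)
        for c in part.clusters:
            for v in c["members"].values():
                seen.extend(v)
        assert sorted(seen) == sorted(D.row_ids)

    def test_every_cluster_satisfies_criteria(self, small_cohort_distances):
        D, tags, _ = small_cohort_distances
        crit = ct.ConsensusCriteria()
        part = ct.extract_consensus_clusters(ct.ward_linkage(D, tags), crit)
        from collections import Counter

        for c in part.clusters:
            counts = Counter({h: len(v) for h, v in c["members"].items()})
            assert crit.admissible(counts, frozenset(tags.values()))

    def test_relaxing_balance_refines_partition(self, small_cohort_distances):
        """Raising the balance tolerance can only split clusters further
        (the partition refines), never merge them."""
        D, tags, _ = small_cohort_distances
        dend = ct.ward_linkage(D, tags)
        prev_sets = None
        for tol in (1.5, 3.0, 6.0):
            crit = ct.ConsensusCriteria(balance_tolerance=tol)
            part = ct.extract_consensus_clusters(
                dend, crit, definition_check=False, split_gap=None
            )
            sets = [
                frozenset(n for v in c["members"].values() for n in v)
                for c in part.clusters
            ]
            if prev_sets is not None:
                assert len(sets) >= len(prev_sets)
                for s in sets:
                    assert any(s <= p for p in prev_sets) or not any(
                        s & p for p in prev_sets
                    )
            prev_sets = sets

    def test_recovers_planted_types_with_default_noise(self, small_cohort_distances):
        D, tags, truth = small_cohort_distances
        part = ct.extract_consensus_clusters(ct.ward_linkage(D, tags))
        labels = part.labels()
        ids = list(truth)
        ari = adjusted_rand_score([truth[i] for i in ids], [labels[i] for i in ids])
        assert ari >= 0.95

    def test_empty_dendrogram_rejected(self):
        dend = ct.Dendrogram(Z=np.zeros((0, 4)), leaf_ids=[], leaf_tags=[])
        with pytest.raises(ValueError, match="empty"):
            ct.extract_consensus_clusters(dend)


class TestClassifyMapping:
    def make_partition(self, mapping):
        """mapping: cluster label -> list of (neuron, hemisphere)."""
        clusters = []
        for lab, members in mapping.items():
            by_h = {}
            for nid, h in members:
                by_h.setdefault(h, []).append(nid)
            clusters.append({"label": lab, "members": by_h, "flagged": False})
        return ct.ConsensusPartition(clusters=clusters)

    def test_identical_partitions_all_one_to_one(self):
        part = self.make_partition(
            {"c1": [("a", "h1"), ("b", "h2")], "c2": [("c", "h1"), ("d", "h2")]}
        )
        ref = {"a": "T1", "b": "T1", "c": "T2", "d": "T2"}
        rep = ct.classify_mapping(part, ref)
        assert rep.fractions == {"one_to_one": 1.0}
        assert rep.new_labels == {"c1": "T1", "c2": "T2"}

    def test_bisected_reference_type_is_split_with_suffixes(self):
        part = self.make_partition(
            {"c1": [("a", "h1"), ("b", "h2")], "c2": [("c", "h1"), ("d", "h2")]}
        )
        ref = {"a": "PS090", "b": "PS090", "c": "PS090", "d": "PS090"}
        rep = ct.classify_mapping(part, ref)
        assert rep.relations == {"c1": "split", "c2": "split"}
        assert sorted(rep.new_labels.values()) == ["PS090a", "PS090b"]

    def test_merged_reference_types_get_composite_label(self):
        part = self.make_partition({"c1": [("a", "h1"), ("b", "h2")]})
        ref = {"a": "SIP078", "b": "SIP080"}
        rep = ct.classify_mapping(part, ref)
        assert rep.relations == {"c1": "merge"}
        assert rep.new_labels == {"c1": "SIP078,SIP080"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_double_labelling_matches_component_oracle(self, seed):
        from oracles import bipartite_relations

        rng = np.random.default_rng(seed)
        neurons = [f"n{i}" for i in range(30)]
        cluster_of = {n: f"c{rng.integers(0, 6)}" for n in neurons}
        type_of = {n: f"T{rng.integers(0, 6)}" for n in neurons}
        mapping = {}
        for n, c in cluster_of.items():
            mapping.setdefault(c, []).append((n, "h1"))
        part = self.make_partition(mapping)
        rep = ct.classify_mapping(part, type_of)
        assert rep.relations == bipartite_relations(cluster_of, type_of)

    def test_disjoint_neuron_sets_rejected(self):
        part = self.make_partition({"c1": [("a", "h1")]})
        with pytest.raises(ValueError, match="share no neurons"):
            ct.classify_mapping(part, {"zzz": "T1"})
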