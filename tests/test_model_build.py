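"""Offline phase: fragmentation, L1 k-means, marker tagging, model building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from irdna import (
    ClusteringParams,
    ClusterModel,
    FeatureSpec,
    FeatureVector,
    FragmentationParams,
    TaggingParams,
    build_model,
    fragment_genome,
    kmeans_cluster,
    nearest_cluster,
    tag_marker_clusters,
    write_community,
)
from irdna.errors import InfeasibleClusteringError, NoTaggedClustersError
from irdna.model import kmeans_objective
from irdna.simulate import CommunitySpec, make_community


def _random_vectors(rng, n):
    raw = rng.random((n, 256))
    return raw / raw.sum(axis=1, keepdims=True)


class TestFragmentGenome:
    @pytest.mark.parametrize(
        "length,expected", [(2500, 2), (1000, 1), (999, 0), (2000, 2)]
    )
    def test_window_arithmetic(self, length, expected):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        frags = fragment_genome(seq, "g", FragmentationParams(fragment_length=1000))
        assert len(frags) == expected
        for i, f in enumerate(frags):
            assert (f.start, f.end) == (i * 1000, (i + 1) * 1000)
            assert f.source_id == "g"

    def test_fragment_vectors_match_subsequences(self):
        from irdna import tetra_vector

        seq = "ACGT" * 600
        frags = fragment_genome(seq, "g", FragmentationParams(fragment_length=1000))
        for f in frags:
            np.testing.assert_allclose(
                f.vector.values, tetra_vector(seq[f.start : f.end]).values
            )


class TestKmeans:
    def test_recovers_well_separated_groups(self):
        rng = np.random.default_rng(1)
        a = _random_vectors(rng, 1)[0]
        b = _random_vectors(rng, 1)[0]
        X = np.vstack(
            [a + rng.normal(0, 1e-4, (5, 256)), b + rng.normal(0, 1e-4, (5, 256))]
        )
        assign, centroids, sizes = kmeans_cluster(X, ClusteringParams(n_clusters=2))
        assert len(set(assign[:5])) == 1 and len(set(assign[5:])) == 1
        assert assign[0] != assign[5]
        assert sorted(sizes) == [5, 5]

    def test_single_cluster_centroid_is_mean(self):
        rng = np.random.default_rng(2)
        X = _random_vectors(rng, 20)
        _, centroids, sizes = kmeans_cluster(X, ClusteringParams(n_clusters=1))
        np.testing.assert_allclose(centroids[0], X.mean(axis=0))
        assert sizes[0] == 20

    def test_assignment_step_never_increases_objective(self):
        rng = np.random.default_rng(3)
        X = _random_vectors(rng, 120)
        history = []
        kmeans_cluster(X, ClusteringParams(n_clusters=8), objective_history=history)
        assert history, "expected at least one recorded iteration"
        for pre, post in history:
            assert post <= pre + 1e-9

    def test_returned_assignment_minimizes_pointwise(self):
        rng = np.random.default_rng(4)
        X = _random_vectors(rng, 60)
        assign, centroids, _ = kmeans_cluster(X, ClusteringParams(n_clusters=5))
        D = cdist(X, centroids, metric="cityblock")
        np.testing.assert_array_equal(assign, D.argmin(axis=1))
        assert kmeans_objective(X, centroids, assign) == pytest.approx(
            D.min(axis=1).sum()
        )

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(5)
        X = _random_vectors(rng, 80)
        p = ClusteringParams(n_clusters=6, random_seed=11)
        out1 = kmeans_cluster(X, p)
        out2 = kmeans_cluster(X, p)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)

    def test_infeasible_when_fewer_points_than_clusters(self):
        rng = np.random.default_rng(6)
        with pytest.raises(InfeasibleClusteringError):
            kmeans_cluster(_random_vectors(rng, 3), ClusteringParams(n_clusters=5))

    def test_sizes_conserve_points(self):
        rng = np.random.default_rng(7)
        X = _random_vectors(rng, 97)
        _, _, sizes = kmeans_cluster(X, ClusteringParams(n_clusters=13))
        assert sizes.sum() == 97


def _model_from(centroids, sizes=None, tagged=()):
    k = len(centroids)
    return ClusterModel(
        spec=FeatureSpec(),
        centroids=centroids,
        sizes=np.full(k, 10) if sizes is None else np.asarray(sizes),
        tagged_cluster_ids=set(tagged),
    )


class TestNearestCluster:
    def test_exact_centroid_and_tie_rule(self):
        rng = np.random.default_rng(8)
        C = _random_vectors(rng, 6)
        C[5] = C[2]  # exact tie between ids 2 and 5
        model = _model_from(C)
        v = FeatureVector(C[3], 1)
        assert nearest_cluster(v, model) == 3
        assert nearest_cluster(FeatureVector(C[2], 1), model) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50)
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        C = _random_vectors(rng, int(rng.integers(2, 20)))
        model = _model_from(C)
        v = FeatureVector(_random_vectors(rng, 1)[0], 1)
        expected = int(np.argmin([np.abs(c - v.values).sum() for c in C]))
        assert nearest_cluster(v, model) == expected


class TestTagging:
    def _vectors_at(self, centroids, counts):
        out = []
        for cid, n in counts.items():
            out.extend(FeatureVector(centroids[cid], 1) for _ in range(n))
        return out

    def test_absolute_threshold(self):
        rng = np.random.default_rng(9)
        C = _random_vectors(rng, 8)
        model = _model_from(C)
        vectors = self._vectors_at(C, {3: 12, 7: 9})
        tagged = tag_marker_clusters(
            vectors, model, TaggingParams(min_pick_count=10, min_pick_fraction=None)
        )
        assert tagged == {3} == model.tagged_cluster_ids

    def test_fractional_threshold(self):
        rng = np.random.default_rng(10)
        C = _random_vectors(rng, 4)
        model = _model_from(C)
        vectors = self._vectors_at(C, {1: 6, 2: 4})
        assert tag_marker_clusters(
            vectors, model, TaggingParams(min_pick_fraction=0.5)
        ) == {1}

    def test_unanimous_markers_tag_single_cluster(self):
        rng = np.random.default_rng(11)
        C = _random_vectors(rng, 5)
        model = _model_from(C)
        vectors = self._vectors_at(C, {2: 10})
        assert tag_marker_clusters(
            vectors, model, TaggingParams(min_pick_fraction=1.0)
        ) == {2}

    def test_empty_reference_set_rejected(self):
        from irdna.errors import EmptyReferenceError

        rng = np.random.default_rng(12)
        model = _model_from(_random_vectors(rng, 3))
        with pytest.raises(EmptyReferenceError):
            tag_marker_clusters([], model)

    def test_exactly_one_threshold_mode(self):
        with pytest.raises(ValueError):
            TaggingParams(min_pick_count=5, min_pick_fraction=0.2)
        with pytest.raises(ValueError):
            TaggingParams(min_pick_count=None, min_pick_fraction=None)


class TestBuildModel:
    def test_fixture_model_shape_and_conservation(self, community, model):
        expected_fragments = sum(
            len(seq) // 1000 for seq in community.genomes.values()
        )
        assert model.total_fragments == expected_fragments
        assert model.tagged_cluster_ids
        assert model.tagged_cluster_ids <= set(range(model.n_clusters))

    def test_marker_localization(self, community, model):
        """The premise: marker vectors concentrate on few clusters."""
        from irdna import tetra_vector

        assert len(model.tagged_cluster_ids) <= 0.2 * model.n_clusters
        picks = [
            nearest_cluster(tetra_vector(seq), model)
            for seq in community.markers.values()
        ]
        in_tagged = sum(p in model.tagged_cluster_ids for p in picks)
        assert in_tagged >= 0.8 * len(picks)

    def test_determinism(self, community_paths, model, tmp_path):
        from irdna import load_model, save_model

        rebuilt = build_model(community_paths["genomes"], community_paths["markers"])
        np.testing.assert_array_equal(rebuilt.centroids, model.centroids)
        np.testing.assert_array_equal(rebuilt.sizes, model.sizes)
        assert rebuilt.tagged_cluster_ids == model.tagged_cluster_ids
        # byte-identical model files from identical inputs + seed
        save_model(model, tmp_path / "a.irdna")
        save_model(rebuilt, tmp_path / "b.irdna")
        a, b = (load_model(tmp_path / n) for n in ("a.irdna", "b.irdna"))
        assert a.digest() == b.digest()

    def test_background_markers_cannot_tag(self, small_community, tmp_path):
        """References without a conserved family scatter: nothing is tagged.

        Each "marker" is a background slice of a different genome, so each
        reference follows its own genome's signature and no cluster can
        collect a conserved-family majority.
        """
        from irdna import write_fasta

        com = small_community
        fake_markers = {}
        for gid, seq in com.genomes.items():
            start = next(
                s
                for s in range(0, len(seq) - 1500, 500)
                if all(e <= s or b >= s + 1500 for b, e in com.marker_regions[gid])
            )
            fake_markers[f"{gid}_bg"] = seq[start : start + 1500]
        paths = write_community(com, tmp_path)
        write_fasta(tmp_path / "bg_markers.fasta", fake_markers.items())
        with pytest.raises(NoTaggedClustersError):
            build_model(
                paths["genomes"], tmp_path / "bg_markers.fasta",
                clus=ClusteringParams(n_clusters=16, random_seed=0),
                tag=TaggingParams(min_pick_fraction=0.9),
            )
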