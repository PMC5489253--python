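import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mousebrainsim import (
    Connectome,
    ConnectomeError,
    LesionSpec,
    build_region_volume_mapping,
    euclidean_tract_lengths,
    lesion_connectome,
    load_connectome,
    mirror_hemisphere,
)


def two_region():
    return Connectome(
        weights=[[0.0, 1.0], [1.0, 0.0]],
        region_labels=["A", "B"],
        centres=[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
    )


class TestEuclideanTractLengths:
    def test_pythagorean_triple(self):
        c = two_region()
        assert c.tract_lengths[0, 1] == pytest.approx(5.0)

    def test_coincident_centres_are_zero(self):
        tl = euclidean_tract_lengths([[1, 2, 3], [1, 2, 3]])
        assert tl[0, 1] == 0.0

    def test_hand_computed_distance(self):
        tl = euclidean_tract_lengths([[1, 1, 1], [2, 3, 6]])
        assert tl[0, 1] == pytest.approx(np.sqrt(30.0))

    def test_non_finite_centre_names_region(self):
        with pytest.raises(ConnectomeError, match="B"):
            euclidean_tract_lengths([[0, 0, 0], [np.nan, 0, 0]], ["A", "B"])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_is_a_metric_on_random_centres(self, seed):
        centres = np.random.default_rng(seed).normal(size=(6, 3)) * 10
        tl = euclidean_tract_lengths(centres)
        assert np.allclose(tl, tl.T)
        assert np.all(np.diag(tl) == 0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert tl[i, j] <= tl[i, k] + tl[k, j] + 1e-9


class TestValidation:
    def test_non_square_weights_rejected(self, tmp_path):
        (tmp_path / "weights.txt").write_text("0 1 2\n3 4 5\n")
        (tmp_path / "centres.txt").write_text("A 0 0 0\nB 1 0 0\n")
        with pytest.raises(ConnectomeError, match="non-square"):
            load_connectome(tmp_path)

    def test_negative_weight_rejected_with_entry(self, tmp_path):
        (tmp_path / "weights.txt").write_text("0 1\n-0.1 0\n")
        (tmp_path / "centres.txt").write_text("A 0 0 0\nB 1 0 0\n")
        with pytest.raises(ConnectomeError, match=r"\(1, 0\)"):
            load_connectome(tmp_path)

    def test_label_count_mismatch(self, tmp_path):
        (tmp_path / "weights.txt").write_text("0 1\n1 0\n")
        (tmp_path / "centres.txt").write_text("A 0 0 0\n")
        with pytest.raises(ConnectomeError, match="1 labels"):
            load_connectome(tmp_path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConnectomeError, match="unique"):
            Connectome(
                weights=np.zeros((2, 2)),
                region_labels=["A", "A"],
                centres=np.zeros((2, 3)),
            )


class TestRoundTrip:
    @pytest.mark.parametrize("as_zip", [False, True])
    def test_save_load_identity(self, tmp_path, small_connectome, as_zip):
        target = tmp_path / ("c.zip" if as_zip else "c")
        small_connectome.save(target)
        back = load_connectome(target)
        assert np.allclose(back.weights, small_connectome.weights)
        assert np.allclose(back.tract_lengths, small_connectome.tract_lengths)
        assert np.allclose(back.centres, small_connectome.centres)
        assert list(back.region_labels) == list(small_connectome.region_labels)
        assert list(back.hemispheres) == list(small_connectome.hemispheres)

    def test_volume_round_trip(self, tmp_path):
        from mousebrainsim import make_connectome

        conn = make_connectome(4, seed=0, with_volume=True)
        conn.save(tmp_path / "c")
        back = load_connectome(tmp_path / "c")
        assert np.array_equal(back.volume, conn.volume)

    def test_missing_lengths_recomputed(self, tmp_path):
        c = two_region()
        c.save(tmp_path / "c")
        (tmp_path / "c" / "tract_lengths.txt").unlink()
        back = load_connectome(tmp_path / "c")
        assert back.tract_lengths[0, 1] == pytest.approx(5.0)


class TestMirrorHemisphere:
    def test_single_region_hemisphere(self):
        out = mirror_hemisphere([[0.0]], [[7.0]])
        assert np.array_equal(out, [[0.0, 7.0], [7.0, 0.0]])

    def test_two_region_blocks_repeat(self):
        rr = [[0, 2], [1, 0]]
        rl = [[5, 6], [7, 8]]
        out = mirror_hemisphere(rr, rl)
        expected = np.array(
            [
                [0, 2, 5, 6],
                [1, 0, 7, 8],
                [5, 6, 0, 2],
                [7, 8, 1, 0],
            ],
            dtype=float,
        )
        assert np.array_equal(out, expected)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_block_symmetry_exact(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(1, 6))
        rr = rng.random((h, h))
        rl = rng.random((h, h))
        out = mirror_hemisphere(rr, rl)
        assert np.array_equal(out[:h, :h], out[h:, h:])
        assert np.array_equal(out[:h, h:], out[h:, :h])

    def test_shape_mismatch_error(self):
        with pytest.raises(ConnectomeError, match="differ"):
            mirror_hemisphere(np.zeros((2, 2)), np.zeros((3, 3)))


class TestRegionVolumeMapping:
    def test_direct_relabel(self):
        annotation = np.array([[[10, 0], [20, 10]]])
        out = build_region_volume_mapping(annotation, [10, 20])
        assert np.array_equal(out, [[[0, -1], [1, 0]]])

    def test_background_all_minus_one(self):
        out = build_region_volume_mapping(np.zeros((2, 2, 2), dtype=int), [10])
        assert np.all(out == -1)

    def test_unlisted_id_maps_to_background(self):
        annotation = np.array([[[10, 30]]])
        out = build_region_volume_mapping(annotation, [10])
        assert out[0, 0, 0] == 0 and out[0, 0, 1] == -1


class TestLesion:
    def test_conserving_lesion_matches_hand_result(self):
        conn = Connectome(
            weights=[[0, 1, 1], [1, 0, 1], [1, 1, 0]],
            region_labels=["a", "b", "c"],
            centres=np.eye(3),
        )
        out = lesion_connectome(conn, LesionSpec(region_names=("c",)))
        # remaining sum 2 scaled back to 6 -> factor 3
        assert np.allclose(out.weights, [[0, 3, 0], [3, 0, 0], [0, 0, 0]])
        assert out.weights.sum() == pytest.approx(conn.weights.sum())

    def test_empty_lesion_set_rejected(self, small_connectome):
        with pytest.raises(ConnectomeError, match="empty"):
            lesion_connectome(small_connectome, LesionSpec(region_names=()))

    def test_without_conservation_no_rescale(self, small_connectome):
        spec = LesionSpec(region_names=("R00",), conserve_total_weight=False)
        out = lesion_connectome(small_connectome, spec)
        i = small_connectome.index("R00")
        keep = [j for j in range(small_connectome.n_regions) if j != i]
        assert np.array_equal(
            out.weights[np.ix_(keep, keep)], small_connectome.weights[np.ix_(keep, keep)]
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_total_weight_conserved_and_rows_zeroed(self, seed):
        from mousebrainsim import make_connectome

        conn = make_connectome(8, seed=seed)
        out = lesion_connectome(conn, LesionSpec(region_names=("R01", "L02")))
        assert abs(out.weights.sum() - conn.weights.sum()) < 1e-9 * conn.weights.sum()
        for name in ("R01", "L02"):
            i = conn.index(name)
            assert np.all(out.weights[i, :] == 0)
            assert np.all(out.weights[:, i] == 0)

    def test_lesion_all_regions_rejected(self, small_connectome):
        with pytest.raises(ConnectomeError, match="all regions"):
            lesion_connectome(
                small_connectome,
                LesionSpec(region_names=tuple(small_connectome.region_labels)),
            )
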