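"""Delta-Map pipeline: feature extraction, differencing oracle, binarization, march."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltamarch import nn
from deltamarch.nn import random_conv_filter
from deltamarch.delta_march import (
    DeltaMap,
    compute_delta_map,
    extract_features,
    march,
    normalize_binarize,
    sub_transition_indices,
    upscale_bilinear,
)
from deltamarch.traversal import Trajectory, TrajectoryNode
from oracles import brute_force_delta, hand_filter


class TestExtractFeatures:
    def test_deterministic_and_shaped(self, filter_net):
        img = np.random.default_rng(0).random((32, 32, 3))
        f1 = extract_features(img, filter_net)
        f2 = extract_features(img, filter_net)
        assert np.array_equal(f1.values, f2.values)
        assert f1.values.shape == (32, 8, 8)  # two pool stages

    def test_zero_image_through_biasfree_linear_filter(self):
        filt, w, _ = hand_filter()
        filt.layers[0].b[:] = 0.0
        f = extract_features(np.zeros((8, 8, 3)), filt)
        assert np.all(f.values == 0.0)

    def test_excessive_depth_rejected(self, filter_net):
        img = np.zeros((32, 32, 3))
        with pytest.raises(ValueError, match="depth"):
            extract_features(img, filter_net, depth=99)


class TestComputeDeltaMap:
    def test_identical_pair_zero(self, filter_net):
        img = np.random.default_rng(1).random((32, 32, 3))
        dm = compute_delta_map(img, img, filter_net)
        assert np.all(dm.raw == 0.0)

    def test_symmetry_exact(self, filter_net):
        rng = np.random.default_rng(2)
        a, b = rng.random((32, 32, 3)), rng.random((32, 32, 3))
        d1 = compute_delta_map(a, b, filter_net)
        d2 = compute_delta_map(b, a, filter_net)
        assert np.array_equal(d1.raw, d2.raw)

    def test_size_mismatch_rejected(self, filter_net):
        with pytest.raises(ValueError):
            compute_delta_map(np.zeros((32, 32, 3)), np.zeros((16, 16, 3)), filter_net)

    def test_matches_brute_force_oracle_8x8(self):
        filt, w, b = hand_filter()
        rng = np.random.default_rng(7)
        a, r = rng.random((8, 8, 3)), rng.random((8, 8, 3))
        dm = compute_delta_map(a, r, filt)
        oracle = brute_force_delta(a, r, w, b)
        assert np.max(np.abs(dm.raw - oracle)) < 1e-6

    def test_scale_covariance_linear_filter(self):
        """Scaling a linear filter's weights by c scales raw maps by |c|."""
        filt, w, b = hand_filter()
        filt.layers[0].b[:] = 0.0
        rng = np.random.default_rng(8)
        a, r = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        base = compute_delta_map(a, r, filt).raw
        filt.layers[0].w *= -3.0
        scaled = compute_delta_map(a, r, filt).raw
        assert np.allclose(scaled, 3.0 * base)


class TestNormalizeBinarize:
    def test_constant_map_degenerates_to_zero(self):
        dm = normalize_binarize(DeltaMap(raw=np.full((8, 8), 2.5)))
        assert np.all(dm.normalized == 0.0) and np.all(dm.binary == 0)

    def test_checkerboard_binary(self):
        raw = np.indices((8, 8)).sum(axis=0) % 2
        dm = normalize_binarize(DeltaMap(raw=raw.astype(float)))
        assert np.array_equal(dm.binary, raw)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_binary_count_matches_enumeration(self, seed):
        raw = np.random.default_rng(seed).random((16, 16))
        dm = normalize_binarize(DeltaMap(raw=raw.copy()))
        midrange = (raw.min() + raw.max()) / 2
        expected = sum(1 for v in raw.ravel() if v > midrange)
        assert int(dm.binary.sum()) == expected

    def test_min_only_mode(self):
        raw = np.array([[0.0, 1.0], [2.0, 3.0]])
        dm = normalize_binarize(DeltaMap(raw=raw), threshold=0.5, mode="min")
        assert np.array_equal(dm.normalized, raw)
        assert np.array_equal(dm.binary, (raw > 0.5).astype(np.uint8))


def _fake_trajectory(images, grades, direction=4):
    nodes = [TrajectoryNode(code=np.zeros(2), image=im, predicted_grade=g)
             for im, g in zip(images, grades)]
    return Trajectory(start=nodes[0], end=nodes[-1], nodes=nodes[1:-1], state=0,
                      direction_class=direction, n_shift_steps=2, halted_by="terminal_grade")


class TestMarch:
    def test_identical_images_all_maps_zero(self, filter_net):
        img = np.random.default_rng(3).random((32, 32, 3))
        traj = _fake_trajectory([img] * 6, [1, 2, 2, 3, 4, 4])
        maps = march(traj, filter_net)
        assert len(maps) == 3
        assert all(np.all(m.raw == 0) for m in maps)

    def test_one_to_four_gives_three_sub_transitions(self, sample_trajectory, filter_net):
        maps = march(sample_trajectory, filter_net)
        assert [m.label for m in maps] == ["1->2", "2->3", "3->4"]

    def test_direct_jump_map_appended(self, sample_trajectory, filter_net):
        maps = march(sample_trajectory, filter_net, include_direct=True)
        assert maps[-1].label == "direct"

    def test_single_image_trajectory_rejected(self, filter_net):
        img = np.zeros((32, 32, 3))
        node = TrajectoryNode(code=np.zeros(2), image=img, predicted_grade=1)
        traj = Trajectory(start=node, end=node, nodes=[], state=0, direction_class=4,
                          n_shift_steps=0, halted_by="terminal_grade")
        traj.end = traj.start
        traj.nodes = []
        # make all_nodes return a single element to model a malformed trajectory
        traj.all_nodes = lambda: [node]
        with pytest.raises(ValueError, match="two images"):
            march(traj, filter_net)

    def test_delta_concentrates_on_tumor_nuclei(self, tumor_only_march, filter_net):
        """Where only tumor nuclei grow with grade, binary Delta-Maps light up
        tumor-nucleus pixels more than background pixels."""
        items, trajectories = tumor_only_march
        traj = trajectories[0]
        maps = march(traj, random_conv_filter(seed=21))
        nodes = traj.all_nodes()
        for dm, (label, i, j) in zip(maps, sub_transition_indices(traj)):
            tumor = (nodes[i].patch.nuclei_mask == 2) | (nodes[j].patch.nuclei_mask == 2)
            bg = (nodes[i].patch.nuclei_mask == 0) & (nodes[j].patch.nuclei_mask == 0) \
                & (nodes[i].patch.vasc_mask == 0) & (nodes[j].patch.vasc_mask == 0)
            assert dm.binary[tumor].mean() > dm.binary[bg].mean()


class TestUpscale:
    def test_identity_when_same_size(self):
        a = np.random.default_rng(4).random((8, 8))
        assert np.allclose(upscale_bilinear(a, 8, 8), a)

    def test_constant_preserved(self):
        assert np.allclose(upscale_bilinear(np.full((4, 4), 3.3), 16, 16), 3.3)


def test_save_delta_map_writes_artifacts(tmp_path, filter_net):
    from deltamarch.delta_march import save_delta_map

    rng = np.random.default_rng(9)
    dm = compute_delta_map(rng.random((32, 32, 3)), rng.random((32, 32, 3)), filter_net)
    dm = normalize_binarize(dm)
    save_delta_map(dm, tmp_path, "t", manifest={"filter": "random", "depth": None})
    for suffix in ("t_raw.tif", "t_norm.png", "t_binary.png", "t_manifest.json"):
        assert (tmp_path / suffix).exists()
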