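import numpy as np
import pytest

from fcvessel import (
    AffinityParams,
    Scene,
    affinity,
    build_lut,
    compute_connectivity,
    connectivity_oracle,
    path_strength,
)
from conftest import random_scene


class TestPathStrength:
    def test_single_voxel_path_is_one(self):
        scene = Scene(np.full((2, 2, 2), 100, dtype=np.uint8))
        assert path_strength([(0, 0, 0)], scene, AffinityParams(m=100, s=10)) == 1.0

    def test_chain_strength_is_weakest_link(self):
        # 1x1x3 chain: links (100,100) -> 1.0 and (100,140) -> gauss(120)
        scene = Scene(np.array([[[100, 100, 140]]], dtype=np.uint8))
        p = AffinityParams(m=100, s=10)
        path = [(0, 0, 0), (0, 0, 1), (0, 0, 2)]
        assert path_strength(path, scene, p) == affinity(100, 140, p)

    def test_reversal_invariant(self):
        rng = np.random.default_rng(1)
        scene = random_scene(rng, (1, 1, 5))
        p = AffinityParams(m=120, s=20)
        path = [(0, 0, z) for z in range(5)]
        assert path_strength(path, scene, p) == path_strength(path[::-1], scene, p)

    def test_non_adjacent_consecutive_pair_rejected(self):
        scene = Scene(np.zeros((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="not 6-adjacent"):
            path_strength([(0, 0, 0), (0, 0, 2)], scene, AffinityParams(m=0, s=1))


class TestOracle:
    def test_single_voxel_scene(self):
        cs = connectivity_oracle(Scene(np.array([[[7]]], dtype=np.uint8)), (0, 0, 0),
                                 AffinityParams(m=7, s=1))
        assert cs.values.tolist() == [[[1.0]]]

    def test_chain_connectivity_equals_single_path_minimum(self):
        # only one simple path to each voxel on a 1x1x4 chain
        scene = Scene(np.array([[[100, 102, 130, 120]]], dtype=np.uint8))
        p = AffinityParams(m=100, s=10)
        cs = connectivity_oracle(scene, (0, 0, 0), p)
        links = [affinity(100, 102, p), affinity(102, 130, p), affinity(130, 120, p)]
        expected = [1.0, links[0], min(links[:2]), min(links)]
        assert cs.values[0, 0].tolist() == expected

    def test_loop_prefers_stronger_roundabout_path(self):
        # 2x2x1 loop: seed at (0,0)=140; the direct link to (1,0)=160 has
        # pair mean 150 (far from m=100), while the path through the two
        # 100-voxels reaches it with a much stronger weakest link
        vals = np.array([[[140], [100]], [[160], [100]]], dtype=np.uint8)
        scene = Scene(vals)
        p = AffinityParams(m=100, s=15)
        cs = connectivity_oracle(scene, (0, 0, 0), p)
        direct = path_strength([(0, 0, 0), (1, 0, 0)], scene, p)
        around = path_strength([(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)], scene, p)
        assert around > direct
        assert cs.values[1, 0, 0] == max(direct, around)


class TestComputeConnectivity:
    def test_matches_oracle_on_random_scenes(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            scene = random_scene(rng)
            p = AffinityParams(m=float(rng.uniform(50, 200)), s=float(rng.uniform(5, 40)))
            seed = tuple(int(rng.integers(0, n)) for n in scene.shape)
            oracle = connectivity_oracle(scene, seed, p)
            queue = compute_connectivity(scene, seed, params=p)
            np.testing.assert_array_equal(queue.values, oracle.values)

    def test_uniform_scene_at_vessel_mean_fully_connected(self):
        scene = Scene(np.full((5, 5, 5), 160, dtype=np.uint8))
        cs = compute_connectivity(scene, (2, 2, 2), params=AffinityParams(m=160, s=10))
        assert np.all(cs.values == 1.0)

    def test_underflow_slab_disconnects_far_side(self):
        # a slab at intensity 0 splits a bright scene; with s=2 the link
        # Gaussian underflows to exactly 0, so nothing beyond is reached
        vals = np.full((3, 3, 7), 200, dtype=np.uint8)
        vals[:, :, 3] = 0
        cs = compute_connectivity(Scene(vals), (1, 1, 0), params=AffinityParams(m=200, s=2))
        assert np.all(cs.values[:, :, :3] > 0)
        assert np.all(cs.values[:, :, 3:] == 0.0)

    def test_lut_and_direct_evaluation_bit_identical(self):
        rng = np.random.default_rng(9)
        scene = random_scene(rng, (6, 6, 6))
        p = AffinityParams(m=140.5, s=22.25)
        direct = compute_connectivity(scene, (3, 3, 3), params=p)
        via_lut = compute_connectivity(scene, (3, 3, 3), lut=build_lut(p))
        np.testing.assert_array_equal(direct.values, via_lut.values)

    def test_tie_break_order_does_not_change_result(self):
        rng = np.random.default_rng(4)
        scene = random_scene(rng, (5, 5, 4))
        lut = build_lut(AffinityParams(m=128, s=30))
        fifo = compute_connectivity(scene, (2, 2, 2), lut=lut, tie_break="fifo")
        lifo = compute_connectivity(scene, (2, 2, 2), lut=lut, tie_break="lifo")
        np.testing.assert_array_equal(fifo.values, lifo.values)

    def test_popped_values_non_increasing(self):
        rng = np.random.default_rng(2)
        scene = random_scene(rng, (6, 6, 5))
        pops = []
        compute_connectivity(scene, (0, 0, 0), params=AffinityParams(m=100, s=25), pop_log=pops)
        assert all(a >= b for a, b in zip(pops, pops[1:]))

    def test_first_link_bounds_all_connectivity(self):
        rng = np.random.default_rng(6)
        scene = random_scene(rng, (5, 5, 5))
        p = AffinityParams(m=120, s=15)
        seed = (2, 2, 2)
        cs = compute_connectivity(scene, seed, params=p)
        f_seed = float(scene.values[seed])
        first_links = [
            affinity(f_seed, float(scene.values[n]), p)
            for n in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]
        ]
        mask = np.ones(scene.shape, dtype=bool)
        mask[seed] = False
        assert cs.values[mask].max() <= max(first_links)

    def test_invalid_arguments_rejected(self):
        scene = Scene(np.zeros((2, 2, 2), dtype=np.uint8))
        p = AffinityParams(m=0, s=1)
        with pytest.raises(ValueError, match="exactly one"):
            compute_connectivity(scene, (0, 0, 0))
        with pytest.raises(ValueError, match="exactly one"):
            compute_connectivity(scene, (0, 0, 0), lut=build_lut(p), params=p)
        with pytest.raises(ValueError, match="outside"):
            compute_connectivity(scene, (2, 0, 0), params=p)
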