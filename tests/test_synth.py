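"""Scene-generator properties: determinism, planted geometry, rendering
physics (linearity, flux conservation), round simulation, and the planted
statistical conditions (pair mixture, nearest-neighbor spacing)."""

import io as _io

import numpy as np
import pytest
from scipy.spatial import cKDTree

from speconn.io import write_swc
from speconn.synth import (NoiseConfig, SceneConfig, assign_colors,
                           build_scene, generate_puncta_field,
                           generate_skeletons, render_blobs, render_scene,
                           sample_simplex_centers, simulate_rounds,
                           surface_points)
from speconn.types import SWC_AXON, SWC_DENDRITE, SWC_SOMA, ColorVector, VoxelGrid

TINY = dict(size_um=(20.0, 20.0, 12.0), n_neurons=1, n_external_axons=2,
            soma_radius_um=(4.0, 4.5), dendrite_total_um=120.0,
            n_synapses=5, n_distractor_contact=0, n_distractor_unlabeled=0,
            n_color_clusters=3, fiducial_n_blobs=40)


class TestSkeletons:
    def test_single_neuron_tree(self):
        cfg = SceneConfig(seed=1, **{**TINY, "n_external_axons": 0})
        sks = generate_skeletons(cfg, 1)
        assert len(sks) == 1
        sk = sks[0]
        assert sum(1 for n in sk.nodes if n.parent_id == -1) == 1
        assert sk.root.swc_type == SWC_SOMA

    def test_determinism_byte_for_byte(self, tmp_path):
        cfg = SceneConfig(seed=5, **TINY)
        paths = []
        for run in range(2):
            sks = generate_skeletons(cfg, 5)
            p = tmp_path / f"run{run}.swc"
            write_swc(sks, [], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_path_length_matches_independent_traversal(self):
        cfg = SceneConfig(seed=2, **TINY)
        sk = generate_skeletons(cfg, 2)[0]
        # oracle: brute-force walk over explicit (parent, child) pairs
        total = 0.0
        index = {n.node_id: n for n in sk.nodes}
        for n in sk.nodes:
            if n.parent_id != -1:
                p = index[n.parent_id]
                total += float(np.linalg.norm(np.subtract(n.position, p.position)))
        from_edges = sum(float(np.linalg.norm(np.subtract(c.position, p.position)))
                         for p, c in sk.edges())
        assert from_edges == pytest.approx(total)

    def test_node_spacing_bound(self):
        cfg = SceneConfig(seed=3, **TINY)
        sk = generate_skeletons(cfg, 3)[0]
        seglens = [np.linalg.norm(np.subtract(c.position, p.position))
                   for p, c in sk.edges()
                   if p.swc_type != SWC_SOMA and c.swc_type != SWC_SOMA]
        assert max(seglens) <= cfg.node_spacing_nm + 1e-6


class TestColors:
    def test_center_separation(self, rng):
        centers = sample_simplex_centers(3, 0.5, rng)
        d = [np.linalg.norm(centers[i] - centers[j])
             for i in range(3) for j in range(i + 1, 3)]
        assert min(d) >= 0.5
        assert np.allclose(centers.sum(axis=1), 1.0)

    def test_dense_packing_via_lattice(self, rng):
        centers = sample_simplex_centers(40, 0.15, rng)
        t = cKDTree(centers)
        assert t.query(centers, k=2)[0][:, 1].min() >= 0.15 - 1e-9

    def test_single_cluster_and_zero_jitter(self, rng):
        cfg = SceneConfig(seed=4, **TINY)
        sks = generate_skeletons(cfg, 4)
        centers = assign_colors(sks, 1, 0.3, rng, jitter=0.0)
        for sk in sks:
            assert sk.color.simplex == pytest.approx(tuple(centers[0]))


class TestRendering:
    def test_hollow_tube_profile_is_bimodal(self):
        # straight tube along x, no noise: a profile across it crosses two
        # membrane walls
        from speconn.types import Skeleton, SkeletonNode
        nodes = [SkeletonNode(i + 1, SWC_AXON, (x, 5000.0, 3000.0), 600.0,
                              -1 if i == 0 else i)
                 for i, x in enumerate(np.arange(0, 10000, 37.5))]
        sk = Skeleton(neuron_id="A", nodes=nodes)
        sk.color = ColorVector(raw=(1.0, 0.0, 0.0))
        cfg = SceneConfig(seed=0, size_um=(10, 10, 6), n_neurons=0,
                          n_external_axons=0, n_synapses=0,
                          n_distractor_contact=0, n_distractor_unlabeled=0)
        grid = render_scene([sk], cfg, seed=0)
        ch = grid.channel("FP1")
        zi = int(round(3000 / cfg.pitch_nm[0]))
        xi = int(round(5000 / cfg.pitch_nm[2]))
        profile = ch[zi, :, xi]
        yc = int(round(5000 / 75.0))
        inner = profile[yc]
        walls = (profile[yc - 8:yc - 2].max(), profile[yc + 3:yc + 9].max())
        assert min(walls) > inner * 1.3  # membrane brighter than lumen

    def test_color_linearity(self):
        from speconn.types import Skeleton, SkeletonNode
        nodes = [SkeletonNode(i + 1, SWC_AXON, (x, 5000.0, 3000.0), 400.0,
                              -1 if i == 0 else i)
                 for i, x in enumerate(np.arange(0, 8000, 37.5))]
        cfg = SceneConfig(seed=0, size_um=(10, 10, 6), n_neurons=0,
                          n_external_axons=0, n_synapses=0,
                          n_distractor_contact=0, n_distractor_unlabeled=0)
        out = []
        for w in (0.3, 0.6):
            sk = Skeleton(neuron_id="A", nodes=[SkeletonNode(
                n.node_id, n.swc_type, n.position, n.radius, n.parent_id)
                for n in nodes])
            sk.color = ColorVector(raw=(w, 0.0, 0.0))
            out.append(render_scene([sk], cfg, seed=0).channel("FP1"))
        np.testing.assert_allclose(out[1], 2.0 * out[0], rtol=1e-5, atol=1e-4)

    def test_flux_conservation_under_psf(self):
        # integrated pre-noise intensity equals splatted point count x weight
        # (normalized PSF conserves flux away from the boundary)
        from speconn.types import Skeleton, SkeletonNode
        nodes = [SkeletonNode(i + 1, SWC_AXON, (x, 5000.0, 3000.0), 300.0,
                              -1 if i == 0 else i)
                 for i, x in enumerate(np.arange(3000, 7000, 37.5))]
        sk = Skeleton(neuron_id="A", nodes=nodes)
        sk.color = ColorVector(raw=(1.0, 0.0, 0.0))
        cfg = SceneConfig(seed=0, size_um=(10, 10, 6), n_neurons=0,
                          n_external_axons=0, n_synapses=0,
                          n_distractor_contact=0, n_distractor_unlabeled=0)
        grid = render_scene([sk], cfg, seed=0)
        rng0 = np.random.default_rng(0)
        npts = len(surface_points(sk, cfg.node_spacing_nm, rng0))
        total = float(grid.channel("FP1").sum())
        expected = npts * cfg.fp_amplitude  # weight = raw[0] * amplitude
        assert total == pytest.approx(expected, rel=0.02)


class TestPlanting:
    def test_synapses_on_post_membrane(self, small_scene):
        # every ground-truth synapse within one shell thickness of its post
        # skeleton's surface
        gt = small_scene.ground_truth
        by_id = {sk.neuron_id: sk for sk in small_scene.skeletons}
        for s in gt.synapses:
            sk = by_id[s.post_neuron_id]
            best = np.inf
            for n in sk.nodes:
                if n.swc_type == SWC_SOMA and n.parent_id != -1:
                    continue  # surface bookkeeping nodes
                if n.swc_type == SWC_AXON:
                    continue
                d = abs(np.linalg.norm(np.subtract(s.position, n.position)) - n.radius)
                best = min(best, d)
            assert best <= gt.config.membrane_thickness_nm + 60.0

    def test_connectivity_totals(self, small_scene):
        gt = small_scene.ground_truth
        assert int(gt.connectivity.to_numpy().sum()) == len(gt.synapses)

    def test_mutually_exclusive_psd(self, small_scene):
        # each planted pair has exactly one PSD kind
        for s in small_scene.ground_truth.synapses:
            assert s.kind in ("excitatory", "inhibitory")

    def test_determinism_full_scene(self):
        cfg = SceneConfig(seed=21, **TINY)
        a = build_scene(cfg)
        b = build_scene(cfg)
        np.testing.assert_array_equal(a.grid.data, b.grid.data)
        assert [s.synapse_id for s in a.ground_truth.synapses] == \
               [s.synapse_id for s in b.ground_truth.synapses]

    def test_mixture_and_spacing(self, default_scene):
        gt = default_scene.ground_truth
        kinds = np.array([s.kind for s in gt.synapses])
        n_pairs = len(kinds) + len(gt.orphan_bassoon_xyz)
        frac_ex = (kinds == "excitatory").sum() / n_pairs
        frac_in = (kinds == "inhibitory").sum() / n_pairs
        # multinomial tolerance at n~150
        assert frac_ex == pytest.approx(0.77, abs=0.10)
        assert frac_in == pytest.approx(0.21, abs=0.10)
        pos = np.array([s.position for s in gt.synapses])
        nn = cKDTree(pos).query(pos, k=2)[0][:, 1]
        assert (nn > 300.0).mean() >= 0.90


@pytest.fixture(scope="module")
def tiny_scene():
    cfg = SceneConfig(seed=9, noise=NoiseConfig(enabled=False), **TINY)
    return build_scene(cfg), cfg


class TestRounds:

    def test_identity_round_one(self, tiny_scene):
        bundle, cfg = tiny_scene
        cfg2 = SceneConfig(**{**cfg.to_dict(), "n_rounds": 1,
                              "noise": {"enabled": False}})
        rounds = simulate_rounds(bundle.grid, cfg2, 0)
        np.testing.assert_array_equal(rounds[0].data, bundle.grid.data)

    def test_decay_multiplicativity(self, tiny_scene):
        bundle, cfg = tiny_scene
        cfg3 = SceneConfig(**{**cfg.to_dict(), "n_rounds": 3, "decay": 0.7,
                              "round_translation_vox": 0.0,
                              "round_rotation_deg": 0.0,
                              "round_scale_range": (1.0, 1.0),
                              "round_wobble_vox": 0.0,
                              "noise": {"enabled": False}})
        rounds = simulate_rounds(bundle.grid, cfg3, 0, bundle.ground_truth)
        fp1 = bundle.grid.channels.index("FP1")
        r3_over_r1 = rounds[2].data[fp1].sum() / rounds[0].data[fp1].sum()
        assert r3_over_r1 == pytest.approx(0.49, rel=1e-3)
        # fiducial is re-stained: no decay
        fid = bundle.grid.channels.index("fiducial")
        assert rounds[2].data[fid].sum() == pytest.approx(
            rounds[0].data[fid].sum(), rel=1e-3)

    def test_planted_warp_recorded(self, tiny_scene):
        bundle, cfg = tiny_scene
        cfg2 = SceneConfig(**{**cfg.to_dict(), "n_rounds": 2,
                              "noise": {"enabled": False}})
        gt = bundle.ground_truth
        simulate_rounds(bundle.grid, cfg2, 3, gt)
        assert len(gt.round_warps) == 2 and gt.round_warps[0] is None
        assert gt.round_warps[1].linear.shape == (3, 3)


class TestPunctaField:
    def test_composition_bookkeeping(self):
        cfg = SceneConfig(seed=2, size_um=(12, 12, 6), n_neurons=0,
                          n_external_axons=0, n_synapses=0,
                          n_distractor_contact=0, n_distractor_unlabeled=0)
        grid, comp = generate_puncta_field(cfg, 40, 2)
        assert sum(comp.values()) == 40
        assert grid.channels == ["Bassoon", "Gephyrin", "Homer1"]
        assert grid.channel("Bassoon").max() > 0
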