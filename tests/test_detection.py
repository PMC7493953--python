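"""Puncta segmentation, pairing, line profiles, and trio classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from speconn.detection import (SegmentationParams, TrioCriteria,
                               classify_trio, extract_line_profile,
                               link_and_compartmentalize, nn_spacing,
                               pair_puncta, segment_puncta)
from speconn.synth.render import render_blobs
from speconn.types import (Punctum, Skeleton, SkeletonNode, TrioVerdict,
                           ValidationError, VoxelGrid)

PITCH = (200.0, 75.0, 75.0)


def blob_grid(centers, sigmas=90.0, amps=200.0, shape=(20, 64, 64),
              channel="Gephyrin"):
    centers = np.atleast_2d(centers)
    data = render_blobs(shape, PITCH, centers,
                        np.broadcast_to(np.asarray(sigmas, float), (len(centers),)),
                        np.broadcast_to(np.asarray(amps, float), (len(centers),)))
    return VoxelGrid(channels=[channel], data=data[None], pitch_nm=PITCH)


def punctum(pid, xyz, channel="Bassoon"):
    return Punctum(punctum_id=pid, channel=channel, centroid=tuple(xyz),
                   volume_um3=0.02, peak_intensity=100.0, voxel_count=10)


class TestSegmentPuncta:
    def test_two_blobs_recovered(self):
        centers = np.array([[1500.0, 1500.0, 1500.0], [2100.0, 1500.0, 1500.0]])
        g = blob_grid(centers)
        out = segment_puncta(g, "Gephyrin")
        assert len(out) == 2
        found = np.array(sorted(p.centroid for p in out))
        np.testing.assert_allclose(found, np.array(sorted(map(tuple, centers))),
                                   atol=75.0)

    def test_blank_channel(self):
        g = VoxelGrid(channels=["Gephyrin"], data=np.zeros((1, 8, 16, 16)),
                      pitch_nm=PITCH)
        assert segment_puncta(g, "Gephyrin") == []

    def test_subresolution_pair_undersplits(self):
        # 150 nm apart with 300 nm seed separation: one punctum by design
        centers = np.array([[1500.0, 1500.0, 1500.0], [1650.0, 1500.0, 1500.0]])
        out = segment_puncta(blob_grid(centers), "Gephyrin")
        assert len(out) == 1

    def test_matches_connected_components_when_no_split(self, rng):
        # oracle equivalence on >= 20 random sparse instances
        for trial in range(20):
            r = np.random.default_rng(trial)
            n = int(r.integers(1, 6))
            centers = np.stack([r.uniform(900, 3600, n), r.uniform(900, 3600, n),
                                r.uniform(900, 2900, n)], axis=1)
            # enforce >= 800 nm spacing so neither merging nor splitting occurs
            keep = []
            for c in centers:
                if all(np.linalg.norm(c - centers[k]) >= 800 for k in keep):
                    keep.append(int(np.where((centers == c).all(1))[0][0]))
            centers = centers[sorted(set(keep))]
            g = blob_grid(centers)
            params = SegmentationParams(threshold=40.0, min_voxels=2)
            out = segment_puncta(g, "Gephyrin", params)
            _, n_cc = ndimage.label(g.channel("Gephyrin") > 40.0)
            assert len(out) == n_cc


class TestPairPuncta:
    def test_nearest_wins_and_exclusivity(self):
        b = [punctum(1, (0, 0, 0))]
        geph = [punctum(2, (150.0, 0, 0), "Gephyrin")]
        hom = [punctum(3, (250.0, 0, 0), "Homer1")]
        pairs, orphans = pair_puncta(b, geph, hom)
        assert len(pairs) == 1 and pairs[0].post.channel == "Gephyrin"
        assert pairs[0].kind == "inhibitory"
        assert [p.punctum_id for p in orphans["Homer1"]] == [3]

    def test_empty_bassoon(self):
        geph = [punctum(1, (0, 0, 0), "Gephyrin")]
        pairs, orphans = pair_puncta([], geph, [])
        assert pairs == [] and len(orphans["Gephyrin"]) == 1

    def test_cutoff(self):
        b = [punctum(1, (0, 0, 0))]
        geph = [punctum(2, (400.0, 0, 0), "Gephyrin")]
        pairs, orphans = pair_puncta(b, geph, [], max_sep_nm=300.0)
        assert pairs == [] and len(orphans["Bassoon"]) == 1

    @given(st.integers(0, 10_000))
    def test_matching_property(self, seed):
        # greedy matching is a matching: no punctum used twice; Gephyrin and
        # Homer1 never share a Bassoon
        r = np.random.default_rng(seed)
        nb, ng, nh = (int(r.integers(0, 6)) for _ in range(3))
        mk = lambda i, c: punctum(i, r.uniform(0, 1200, 3), c)
        b = [mk(i, "Bassoon") for i in range(nb)]
        g = [mk(100 + i, "Gephyrin") for i in range(ng)]
        h = [mk(200 + i, "Homer1") for i in range(nh)]
        pairs, orphans = pair_puncta(b, g, h)
        pre_ids = [id(p.pre) for p in pairs]
        post_ids = [id(p.post) for p in pairs]
        assert len(set(pre_ids)) == len(pre_ids)
        assert len(set(post_ids)) == len(post_ids)
        assert len(pairs) + len(orphans["Bassoon"]) == nb
        assert (len(pairs) + len(orphans["Gephyrin"]) + len(orphans["Homer1"])
                == ng + nh)


class TestNnSpacing:
    def test_hand_example(self):
        pts = np.array([[0, 0, 0], [400.0, 0, 0], [1000.0, 0, 0]])
        d, frac = nn_spacing(pts, 300.0)
        np.testing.assert_allclose(sorted(d), [400, 400, 600])
        assert frac == 1.0

    def test_duplicate_points(self):
        d, frac = nn_spacing(np.array([[1.0, 2, 3], [1.0, 2, 3]]))
        np.testing.assert_allclose(d, [0, 0])
        assert frac == 0.0

    def test_single_point_undefined(self):
        d, frac = nn_spacing(np.array([[0.0, 0, 0]]))
        assert len(d) == 0 and frac is None


class TestLineProfile:
    def test_constant_channel_normalizes_to_zeros(self):
        g = VoxelGrid(channels=["c"], data=np.full((1, 8, 16, 16), 7.0),
                      pitch_nm=PITCH)
        prof = extract_line_profile(g, (0, 0, 0), (800.0, 0, 0), 30.0, ["c"])
        assert np.all(prof.normalized["c"] == 0)
        assert np.all(prof.raw["c"] == 7.0)

    def test_zero_length_refused(self):
        g = VoxelGrid(channels=["c"], data=np.zeros((1, 4, 8, 8)), pitch_nm=PITCH)
        with pytest.raises(ValidationError, match="zero-length"):
            extract_line_profile(g, (10, 10, 10), (10, 10, 10), 30.0, ["c"])

    def test_step_bound(self):
        g = VoxelGrid(channels=["c"], data=np.zeros((1, 4, 8, 8)), pitch_nm=PITCH)
        with pytest.raises(ValidationError, match="step_nm"):
            extract_line_profile(g, (0, 0, 0), (500.0, 0, 0), 60.0, ["c"])

    @pytest.mark.parametrize("sep", [100.0, 150.0, 200.0])
    def test_separation_recovery(self, sep):
        # two sub-resolution blobs in different channels: profile peak-to-peak
        # distance recovers the planted separation within one lateral voxel
        p0 = np.array([2000.0, 2000.0, 1500.0])
        p1 = p0 + np.array([sep, 0, 0])
        shape = (20, 64, 64)
        geph = render_blobs(shape, PITCH, p0[None], [100.0], [200.0],
                            psf_sigma_nm=(85.0, 32.0, 32.0))
        bas = render_blobs(shape, PITCH, p1[None], [90.0], [200.0],
                           psf_sigma_nm=(85.0, 32.0, 32.0))
        g = VoxelGrid(channels=["Gephyrin", "Bassoon"],
                      data=np.stack([geph, bas]), pitch_nm=PITCH)
        a = p0 - np.array([400.0, 0, 0])
        b = p1 + np.array([400.0, 0, 0])
        prof = extract_line_profile(g, a, b, 25.0, ["Gephyrin", "Bassoon"])
        s_g = prof.positions_nm[np.argmax(prof.normalized["Gephyrin"])]
        s_b = prof.positions_nm[np.argmax(prof.normalized["Bassoon"])]
        assert abs(abs(s_b - s_g) - sep) <= 75.0


class TestClassifyTrio:
    def test_planted_trios_accepted_with_expected_order(self, small_scene,
                                                        small_detection):
        gt = small_scene.ground_truth
        accepted = [v for v in small_detection.verdicts if v.accepted]
        assert len(accepted) >= 0.8 * len(gt.synapses)
        for v in accepted:
            # PSD peak, membrane, Bassoon in the expected order (membrane may
            # sit PSD-ward of the PSD peak because the cleft is unresolvable)
            assert v.membrane_peak_nm is not None
            assert v.membrane_peak_nm <= max(v.psd_peak_nm, v.bassoon_peak_nm)
            lo, hi = TrioCriteria().separation_window_nm
            assert lo <= v.separation_nm <= hi

    def test_unlabeled_partner_rejected(self, small_scene, small_detection):
        reasons = small_detection.reason_counts()
        assert reasons.get("unlabeled-partner", 0) >= \
            0.5 * len(small_scene.ground_truth.distractors_unlabeled)

    def test_window_monotonicity(self, small_scene, small_detection):
        # shrinking the separation window never increases the accepted set
        from speconn.detection import SceneIndex
        index = SceneIndex(small_scene.skeletons)
        wide = TrioCriteria(separation_window_nm=(100.0, 200.0))
        narrow = TrioCriteria(separation_window_nm=(130.0, 170.0))
        acc_wide, acc_narrow = set(), set()
        for i, pair in enumerate(small_detection.pairs):
            vw = classify_trio(pair, small_scene.grid, small_scene.skeletons,
                               wide, index)
            vn = classify_trio(pair, small_scene.grid, small_scene.skeletons,
                               narrow, index)
            if vw.accepted:
                acc_wide.add(i)
            if vn.accepted:
                acc_narrow.add(i)
        assert acc_narrow <= acc_wide

    def test_out_of_window_pair_rejected(self, small_scene, small_detection):
        # a real pair whose separation falls outside the criteria window must
        # be rejected with the separation reason
        from speconn.detection import SceneIndex
        index = SceneIndex(small_scene.skeletons)
        pair = next(v.pair for v in small_detection.verdicts if v.accepted)
        crit = TrioCriteria(separation_window_nm=(10.0, 80.0))
        v = classify_trio(pair, small_scene.grid, small_scene.skeletons,
                          crit, index)
        assert not v.accepted and v.reason == "separation-out-of-range"


class TestLinking:
    def make_skeleton(self):
        nodes = [
            SkeletonNode(1, 1, (0, 0, 0), 4000.0, -1),
            SkeletonNode(3, 1, (4000.0, 0, 0), 400.0, 1),
            SkeletonNode(9, 3, (8000.0, 0, 0), 400.0, 3),
        ]
        return Skeleton(neuron_id="N1", nodes=nodes)

    def _verdict(self, sk, xyz):
        from speconn.types import MarkerPair
        pair = MarkerPair(pre=punctum(1, np.asarray(xyz) + [150.0, 0, 0]),
                          post=punctum(2, xyz, "Gephyrin"), separation_nm=150.0)
        return TrioVerdict(pair=pair, accepted=True, reason="accepted",
                           post_neuron_id="N1", pre_axon_id="A1")

    def test_somatic_compartment(self):
        sk = self.make_skeleton()
        recs, q = link_and_compartmentalize([self._verdict(sk, (3950.0, 0, 0))], [sk])
        assert not q and recs[0].compartment == "somatic" and recs[0].node_id == 3

    def test_equidistant_tie_goes_to_lower_node_id(self):
        sk = self.make_skeleton()
        recs, _ = link_and_compartmentalize([self._verdict(sk, (6000.0, 0, 0))], [sk])
        # exactly halfway between node 3 (soma) and node 9 (dendrite)
        assert recs[0].node_id == 3 and recs[0].compartment == "somatic"

    def test_compartments_match_ground_truth(self, small_scene, small_detection):
        from scipy.spatial import cKDTree
        gt = small_scene.ground_truth
        gt_pos = np.array([s.position for s in gt.synapses])
        tree = cKDTree(gt_pos)
        ok = n = 0
        for r in small_detection.records:
            d, i = tree.query(np.asarray(r.position))
            if d < 150:
                n += 1
                ok += r.compartment == gt.synapses[i].compartment
        assert n > 0 and ok / n >= 0.99
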