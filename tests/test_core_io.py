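"""Domain types, volume/SWC/CSV round-trips, and z-histogram matching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from speconn.io import FormatError, read_swc, read_synapse_csv, read_volume, \
    write_swc, write_synapse_csv, write_volume
from speconn.preprocess import histogram_match_z, match_plane
from speconn.types import (ColorVector, Skeleton, SkeletonNode, SynapseRecord,
                           ValidationError, VoxelGrid)


def make_grid(data, channels=None, pitch=(200.0, 75.0, 75.0)):
    data = np.asarray(data, dtype=float)
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    return VoxelGrid(channels=channels, data=data, pitch_nm=pitch)


class TestVoxelGrid:
    def test_invariants(self):
        g = make_grid(np.zeros((2, 4, 8, 8)))
        assert g.shape == (4, 8, 8)
        with pytest.raises(ValidationError):
            make_grid(np.zeros((3, 4, 8, 8)), channels=["a", "b"])
        with pytest.raises(ValidationError):
            make_grid(np.zeros((1, 4, 8, 8)), pitch=(0.0, 75.0, 75.0))

    def test_coordinate_round_trip(self, rng):
        g = make_grid(np.zeros((1, 5, 6, 7)))
        xyz = rng.uniform(0, 300, size=(10, 3))
        back = g.index_to_xyz(g.xyz_to_index(xyz))
        np.testing.assert_allclose(back, xyz, atol=1e-9)

    def test_expansion_conversion_invertible(self):
        # pre-expansion pitch * expansion factor = physical gel pitch,
        # and dividing back is exact
        g = make_grid(np.zeros((1, 4, 4, 4)))
        g.expansion_factor = 4.0
        gel = np.array(g.pitch_nm) * g.expansion_factor
        np.testing.assert_allclose(gel / g.expansion_factor, g.pitch_nm)


class TestVolumeIO:
    def test_round_trip_uint16(self, tmp_path, rng):
        data = rng.integers(0, 5000, size=(2, 4, 8, 8)).astype(float)
        g = make_grid(data)
        g.expansion_factor = 4.0
        g.round_id = 2
        write_volume(g, tmp_path / "v.tif")
        g2 = read_volume(tmp_path / "v.tif")
        np.testing.assert_array_equal(g2.data, g.data)
        assert g2.channels == g.channels
        assert g2.pitch_nm == g.pitch_nm
        assert g2.expansion_factor == 4.0 and g2.round_id == 2

    def test_round_trip_float(self, tmp_path, rng):
        data = rng.random((1, 3, 5, 5)).astype(np.float32).astype(float)
        g = make_grid(data)
        write_volume(g, tmp_path / "v.tif")
        np.testing.assert_array_equal(read_volume(tmp_path / "v.tif").data, data)

    def test_page_count_mismatch(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "v.tif", np.zeros((5, 4, 4), dtype=np.uint16))
        meta = {"channels": ["a", "b"], "pitch_nm": [200, 75, 75]}
        with pytest.raises(FormatError, match="not divisible"):
            read_volume(tmp_path / "v.tif", metadata=meta)

    def test_nan_refused(self, tmp_path):
        g = make_grid(np.zeros((1, 2, 2, 2)))
        g.data[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            write_volume(g, tmp_path / "v.tif")

    def test_empty_channels_refused(self, tmp_path):
        with pytest.raises(ValidationError):
            VoxelGrid(channels=[], data=np.zeros((0, 2, 2, 2)),
                      pitch_nm=(200, 75, 75))


def chain_skeleton():
    nodes = [
        SkeletonNode(1, 1, (0, 0, 0), 5000.0, -1),
        SkeletonNode(2, 3, (0, 0, 5000), 400.0, 1),
        SkeletonNode(3, 3, (0, 0, 10000), 400.0, 2),
    ]
    return Skeleton(neuron_id="N1", nodes=nodes, label="PV")


class TestSwcIO:
    def test_chain_round_trip(self, tmp_path):
        sk = chain_skeleton()
        syn = [SynapseRecord(synapse_id="S1", kind="inhibitory",
                             position=(0, 0, 9000), post_neuron_id="N1",
                             compartment="dendritic", node_id=3)]
        write_swc([sk], syn, tmp_path / "n.swc")
        back = read_swc(tmp_path / "n.swc")
        assert len(back) == 1
        assert [n.swc_type for n in back[0].nodes] == [1, 3, 3]
        assert back[0].node(3).synapse_ids == ["S1"]
        assert back[0].node(2).synapse_ids == []
        assert back[0].neuron_id == "N1" and back[0].label == "PV"

    def test_seven_column_file(self, tmp_path):
        (tmp_path / "n.swc").write_text("1 1 0 0 0 5 -1\n2 3 0 0 5 1 1\n")
        sk = read_swc(tmp_path / "n.swc")[0]
        assert all(n.synapse_ids == [] for n in sk.nodes)

    def test_dangling_parent(self, tmp_path):
        (tmp_path / "n.swc").write_text("1 1 0 0 0 5 -1\n2 3 0 0 5 1 7\n")
        # 8-column variant: parent 7 is missing -> write as 7 columns
        (tmp_path / "bad.swc").write_text("1 1 0 0 0 5 -1\n2 3 0 0 5 1 99\n")
        with pytest.raises(FormatError, match="absent parent"):
            read_swc(tmp_path / "bad.swc")

    def test_duplicate_node_id(self, tmp_path):
        (tmp_path / "n.swc").write_text("1 1 0 0 0 5 -1\n1 3 0 0 5 1 -1\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_swc(tmp_path / "n.swc")

    def test_unknown_post_neuron_refused(self, tmp_path):
        syn = [SynapseRecord(synapse_id="S1", kind="inhibitory",
                             position=(0, 0, 0), post_neuron_id="NOPE")]
        with pytest.raises(ValidationError, match="unknown neuron"):
            write_swc([chain_skeleton()], syn, tmp_path / "n.swc")

    def test_zero_synapses(self, tmp_path):
        write_swc([chain_skeleton()], [], tmp_path / "n.swc")
        assert (tmp_path / "n.csv").read_text().strip().startswith("id,")
        assert read_synapse_csv(tmp_path / "n.csv") == []

    def test_synapse_csv_round_trip(self, tmp_path):
        recs = [SynapseRecord(synapse_id=f"S{i}", kind="excitatory",
                              position=(i * 10.0, 5.0, 7.0),
                              post_neuron_id="N1", pre_axon_id="A2",
                              compartment="somatic", psd_volume_um3=0.03)
                for i in range(3)]
        write_synapse_csv(recs, tmp_path / "s.csv")
        back = read_synapse_csv(tmp_path / "s.csv")
        assert [r.synapse_id for r in back] == ["S0", "S1", "S2"]
        assert back[1].position == (10.0, 5.0, 7.0)
        assert back[0].psd_volume_um3 == pytest.approx(0.03)


class TestColorVector:
    def test_simplex_normalization(self):
        assert ColorVector(raw=(2, 2, 2)).simplex == pytest.approx((1 / 3,) * 3)

    def test_undefined(self):
        c = ColorVector(raw=(0, 0, 0))
        assert not c.defined
        with pytest.raises(ValidationError):
            _ = c.simplex


class TestSynapseRecordInvariant:
    def test_separation_consistency(self):
        r = SynapseRecord(synapse_id="S", kind="inhibitory", position=(0, 0, 0),
                          post_neuron_id="N", gephyrin_or_homer_peak=(0, 0, 0),
                          bassoon_peak=(150.0, 0, 0))
        assert r.peak_separation_nm == pytest.approx(150.0)
        with pytest.raises(ValidationError):
            SynapseRecord(synapse_id="S", kind="inhibitory", position=(0, 0, 0),
                          post_neuron_id="N", gephyrin_or_homer_peak=(0, 0, 0),
                          bassoon_peak=(150.0, 0, 0), peak_separation_nm=120.0)


class TestHistogramMatchZ:
    def make(self, rng, nz=5):
        data = rng.random((1, nz, 16, 16)) * 100
        return make_grid(data, channels=["FP1"])

    def test_identical_planes_fixed_point(self, rng):
        plane = rng.random((16, 16)) * 50
        g = make_grid(np.broadcast_to(plane, (1, 4, 16, 16)).copy(), ["FP1"])
        out = histogram_match_z(g, "FP1", 1)
        np.testing.assert_allclose(out.channel("FP1"), g.channel("FP1"), atol=1e-12)

    def test_scaled_plane_recovers_reference_multiset(self, rng):
        ref = rng.random((16, 16)) * 100
        g = make_grid(np.stack([ref, ref * 0.5])[None], ["FP1"])
        out = histogram_match_z(g, "FP1", 0)
        np.testing.assert_allclose(np.sort(out.channel("FP1")[1].ravel()),
                                   np.sort(ref.ravel()), atol=1e-9)

    def test_reference_plane_unchanged_and_other_channels_untouched(self, rng):
        g = make_grid(rng.random((2, 4, 8, 8)), ["FP1", "FP2"])
        out = histogram_match_z(g, "FP1", 2)
        np.testing.assert_array_equal(out.channel("FP1")[2], g.channel("FP1")[2])
        np.testing.assert_array_equal(out.channel("FP2"), g.channel("FP2"))

    def test_constant_reference_rejected(self):
        g = make_grid(np.ones((1, 3, 8, 8)), ["FP1"])
        with pytest.raises(ValidationError, match="degenerate"):
            histogram_match_z(g, "FP1", 0)

    def test_matches_skimage_reference_implementation(self, rng):
        from skimage.exposure import match_histograms
        src = rng.random((20, 20)) * 60
        ref = rng.gamma(2.0, 10.0, size=(20, 20))
        np.testing.assert_allclose(match_plane(src, ref),
                                   match_histograms(src, ref), atol=1e-8)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotonicity_property(self, seed):
        # input ordering implies output ordering (ties allowed)
        r = np.random.default_rng(seed)
        src = r.integers(0, 30, size=200).astype(float)
        ref = r.random(200) * 10
        out = match_plane(src, ref)
        order = np.argsort(src, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)
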