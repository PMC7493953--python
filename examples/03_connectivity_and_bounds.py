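"""Connectivity matrix, convergence bounds, and synaptic input maps.

From detected synapses: counts by (presynaptic axon, postsynaptic neuron),
the color-based bracket on how many distinct source neurons innervate each
target, and the distribution of inputs along dendritic distance from the
soma.
"""

from speconn.connectivity import (build_matrix, convergence_bounds,
                                  extract_axon_color, input_map,
                                  morphology_features)
from speconn.detection import run_detection
from speconn.synth import SceneConfig, build_scene

cfg = SceneConfig(
    seed=11, size_um=(26.0, 26.0, 13.0), n_neurons=3, n_external_axons=8,
    soma_radius_um=(4.0, 4.8), n_synapses=25, n_distractor_contact=3,
    n_distractor_unlabeled=3, dendrite_total_um=220.0, n_color_clusters=5,
    fiducial_n_blobs=120,
)
bundle = build_scene(cfg)
res = run_detection(bundle.grid, bundle.skeletons)

matrix = build_matrix(res.records, bundle.skeletons)
print("connectivity matrix (synapse counts, pre x post):")
print(matrix.counts)

by_id = {sk.neuron_id: sk for sk in bundle.skeletons}
pre_ids = {r.pre_axon_id for r in res.records if r.pre_axon_id != "unlabeled"}
colors = {p: extract_axon_color(bundle.grid, by_id[p]) for p in sorted(pre_ids)}
for sk in bundle.skeletons:
    if not sk.has_soma:
        continue
    cb = convergence_bounds(sk.neuron_id, res.records, colors)
    im = input_map(sk, res.records)
    mf = morphology_features(sk)
    print(f"{sk.neuron_id}: {cb.lower} <= distinct sources <= {cb.upper} "
          f"({cb.upper} innervating fragments); "
          f"{sum(im.somatic_counts.values())} somatic + "
          f"{sum(int(v.sum()) for v in im.counts_by_kind.values())} dendritic "
          f"inputs; dendrites {mf.total_path_um:.0f} um, "
          f"{mf.n_branches} branches")
# The lower bound counts unique axon colors (k-means elbow on the ternary
# simplex); same-colored fragments may share a source, so the true number of
# presynaptic neurons lies between the two bounds.
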