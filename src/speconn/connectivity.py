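"""Axon identity, convergence bounds, connectivity matrices, input maps,
morphology features, and round-quality metrics.

Convergence bounds: for one target neuron, the number of spatially distinct
innervating axon fragments is an *upper* bound on the number of distinct
source neurons, and the number of unique colors among those fragments
(k-means on the ternary simplex with a conservative elbow rule) is a
*lower* bound — same-colored fragments may or may not share a source, but
differently-colored ones cannot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from sklearn.cluster import KMeans

from .types import (SWC_AXON, SWC_DENDRITE, SWC_SOMA, ColorVector, Skeleton,
                    SynapseRecord, ValidationError, VoxelGrid)
from .synth.render import surface_points

__all__ = [
    "extract_axon_color", "count_color_clusters", "convergence_bounds",
    "ConvergenceBound", "build_matrix", "ConnectivityMatrix", "input_map",
    "InputMap", "morphology_features", "MorphologyFeatures", "sholl_profile",
    "compute_snr", "SnrReport", "path_distances_to_soma",
]


# ---------------------------------------------------------------------------
# axon color
# ---------------------------------------------------------------------------

def extract_axon_color(grid: VoxelGrid, skeleton: Skeleton,
                       max_points: int = 4000) -> Optional[ColorVector]:
    """Mean FP intensity over membrane-shell sample points of a fragment,
    projected to the color simplex.  Returns None (undefined color) when the
    fragment carries no FP signal; such fragments count toward the upper
    convergence bound only."""
    fp_channels = [c for c in ("FP1", "FP2", "FP3") if grid.has_channel(c)]
    if len(fp_channels) != 3:
        raise ValidationError("extract_axon_color needs channels FP1, FP2, FP3")
    pts = surface_points(skeleton, spacing_nm=4 * min(grid.pitch_nm),
                         rng=np.random.default_rng(0))
    if len(pts) == 0:
        return None
    if len(pts) > max_points:
        pts = pts[:: len(pts) // max_points + 1]
    pz, py, px = grid.pitch_nm
    coords = np.stack([pts[:, 2] / pz, pts[:, 1] / py, pts[:, 0] / px])
    means = []
    for ch in fp_channels:
        vals = map_coordinates(grid.channel(ch), coords, order=1,
                               mode="constant", cval=np.nan)
        means.append(float(np.nanmean(vals)) if np.isfinite(vals).any() else 0.0)
    raw = np.maximum(np.array(means), 0.0)
    if raw.sum() <= 0:
        return None
    return ColorVector(raw=tuple(raw))


def count_color_clusters(colors: np.ndarray, k_max: int,
                         seed: int = 0, tau: float = 0.10,
                         n_restarts: int = 10,
                         color_resolution: float = 0.04):
    """Conservative elbow estimate of the number of color clusters.

    Runs k-means (``n_restarts`` restarts, fixed seed) for k = 1..k_max on
    simplex coordinates.  The estimate is the smallest k at which either
    (a) the relative within-cluster-sum-of-squares improvement
    (W(k) - W(k+1)) / W(k) falls below ``tau``, or (b) the per-point RMS
    scatter within clusters drops below ``color_resolution`` — colors closer
    than the measurement jitter are not distinguishable, so splitting
    further cannot indicate additional sources.  Smaller k wins ties, hence
    "conservative".  Returns ``(k_estimate, labels, wcss)``.
    """
    colors = np.atleast_2d(np.asarray(colors, dtype=float))
    n = len(colors)
    if n == 0:
        raise ValidationError("no colors supplied")
    k_max = int(min(k_max, n))
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if np.allclose(colors, colors[0]):
        return 1, np.zeros(n, dtype=int), {1: 0.0}
    floor = n * color_resolution ** 2
    wcss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    k_est = None
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(colors)
        wcss[k] = float(km.inertia_)
        labels[k] = km.labels_
        if wcss[k] <= floor:
            k_est = k
            break
        if k >= 2 and (wcss[k - 1] - wcss[k]) / wcss[k - 1] < tau:
            k_est = k - 1
            break
    if k_est is None:
        k_est = max(wcss)
    return k_est, labels[k_est], wcss


@dataclass
class ConvergenceBound:
    """Bracket on how many distinct source neurons innervate one target."""

    target: str
    lower: int
    upper: int
    fragment_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.upper >= 1 and not (1 <= self.lower <= self.upper):
            raise ValidationError(
                f"bounds must satisfy 1 <= lower <= upper, got ({self.lower}, {self.upper})"
            )


def convergence_bounds(target: str, synapses: Sequence[SynapseRecord],
                       axon_colors: dict[str, Optional[ColorVector]],
                       seed: int = 0, tau: float = 0.10) -> ConvergenceBound:
    """Upper bound = distinct labeled pre-axon fragments with a synapse onto
    ``target``; lower bound = number of color clusters among those fragments
    (fragments with undefined color contribute to the upper bound only)."""
    frags = sorted({
        s.pre_axon_id for s in synapses
        if s.post_neuron_id == target and s.pre_axon_id != "unlabeled"
    })
    upper = len(frags)
    if upper == 0:
        return ConvergenceBound(target=target, lower=0, upper=0)
    colored = [f for f in frags
               if axon_colors.get(f) is not None and axon_colors[f].defined]
    if not colored:
        return ConvergenceBound(target=target, lower=1, upper=upper,
                                fragment_ids=frags)
    simplex = np.array([axon_colors[f].simplex for f in colored])
    k, _, _ = count_color_clusters(simplex, k_max=len(colored), seed=seed, tau=tau)
    return ConvergenceBound(target=target, lower=max(1, k), upper=upper,
                            fragment_ids=frags)


# ---------------------------------------------------------------------------
# connectivity matrix
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Synapse counts by (presynaptic axon, postsynaptic neuron)."""

    counts: pd.DataFrame                       # rows pre (incl. "unlabeled"), cols post
    compartment_counts: pd.DataFrame           # MultiIndex (pre, compartment) x post
    axon_stats: pd.DataFrame                   # per-axon synapse count + targeting class

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def somatic_fraction_from(self, pre_ids: Sequence[str]) -> pd.Series:
        """Per-target fraction of somatic synapses coming from ``pre_ids``
        (e.g. the molecularly identified axon set)."""
        som = self.compartment_counts.xs("somatic", level=1)
        tot = som.sum(axis=0)
        sub = som.loc[som.index.intersection(pre_ids)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (sub / tot).where(tot > 0)


def build_matrix(synapses: Sequence[SynapseRecord],
                 skeletons: Sequence[Skeleton]) -> ConnectivityMatrix:
    """Connectivity matrix over linked synapses, a compartment-resolved
    variant, and per-axon targeting statistics (an axon is soma-targeting if
    the majority of its synapses are somatic)."""
    posts = sorted({sk.neuron_id for sk in skeletons if sk.has_soma})
    pres = sorted({s.pre_axon_id for s in synapses})
    counts = pd.DataFrame(0, index=pres, columns=posts, dtype=int)
    idx = pd.MultiIndex.from_product([pres, ["somatic", "dendritic"]],
                                     names=["pre", "compartment"])
    comp = pd.DataFrame(0, index=idx, columns=posts, dtype=int)
    for s in synapses:
        if s.post_neuron_id not in counts.columns:
            counts[s.post_neuron_id] = 0
            comp[s.post_neuron_id] = 0
        counts.loc[s.pre_axon_id, s.post_neuron_id] += 1
        comp.loc[(s.pre_axon_id, s.compartment), s.post_neuron_id] += 1
    rows = []
    for pre in pres:
        n_som = int(comp.loc[(pre, "somatic")].sum())
        n_den = int(comp.loc[(pre, "dendritic")].sum())
        rows.append({
            "pre": pre, "n_synapses": n_som + n_den,
            "n_somatic": n_som, "n_dendritic": n_den,
            "targeting": "somatic" if n_som > n_den else "dendritic",
        })
    stats = pd.DataFrame(rows).set_index("pre") if rows else pd.DataFrame(
        columns=["n_synapses", "n_somatic", "n_dendritic", "targeting"])
    return ConnectivityMatrix(counts=counts, compartment_counts=comp,
                              axon_stats=stats)


# ---------------------------------------------------------------------------
# input maps (path distance from soma)
# ---------------------------------------------------------------------------

def path_distances_to_soma(skeleton: Skeleton) -> dict[int, float]:
    """Per-node path distance (nm) to the nearest soma node along the tree.

    Soma-type nodes have distance 0; each other node adds its parent-child
    segment length to its parent's distance (unique, since the tree has one
    path to the soma)."""
    dist: dict[int, float] = {}
    order = list(skeleton.nodes)
    # parents appear before children in SWC order by construction; fall back
    # to iterative resolution otherwise
    pending = order
    guard = 0
    while pending:
        nxt = []
        for n in pending:
            if n.swc_type == SWC_SOMA:
                dist[n.node_id] = 0.0
            elif n.parent_id == -1:
                dist[n.node_id] = 0.0
            elif n.parent_id in dist:
                p = skeleton.node(n.parent_id)
                dist[n.node_id] = dist[n.parent_id] + math.dist(n.position, p.position)
            else:
                nxt.append(n)
        if len(nxt) == len(pending):
            raise ValidationError(f"skeleton {skeleton.neuron_id}: broken tree")
        pending = nxt
        guard += 1
        if guard > len(order) + 2:
            raise ValidationError("path distance resolution did not converge")
    return dist


@dataclass
class InputMap:
    """Synaptic input histogram along dendritic distance from the soma."""

    neuron_id: str
    bin_width_um: float
    bin_edges_um: np.ndarray
    counts_by_kind: dict[str, np.ndarray]     # dendritic synapses only
    somatic_counts: dict[str, int]
    distances_um: dict[str, float]            # synapse id -> path distance
    quarantined: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (sum(int(v.sum()) for v in self.counts_by_kind.values())
                + sum(self.somatic_counts.values()))


def input_map(neuron: Skeleton, synapses: Sequence[SynapseRecord],
              bin_width_um: float = 10.0) -> InputMap:
    """Histogram of dendritic synapse counts vs path distance from the soma
    (somatic synapses tallied separately, as in the inset-style count)."""
    dist = path_distances_to_soma(neuron)
    linked = [s for s in synapses if s.post_neuron_id == neuron.neuron_id]
    distances: dict[str, float] = {}
    somatic = {"excitatory": 0, "inhibitory": 0}
    dendritic: list[tuple[str, float]] = []
    quarantined = []
    for s in linked:
        if s.node_id is None or s.node_id not in dist:
            quarantined.append(s.synapse_id)
            continue
        if s.compartment == "somatic":
            somatic[s.kind] += 1
            distances[s.synapse_id] = 0.0
        else:
            d_um = dist[s.node_id] / 1000.0
            distances[s.synapse_id] = d_um
            dendritic.append((s.kind, d_um))
    max_d = max((d for _, d in dendritic), default=0.0)
    n_bins = max(1, int(math.ceil(max_d / bin_width_um + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width_um
    counts = {k: np.zeros(n_bins, dtype=int) for k in ("excitatory", "inhibitory")}
    for kind, d in dendritic:
        b = min(n_bins - 1, int(d / bin_width_um))
        counts[kind][b] += 1
    return InputMap(neuron_id=neuron.neuron_id, bin_width_um=bin_width_um,
                    bin_edges_um=edges, counts_by_kind=counts,
                    somatic_counts=somatic, distances_um=distances,
                    quarantined=quarantined)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class MorphologyFeatures:
    neuron_id: str
    total_path_um: float
    n_stems: int
    n_bifurcations: int
    n_branches: int
    sholl_radii_um: np.ndarray
    sholl_crossings: np.ndarray


def sholl_profile(skeleton: Skeleton, center_xyz: np.ndarray,
                  step_um: float = 10.0, swc_types=(SWC_DENDRITE,)):
    """Counts of neurite segment crossings through concentric spheres."""
    segs = [(p, c) for p, c in skeleton.edges()
            if c.swc_type in swc_types and p.swc_type in swc_types + (SWC_SOMA,)]
    if not segs:
        return np.array([]), np.array([], dtype=int)
    a = np.array([p.position for p, _ in segs])
    b = np.array([c.position for _, c in segs])
    da = np.linalg.norm(a - center_xyz, axis=1)
    db = np.linalg.norm(b - center_xyz, axis=1)
    lo = np.minimum(da, db)
    hi = np.maximum(da, db)
    rmax = hi.max()
    step_nm = step_um * 1000.0
    radii = np.arange(step_nm, rmax + step_nm, step_nm)
    # a segment crosses radius r when its endpoint distances straddle r
    crossings = ((lo[None, :] < radii[:, None]) & (hi[None, :] >= radii[:, None])).sum(axis=1)
    return radii / 1000.0, crossings.astype(int)


def morphology_features(skeleton: Skeleton, sholl_step_um: float = 10.0,
                        swc_types=(SWC_DENDRITE,)) -> MorphologyFeatures:
    """Total path length, stems, bifurcations, branches, and Sholl profile.

    Counts follow standard SWC conventions: stems are neurite roots attached
    to the soma; bifurcations are neurite nodes with >= 2 children; branches
    are maximal unbranched segments (nodes whose parent is a soma node or a
    branch point start a new branch).  Computed over ``swc_types``
    (dendrites by default)."""
    children = skeleton.children_map()
    sel = [n for n in skeleton.nodes if n.swc_type in swc_types]
    total = 0.0
    for n in sel:
        if n.parent_id != -1:
            total += math.dist(n.position, skeleton.node(n.parent_id).position)
    deg = {n.node_id: sum(1 for c in children[n.node_id]
                          if skeleton.node(c).swc_type in swc_types)
           for n in sel}
    stems = 0
    branches = 0
    bifs = 0
    for n in sel:
        parent_is_soma = (n.parent_id == -1
                          or skeleton.node(n.parent_id).swc_type == SWC_SOMA)
        if parent_is_soma:
            stems += 1
            branches += 1
        elif deg.get(n.parent_id, 0) >= 2:
            branches += 1
        if deg[n.node_id] >= 2:
            bifs += 1
    soma_nodes = skeleton.nodes_of_type(SWC_SOMA)
    if soma_nodes:
        center = np.mean([n.position for n in soma_nodes], axis=0)
    else:
        warnings.warn(f"skeleton {skeleton.neuron_id} has no soma; "
                      "Sholl centered on the root node")
        center = np.asarray(skeleton.root.position)
    radii, crossings = sholl_profile(skeleton, center, sholl_step_um, swc_types)
    return MorphologyFeatures(
        neuron_id=skeleton.neuron_id, total_path_um=total / 1000.0,
        n_stems=stems, n_bifurcations=bifs, n_branches=branches,
        sholl_radii_um=radii, sholl_crossings=crossings,
    )


# ---------------------------------------------------------------------------
# SnR
# ---------------------------------------------------------------------------

@dataclass
class SnrReport:
    round_id: int
    signal_means: list[float]
    background_means: list[float]
    snr: list[float]

    @property
    def background_mean(self) -> float:
        return float(np.mean(self.background_means))


def _roi_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValidationError("boolean ROI shape mismatch")
        return roi
    # (z0,z1,y0,y1,x0,x1) box
    z0, z1, y0, y1, x0, x1 = roi
    m = np.zeros(shape, dtype=bool)
    m[z0:z1, y0:y1, x0:x1] = True
    return m


def compute_snr(grid: VoxelGrid, channel: str, signal_rois, background_rois) -> SnrReport:
    """Per-ROI mean divided by the mean of background-ROI means.

    ROIs are boolean masks or (z0,z1,y0,y1,x0,x1) boxes; signal and
    background ROIs must be disjoint."""
    if not signal_rois or not background_rois:
        raise ValidationError("need at least one signal and one background ROI")
    ch = grid.channel(channel)
    sig_masks = [_roi_mask(r, ch.shape) for r in signal_rois]
    bg_masks = [_roi_mask(r, ch.shape) for r in background_rois]
    union_sig = np.zeros(ch.shape, dtype=bool)
    for m in sig_masks:
        union_sig |= m
    for m in bg_masks:
        if (union_sig & m).any():
            raise ValidationError("signal and background ROIs overlap")
    sig_means = [float(ch[m].mean()) for m in sig_masks]
    bg_means = [float(ch[m].mean()) for m in bg_masks]
    bg = float(np.mean(bg_means))
    if bg == 0:
        raise ValidationError("background mean is zero; SnR undefined")
    return SnrReport(round_id=grid.round_id, signal_means=sig_means,
                     background_means=bg_means, snr=[s / bg for s in sig_means])
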