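"""Synaptic puncta segmentation, pre/post pairing, and trio classification.

The trio criterion defines a putative synapse by three signals in spatial
order along the contact axis: the PSD punctum (Gephyrin for inhibitory,
Homer1 for excitatory), the postsynaptic Brainbow membrane, and the
presynaptic Bassoon punctum, with a PSD-Bassoon peak separation of
~100-200 nm.  Candidate pairs whose geometry instead points to an unlabeled
presynaptic partner (a labeled axon passes nearby but the Bassoon punctum is
outside its membrane envelope) are rejected, as are bare contacts without
machinery (those never produce a pair and are counted separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import (distance_transform_edt, find_objects,
                           gaussian_filter1d, map_coordinates)
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .types import (SWC_AXON, SWC_DENDRITE, SWC_SOMA, ColorVector, LineProfile,
                    MarkerPair, Punctum, Skeleton, SynapseRecord, TrioVerdict,
                    ValidationError, VoxelGrid)

__all__ = [
    "SegmentationParams", "segment_puncta", "pair_puncta", "nn_spacing",
    "extract_line_profile", "TrioCriteria", "SceneIndex", "classify_trio",
    "link_and_compartmentalize", "run_detection", "DetectionResult",
]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    min_voxels: int = 4
    seed_min_separation_nm: float = 300.0
    threshold: Optional[float] = None   # override the Otsu threshold
    max_fg_fraction: float = 0.01       # puncta are sparse; see _otsu_threshold


def _otsu_threshold(ch: np.ndarray, max_fg_fraction: float = 0.01) -> float:
    """Iterated global Otsu for sparse puncta channels.

    On whole volumes the signal class can occupy <0.1% of voxels, so a single
    global Otsu may split the background mode instead.  While the foreground
    fraction stays above ``max_fg_fraction`` the threshold is re-estimated by
    Otsu on the voxels above the current threshold (monotonically
    increasing; stops at a fixed point)."""
    t = float(threshold_otsu(ch, nbins=256))
    for _ in range(8):
        if float(np.mean(ch > t)) <= max_fg_fraction:
            break
        upper = ch[ch > t]
        if upper.size < 256 or np.ptp(upper) == 0:
            break
        t_new = float(threshold_otsu(upper, nbins=256))
        if t_new <= t * (1 + 1e-6):
            break
        t = t_new
    return t


def segment_puncta(grid: VoxelGrid, channel: str,
                   params: SegmentationParams | None = None) -> list[Punctum]:
    """Otsu threshold + watershed split of a puncta channel.

    Connected foreground is split by a watershed on the inverted Euclidean
    distance transform, seeded at local maxima at least
    ``seed_min_separation_nm`` apart; fragments below ``min_voxels`` are
    dropped.  Centroids are intensity-weighted, in pre-expansion nm.
    """
    params = params or SegmentationParams()
    ch = grid.channel(channel)
    if np.ptp(ch) == 0:
        return []
    if float(np.mean(ch >= ch.max())) > 0.5:
        import warnings
        warnings.warn(f"channel {channel} looks saturated")
    thr = (params.threshold if params.threshold is not None
           else _otsu_threshold(ch, params.max_fg_fraction))
    mask = ch > thr
    if not mask.any():
        return []
    pz, py, px = grid.pitch_nm
    sep = params.seed_min_separation_nm
    # under-suppressing footprint (half the separation per axis); the exact
    # anisotropic min-separation is enforced in nm on the seed list below
    foot = np.ones((2 * max(1, int(sep / 2 / pz)) + 1,
                    2 * max(1, int(sep / 2 / py)) + 1,
                    2 * max(1, int(sep / 2 / px)) + 1), dtype=bool)
    comps, n_comp = cc_label(mask, return_num=True, connectivity=1)
    # drop sub-minimum components before the per-component watershed pass
    sizes = np.bincount(comps.ravel())
    puncta: list[Punctum] = []
    pid = 0
    slices = find_objects(comps)
    for ci, slc in enumerate(slices, start=1):
        if slc is None or sizes[ci] < params.min_voxels:
            continue
        sub_mask = comps[slc] == ci
        sub_int = ch[slc]
        edt = distance_transform_edt(sub_mask, sampling=(pz, py, px))
        seeds = peak_local_max(edt, footprint=foot, labels=sub_mask,
                               exclude_border=False)
        # enforce the min separation in physical nm (EDT plateaus can yield
        # several equal maxima inside one blob)
        if len(seeds) > 1:
            vals = edt[tuple(seeds.T)]
            order = np.argsort(-vals, kind="stable")
            phys = seeds[order] * np.array([pz, py, px])
            kept: list[int] = []
            for j in range(len(order)):
                if all(np.linalg.norm(phys[j] - phys[m]) >= sep for m in kept):
                    kept.append(j)
            seeds = seeds[order][kept]
        markers = np.zeros(sub_mask.shape, dtype=np.int32)
        for k, s in enumerate(seeds, start=1):
            markers[tuple(s)] = k
        if markers.max() <= 1:
            lab = sub_mask.astype(np.int32)
        else:
            lab = watershed(-edt, markers=markers, mask=sub_mask)
        z0 = np.array([s.start for s in slc])
        for k in range(1, int(lab.max()) + 1):
            sel = lab == k
            nvox = int(sel.sum())
            if nvox < params.min_voxels:
                continue
            zz, yy, xx = np.nonzero(sel)
            w = sub_int[zz, yy, xx].astype(float)
            wsum = w.sum()
            if wsum <= 0:
                continue
            cz = ((zz + z0[0]) * pz * w).sum() / wsum
            cy = ((yy + z0[1]) * py * w).sum() / wsum
            cx = ((xx + z0[2]) * px * w).sum() / wsum
            pid += 1
            puncta.append(Punctum(
                punctum_id=pid, channel=channel, centroid=(cx, cy, cz),
                volume_um3=nvox * grid.voxel_volume_um3,
                peak_intensity=float(sub_int[sel].max()), voxel_count=nvox,
            ))
    return _merge_close_puncta(puncta, sep)


def _merge_close_puncta(puncta: list[Punctum], sep_nm: float) -> list[Punctum]:
    """Union puncta whose centroids violate the seed min-separation (ragged
    noisy masks can still watershed one blob into two nearby fragments)."""
    if len(puncta) < 2:
        return puncta
    changed = True
    while changed:
        changed = False
        pos = np.array([p.centroid for p in puncta])
        tree = cKDTree(pos)
        for i, j in sorted(tree.query_pairs(sep_nm)):
            a, b = puncta[i], puncta[j]
            if a is None or b is None:
                continue
            w = a.voxel_count + b.voxel_count
            centroid = tuple(
                (np.asarray(a.centroid) * a.voxel_count
                 + np.asarray(b.centroid) * b.voxel_count) / w)
            puncta[i] = Punctum(
                punctum_id=a.punctum_id, channel=a.channel, centroid=centroid,
                volume_um3=a.volume_um3 + b.volume_um3,
                peak_intensity=max(a.peak_intensity, b.peak_intensity),
                voxel_count=w)
            puncta[j] = None
            changed = True
        puncta = [p for p in puncta if p is not None]
    return puncta


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def pair_puncta(bassoon: Sequence[Punctum], psd_inhib: Sequence[Punctum],
                psd_excit: Sequence[Punctum], max_sep_nm: float = 300.0):
    """Greedy mutual-exclusion matching of Bassoon to PSD puncta.

    Candidate edges are all Bassoon-PSD centroid pairs within ``max_sep_nm``;
    matching proceeds by ascending separation, each Bassoon taking its
    closest available PSD across *both* PSD channels (so Gephyrin and Homer1
    are mutually exclusive per Bassoon).  Ties break on the lower PSD
    punctum id.  Returns ``(pairs, orphans)`` with orphans keyed by channel.
    """
    psds = [("Gephyrin", p) for p in psd_inhib] + [("Homer1", p) for p in psd_excit]
    edges = []
    for bi, b in enumerate(bassoon):
        bc = np.asarray(b.centroid)
        for pi, (_, p) in enumerate(psds):
            d = float(np.linalg.norm(bc - np.asarray(p.centroid)))
            if d <= max_sep_nm:
                edges.append((d, p.punctum_id, bi, pi))
    edges.sort(key=lambda e: (e[0], e[1]))
    used_b: set[int] = set()
    used_p: set[int] = set()
    pairs: list[MarkerPair] = []
    for d, _, bi, pi in edges:
        if bi in used_b or pi in used_p:
            continue
        used_b.add(bi)
        used_p.add(pi)
        pairs.append(MarkerPair(pre=bassoon[bi], post=psds[pi][1], separation_nm=d))
    orphans = {
        "Bassoon": [b for i, b in enumerate(bassoon) if i not in used_b],
        "Gephyrin": [p for i, (c, p) in enumerate(psds) if c == "Gephyrin" and i not in used_p],
        "Homer1": [p for i, (c, p) in enumerate(psds) if c == "Homer1" and i not in used_p],
    }
    return pairs, orphans


def nn_spacing(positions: np.ndarray, threshold_nm: float = 300.0):
    """Nearest-neighbor distances and the fraction exceeding ``threshold_nm``.

    Fewer than two positions -> empty distances and fraction ``None``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        return np.empty(0), None
    tree = cKDTree(positions)
    d = tree.query(positions, k=2)[0][:, 1]
    return d, float(np.mean(d > threshold_nm))


# ---------------------------------------------------------------------------
# line profiles
# ---------------------------------------------------------------------------

def extract_line_profile(grid: VoxelGrid, p0, p1, step_nm: float,
                         channels: Sequence[str]) -> LineProfile:
    """Sample channels along the segment p0 -> p1 (both (x,y,z) nm inside the
    volume) at uniform ``step_nm`` by trilinear interpolation; each channel is
    also normalized to [0, 1] over the profile (constant channels -> zeros)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length < 1e-9:
        raise ValidationError("zero-length profile segment")
    if step_nm > min(grid.pitch_nm) / 2 + 1e-9:
        raise ValidationError(
            f"step_nm={step_nm} exceeds half the smallest pitch {min(grid.pitch_nm)/2}"
        )
    ext = np.array(grid.extent_nm())
    for p in (p0, p1):
        if np.any(p < -1e-6) or np.any(p > ext + 1e-6):
            raise ValidationError(f"profile endpoint {tuple(p)} outside volume extent {tuple(ext)}")
    n = max(2, int(math.ceil(length / step_nm)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    pz, py, px = grid.pitch_nm
    coords = np.stack([pts[:, 2] / pz, pts[:, 1] / py, pts[:, 0] / px])
    raw, norm = {}, {}
    for ch in channels:
        v = map_coordinates(grid.channel(ch), coords, order=1, mode="nearest")
        raw[ch] = v
        ptp = v.max() - v.min()
        norm[ch] = (v - v.min()) / ptp if ptp > 0 else np.zeros_like(v)
    return LineProfile(positions_nm=t * length, raw=raw, normalized=norm,
                       p0=tuple(p0), p1=tuple(p1))


def _refine_peak(pos: np.ndarray, vals: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of a local maximum."""
    if 0 < i < len(vals) - 1:
        y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            off = 0.5 * (y0 - y2) / denom
            off = float(np.clip(off, -0.5, 0.5))
            return float(pos[i] + off * (pos[1] - pos[0]))
    return float(pos[i])


def _channel_peaks(profile: LineProfile, channel: str, prominence: float,
                   smooth_sigma: float):
    v = gaussian_filter1d(profile.normalized[channel], smooth_sigma)
    ptp = v.max() - v.min()
    if ptp <= 0:
        return [], v
    idx, _ = find_peaks(v, prominence=prominence * ptp)
    return [(_refine_peak(profile.positions_nm, v, i), v[i]) for i in idx], v


def _com_refine(profile: LineProfile, channel: str, s_expected: float,
                window_nm: float = 150.0) -> float:
    """Sub-sample peak position by baseline-subtracted center of mass in a
    window around the expected position (robust for flat-topped blobs whose
    discrete argmax wanders under noise)."""
    pos = profile.positions_nm
    v = profile.raw[channel].astype(float)
    sel = np.abs(pos - s_expected) <= window_nm
    if sel.sum() < 3:
        return s_expected
    w = v[sel] - v[sel].min()
    tot = w.sum()
    if tot <= 0:
        return s_expected
    return float((pos[sel] * w).sum() / tot)


# ---------------------------------------------------------------------------
# trio classification
# ---------------------------------------------------------------------------

@dataclass
class TrioCriteria:
    """Acceptance criteria for the trio test (all lengths pre-expansion nm)."""

    separation_window_nm: tuple[float, float] = (100.0, 200.0)
    prominence: float = 0.2               # fraction of normalized range
    smooth_sigma_samples: float = 1.0
    step_nm: float = 25.0
    extend_nm: float = 400.0              # profile extension past both peaks
    membrane_tol_nm: float = 300.0        # membrane may sit this far PSD-ward:
                                          # the apposed axon wall lies up to
                                          # (axon_radius - sep) inside the PSD,
                                          # plus smear from oblique crossings
    post_search_radius_nm: float = 800.0
    pre_search_radius_nm: float = 800.0
    color_tol: float = 0.30               # max simplex residual after unmixing
    min_post_color_fraction: float = 0.15  # post share of the membrane blend
    on_membrane_tol_nm: float = 200.0     # PSD-to-candidate-surface geometric gate
    axon_radius_nm: float = 300.0
    membrane_thickness_nm: float = 40.0
    envelope_extra_nm: float = 75.0       # one lateral voxel

    @property
    def envelope_nm(self) -> float:
        return self.axon_radius_nm + self.membrane_thickness_nm + self.envelope_extra_nm


class SceneIndex:
    """Spatial indices over skeletons used by the classifier and linker."""

    def __init__(self, skeletons: Sequence[Skeleton]):
        self.skeletons = list(skeletons)
        post_pos, post_ref = [], []
        axon_pos, axon_ref = [], []
        self.colors: dict[str, ColorVector] = {}
        for si, sk in enumerate(self.skeletons):
            if sk.color is not None and sk.color.defined:
                self.colors[sk.neuron_id] = sk.color
            for n in sk.nodes:
                if n.swc_type == SWC_AXON:
                    axon_pos.append(n.position)
                    axon_ref.append(si)
                elif sk.has_soma:
                    post_pos.append(n.position)
                    post_ref.append((si, n.node_id, n.swc_type))
        self.post_pos = np.array(post_pos) if post_pos else np.empty((0, 3))
        self.post_ref = post_ref
        self.post_radius = np.array([
            self.skeletons[si].node(nid).radius for si, nid, _t in post_ref
        ]) if post_ref else np.empty(0)
        self.post_tree = cKDTree(self.post_pos) if len(post_pos) else None
        self.axon_pos = np.array(axon_pos) if axon_pos else np.empty((0, 3))
        self.axon_ref = np.array(axon_ref, dtype=int) if axon_ref else np.empty(0, int)
        self.axon_tree = cKDTree(self.axon_pos) if len(axon_pos) else None

    def posts_near(self, xyz, radius) -> list[int]:
        """Indices of skeletons with a post (soma/dendrite) node within radius."""
        if self.post_tree is None:
            return []
        hits = self.post_tree.query_ball_point(np.asarray(xyz), r=radius)
        return sorted({self.post_ref[h][0] for h in hits})

    def surface_distance(self, skeleton_index: int, xyz,
                         search_nm: float = 8000.0) -> float:
        """|distance from xyz to the skeleton's membrane surface| (nm),
        estimated from its nearest soma/dendrite node minus the node radius."""
        xyz = np.asarray(xyz)
        hits = self.post_tree.query_ball_point(xyz, r=search_nm) if self.post_tree else []
        best = float("inf")
        for h in hits:
            if self.post_ref[h][0] != skeleton_index:
                continue
            d = abs(np.linalg.norm(self.post_pos[h] - xyz) - self.post_radius[h])
            best = min(best, d)
        return best

    def nearest_labeled_axon(self, xyz):
        """(distance_nm, skeleton) of the closest labeled axon node, or
        (inf, None)."""
        if self.axon_tree is None:
            return float("inf"), None
        d, i = self.axon_tree.query(np.asarray(xyz))
        return float(d), self.skeletons[int(self.axon_ref[i])]


def _unmix_color(m: np.ndarray, post: np.ndarray,
                 axon: Optional[np.ndarray]) -> tuple[float, float]:
    """Fit measured simplex color ``m`` as a convex blend of ``post`` and
    ``axon``; returns (residual L2, post fraction).  Without an axon (or with
    indistinguishable colors) this reduces to the plain distance to
    ``post`` with post fraction 1."""
    if axon is None or np.linalg.norm(post - axon) < 0.1:
        return float(np.linalg.norm(m - post)), 1.0
    d = post - axon
    a = float(np.clip(np.dot(m - axon, d) / np.dot(d, d), 0.0, 1.0))
    blend = axon + a * d
    return float(np.linalg.norm(m - blend)), a


def _clip_to_volume(p0: np.ndarray, p1: np.ndarray, ext: np.ndarray):
    """Clip segment p0->p1 to the axis-aligned box [0, ext]."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        ta = (0.0 - p0[ax]) / d[ax]
        tb = (ext[ax] - p0[ax]) / d[ax]
        lo, hi = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, lo), min(t1, hi)
    t0, t1 = max(0.0, t0), min(1.0, t1)
    return p0 + t0 * d, p0 + t1 * d


def classify_trio(pair: MarkerPair, grid: VoxelGrid,
                  skeletons: Sequence[Skeleton],
                  criteria: TrioCriteria | None = None,
                  index: SceneIndex | None = None) -> TrioVerdict:
    """Apply the trio criterion to one marker pair.

    Accept iff (a) the PSD-Bassoon peak separation measured on the line
    profile falls in the separation window, (b) a Brainbow membrane peak lies
    between the two marker peaks (or within ``membrane_tol_nm`` on the PSD
    side), (c) the membrane color matches a skeleton with a node within the
    post search radius, and (d) when a labeled axon passes within the pre
    search radius, the Bassoon punctum lies inside that axon's membrane
    envelope — otherwise the pair belongs to an unlabeled partner.
    """
    criteria = criteria or TrioCriteria()
    index = index or SceneIndex(skeletons)
    psd_c = np.asarray(pair.post.centroid)
    bas_c = np.asarray(pair.pre.centroid)
    axis = bas_c - psd_c
    d0 = np.linalg.norm(axis)
    if d0 < 1e-9:
        return TrioVerdict(pair=pair, accepted=False, reason="separation-out-of-range")
    u = axis / d0
    ext = np.array(grid.extent_nm())
    p0, p1 = _clip_to_volume(psd_c - criteria.extend_nm * u,
                             bas_c + criteria.extend_nm * u, ext)
    fp_channels = [c for c in ("FP1", "FP2", "FP3") if grid.has_channel(c)]
    profile = extract_line_profile(
        grid, p0, p1, criteria.step_nm,
        channels=[pair.post.channel, "Bassoon", *fp_channels],
    )
    # summed-FP profile for membrane detection (color splits across channels)
    fp_sum = np.sum([profile.raw[c] for c in fp_channels], axis=0)
    ptp = fp_sum.max() - fp_sum.min()
    profile.raw["FPsum"] = fp_sum
    profile.normalized["FPsum"] = ((fp_sum - fp_sum.min()) / ptp
                                   if ptp > 0 else np.zeros_like(fp_sum))

    def expected(pos3d):
        return float(np.dot(np.asarray(pos3d) - p0, u))

    psd_peaks, _ = _channel_peaks(profile, pair.post.channel,
                                  criteria.prominence, criteria.smooth_sigma_samples)
    bas_peaks, _ = _channel_peaks(profile, "Bassoon",
                                  criteria.prominence, criteria.smooth_sigma_samples)
    if not psd_peaks or not bas_peaks:
        return TrioVerdict(pair=pair, accepted=False, reason="no-machinery",
                           profile=profile)
    # a detectable peak must exist near the expected position; its location is
    # then refined by center of mass around the centroid projection
    s_psd0 = min(psd_peaks, key=lambda pk: abs(pk[0] - expected(psd_c)))[0]
    s_bas0 = min(bas_peaks, key=lambda pk: abs(pk[0] - expected(bas_c)))[0]
    if (abs(s_psd0 - expected(psd_c)) > 250.0
            or abs(s_bas0 - expected(bas_c)) > 250.0):
        return TrioVerdict(pair=pair, accepted=False, reason="no-machinery",
                           profile=profile)
    s_psd = _com_refine(profile, pair.post.channel, expected(psd_c))
    s_bas = _com_refine(profile, "Bassoon", expected(bas_c))
    # the window test uses the 3-D peak (intensity-weighted centroid)
    # separation; the along-profile positions serve the order check below
    sep = float(pair.separation_nm)
    lo, hi = criteria.separation_window_nm
    base = dict(pair=pair, profile=profile, psd_peak_nm=s_psd,
                bassoon_peak_nm=s_bas, separation_nm=sep)
    if not (lo <= sep <= hi):
        return TrioVerdict(accepted=False, reason="separation-out-of-range", **base)

    # membrane peaks: union over the summed and individual FP profiles (the
    # post membrane is prominent in its own dominant FP channel even when a
    # brighter differently-colored structure dominates the sum)
    mem_peaks = []
    for ch in ("FPsum", *fp_channels):
        pks, _ = _channel_peaks(profile, ch, criteria.prominence,
                                criteria.smooth_sigma_samples)
        mem_peaks.extend(pks)
    lo_s, hi_s = min(s_psd, s_bas), max(s_psd, s_bas)
    in_window = [pk for pk, _h in mem_peaks
                 if lo_s - criteria.membrane_tol_nm <= pk <= hi_s]
    if not in_window:
        beyond = [pk for pk, _h in mem_peaks
                  if hi_s < pk <= hi_s + criteria.membrane_tol_nm + 50.0]
        reason = "order-violation" if beyond else "post-membrane-absent"
        return TrioVerdict(accepted=False, reason=reason, **base)
    s_mem = min(in_window, key=lambda pk: abs(pk - s_psd))
    base["membrane_peak_nm"] = s_mem

    # (c) membrane color must match a nearby skeleton.  The synaptic cleft is
    # unresolvable, so the light at the membrane peak is a blend of the post
    # membrane and the apposed axon membrane: each candidate is scored by
    # unmixing the measured color as a nonnegative post+axon combination.
    k = int(np.clip(round(s_mem / (profile.positions_nm[1] - profile.positions_nm[0])),
                    1, len(profile.positions_nm) - 2))
    raw_fp = np.array([profile.raw[c][k - 1:k + 2].mean() for c in fp_channels])
    cand = index.posts_near(psd_c, criteria.post_search_radius_nm)
    if raw_fp.sum() <= 0 or not cand:
        return TrioVerdict(accepted=False, reason="post-membrane-absent", **base)
    m = raw_fp / raw_fp.sum()
    d_ax0, ax0 = index.nearest_labeled_axon(bas_c)
    axon_color = (np.array(ax0.color.simplex)
                  if (ax0 is not None and d_ax0 <= criteria.pre_search_radius_nm
                      and ax0.color is not None and ax0.color.defined) else None)
    # a candidate qualifies if the blend fits its color AND there is positive
    # evidence it owns the membrane: either a visible post color share or the
    # PSD sitting geometrically on its traced surface
    best, best_key = None, (float("inf"), float("inf"))
    for si in cand:
        sk = index.skeletons[si]
        if sk.color is None or not sk.color.defined:
            continue
        p = np.array(sk.color.simplex)
        res_d, post_frac = _unmix_color(m, p, axon_color)
        if res_d > criteria.color_tol:
            continue
        surf_d = index.surface_distance(si, psd_c)
        if (post_frac < criteria.min_post_color_fraction
                and surf_d > criteria.on_membrane_tol_nm):
            continue
        key = (surf_d, res_d)
        if key < best_key:
            best, best_key = sk, key
    if best is None:
        return TrioVerdict(accepted=False, reason="post-membrane-absent", **base)
    base["post_neuron_id"] = best.neuron_id

    # (d) presynaptic side: labeled axon must own the Bassoon punctum
    d_ax, ax_sk = index.nearest_labeled_axon(bas_c)
    if d_ax <= criteria.envelope_nm:
        pre_id = ax_sk.neuron_id
    elif d_ax <= criteria.pre_search_radius_nm:
        return TrioVerdict(accepted=False, reason="unlabeled-partner", **base)
    else:
        pre_id = None
    return TrioVerdict(accepted=True, reason="accepted", pre_axon_id=pre_id, **base)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_and_compartmentalize(verdicts: Sequence[TrioVerdict],
                              skeletons: Sequence[Skeleton],
                              search_radius_nm: float = 2000.0):
    """Turn accepted verdicts into SynapseRecords linked to skeleton nodes.

    Each synapse links to the nearest soma/dendrite node of its matched post
    skeleton (exact ties -> lower node id); compartment is somatic iff that
    node is soma-type.  Returns ``(records, quarantined_verdicts)``.
    """
    by_id = {sk.neuron_id: sk for sk in skeletons}
    trees: dict[str, tuple[cKDTree, list]] = {}
    records: list[SynapseRecord] = []
    quarantine: list[TrioVerdict] = []
    for v in verdicts:
        if not v.accepted:
            continue
        sk = by_id[v.post_neuron_id]
        if sk.neuron_id not in trees:
            nodes = [n for n in sk.nodes if n.swc_type in (SWC_SOMA, SWC_DENDRITE)]
            trees[sk.neuron_id] = (cKDTree(np.array([n.position for n in nodes])), nodes)
        tree, nodes = trees[sk.neuron_id]
        pos = np.asarray(v.pair.post.centroid)
        k = min(4, len(nodes))
        dists, idxs = tree.query(pos, k=k)
        dists = np.atleast_1d(dists)
        idxs = np.atleast_1d(idxs)
        if dists[0] > search_radius_nm:
            quarantine.append(v)
            continue
        tied = [nodes[i] for d, i in zip(dists, idxs) if d - dists[0] < 1e-9]
        node = min(tied, key=lambda n: n.node_id)
        psd_peak = v.pair.post.centroid
        bas_peak = v.pair.pre.centroid
        records.append(SynapseRecord(
            synapse_id=f"D{len(records)+1:03d}",
            kind=v.pair.kind,
            position=v.pair.post.centroid,
            post_neuron_id=v.post_neuron_id,
            pre_axon_id=v.pre_axon_id if v.pre_axon_id else "unlabeled",
            gephyrin_or_homer_peak=psd_peak,
            bassoon_peak=bas_peak,
            peak_separation_nm=None,   # derived from the peak fields
            compartment="somatic" if node.swc_type == SWC_SOMA else "dendritic",
            psd_volume_um3=v.pair.post.volume_um3,
            node_id=node.node_id,
        ))
    return records, quarantine


def _profile_dir(v: TrioVerdict) -> np.ndarray:
    d = np.asarray(v.profile.p1) - np.asarray(v.profile.p0)
    return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# one-call detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionResult:
    puncta: dict[str, list[Punctum]]
    pairs: list[MarkerPair]
    orphans: dict[str, list[Punctum]]
    verdicts: list[TrioVerdict]
    records: list[SynapseRecord]
    quarantined: list[TrioVerdict] = field(default_factory=list)

    @property
    def accepted(self) -> list[TrioVerdict]:
        return [v for v in self.verdicts if v.accepted]

    def reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.verdicts:
            out[v.reason] = out.get(v.reason, 0) + 1
        return out


def run_detection(grid: VoxelGrid, skeletons: Sequence[Skeleton],
                  criteria: TrioCriteria | None = None,
                  seg_params: SegmentationParams | None = None,
                  max_pair_sep_nm: float = 300.0) -> DetectionResult:
    """Segment the three marker channels, pair, classify, and link."""
    criteria = criteria or TrioCriteria()
    puncta = {ch: segment_puncta(grid, ch, seg_params)
              for ch in ("Bassoon", "Gephyrin", "Homer1") if grid.has_channel(ch)}
    pairs, orphans = pair_puncta(puncta.get("Bassoon", []),
                                 puncta.get("Gephyrin", []),
                                 puncta.get("Homer1", []),
                                 max_sep_nm=max_pair_sep_nm)
    index = SceneIndex(skeletons)
    verdicts = [classify_trio(p, grid, skeletons, criteria, index) for p in pairs]
    records, quarantined = link_and_compartmentalize(verdicts, skeletons)
    return DetectionResult(puncta=puncta, pairs=pairs, orphans=orphans,
                           verdicts=verdicts, records=records,
                           quarantined=quarantined)
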