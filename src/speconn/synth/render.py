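"""Rendering synthetic scenes into voxel grids.

Membrane-targeted FPs outline structures, so each skeleton contributes
intensity on a hollow tube/sphere *surface* (sampled at ~``node_spacing_nm``
point spacing and splatted to nearest voxels), weighted per FP channel by the
structure's raw color.  The result is blurred with an anisotropic Gaussian
PSF whose FWHM defaults to the effective imaging resolution, then optionally
degraded with photon-counting noise.  Synaptic puncta and fiducial blobs are
sub-resolution objects and are rendered analytically (Gaussian with the PSF
folded in).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from ..types import SWC_SOMA, Skeleton, VoxelGrid
from .config import NoiseConfig, SceneConfig
from .skeletons import fibonacci_sphere

__all__ = [
    "surface_points", "render_scene", "render_blobs", "apply_noise",
    "render_fiducial", "FP_CHANNELS", "PUNCTA_CHANNELS",
]

FP_CHANNELS = ["FP1", "FP2", "FP3"]
PUNCTA_CHANNELS = ["Bassoon", "Gephyrin", "Homer1"]
FIDUCIAL_CHANNEL = "fiducial"


def surface_points(skeleton: Skeleton, spacing_nm: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample the membrane surface of a skeleton at ~``spacing_nm``.

    Soma roots become sphere surfaces; type-1 surface nodes are skipped (they
    are bookkeeping for the same sphere); neurites become rings perpendicular
    to the local tangent.  Returns (n, 3) (x,y,z) nm.
    """
    rng = rng or np.random.default_rng(0)
    idx = {n.node_id: i for i, n in enumerate(skeleton.nodes)}
    pos = np.array([n.position for n in skeleton.nodes], dtype=float)
    out = []

    # spheres for big type-1 roots
    for n in skeleton.nodes:
        if n.swc_type == SWC_SOMA and (n.parent_id == -1 or
                                       skeleton.node(n.parent_id).swc_type != SWC_SOMA):
            if n.radius < 3 * spacing_nm:
                continue
            npts = max(16, int(4 * math.pi * n.radius ** 2 / spacing_nm ** 2))
            out.append(np.asarray(n.position) + n.radius * fibonacci_sphere(npts))

    # rings for neurites
    tube_nodes = [n for n in skeleton.nodes if n.swc_type != SWC_SOMA]
    if tube_nodes:
        tpos = np.array([n.position for n in tube_nodes])
        radii = np.array([n.radius for n in tube_nodes])
        parents = np.array([
            idx[n.parent_id] if n.parent_id != -1 else idx[n.node_id]
            for n in tube_nodes
        ])
        tang = tpos - pos[parents]
        bad = np.linalg.norm(tang, axis=1) < 1e-9
        if bad.any():
            tang[bad] = np.roll(tang, -1, axis=0)[bad]
            still = np.linalg.norm(tang, axis=1) < 1e-9
            tang[still] = [0.0, 0.0, 1.0]
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        # stable perpendicular frame
        ref = np.where(np.abs(tang[:, 2:3]) < 0.9,
                       np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]]))
        u = np.cross(tang, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(tang, u)
        for r in np.unique(radii):
            sel = radii == r
            m = max(6, int(math.ceil(2 * math.pi * r / spacing_nm)))
            theta = (np.arange(m) / m) * 2 * math.pi
            phase = rng.uniform(0, 2 * math.pi, size=sel.sum())[:, None]
            th = theta[None, :] + phase
            ring = (tpos[sel][:, None, :]
                    + r * (np.cos(th)[..., None] * u[sel][:, None, :]
                           + np.sin(th)[..., None] * v[sel][:, None, :]))
            out.append(ring.reshape(-1, 3))
    if not out:
        return np.empty((0, 3))
    return np.concatenate(out, axis=0)


def _flat_indices(pts_xyz: np.ndarray, shape, pitch_nm) -> np.ndarray:
    """Nearest-voxel flat indices of points; out-of-volume points dropped."""
    nz, ny, nx = shape
    pz, py, px = pitch_nm
    zi = np.rint(pts_xyz[:, 2] / pz).astype(np.int64)
    yi = np.rint(pts_xyz[:, 1] / py).astype(np.int64)
    xi = np.rint(pts_xyz[:, 0] / px).astype(np.int64)
    ok = (zi >= 0) & (zi < nz) & (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx)
    return (zi[ok] * ny + yi[ok]) * nx + xi[ok]


def render_scene(skeletons: list[Skeleton], config: SceneConfig,
                 seed: int | np.random.Generator = 0,
                 noise: bool = False) -> VoxelGrid:
    """Render the three Brainbow FP channels of a scene (noise-free unless
    ``noise=True``).  Structures without an assigned color are skipped."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = config.grid_shape
    if any(f < p for f, p in zip(config.psf_fwhm, config.pitch_nm)):
        warnings.warn("PSF FWHM below voxel pitch: the rendered scene is undersampled")
    nvox = int(np.prod(shape))
    idx_list, raw_list = [], []
    for sk in skeletons:
        if sk.color is None or not sk.color.defined:
            continue
        pts = surface_points(sk, config.node_spacing_nm, rng)
        if len(pts) == 0:
            continue
        idx_list.append(_flat_indices(pts, shape, config.pitch_nm))
        raw_list.append(np.asarray(sk.color.raw, dtype=float) * config.fp_amplitude)
    data = np.zeros((3,) + shape, dtype=np.float32)
    if idx_list:
        counts = np.concatenate(idx_list)
        owner = np.concatenate([
            np.full(len(ix), i, dtype=np.int32) for i, ix in enumerate(idx_list)
        ])
        raws = np.array(raw_list)  # (n_struct, 3)
        for c in range(3):
            w = raws[owner, c]
            data[c] = np.bincount(counts, weights=w, minlength=nvox).reshape(shape)
    sigma_vox = [s / p for s, p in zip(config.psf_sigma_nm, config.pitch_nm)]
    for c in range(3):
        data[c] = gaussian_filter(data[c], sigma=sigma_vox, mode="constant")
    grid = VoxelGrid(channels=list(FP_CHANNELS), data=data,
                     pitch_nm=config.pitch_nm,
                     expansion_factor=config.expansion_factor, round_id=1)
    if noise and config.noise.enabled:
        grid.data = apply_noise(grid.data, config.noise, rng)
    return grid


def render_blobs(shape, pitch_nm, centers_xyz: np.ndarray,
                 sigmas_nm: np.ndarray, amplitudes: np.ndarray,
                 psf_sigma_nm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Analytic Gaussian blobs (PSF folded in); ``amplitudes`` are the final
    observed peak intensities.  ``sigmas_nm`` is (n,) isotropic pre-PSF size."""
    out = np.zeros(shape, dtype=np.float32)
    nz, ny, nx = shape
    pz, py, px = pitch_nm
    centers_xyz = np.atleast_2d(centers_xyz)
    sigmas_nm = np.broadcast_to(np.asarray(sigmas_nm, dtype=float), (len(centers_xyz),))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(centers_xyz),))
    psz, psy, psx = psf_sigma_nm
    for (x, y, z), s, a in zip(centers_xyz, sigmas_nm, amplitudes):
        sz = math.hypot(s, psz)
        sy = math.hypot(s, psy)
        sx = math.hypot(s, psx)
        rz = max(1, int(math.ceil(4 * sz / pz)))
        ry = max(1, int(math.ceil(4 * sy / py)))
        rx = max(1, int(math.ceil(4 * sx / px)))
        cz, cy, cx = z / pz, y / py, x / px
        z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 2)
        y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 2)
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 2)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz = (np.arange(z0, z1) * pz - z) / sz
        yy = (np.arange(y0, y1) * py - y) / sy
        xx = (np.arange(x0, x1) * px - x) / sx
        g = (np.exp(-0.5 * zz ** 2)[:, None, None]
             * np.exp(-0.5 * yy ** 2)[None, :, None]
             * np.exp(-0.5 * xx ** 2)[None, None, :])
        out[z0:z1, y0:y1, x0:x1] += (a * g).astype(np.float32)
    return out


def apply_noise(data: np.ndarray, noise: NoiseConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Shot noise (Poisson on signal + background) plus Gaussian read noise,
    rounded to integer photon counts in [0, 65535]."""
    if not noise.enabled:
        return data
    out = np.empty_like(data, dtype=np.float32)
    flat_in = data.reshape(data.shape[0], -1) if data.ndim == 4 else data[None].reshape(1, -1)
    flat_out = out.reshape(flat_in.shape)
    for c in range(flat_in.shape[0]):
        lam = np.maximum(flat_in[c].astype(np.float64), 0.0) + noise.background_mean
        counts = rng.poisson(lam).astype(np.float64)
        counts += np.rint(rng.normal(0.0, noise.read_sigma, size=counts.shape))
        flat_out[c] = np.clip(counts, 0, 65535)
    return out


def render_fiducial(config: SceneConfig, rng: np.random.Generator,
                    centers_xyz: np.ndarray | None = None):
    """DAPI-like random blob field used for cross-round registration.

    Returns (channel array, blob centers).  Pass ``centers_xyz`` to re-render
    the same field (e.g. for another round)."""
    sx, sy, sz = config.size_nm
    if centers_xyz is None:
        n = config.fiducial_n_blobs
        centers_xyz = np.stack([
            rng.uniform(500.0, sx - 500.0, n),
            rng.uniform(500.0, sy - 500.0, n),
            rng.uniform(500.0, sz - 500.0, n),
        ], axis=1)
    ch = render_blobs(config.grid_shape, config.pitch_nm, centers_xyz,
                      np.full(len(centers_xyz), config.fiducial_sigma_nm),
                      np.full(len(centers_xyz), config.fiducial_amplitude),
                      psf_sigma_nm=config.psf_sigma_nm)
    return ch, centers_xyz
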