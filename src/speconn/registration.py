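"""Round-to-round registration on the fiducial channel.

Rounds are aligned pairwise to round 1: a coarse translation estimate (phase
correlation) is refined to a full affine (rotation / per-axis scale /
translation) by maximizing normalized cross-correlation over a deterministic
coarse-to-fine pyramid, then a free-form deformation on a coarse control grid
is estimated by local block matching (subvoxel phase correlation per block)
with Gaussian smoothing across control points.  Differing expansion states
are handled by linear upsampling to the finer pitch; expansion factors are
measured as the mean of the per-axis affine scale factors.

The residual reported at each stage is the energy-weighted mean magnitude of
the remaining local displacement (nm), measured by block matching between
the fixed image and the aligned moving image; refinement never returns a
transform with a larger residual than its input stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .transforms import DisplacementField, SpatialTransform, resample_through
from .types import ValidationError, VoxelGrid

__all__ = [
    "upsample_to_match", "estimate_affine", "refine_bspline",
    "apply_transform", "estimate_expansion", "ExpansionEstimate",
    "RegistrationError", "block_match_residual",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class ExpansionEstimate:
    """Per-axis scale factors between two expansion states."""

    scales_xyz: tuple[float, float, float]
    residual_nm: float

    @property
    def mean_factor(self) -> float:
        return float(np.mean(self.scales_xyz))


# ---------------------------------------------------------------------------
# resampling helpers
# ---------------------------------------------------------------------------

def upsample_to_match(low_res: VoxelGrid, target_pitch_nm) -> VoxelGrid:
    """Linearly interpolate a grid onto a finer pitch, preserving physical
    extent (voxel-center span).  Downsampling is refused."""
    tp = tuple(float(p) for p in target_pitch_nm)
    sp = low_res.pitch_nm
    if any(t > s + 1e-9 for t, s in zip(tp, sp)):
        raise ValidationError(
            f"target pitch {tp} coarser than source {sp} on some axis; "
            "upsample_to_match does not downsample"
        )
    if np.allclose(tp, sp):
        return low_res.copy()
    new_shape = tuple(
        int(math.ceil((n - 1) * s / t)) + 1
        for n, s, t in zip(low_res.shape, sp, tp)
    )
    nz, ny, nx = new_shape
    coords = np.stack(np.meshgrid(
        np.arange(nz) * tp[0] / sp[0],
        np.arange(ny) * tp[1] / sp[1],
        np.arange(nx) * tp[2] / sp[2],
        indexing="ij",
    )).reshape(3, -1)
    data = np.empty((low_res.n_channels,) + new_shape, dtype=np.float32)
    for c in range(low_res.n_channels):
        data[c] = map_coordinates(low_res.data[c].astype(np.float32), coords,
                                  order=1, mode="nearest").reshape(new_shape)
    return VoxelGrid(channels=list(low_res.channels), data=data, pitch_nm=tp,
                     expansion_factor=low_res.expansion_factor,
                     round_id=low_res.round_id)


def apply_transform(grid: VoxelGrid, transform: SpatialTransform,
                    order: int = 1) -> VoxelGrid:
    """Resample every channel of ``grid`` through ``transform``
    (out(x) = in(T(x)); outside the volume -> 0)."""
    return resample_through(grid, transform, order=order)


def _get_channel(grid: VoxelGrid, channel: str | None) -> np.ndarray:
    name = channel if channel is not None else grid.channels[0]
    return np.asarray(grid.channel(name), dtype=np.float32)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def _sample_objective(fixed: np.ndarray, moving: np.ndarray, pitch, transform,
                      stride: int = 1, box_nm=None) -> float:
    """-NCC between fixed and moving(T(x)) on a strided voxel set.

    Without ``box_nm`` the correlation runs over the samples that land inside
    the moving grid.  With ``box_nm`` = ((x0,x1),(y0,y1),(z0,z1)) the sample
    set is the fixed central box and out-of-bounds samples score as zeros
    (mismatch), which removes the overlap-shrinkage bias of large-scale
    fits."""
    nz, ny, nx = fixed.shape
    pz, py, px = pitch
    sz, sy, sx = (stride, stride, stride) if np.isscalar(stride) else stride
    zz, yy, xx = np.meshgrid(np.arange(0, nz, sz) * pz,
                             np.arange(0, ny, sy) * py,
                             np.arange(0, nx, sx) * px, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    f = fixed[::sz, ::sy, ::sx].ravel()
    if box_nm is not None:
        (x0, x1), (y0, y1), (z0, z1) = box_nm
        sel = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
               & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
               & (pts[:, 2] >= z0) & (pts[:, 2] <= z1))
        pts = pts[sel]
        f = f[sel]
    mapped = transform.map_points(pts)
    coords = np.stack([mapped[:, 2] / pz, mapped[:, 1] / py, mapped[:, 0] / px])
    vals = map_coordinates(moving, coords, order=1, mode="constant", cval=np.nan)
    bad = np.isnan(vals)
    if box_nm is not None:
        vals[bad] = 0.0
        if len(f) < 32:
            return 0.0
        return -_ncc(f, vals)
    ok = ~bad
    if ok.sum() < 32:
        return 0.0
    return -_ncc(f[ok], vals[ok])


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> SpatialTransform:
    rx, ry, rz, lsx, lsy, lsz, tx, ty, tz = p

    def rot(a, axis):
        c, s = math.cos(a), math.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c; m[j, j] = c; m[i, j] = -s; m[j, i] = s
        return m

    linear = rot(rx, 0) @ rot(ry, 1) @ rot(rz, 2) @ np.diag(np.exp([lsx, lsy, lsz]))
    return SpatialTransform(linear=linear, translation_nm=np.array([tx, ty, tz]),
                            center_nm=center)


def _downsample(a: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return a
    sig = [0.5 * (f - 1)] * 3
    return gaussian_filter(a, sig)[::f, ::f, ::f]


def _powell_pyramid(F, M, pitch, center, p0, rot_max, ls_center, ls_max,
                    t_center, t_max, schedule, maxiter: int = 30,
                    box_nm=None) -> np.ndarray:
    """Coarse-to-fine Powell refinement with penalty walls (bounded Powell in
    scipy can return points worse than its start) and a per-level
    keep-the-better-point guarantee."""
    p = np.asarray(p0, dtype=float).copy()
    direc = np.diag([0.02] * 3 + [0.02] * 3 + [float(np.mean(pitch)) * 2] * 3)
    for level, stride in schedule:
        Fl = _downsample(F, level)
        Ml = _downsample(M, level)
        pl = np.asarray(pitch) * level

        def obj(q):
            if (np.any(np.abs(q[0:3]) > rot_max)
                    or np.any(np.abs(q[3:6] - ls_center) > ls_max)
                    or np.any(np.abs(q[6:9] - t_center) > t_max)):
                return 1.0
            return _sample_objective(Fl, Ml, pl, _params_to_transform(q, center),
                                     stride=stride, box_nm=box_nm)

        res = minimize(obj, p, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": maxiter,
                                "direc": direc.copy()})
        if res.fun <= obj(p):
            p = res.x
    return p


def estimate_affine(fixed: VoxelGrid, moving: VoxelGrid,
                    init: SpatialTransform | None = None,
                    channel: str | None = None,
                    similarity_floor: float = 0.1) -> SpatialTransform:
    """Landmark-free coarse alignment: phase-correlation translation followed
    by Powell refinement of rotation/scale/translation over a 3-level
    pyramid.  Deterministic.  Raises :class:`RegistrationError` when the
    final similarity stays below ``similarity_floor``."""
    F = _get_channel(fixed, channel)
    M = _get_channel(moving, channel)
    pitch = np.array(fixed.pitch_nm, dtype=float)
    center = np.array([s / 2 for s in fixed.extent_nm()])  # xyz

    p0 = np.zeros(9)
    if init is not None:
        # translation/scale seed from a provided transform
        p0[6:9] = init.translation_nm
        p0[3:6] = np.log(np.clip(init.axis_scales, 1e-3, None))
    else:
        shift = phase_cross_correlation(F, M, normalization=None)[0]  # (z,y,x) vox
        # F(x) ~ M(x - shift)  =>  T(x) = x - shift_phys
        p0[6:9] = -np.array([shift[2] * pitch[2], shift[1] * pitch[1],
                             shift[0] * pitch[0]])

    ext = np.array(fixed.extent_nm())
    p = _powell_pyramid(F, M, pitch, center, p0,
                        rot_max=0.15, ls_center=np.zeros(3), ls_max=0.15,
                        t_center=p0[6:9], t_max=0.3 * ext,
                        schedule=((4, 1), (2, (1, 2, 2)), (1, (1, 3, 3))))
    t = _params_to_transform(p, center)
    score = -_sample_objective(F, M, pitch, t, stride=2)
    if score < similarity_floor:
        raise RegistrationError(
            f"affine registration failed: NCC={score:.3f} < floor {similarity_floor} "
            f"(translation {np.round(t.translation_nm,1)}, scales {np.round(t.axis_scales,3)})"
        )
    t.residual_nm = block_match_residual(F, M, pitch, t)
    return t


# ---------------------------------------------------------------------------
# block matching / free-form refinement
# ---------------------------------------------------------------------------

def _block_match(F: np.ndarray, W: np.ndarray, pitch, spacing_vox):
    """Local displacements u (xyz nm) on a control grid such that
    F(x) ~ W(x + u(x)).  Returns (grid_shape, u values (3,gz,gy,gx),
    weights, control spacing nm (x,y,z))."""
    nz, ny, nx = F.shape
    sz, sy, sx = spacing_vox
    gz = max(2, nz // sz + 1)
    gy = max(2, ny // sy + 1)
    gx = max(2, nx // sx + 1)
    u = np.zeros((3, gz, gy, gx))
    w = np.zeros((gz, gy, gx))
    for iz in range(gz):
        cz = int(round(iz * (nz - 1) / (gz - 1)))
        z0, z1 = max(0, cz - sz), min(nz, cz + sz + 1)
        for iy in range(gy):
            cy = int(round(iy * (ny - 1) / (gy - 1)))
            y0, y1 = max(0, cy - sy), min(ny, cy + sy + 1)
            for ix in range(gx):
                cx = int(round(ix * (nx - 1) / (gx - 1)))
                x0, x1 = max(0, cx - sx), min(nx, cx + sx + 1)
                fb = F[z0:z1, y0:y1, x0:x1]
                wb = W[z0:z1, y0:y1, x0:x1]
                if fb.std() < 1e-6 or wb.std() < 1e-6:
                    continue
                shift = phase_cross_correlation(
                    fb, wb, upsample_factor=10, normalization=None)[0]
                # F(x) ~ W(x - shift)  =>  u = -shift (to physical xyz)
                u[0, iz, iy, ix] = -shift[2] * pitch[2]
                u[1, iz, iy, ix] = -shift[1] * pitch[1]
                u[2, iz, iy, ix] = -shift[0] * pitch[0]
                w[iz, iy, ix] = fb.std() * wb.std()
    spacing_nm = ((nx - 1) * pitch[2] / (gx - 1), (ny - 1) * pitch[1] / (gy - 1),
                  (nz - 1) * pitch[0] / (gz - 1))
    return u, w, spacing_nm


def _smooth_field(u: np.ndarray, w: np.ndarray, sigma: float = 0.6) -> np.ndarray:
    """Weighted Gaussian smoothing of the control-grid field (acts as the
    bending-energy regularizer of the free-form deformation)."""
    out = np.empty_like(u)
    ws = gaussian_filter(w, sigma)
    ws[ws == 0] = 1.0
    for d in range(3):
        out[d] = gaussian_filter(u[d] * w, sigma) / ws
    return out


def block_match_residual(F: np.ndarray, M: np.ndarray, pitch,
                         transform: SpatialTransform,
                         spacing_vox=(8, 16, 16)) -> float:
    """Energy-weighted mean |local displacement| (nm) after alignment."""
    grid = VoxelGrid(channels=["c"], data=M[None], pitch_nm=tuple(pitch))
    W = resample_through(grid, transform).data[0]
    u, w, _ = _block_match(F, W, pitch, spacing_vox)
    if w.sum() == 0:
        return float("nan")
    mag = np.sqrt((u ** 2).sum(axis=0))
    return float((mag * w).sum() / w.sum())


def refine_bspline(fixed: VoxelGrid, moving: VoxelGrid,
                   affine: SpatialTransform,
                   control_spacing_nm: float = 1500.0,
                   channel: str | None = None,
                   max_displacement_nm: float | None = None,
                   iterations: int = 2) -> SpatialTransform:
    """Free-form refinement of an affine pre-alignment.

    Local block matching against the warped moving image yields a smooth
    displacement field on a coarse control grid, iterated ``iterations``
    times (each pass matches against the previously corrected warp and
    accumulates).  If the refined residual is not better than the affine
    residual, the affine transform is returned unchanged (with a warning),
    so residuals are monotone non-increasing across stages."""
    F = _get_channel(fixed, channel)
    M = _get_channel(moving, channel)
    pitch = np.array(fixed.pitch_nm, dtype=float)
    grid = VoxelGrid(channels=["c"], data=M[None], pitch_nm=tuple(pitch))

    spacing_vox = tuple(max(4, int(round(control_spacing_nm / p))) for p in pitch)

    def build(u_field, spacing_nm):
        # warped(x) = moving(T_aff(x + u(x))) = moving(A(x-c)+c+t + A u(x))
        disp_vals = np.einsum("ij,jzyx->izyx", affine.linear, u_field)
        return SpatialTransform(
            linear=affine.linear.copy(),
            translation_nm=affine.translation_nm.copy(),
            center_nm=affine.center_nm.copy(),
            displacement=DisplacementField(values=disp_vals, spacing_nm=spacing_nm),
        )

    u_total = None
    spacing_nm = None
    current = affine
    for _ in range(max(1, iterations)):
        W = resample_through(grid, current).data[0]
        u, w, spacing_nm = _block_match(F, W, pitch, spacing_vox)
        u = _smooth_field(u, w)
        u_total = u if u_total is None else u_total + u
        if max_displacement_nm is not None:
            mag = np.sqrt((u_total ** 2).sum(axis=0, keepdims=True))
            scale = np.where(mag > max_displacement_nm,
                             max_displacement_nm / np.maximum(mag, 1e-9), 1.0)
            u_total = u_total * scale
        current = build(u_total, spacing_nm)
    refined = current
    aff_res = affine.residual_nm
    if not np.isfinite(aff_res):
        aff_res = block_match_residual(F, M, pitch, affine)
        affine.residual_nm = aff_res
    ref_res = block_match_residual(F, M, pitch, refined)
    if np.isfinite(aff_res) and (not np.isfinite(ref_res) or ref_res > aff_res):
        warnings.warn(
            f"free-form refinement did not improve the residual "
            f"({ref_res:.1f} vs {aff_res:.1f} nm); returning affine-only"
        )
        return affine
    refined.residual_nm = ref_res
    return refined


# ---------------------------------------------------------------------------
# expansion-factor estimation
# ---------------------------------------------------------------------------

def estimate_expansion(pre_grid: VoxelGrid, post_grid: VoxelGrid,
                       channel: str | None = None,
                       scale_range: tuple[float, float] = (1.0, 8.0),
                       shear_warn: float = 0.1) -> ExpansionEstimate:
    """Expansion factor between two imaging states of one structure.

    Fits an affine from the post-expansion grid onto the pre-expansion grid
    (coarse isotropic-scale scan + phase-correlation translation, then full
    affine refinement) and reads the per-axis scale factors from the linear
    part (column norms, i.e. polar-decomposition stretches for small
    rotations); the expansion factor is their arithmetic mean."""
    # fixed = pre-expansion state: mapping pre positions into the post image
    # carries the expansion factor in its linear part
    F = _get_channel(pre_grid, channel)
    M = _get_channel(post_grid, channel)
    pitch = np.array(pre_grid.pitch_nm, dtype=float)
    center = np.array([s / 2 for s in pre_grid.extent_nm()])

    lo, hi = scale_range
    best = (None, -np.inf)
    F2 = _downsample(F, 2)
    M2 = _downsample(M, 2)
    for s in np.geomspace(lo, hi, 40):
        t = SpatialTransform(linear=np.eye(3) * s, center_nm=center)
        score = -_sample_objective(F2, M2, pitch * 2, t, stride=2)
        if score > best[1]:
            best = (s, score)
    s0 = best[0]
    p0 = np.zeros(9)
    p0[3:6] = math.log(s0)

    # constrained refinement: the overlap between expansion states is a small
    # central region, so an unconstrained search can drift into degenerate
    # scales that map almost everything outside the moving grid
    ext = np.array(pre_grid.extent_nm())
    # fixed central evaluation box: stays inside the post grid for any scale
    # up to 1.15 * s0, so the sample set cannot shrink with the scale
    half = ext / (2 * s0 * 1.15)
    box = tuple((c - h, c + h) for c, h in zip(center, half))
    p = _powell_pyramid(F, M, pitch, center, p0,
                        rot_max=0.1, ls_center=p0[3:6], ls_max=0.25,
                        t_center=np.zeros(3), t_max=0.2 * ext,
                        schedule=((2, (1, 2, 2)), (1, (1, 2, 2))),
                        maxiter=60, box_nm=box)
    t = _params_to_transform(p, center)

    # shear diagnostic: asymmetry of the polar-decomposition stretch
    A = t.linear
    P = A.T @ A
    offd = np.abs(P - np.diag(np.diag(P))).max()
    if offd / np.abs(np.diag(P)).max() > shear_warn:
        warnings.warn("non-affine distortion: shear exceeds threshold")
    scales = t.axis_scales  # (x, y, z)
    res = block_match_residual(F, M, pitch, t)
    return ExpansionEstimate(scales_xyz=tuple(float(s) for s in scales),
                             residual_nm=res)
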