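"""Masks and skeletons locating where V:SA is computed and normalized.

The measurement needs five co-registered binary volumes: the cell, the bath
(the normalization reference for the volume dye), the surface sarcolemma
skeleton (the normalization reference for the membrane dye), the t-tubule
skeleton (where the ratio is evaluated) and the cytosol (where background is
sampled).  All are derived from the two dye channels with standard
morphology: Otsu thresholds, closing, topology-preserving 3D thinning.

Connectivity conventions: 26-connectivity for foreground, 6 for background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._thinning import thin_3d
from .image import VolumeImage
from .psf import PSFSpec

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaskSet:
    """Co-registered binary volumes used by the measurement.

    Invariants: the TT skeleton lies inside the cell mask; SS and TT
    skeletons are disjoint; bath and cell are disjoint; skeletons are one
    voxel wide.
    """

    cell: np.ndarray
    cytosol: np.ndarray
    bath: np.ndarray
    membrane_skeleton: np.ndarray
    ss_skeleton: np.ndarray
    tt_skeleton: np.ndarray
    voxel_um: tuple[float, float, float]


def save_masks(masks: "MaskSet", out_dir) -> None:
    """Write each binary volume as 8-bit multi-page TIFF and the skeletons
    as CSV voxel lists (z, y, x, branch-point flag)."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cell", "cytosol", "bath", "membrane_skeleton", "ss_skeleton", "tt_skeleton"):
        arr = getattr(masks, name).astype(np.uint8) * 255
        tifffile.imwrite(out / f"{name}.tif", arr, photometric="minisblack")
    for name in ("ss_skeleton", "tt_skeleton"):
        skel = getattr(masks, name)
        bp = branch_points(skel)
        coords = np.argwhere(skel)
        flags = bp[tuple(coords.T)].astype(int) if coords.size else np.empty((0,), int)
        rows = np.column_stack([coords, flags]) if coords.size else np.empty((0, 4), int)
        np.savetxt(
            out / f"{name}.csv", rows, fmt="%d", delimiter=",",
            header="z,y,x,branch_point", comments="",
        )


def otsu_threshold(image: VolumeImage, within: np.ndarray | None = None) -> float:
    """Otsu's threshold (256-bin histogram over the observed range).

    ``within`` optionally restricts the histogram to a region.  Raises on a
    constant image, where no between-class variance exists.
    """
    values = image.data[within] if within is not None else image.data.ravel()
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0 or values.max() == values.min():
        raise ValueError("cannot threshold a constant (or empty) region")
    return float(threshold_otsu(values, nbins=256))


def skeletonize_3d(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to 1-voxel-wide lines (26-connectivity).

    Border-sequential curve thinning with exact simple-point tests;
    idempotent on its own output (see :mod:`ttvsa._thinning`).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return thin_3d(mask)


def _ball_footprint(radius_um: float, voxel_um: tuple[float, float, float]) -> np.ndarray:
    """Anisotropy-aware ellipsoidal structuring element of physical radius."""
    r_vox = [max(int(np.ceil(radius_um / v)), 1) for v in voxel_um]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in r_vox)]
    dist2 = sum(((g * v) / radius_um) ** 2 for g, v in zip(grids, voxel_um))
    return dist2 <= 1.0 + 1e-9


def cell_mask(
    volume_channel: VolumeImage,
    psf: PSFSpec,
    closing_um: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell and bath masks from the extracellular volume-dye channel.

    The cell interior is dye-poor, so the cell is the below-threshold region
    after a morphological closing (which folds thin bright tubule lumina
    into the cell body) and largest-component selection.  The bath is the
    above-threshold region eroded away from the cell boundary by one
    symmetrized-PSF FWHM, so blur roll-off near the surface cannot bias the
    bath normalization.
    """
    t = otsu_threshold(volume_channel)
    below = volume_channel.data < t
    if not below.any():
        raise ValueError("no below-threshold region: the field appears to be all bath")

    footprint = _ball_footprint(closing_um, volume_channel.voxel_um)
    # pad with edge values so the closing cannot eat a rim at the stack faces
    pad = [(s // 2,) * 2 for s in footprint.shape]
    padded = np.pad(below, pad, mode="edge")
    closed = ndimage.binary_closing(padded, structure=footprint)
    cell = closed[tuple(slice(p, p + n) for (p, _), n in zip(pad, below.shape))]
    labels, n = ndimage.label(cell, structure=_STRUCT26)
    if n == 0:
        raise ValueError("no cell component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    cell = labels == (1 + int(np.argmax(sizes)))

    fwhm = psf.symmetrized().fwhm_z
    guard = _ball_footprint(fwhm, volume_channel.voxel_um)
    bath = (~cell) & ~ndimage.binary_dilation(cell, structure=guard)
    return cell, bath


def _boundary_normals(cell: np.ndarray, voxel_um, smooth_um: float = 0.2):
    """Outward normals of the cell boundary from the smoothed mask gradient."""
    sigma_vox = [smooth_um / v for v in voxel_um]
    smooth = ndimage.gaussian_filter(cell.astype(np.float64), sigma=sigma_vox)
    grads = np.gradient(smooth, *voxel_um)  # d/dz, d/dy, d/dx (physical)
    g = np.stack(grads, axis=-1)
    norm = np.linalg.norm(g, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = -g / norm[..., None]  # outward: toward decreasing occupancy
    return n, smooth


def surface_skeleton(
    membrane_channel: VolumeImage,
    volume_channel: VolumeImage,
    cell: np.ndarray,
    max_normal_tilt_deg: float = 60.0,
    max_curvature_per_um: float = 1.5,
    snap_radius_vox: int = 2,
) -> np.ndarray:
    """Select surface-sarcolemma reference voxels on the cell boundary.

    Keeps boundary voxels where (a) both dye channels show a strong edge
    (gradient magnitudes above their Otsu cutoffs), (b) the boundary normal
    lies within ``max_normal_tilt_deg`` of the lateral (x-y) plane — i.e.
    in-focus side walls, not the poorly resolved top/bottom caps — and (c)
    the local mean curvature is small, rejecting z-groove mouths where
    tubules invaginate.  Each kept voxel is then snapped to the
    membrane-channel maximum within ±``snap_radius_vox`` voxels along its
    normal, so the SS reference samples the blurred membrane peak rather
    than a threshold-dependent offset surface.
    """
    if cell is None or not np.asarray(cell).any():
        raise ValueError("cell mask is empty")
    cell = np.asarray(cell, dtype=bool)
    voxel_um = membrane_channel.voxel_um

    # border_value=1 so faces of the stack do not count as cell surface
    boundary = cell & ~ndimage.binary_erosion(
        cell, structure=np.ones((3, 3, 3), bool), border_value=1
    )
    if not boundary.any():
        raise ValueError("cell mask has no interior boundary (touches every stack face?)")
    normals, smooth = _boundary_normals(cell, voxel_um)

    # (a) gradient cutoffs from the boundary population of each channel:
    # Otsu separates true dye edges from weak residual boundary voxels
    keep = boundary.copy()
    for ch in (membrane_channel, volume_channel):
        gm = ndimage.gaussian_gradient_magnitude(
            np.asarray(ch.data, dtype=np.float64), sigma=[0.12 / v for v in voxel_um]
        )
        vals = gm[boundary]
        if vals.max() > vals.min() * (1 + 1e-6):
            cutoff = float(threshold_otsu(vals, nbins=256))
            keep &= gm >= cutoff

    # (b) normal within a cone of the lateral plane: reject caps (|n_z| large)
    nz = np.abs(normals[..., 0])
    keep &= nz <= np.sin(np.radians(max_normal_tilt_deg))

    # (c) curvature: divergence of the unit normal field of the smoothed mask
    div = np.zeros_like(smooth)
    for axis in range(3):
        div += np.gradient(np.nan_to_num(-normals[..., axis]), voxel_um[axis], axis=axis)
    keep &= np.abs(div) <= 2.0 * max_curvature_per_um

    if not keep.any():
        raise ValueError(
            "no surface-sarcolemma voxels survived the gradient/orientation/curvature "
            "criteria; relax max_normal_tilt_deg or max_curvature_per_um"
        )

    # snap to the membrane peak along the outward normal
    mem = np.asarray(membrane_channel.data, dtype=np.float64)
    idx = np.argwhere(keep)
    nvec = normals[keep]
    shape = mem.shape
    ss = np.zeros_like(keep)
    offsets = np.arange(-snap_radius_vox, snap_radius_vox + 1)
    # candidate positions: voxel index + k * normal (in voxel steps per axis)
    step = nvec / np.array(voxel_um)[None, :]
    step = step / np.maximum(np.linalg.norm(step, axis=1, keepdims=True), 1e-12)
    best_val = np.full(idx.shape[0], -np.inf)
    best_pos = idx.copy()
    for k in offsets:
        cand = np.rint(idx + k * step).astype(int)
        ok = np.all((cand >= 0) & (cand < np.array(shape)[None, :]), axis=1)
        vals = np.full(idx.shape[0], -np.inf)
        vals[ok] = mem[tuple(cand[ok].T)]
        better = vals > best_val
        best_val[better] = vals[better]
        best_pos[better] = cand[better]
    ss[tuple(best_pos.T)] = True
    return ss


def tt_skeleton(
    membrane_skeleton: np.ndarray,
    cell: np.ndarray,
    ss_skeleton: np.ndarray,
    psf: PSFSpec,
    voxel_um: tuple[float, float, float],
    min_spur_vox: int = 2,
) -> np.ndarray:
    """The t-tubule skeleton: membrane skeleton restricted to the deep cell.

    The cell mask is eroded by one symmetrized FWHM so voxels whose blur
    overlaps the surface sarcolemma are excluded; SS voxels are removed
    explicitly; spurs shorter than ``min_spur_vox`` are pruned.  May be
    empty (a cell without tubules is a valid scene).
    """
    fwhm = psf.symmetrized().fwhm_z
    guard = _ball_footprint(fwhm, voxel_um)
    deep = ndimage.binary_erosion(np.asarray(cell, bool), structure=guard)
    skel = np.asarray(membrane_skeleton, bool) & deep & ~np.asarray(ss_skeleton, bool)
    return prune_spurs(skel, min_spur_vox)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    return ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")


def _neighbors_26(idx: tuple[int, int, int], skel: np.ndarray) -> list[tuple[int, int, int]]:
    z, y, x = idx
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                q = (z + dz, y + dy, x + dx)
                if all(0 <= q[a] < skel.shape[a] for a in range(3)) and skel[q]:
                    out.append(q)
    return out


def prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove terminal branches shorter than ``min_len`` voxels.

    Walks from each endpoint toward the nearest branch point; only walks
    that hit a branch point within ``min_len`` steps are deleted (true
    spurs).  Straight, unbranched lines are left untouched.
    """
    skel = np.asarray(skel, bool).copy()
    if min_len <= 0 or not skel.any():
        return skel
    counts = _neighbor_counts(skel)
    endpoints = [tuple(p) for p in np.argwhere(skel & (counts == 1))]
    for ep in endpoints:
        path = [ep]
        prev = None
        cur = ep
        is_spur = False
        while len(path) <= min_len:
            nbs = [q for q in _neighbors_26(cur, skel) if q != prev]
            if len(nbs) != 1:
                # branch point (or dead end): a short walk ending here is a spur
                is_spur = len(nbs) > 1
                break
            prev, cur = cur, nbs[0]
            path.append(cur)
        if is_spur and len(path) <= min_len:
            for p in path[:-1]:  # keep the branch point itself
                skel[p] = False
    return skel


def reclaim_ends(skel: np.ndarray, mask: np.ndarray, max_steps: int = 50) -> np.ndarray:
    """Extend skeleton endpoints through the mask they were thinned from.

    Thinning retracts open line ends by a few voxels (endpoint protection
    only engages once the end is one voxel wide).  Each endpoint is stepped
    onward along its incoming direction for as long as the original mask
    continues, restoring the full physical length of unbranched tubules.
    """
    skel = np.asarray(skel, bool).copy()
    mask = np.asarray(mask, bool)
    counts = _neighbor_counts(skel)
    tips = [tuple(p) for p in np.argwhere(skel & (counts == 1))]
    for tip in tips:
        # estimate the outgoing direction from several voxels of back-path,
        # not just the adjacent one, so a diagonal last step cannot send the
        # extension off at a false angle
        path = [tip]
        prev, cur = None, tip
        for _ in range(6):
            nbs = [q for q in _neighbors_26(cur, skel) if q != prev]
            if len(nbs) != 1:
                break
            prev, cur = cur, nbs[0]
            path.append(cur)
        if len(path) < 2:
            continue
        v = np.array(tip, dtype=float) - np.array(path[-1], dtype=float)
        v /= max(np.abs(v).max(), 1.0)
        d = tuple(int(np.sign(c)) if abs(c) >= 0.5 else 0 for c in v)
        if d == (0, 0, 0):
            continue
        cur = tip
        for _ in range(max_steps):
            nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if not all(0 <= nxt[a] < skel.shape[a] for a in range(3)):
                break
            if not mask[nxt] or skel[nxt]:
                break
            skel[nxt] = True
            cur = nxt
    return skel


def branch_points(skel: np.ndarray) -> np.ndarray:
    """Skeleton voxels with more than two skeleton neighbors."""
    skel = np.asarray(skel, bool)
    return skel & (_neighbor_counts(skel) > 2)


def cytosol_mask(
    cell: np.ndarray,
    tt_skel: np.ndarray,
    voxel_um: tuple[float, float, float],
    dilation_um: float,
    exclude_boundary: bool = True,
) -> np.ndarray:
    """Cell interior excluding the TT neighborhood (background sampling region).

    A band of the same physical radius around the cell boundary is excluded
    as well: those voxels carry the blur tails of the surface sarcolemma and
    of the bath, which are signal, not background.
    """
    cell = np.asarray(cell, bool)
    guard = _ball_footprint(dilation_um, voxel_um)
    tt_zone = ndimage.binary_dilation(np.asarray(tt_skel, bool), structure=guard)
    cyt = cell & ~tt_zone
    if exclude_boundary:
        cyt &= ndimage.binary_erosion(cell, structure=guard, border_value=1)
    if not cyt.any():
        raise ValueError("cytosol mask is empty: TT neighborhood covers the whole cell")
    return cyt


def build_masks(
    membrane_channel: VolumeImage,
    volume_channel: VolumeImage,
    psf: PSFSpec,
    closing_um: float = 0.3,
    min_spur_vox: int = 2,
    max_normal_tilt_deg: float = 60.0,
    max_curvature_per_um: float = 1.5,
    tt_contrast_floor: float = 0.05,
) -> MaskSet:
    """Run the full mask-construction stage on a channel pair."""
    voxel_um = membrane_channel.voxel_um
    cell, bath = cell_mask(volume_channel, psf, closing_um=closing_um)
    ss = surface_skeleton(
        membrane_channel,
        volume_channel,
        cell,
        max_normal_tilt_deg=max_normal_tilt_deg,
        max_curvature_per_um=max_curvature_per_um,
    )
    # threshold the membrane channel inside the deep cell interior: the far
    # brighter surface sarcolemma would otherwise dominate the histogram and
    # push the Otsu cutoff above faint tubule signal
    fwhm_sym = psf.symmetrized().fwhm_z
    deep = ndimage.binary_erosion(cell, structure=_ball_footprint(fwhm_sym, voxel_um))
    try:
        memb_thresh = otsu_threshold(membrane_channel, within=deep)
    except ValueError:  # featureless interior: no tubules
        memb_thresh = np.inf
    # a featureless interior still yields an Otsu split of its residual blur
    # tails; require genuine tubule contrast against the brightest membrane
    if memb_thresh < tt_contrast_floor * float(membrane_channel.data.max()):
        memb_thresh = np.inf
    memb_mask = (membrane_channel.data >= memb_thresh) & deep
    memb_skel = reclaim_ends(skeletonize_3d(memb_mask), memb_mask)
    tt = tt_skeleton(memb_skel, cell, ss, psf, voxel_um, min_spur_vox=min_spur_vox)
    fwhm = psf.symmetrized().fwhm_z
    cyt = cytosol_mask(cell, tt, voxel_um, dilation_um=fwhm)
    log.info(
        "masks: cell=%d bath=%d ss=%d tt=%d cytosol=%d voxels",
        cell.sum(), bath.sum(), ss.sum(), tt.sum(), cyt.sum(),
    )
    return MaskSet(
        cell=cell,
        cytosol=cyt,
        bath=bath,
        membrane_skeleton=memb_skel,
        ss_skeleton=ss,
        tt_skeleton=tt,
        voxel_um=voxel_um,
    )
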