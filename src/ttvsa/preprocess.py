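"""Background subtraction, PSF symmetrization and physical normalization.

The processing order is fixed: background subtraction, then the lateral
blur that symmetrizes the PSF, then normalization.  The volume channel is
normalized so the bath mean is 1 (a dimensionless extracellular volume
fraction); the membrane channel so its mean over the surface-sarcolemma
skeleton is 1 (relative surface density, SS ≡ 1).  With both conventions in
place the channel ratio at a tubule is a calibrated volume-to-surface-area
ratio: ~0.5 at the SS itself, and proportional to tubule diameter on the TT
skeleton.

Negative intermediate values are kept (blur must average them correctly);
clipping to zero happens only when the final ratio is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import trim_mean

from .image import VolumeImage
from .psf import PSFSpec, apply_blur, symmetrization_blur
from .segmentation import MaskSet

log = logging.getLogger(__name__)


@dataclass
class NormalizedPair:
    """Background-subtracted, symmetrized, normalized channel pair.

    ``volume.data`` has bath mean 1; ``membrane.data`` has SS-skeleton mean
    1.  ``provenance`` records the PSF, the normalization constants and the
    masks' voxel counts, so every downstream number is auditable.
    """

    volume: VolumeImage
    membrane: VolumeImage
    psf: PSFSpec
    provenance: dict = field(default_factory=dict)


def _median_smooth(data: np.ndarray, radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return data
    size = 2 * radius_vox + 1
    return ndimage.median_filter(data, size=size)


def nearest_cytosol_lookup(
    cytosol: np.ndarray,
    targets: np.ndarray,
    voxel_um: tuple[float, float, float],
) -> np.ndarray:
    """Index (into the image) of the nearest cytosol voxel for each target.

    Distances are Euclidean in physical units.  Exact ties are broken
    deterministically toward the lowest (z, y, x) index.  ``targets`` is an
    (M, 3) integer array of voxel indices; returns an (M, 3) array.
    """
    cyt_idx = np.argwhere(cytosol)
    if cyt_idx.size == 0:
        raise ValueError("cytosol mask is empty")
    # lexicographic order so tie-breaking can pick the first candidate
    order = np.lexsort((cyt_idx[:, 2], cyt_idx[:, 1], cyt_idx[:, 0]))
    cyt_idx = cyt_idx[order]
    scale = np.asarray(voxel_um)
    tree = cKDTree(cyt_idx * scale)
    eps = 1e-9
    if cyt_idx.shape[0] == 1:
        return np.repeat(cyt_idx, targets.shape[0], axis=0)
    d, j = tree.query(targets * scale, k=2)
    out = cyt_idx[j[:, 0]].copy()
    # resolve exact-distance ties toward the lexicographically smallest voxel
    tied = np.flatnonzero(d[:, 1] - d[:, 0] < eps)
    for m in tied:
        cands = tree.query_ball_point(targets[m] * scale, d[m, 0] + eps)
        out[m] = cyt_idx[min(cands)]
    return out


def estimate_background(
    image: VolumeImage,
    cytosol: np.ndarray,
    tt_skel: np.ndarray,
    outside_value: float = 0.0,
    median_radius_vox: int = 2,
    interpolate_within: np.ndarray | None = None,
) -> VolumeImage:
    """Background field for one channel.

    Over the cytosol the background is the (median-smoothed) image itself;
    at TT-skeleton voxels — and at every voxel of ``interpolate_within``
    (typically the whole cell mask) outside the cytosol — it is
    nearest-neighbor interpolated from the cytosol (physical-unit Euclidean
    distance, lowest-(z,y,x) tie-break); elsewhere it is ``outside_value``
    (0 for the membrane channel; for the volume channel the caller restricts
    subtraction to the cell, since the bath is signal).
    """
    cytosol = np.asarray(cytosol, bool)
    if not cytosol.any():
        raise ValueError("cytosol mask is empty")
    tt_skel = np.asarray(tt_skel, bool)

    smoothed = _median_smooth(np.asarray(image.data, dtype=np.float64), median_radius_vox)
    bg = np.full(image.shape, float(outside_value), dtype=np.float64)
    bg[cytosol] = smoothed[cytosol]

    interp = tt_skel if interpolate_within is None else (
        tt_skel | np.asarray(interpolate_within, bool)
    )
    targets = np.argwhere(interp & ~cytosol)
    if targets.size:
        src = nearest_cytosol_lookup(cytosol, targets, image.voxel_um)
        bg[tuple(targets.T)] = smoothed[tuple(src.T)]
    return image.like(bg)


def subtract_background(image: VolumeImage, background: VolumeImage) -> VolumeImage:
    """Elementwise subtraction (no clipping; see module docstring)."""
    if image.shape != background.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs background {background.shape}"
        )
    return image.like(np.asarray(image.data, np.float64) - np.asarray(background.data, np.float64))


def _trimmed_mean(values: np.ndarray, trim: float = 0.1) -> float:
    """Mean of the central (1 − 2·trim) fraction; robust to stray debris."""
    return float(trim_mean(np.asarray(values, dtype=np.float64), trim))


def normalize_pair(
    volume_channel: VolumeImage,
    membrane_channel: VolumeImage,
    masks: MaskSet,
    psf: PSFSpec,
    symmetrize: bool = True,
    subtract: bool = True,
    median_radius_vox: int = 2,
) -> NormalizedPair:
    """Run the full preprocessing chain on a raw channel pair.

    Steps: cytosol-based background subtraction (volume channel inside the
    cell only — the bath is signal; membrane channel everywhere against a
    zero far field), lateral symmetrization blur, then normalization of the
    volume channel to the bath trimmed mean and of the membrane channel to
    the SS-skeleton trimmed mean.  Both normalizations are scale-invariant:
    regaining either detector leaves the output unchanged.
    """
    if not np.asarray(masks.bath, bool).any():
        raise ValueError("bath mask is empty; cannot normalize the volume channel")
    if not np.asarray(masks.ss_skeleton, bool).any():
        raise ValueError("SS skeleton is empty; cannot normalize the membrane channel")

    vol = volume_channel
    mem = membrane_channel
    if subtract:
        vol_bg = estimate_background(
            vol, masks.cytosol, masks.tt_skeleton,
            median_radius_vox=median_radius_vox, interpolate_within=masks.cell,
        )
        # bath region of the volume channel is signal: no subtraction there
        vol_bg_data = vol_bg.data.copy()
        vol_bg_data[~np.asarray(masks.cell, bool)] = 0.0
        vol = subtract_background(vol, vol.like(vol_bg_data))
        mem_bg = estimate_background(
            mem, masks.cytosol, masks.tt_skeleton,
            median_radius_vox=median_radius_vox, interpolate_within=masks.cell,
        )
        mem = subtract_background(mem, mem_bg)

    if symmetrize and psf.state != "symmetrized" and not psf.is_isotropic:
        extra = symmetrization_blur(psf)
        vol = apply_blur(vol, extra)
        mem = apply_blur(mem, extra)
    psf_out = psf if psf.state == "symmetrized" else psf.symmetrized()

    bath_ref = _trimmed_mean(vol.data[np.asarray(masks.bath, bool)])
    ss_ref = _trimmed_mean(mem.data[np.asarray(masks.ss_skeleton, bool)])
    if bath_ref <= 0:
        raise ValueError(f"bath normalization constant must be positive, got {bath_ref}")
    if ss_ref <= 0:
        raise ValueError(f"SS normalization constant must be positive, got {ss_ref}")

    vol_n = vol.like(vol.data / bath_ref)
    mem_n = mem.like(mem.data / ss_ref)
    provenance = {
        "bath_reference": bath_ref,
        "ss_reference": ss_ref,
        "psf_fwhm_um_zyx": list(psf_out.fwhm_zyx),
        "bath_voxels": int(np.asarray(masks.bath, bool).sum()),
        "ss_voxels": int(np.asarray(masks.ss_skeleton, bool).sum()),
        "tt_voxels": int(np.asarray(masks.tt_skeleton, bool).sum()),
        "background_subtracted": bool(subtract),
        "symmetrized": bool(symmetrize),
    }
    log.info("normalization: bath=%.6g ss=%.6g", bath_ref, ss_ref)
    return NormalizedPair(volume=vol_n, membrane=mem_n, psf=psf_out, provenance=provenance)
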