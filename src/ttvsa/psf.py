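"""Point-spread-function estimation and symmetrization.

The microscope blur is modelled throughout as a separable anisotropic
Gaussian, summarised by its full width at half maximum (FWHM) per axis.
Confocal stacks resolve worse along the optical (z) axis than laterally, so
intensity read off a thin tubule depends on the tubule's orientation.  The
fix is to blur the data laterally until the effective PSF is spherical with
FWHM equal to the raw axial FWHM ("symmetrization"); sizing is then
orientation-independent.

Gaussian widths convert as ``FWHM = 2 sqrt(2 ln 2) σ``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .image import VolumeImage

log = logging.getLogger(__name__)

#: FWHM / sigma for a Gaussian.
FWHM_PER_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class PSFSpec:
    """Gaussian-equivalent resolution of the imaging system.

    ``fwhm_x/y/z`` are full widths at half maximum in μm.  ``state`` records
    whether this describes the raw microscope PSF or the spherically
    symmetrized effective PSF.
    """

    fwhm_x: float
    fwhm_y: float
    fwhm_z: float
    state: str = "raw"  # "raw" | "symmetrized"

    def __post_init__(self) -> None:
        for name in ("fwhm_x", "fwhm_y", "fwhm_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.state not in ("raw", "symmetrized"):
            raise ValueError(f"state must be 'raw' or 'symmetrized', got {self.state!r}")

    @property
    def sigma_um(self) -> tuple[float, float, float]:
        """Gaussian σ per axis in (z, y, x) order, μm."""
        return (fwhm_to_sigma(self.fwhm_z), fwhm_to_sigma(self.fwhm_y), fwhm_to_sigma(self.fwhm_x))

    @property
    def fwhm_zyx(self) -> tuple[float, float, float]:
        return (self.fwhm_z, self.fwhm_y, self.fwhm_x)

    def symmetrized(self) -> "PSFSpec":
        """The spherical PSF reached by lateral blurring (FWHM = raw z FWHM)."""
        return PSFSpec(self.fwhm_z, self.fwhm_z, self.fwhm_z, state="symmetrized")

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.fwhm_x, self.fwhm_z) and np.isclose(self.fwhm_y, self.fwhm_z)


def symmetrization_blur(raw: PSFSpec) -> tuple[float, float, float]:
    """Extra Gaussian widths (σ in μm, (z, y, x) order) that make the PSF spherical.

    Gaussian blurs compose in quadrature, so the lateral deficit is
    ``σ_extra = sqrt(σ_z² − σ_axis²)`` and no extra axial blur is applied.
    Raises if z is not the lowest-resolution axis: the method assumes the
    optical axis is worst and does not silently reinterpret the axes.
    """
    if raw.fwhm_z < raw.fwhm_x or raw.fwhm_z < raw.fwhm_y:
        raise ValueError(
            f"axial FWHM ({raw.fwhm_z} μm) must be >= lateral FWHMs "
            f"({raw.fwhm_x}, {raw.fwhm_y} μm); symmetrization blurs laterally only"
        )
    sz, sy, sx = raw.sigma_um
    return (0.0, float(np.sqrt(sz**2 - sy**2)), float(np.sqrt(sz**2 - sx**2)))


def apply_blur(
    image: VolumeImage,
    sigma_um: tuple[float, float, float],
    mode: str = "nearest",
) -> VolumeImage:
    """Separable Gaussian convolution with σ given in physical units (z, y, x).

    The kernel is truncated at 4σ.  Replicate padding keeps flat regions flat
    at the stack faces, so the bath stays at the bath level and normalization
    regions are not contaminated by edge roll-off.
    """
    sigma_vox = tuple(s / v for s, v in zip(sigma_um, image.voxel_um))
    for s in sigma_vox:
        if 0 < s < 0.5:
            log.warning("blur sigma %.3f voxels is under-sampled (< 0.5 voxel)", s)
    if all(s == 0 for s in sigma_vox):
        return image.like(image.data.astype(np.float64, copy=True))
    out = ndimage.gaussian_filter(
        np.asarray(image.data, dtype=np.float64), sigma=sigma_vox, mode=mode, truncate=4.0
    )
    return image.like(out)


def _gaussian_1d(x, amp, center, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _fit_axis_fwhm(profile: np.ndarray, spacing: float) -> float:
    """FWHM (μm) of a 1D bead profile by least-squares Gaussian fit."""
    x = np.arange(profile.size) * spacing
    offset0 = float(profile.min())
    amp0 = float(profile.max() - offset0)
    center0 = float(x[np.argmax(profile)])
    # second-moment width as the starting σ
    w = np.clip(profile - offset0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - center0) ** 2) / max(w.sum(), 1e-12)))
    sigma0 = max(sigma0, spacing / 2)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_1d, x, profile, p0=(amp0, center0, sigma0, offset0), maxfev=5000
        )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    return sigma_to_fwhm(abs(float(popt[2])))


def measure_psf(
    bead_stack: VolumeImage,
    bead_diameter_um: float,
    min_snr: float = 3.0,
) -> PSFSpec:
    """Estimate the raw PSF from a stack of a single sub-resolution bead.

    Fits a 1D Gaussian to the intensity profile through the bead centroid
    along each axis, then removes the finite bead size by quadrature: a solid
    sphere of diameter d has the same second moment as a Gaussian with
    σ_bead = d / (2 sqrt(5)), so
    ``FWHM_psf = sqrt(FWHM_fit² − FWHM_bead²)``.

    Raises
    ------
    ValueError
        If no clear peak rises above background (SNR below ``min_snr``) or a
        fit fails, e.g. for a bead clipped by the stack boundary.
    """
    data = np.asarray(bead_stack.data, dtype=np.float64)
    background = float(np.median(data))
    noise = float(np.std(data[data <= np.percentile(data, 50)]))
    peak = float(data.max())
    if noise == 0:
        noise = 1e-12
    if (peak - background) / noise < min_snr and peak <= background:
        raise ValueError("no bead peak above background")

    center = np.unravel_index(np.argmax(data), data.shape)
    # refuse beads clipped by the boundary: the profile must cover ±2 voxels
    for axis, c in enumerate(center):
        if c < 2 or c > data.shape[axis] - 3:
            raise ValueError(
                f"bead peak at index {center} is too close to the stack boundary on axis {axis}"
            )

    fwhm_zyx = []
    for axis in range(3):
        sl = list(center)
        sl[axis] = slice(None)
        profile = data[tuple(sl)]
        fwhm_zyx.append(_fit_axis_fwhm(profile, bead_stack.voxel_um[axis]))

    # quadrature correction for finite bead size (equal-second-moment Gaussian)
    bead_fwhm = sigma_to_fwhm(bead_diameter_um / (2.0 * np.sqrt(5.0)))
    corrected = []
    for f in fwhm_zyx:
        if f <= bead_fwhm:
            raise ValueError(
                f"fitted FWHM {f:.3f} μm is not larger than the bead-size width "
                f"{bead_fwhm:.3f} μm; the bead is not sub-resolution enough to correct"
            )
        corrected.append(float(np.sqrt(f**2 - bead_fwhm**2)))
    fz, fy, fx = corrected
    return PSFSpec(fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, state="raw")


def psf_to_yaml_dict(psf: PSFSpec) -> dict:
    """External schema: FWHMs listed in (x, y, z) order."""
    return {"fwhm_um": [psf.fwhm_x, psf.fwhm_y, psf.fwhm_z], "state": psf.state}


def psf_from_yaml_dict(d: dict) -> PSFSpec:
    fx, fy, fz = d["fwhm_um"]
    return PSFSpec(fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, state=d.get("state", "raw"))
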