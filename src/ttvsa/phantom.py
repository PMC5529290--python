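"""Forward simulator of dual-dye confocal imaging of tubule networks.

The simulated scene is a cardiomyocyte-like cell bounded by a planar surface
(optionally corrugated with z-grooves), bathed in a volume dye (e.g. calcein)
that also fills the lumina of tubules invaginating into the cell, and with a
membrane dye (e.g. FM4-64) on the cell surface and on tubule walls.  Both
channels are convolved with an anisotropic Gaussian PSF and optionally
degraded with noise, producing the inputs the measurement pipeline expects —
with full ground truth retained for scoring.

Geometric conventions (shared package-wide): arrays are (z, y, x); voxel
centres at ``(index + 0.5) · voxel_size``; lengths in μm; intensities
dimensionless.  The volume channel is ``bath_amplitude`` times the indicator
of extracellular space (bath ∪ tubule lumina).  The membrane channel is an
area-density field: a thin shell rasterized by supersampling and then
renormalized so it integrates to (true membrane area × ``membrane_density``)
— the nominal shell thickness therefore never leaks into downstream
volume-to-surface-area ratios.

Tubules are open cylinders (flat ends, no cap membrane), so the analytic
truth values are exact: lumen volume π·a·b·L and wall area P(a, b)·L with
P the ellipse perimeter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from .image import VolumeImage
from .psf import PSFSpec, apply_blur

_AXES = {"z": 0, "y": 1, "x": 2}


def ellipse_perimeter(major_semi: float, minor_semi: float) -> float:
    """Perimeter of an ellipse via the complete elliptic integral E(m)."""
    if minor_semi > major_semi:
        major_semi, minor_semi = minor_semi, major_semi
    m = 1.0 - (minor_semi / major_semi) ** 2
    return 4.0 * major_semi * float(special.ellipe(m))


@dataclass
class Tubule:
    """A tubule: polyline centerline with an elliptical cross-section.

    ``points_um`` is an (N, 3) array of (z, y, x) positions in μm.
    ``diameter_um`` is the circular-equivalent diameter: for ellipticity
    E < 1 the cross-section keeps the same area as the circle, with
    minor/major axis ratio E.  ``major_axis`` optionally fixes the direction
    of the major axis in the plane normal to the tubule (z, y, x components);
    by default the major axis is chosen perpendicular to both the tubule and
    the z axis.
    """

    points_um: np.ndarray
    diameter_um: float
    ellipticity: float = 1.0
    major_axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=np.float64))
        if self.points_um.shape[0] < 2 or self.points_um.shape[1] != 3:
            raise ValueError("tubule centerline needs >= 2 points of (z, y, x)")
        if self.diameter_um <= 0:
            raise ValueError("tubule diameter must be positive")
        if not (0.0 < self.ellipticity <= 1.0):
            raise ValueError("ellipticity must lie in (0, 1]")

    @property
    def semi_axes_um(self) -> tuple[float, float]:
        """(major, minor) semi-axes preserving the circular cross-section area."""
        r = self.diameter_um / 2.0
        major = r / np.sqrt(self.ellipticity)
        return (float(major), float(r * np.sqrt(self.ellipticity)))

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())

    @property
    def lumen_volume_um3(self) -> float:
        a, b = self.semi_axes_um
        return float(np.pi * a * b * self.length_um)

    @property
    def membrane_area_um2(self) -> float:
        a, b = self.semi_axes_um
        return float(ellipse_perimeter(a, b) * self.length_um)


@dataclass
class CellGeometry:
    """Half-space cell bounded by a plane orthogonal to one axis.

    The cell occupies coordinates *greater* than ``surface_um`` along
    ``axis``; the bath fills the other side.  Optional z-groove corrugation
    makes the surface position oscillate sinusoidally along ``groove_axis``
    (the cell's long axis) with the given amplitude and period (sarcomere
    spacing, ~1.8 μm, by default).
    """

    axis: str = "x"
    surface_um: float = 1.5
    groove_amplitude_um: float = 0.0
    groove_period_um: float = 1.8
    long_axis: str = "y"

    def __post_init__(self) -> None:
        if self.axis not in _AXES or self.long_axis not in _AXES:
            raise ValueError("axes must be one of 'z', 'y', 'x'")
        if self.axis == self.long_axis:
            raise ValueError("surface normal and long axis must differ")
        if self.groove_amplitude_um < 0 or self.groove_period_um <= 0:
            raise ValueError("groove amplitude must be >= 0 and period > 0")

    def surface_position(self, u_um) -> np.ndarray:
        """Surface position along ``axis`` as a function of long-axis coordinate."""
        u = np.asarray(u_um, dtype=float)
        if self.groove_amplitude_um == 0:
            return np.full_like(u, self.surface_um)
        return self.surface_um + self.groove_amplitude_um * np.sin(
            2.0 * np.pi * u / self.groove_period_um
        )


@dataclass
class PhantomSpec:
    """Full description of a synthetic dual-dye scene."""

    shape: tuple[int, int, int] = (64, 256, 256)
    voxel_um: tuple[float, float, float] = (0.18, 0.06, 0.06)
    cell: CellGeometry = field(default_factory=CellGeometry)
    tubules: list[Tubule] = field(default_factory=list)
    bath_amplitude: float = 1.0
    membrane_density: float = 1.0
    noise: str = "none"  # "none" | "gaussian" | "poisson"
    noise_sd: float = 0.0  # additive Gaussian sd (intensity units)
    photons_per_unit: float = 500.0  # Poisson scaling: counts per intensity unit
    seed: int = 0
    supersample: int = 3  # sub-voxels per *smallest* voxel edge

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if self.bath_amplitude <= 0 or self.membrane_density <= 0:
            raise ValueError("dye amplitudes must be positive")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError("noise must be 'none', 'gaussian' or 'poisson'")
        if self.supersample < 1:
            raise ValueError("supersample factor must be >= 1")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_um))

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_um[0] * self.voxel_um[1] * self.voxel_um[2]

    def supersample_per_axis(self) -> tuple[int, int, int]:
        """Sub-voxel counts chosen so fine spacing is ~isotropic.

        The smallest voxel edge is split ``supersample`` times; coarser axes
        (typically z) get proportionally more sub-voxels.
        """
        target = min(self.voxel_um) / self.supersample
        return tuple(max(1, int(round(v / target))) for v in self.voxel_um)


@dataclass
class PhantomTruth:
    """Ground truth retained from a rendered scene, for scoring recovery."""

    tubule_diameters_um: list[float]
    tubule_ellipticities: list[float]
    tubule_orientations_deg: list[float]  # angle from the transverse plane
    tubule_lengths_um: list[float]
    cell_volume_um3: float
    tt_membrane_area_um2: float
    tt_lumen_volume_um3: float
    long_axis: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# rasterization helpers


def _fine_grid_1d(n: int, voxel: float, ss: int) -> np.ndarray:
    """Centres of the fine sub-voxels along one axis, in μm."""
    return (np.arange(n * ss) + 0.5) * (voxel / ss)


def _segment_frames(tubule: Tubule):
    """Per segment: (origin, direction, length, major_axis_unit, minor_axis_unit)."""
    frames = []
    for p0, p1 in zip(tubule.points_um[:-1], tubule.points_um[1:]):
        d = p1 - p0
        length = float(np.linalg.norm(d))
        if length == 0:
            continue
        t = d / length
        if tubule.major_axis is not None:
            m = np.asarray(tubule.major_axis, dtype=np.float64)
            m = m - t * (m @ t)
            if np.linalg.norm(m) < 1e-9:
                raise ValueError("major_axis is parallel to the tubule direction")
        else:
            zhat = np.array([1.0, 0.0, 0.0])
            m = np.cross(t, zhat)
            if np.linalg.norm(m) < 1e-9:  # tubule along z: any transverse direction
                m = np.array([0.0, 1.0, 0.0])
        m = m / np.linalg.norm(m)
        n = np.cross(t, m)
        frames.append((p0, t, length, m, n))
    return frames


def _tubule_rho(points: np.ndarray, tubule: Tubule) -> np.ndarray:
    """Scaled elliptical radial coordinate (ρ < 1 inside the lumen).

    ``points`` is (M, 3) in μm.  For each segment ρ is evaluated only for
    points whose axial projection falls within the segment (flat, open
    ends); elsewhere it is +inf.  The minimum over segments is returned.
    """
    A, B = tubule.semi_axes_um
    rho = np.full(points.shape[0], np.inf)
    for p0, t, length, m, n in _segment_frames(tubule):
        rel = points - p0
        s = rel @ t
        in_span = (s >= 0.0) & (s <= length)
        w = rel - np.outer(s, t)
        r = np.sqrt((w @ m / A) ** 2 + (w @ n / B) ** 2)
        r[~in_span] = np.inf
        rho = np.minimum(rho, r)
    return rho


def _bbox_slices(spec: PhantomSpec, lo_um: np.ndarray, hi_um: np.ndarray) -> tuple[slice, ...]:
    sl = []
    for axis in range(3):
        v = spec.voxel_um[axis]
        i0 = max(int(np.floor(lo_um[axis] / v)) - 1, 0)
        i1 = min(int(np.ceil(hi_um[axis] / v)) + 2, spec.shape[axis])
        if i0 >= i1:
            raise ValueError("tubule lies outside the image grid")
        sl.append(slice(i0, i1))
    return tuple(sl)


def _coarsen(fine: np.ndarray, ss: tuple[int, int, int]) -> np.ndarray:
    """Average fine samples back to the coarse grid."""
    n0, n1, n2 = (fine.shape[i] // ss[i] for i in range(3))
    return fine.reshape(n0, ss[0], n1, ss[1], n2, ss[2]).mean(axis=(1, 3, 5))


def _rasterize_tubule(
    spec: PhantomSpec, tubule: Tubule, lumen: np.ndarray, membrane: np.ndarray
) -> None:
    """Add one tubule's lumen occupancy and membrane shell to the fields."""
    ss = spec.supersample_per_axis()
    A, B = tubule.semi_axes_um
    lo = tubule.points_um.min(axis=0) - A
    hi = tubule.points_um.max(axis=0) + A
    sl = _bbox_slices(spec, lo, hi)

    fine = [
        _fine_grid_1d(spec.shape[a], spec.voxel_um[a], ss[a])[
            sl[a].start * ss[a] : sl[a].stop * ss[a]
        ]
        for a in range(3)
    ]
    Z, Y, X = np.meshgrid(*fine, indexing="ij")
    fine_shape = Z.shape
    pts = np.column_stack([Z.ravel(), Y.ravel(), X.ravel()])
    rho = _tubule_rho(pts, tubule)

    # antialiased lumen indicator: linear ramp over one fine sub-voxel at the
    # wall, so the integrated volume converges at first order
    t_fine = min(spec.voxel_um) / spec.supersample
    wall_dist = (1.0 - rho) * (A + B) / 2.0  # ~geometric distance to the wall
    occ_fine = np.clip(0.5 + wall_dist / t_fine, 0.0, 1.0)
    occ = _coarsen(occ_fine.reshape(fine_shape), ss)
    lumen_view = lumen[sl]
    np.maximum(lumen_view, occ, out=lumen_view)

    # membrane shell: triangular weight around rho = 1, nominal radial
    # half-thickness one fine sub-voxel, then renormalized to the true area
    delta = 2.0 * t_fine / (A + B)
    shell_w = np.clip(1.0 - np.abs(rho - 1.0) / delta, 0.0, None)
    shell = _coarsen(shell_w.reshape(fine_shape), ss)
    total = shell.sum() * spec.voxel_volume_um3
    if total <= 0:
        raise ValueError(
            f"tubule membrane shell rasterized to nothing (D={tubule.diameter_um} μm); "
            "increase supersample"
        )
    membrane[sl] += shell * (tubule.membrane_area_um2 / total)


def _bath_fraction_column(pos_um: float, n: int, voxel: float) -> np.ndarray:
    """Per-voxel fraction lying below ``pos_um`` along an axis of n voxels."""
    lower_edges = np.arange(n) * voxel
    return np.clip((pos_um - lower_edges) / voxel, 0.0, 1.0)


def _plane_deposit_column(pos_um: float, n: int, voxel: float) -> np.ndarray:
    """Cloud-in-cell deposit of a unit-density plane at ``pos_um``.

    Linear weights between the two bracketing voxel centres keep the
    integrated area and the surface centroid exact.
    """
    col = np.zeros(n)
    fc = pos_um / voxel - 0.5
    i0 = int(np.floor(fc))
    w1 = fc - i0
    for i, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
        if 0 <= i < n:
            col[i] += w / voxel
    return col


def _rasterize_cell_surface(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(bath occupancy, surface-membrane density) for the half-space cell."""
    ax = _AXES[spec.cell.axis]
    lax = _AXES[spec.cell.long_axis]
    n = spec.shape[ax]
    v = spec.voxel_um[ax]
    bath = np.zeros(spec.shape, dtype=np.float64)
    memb = np.zeros(spec.shape, dtype=np.float64)

    def place(j_lax: int | None, col_b: np.ndarray, col_m: np.ndarray) -> None:
        """Broadcast 1D columns (along ``ax``) into the 3D fields."""
        idx: list = [slice(None)] * 3
        if j_lax is not None:
            idx[lax] = j_lax
            rem = sorted({0, 1, 2} - {lax})
            shape2 = [1, 1]
            shape2[rem.index(ax)] = n
            bath[tuple(idx)] += col_b.reshape(shape2)
            memb[tuple(idx)] += col_m.reshape(shape2)
        else:
            shape3 = [1, 1, 1]
            shape3[ax] = n
            bath[...] += col_b.reshape(shape3)
            memb[...] += col_m.reshape(shape3)

    if spec.cell.groove_amplitude_um == 0:
        pos = spec.cell.surface_um
        place(None, _bath_fraction_column(pos, n, v), _plane_deposit_column(pos, n, v))
        return bath, memb

    # corrugated surface: fine sampling along the long axis; the membrane
    # area element carries the slope factor sqrt(1 + (dp/du)^2)
    ssu = spec.supersample_per_axis()[lax] * 2
    nu = spec.shape[lax]
    vu = spec.voxel_um[lax]
    u_fine = _fine_grid_1d(nu, vu, ssu)
    pos = spec.cell.surface_position(u_fine)
    dpdu = np.gradient(pos, u_fine)
    slope = np.sqrt(1.0 + dpdu**2)
    for j in range(nu):
        col_b = np.zeros(n)
        col_m = np.zeros(n)
        for k in range(j * ssu, (j + 1) * ssu):
            col_b += _bath_fraction_column(float(pos[k]), n, v) / ssu
            col_m += _plane_deposit_column(float(pos[k]), n, v) * (float(slope[k]) / ssu)
        place(j, col_b, col_m)
    return bath, memb


def _check_tubules_inside(spec: PhantomSpec) -> None:
    extent = np.array(spec.extent_um)
    ax = _AXES[spec.cell.axis]
    lax = _AXES[spec.cell.long_axis]
    for t in spec.tubules:
        r = t.semi_axes_um[0]
        if np.any(t.points_um - r < 0) or np.any(t.points_um + r > extent):
            raise ValueError(
                f"tubule (D={t.diameter_um} μm) extends outside the image grid {extent}"
            )
        surf = spec.cell.surface_position(t.points_um[:, lax])
        if np.any(t.points_um[:, ax] < surf):
            raise ValueError("tubule centerline leaves the cell region (crosses into the bath)")


def _apply_noise(data: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise == "none":
        return data
    if spec.noise == "gaussian":
        return data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    counts = rng.poisson(np.clip(data, 0, None) * spec.photons_per_unit)
    return counts.astype(np.float64) / spec.photons_per_unit


def render_phantom(
    spec: PhantomSpec, psf: PSFSpec
) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Render the membrane and volume channels of a synthetic scene.

    Returns ``(membrane, volume, truth)``.  Both channels are convolved with
    the same anisotropic Gaussian PSF; noise (if any) is applied after the
    blur.  The PSF must be sampled by at least 2 voxels per FWHM on every
    axis.
    """
    for f, v, name in zip(psf.fwhm_zyx, spec.voxel_um, "zyx"):
        if f < 2 * v:
            raise ValueError(
                f"PSF FWHM {f} μm along {name} is under-sampled: needs >= 2 voxels ({2 * v} μm)"
            )
    _check_tubules_inside(spec)

    bath, surf_memb = _rasterize_cell_surface(spec)
    lumen = np.zeros(spec.shape, dtype=np.float64)
    tt_memb = np.zeros(spec.shape, dtype=np.float64)
    for t in spec.tubules:
        _rasterize_tubule(spec, t, lumen, tt_memb)

    extracellular = np.clip(bath + lumen, 0.0, 1.0)
    volume_raw = spec.bath_amplitude * extracellular
    membrane_raw = spec.membrane_density * (surf_memb + tt_memb)

    sigma = psf.sigma_um
    vol_img = apply_blur(VolumeImage(volume_raw, spec.voxel_um), sigma)
    mem_img = apply_blur(VolumeImage(membrane_raw, spec.voxel_um), sigma)

    rng = np.random.default_rng(spec.seed)
    vol_img = vol_img.like(_apply_noise(vol_img.data, spec, rng))
    mem_img = mem_img.like(_apply_noise(mem_img.data, spec, rng))

    lax = _AXES[spec.cell.long_axis]
    axis_vec = np.zeros(3)
    axis_vec[lax] = 1.0
    orientations = []
    for t in spec.tubules:
        d = t.points_um[-1] - t.points_um[0]
        d = d / np.linalg.norm(d)
        orientations.append(float(np.degrees(np.arcsin(abs(float(d @ axis_vec))))))

    truth = PhantomTruth(
        tubule_diameters_um=[t.diameter_um for t in spec.tubules],
        tubule_ellipticities=[t.ellipticity for t in spec.tubules],
        tubule_orientations_deg=orientations,
        tubule_lengths_um=[t.length_um for t in spec.tubules],
        cell_volume_um3=float((1.0 - bath).sum() * spec.voxel_volume_um3),
        tt_membrane_area_um2=float(sum(t.membrane_area_um2 for t in spec.tubules)),
        tt_lumen_volume_um3=float(sum(t.lumen_volume_um3 for t in spec.tubules)),
        long_axis=spec.cell.long_axis,
    )
    return mem_img, vol_img, truth


def render_bead_stack(
    psf: PSFSpec,
    bead_diameter_um: float,
    shape: tuple[int, int, int] = (48, 64, 64),
    voxel_um: tuple[float, float, float] = (0.18, 0.06, 0.06),
    supersample: int = 5,
) -> VolumeImage:
    """A single fluorescent bead (solid sphere) imaged by the PSF.

    The bead is centred mid-grid; it must fit well inside the stack together
    with the PSF skirt.
    """
    extent = np.array([n * v for n, v in zip(shape, voxel_um)])
    r = bead_diameter_um / 2.0
    margin = np.array(psf.fwhm_zyx) * 2 + r
    if np.any(extent / 2.0 <= margin):
        raise ValueError(f"bead + PSF (needs {margin} μm half-extent) too large for grid {extent}")
    # snap the centre to a voxel centre so axis profiles pass through the peak
    center = np.array(
        [(shape[a] // 2 + 0.5) * voxel_um[a] for a in range(3)]
    )

    occ = np.zeros(shape, dtype=np.float64)
    sl = []
    for a in range(3):
        i0 = int(np.floor((center[a] - r) / voxel_um[a])) - 1
        i1 = int(np.ceil((center[a] + r) / voxel_um[a])) + 1
        sl.append(slice(max(i0, 0), min(i1, shape[a])))
    fine = [
        _fine_grid_1d(shape[a], voxel_um[a], supersample)[
            sl[a].start * supersample : sl[a].stop * supersample
        ]
        for a in range(3)
    ]
    Z, Y, X = np.meshgrid(*fine, indexing="ij")
    inside = (
        ((Z - center[0]) ** 2 + (Y - center[1]) ** 2 + (X - center[2]) ** 2) < r**2
    ).astype(np.float64)
    occ[tuple(sl)] = _coarsen(inside, (supersample,) * 3)

    img = VolumeImage(occ, voxel_um)
    return apply_blur(img, psf.sigma_um)


def render_halfspace_calibration(
    psf: PSFSpec,
    shape: tuple[int, int, int] = (48, 64, 160),
    voxel_um: tuple[float, float, float] = (0.18, 0.06, 0.06),
    surface_um: float | None = None,
) -> tuple[VolumeImage, VolumeImage]:
    """Noise-free flat-interface scene used to verify the SS normalization.

    Returns ``(membrane, volume)``: the volume channel is a blurred
    half-space step (bath side = 1) and the membrane channel a blurred plane
    of unit surface density at the interface.  The plane is orthogonal to x
    at mid-grid, snapped to a voxel centre so the discrete peak sits on the
    plane.
    """
    if surface_um is None:
        surface_um = (shape[2] // 2 + 0.5) * voxel_um[2]
    spec = PhantomSpec(
        shape=shape,
        voxel_um=voxel_um,
        cell=CellGeometry(axis="x", surface_um=surface_um),
        tubules=[],
        noise="none",
    )
    membrane, volume, _ = render_phantom(spec, psf)
    return membrane, volume
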