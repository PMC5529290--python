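"""TT network organization: length density, orientation, derived fractions.

Length is measured on the skeleton graph with anisotropy-aware edge weights
(each 26-neighbor step contributes its physical Euclidean length), local
orientation from the structure tensor of skeleton coordinates in a spherical
physical window, and the membrane/volume fractions follow from cylinder
arithmetic: area density π·D̄·L and volume fraction (π·D̄²/4)·L.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class NetworkStats:
    """Summary of TT network geometry for one cell."""

    length_density_um_per_um3: float
    transverse_pct: float
    axial_pct: float
    oblique_pct: float
    mean_diameter_um: float | None = None
    area_density_um2_per_um3: float | None = None
    volume_fraction_pct: float | None = None
    membrane_in_tt_pct: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv_row(self, path) -> None:
        """One-row CSV mirroring the per-cell network summary table."""
        d = self.to_dict()
        from pathlib import Path

        header = ",".join(d)
        row = ",".join("" if v is None else f"{v:.6g}" for v in d.values())
        Path(path).write_text(header + "\n" + row + "\n")


def _skeleton_edges(
    skel: np.ndarray, voxel_um: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Unique 26-neighbor voxel pairs of the skeleton and their physical lengths."""
    coords = np.argwhere(np.asarray(skel, bool))
    if coords.size == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    index = {tuple(c): i for i, c in enumerate(coords)}
    scale = np.asarray(voxel_um)
    pairs = []
    lengths = []
    # enumerate each unique pair once (offset lexicographically positive)
    half = [o for o in _NEIGHBOR_OFFSETS if tuple(o) > (0, 0, 0)]
    for off in half:
        for i, c in enumerate(coords):
            j = index.get(tuple(c + off))
            if j is not None:
                pairs.append((i, j))
                lengths.append(np.linalg.norm(off * scale))
    return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(lengths)


def skeleton_length_um(skel: np.ndarray, voxel_um: tuple[float, float, float]) -> float:
    """Total physical length of a skeleton (sum of inter-voxel step lengths)."""
    _, lengths = _skeleton_edges(skel, voxel_um)
    return float(lengths.sum())


def skeleton_length_density(
    skel: np.ndarray,
    cell: np.ndarray,
    voxel_um: tuple[float, float, float],
) -> float:
    """Skeleton length per cell volume, μm/μm³."""
    cell = np.asarray(cell, bool)
    if not cell.any():
        raise ValueError("cell mask is empty")
    vv = voxel_um[0] * voxel_um[1] * voxel_um[2]
    return skeleton_length_um(skel, voxel_um) / (float(cell.sum()) * vv)


def principal_axis(mask: np.ndarray, voxel_um: tuple[float, float, float]) -> np.ndarray:
    """Principal axis (unit vector, z-y-x components) of a binary mask.

    The cell's long axis, from the largest-eigenvalue eigenvector of the
    coordinate covariance in physical units.
    """
    coords = np.argwhere(np.asarray(mask, bool)) * np.asarray(voxel_um)
    if coords.shape[0] < 3:
        raise ValueError("mask too small to define an axis")
    cov = np.cov(coords.T)
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def local_orientation(
    skel: np.ndarray,
    voxel_um: tuple[float, float, float],
    long_axis: np.ndarray,
    window_um: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-skeleton-voxel tubule angle from the transverse plane, degrees.

    For each skeleton voxel, the dominant direction is the principal
    eigenvector of the second-moment (structure) tensor of the skeleton
    coordinates within a spherical window of physical radius ``window_um`` (default 0.75 μm, comfortably above the symmetrized PSF FWHM so blur-scale skeleton wiggles average out).
    The angle is measured against the cell's long axis and mapped so that
    0° means the tubule runs in the transverse plane and 90° along the cell
    axis.  Voxels with fewer than 3 neighbors in the window are returned as
    unclassified (NaN).

    Returns ``(coords, angles_deg, classified)``.
    """
    coords = np.argwhere(np.asarray(skel, bool))
    if coords.shape[0] == 0:
        raise ValueError("skeleton is empty")
    axis = np.asarray(long_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    pts = coords * np.asarray(voxel_um)
    tree = cKDTree(pts)
    angles = np.full(coords.shape[0], np.nan)
    neighborhoods = tree.query_ball_point(pts, window_um)
    for i, nb in enumerate(neighborhoods):
        if len(nb) < 3:
            continue
        local = pts[nb] - pts[nb].mean(axis=0)
        tensor = local.T @ local
        w, v = np.linalg.eigh(tensor)
        direction = v[:, np.argmax(w)]
        angles[i] = np.degrees(np.arcsin(np.clip(abs(float(direction @ axis)), 0.0, 1.0)))
    return coords, angles, ~np.isnan(angles)


def classify_orientation(
    angles_deg: np.ndarray,
    weights: np.ndarray | None = None,
    cone_deg: float = 15.0,
) -> dict:
    """Transverse/axial/oblique fractions of classified skeleton length.

    Class intervals are closed at the cone edge: transverse is
    [0°, cone], axial [90° − cone, 90°], oblique the open remainder.
    ``weights`` (e.g. per-voxel step lengths) default to uniform.
    """
    a = np.asarray(angles_deg, dtype=np.float64)
    ok = ~np.isnan(a)
    a = a[ok]
    if a.size == 0:
        return {"transverse_pct": np.nan, "axial_pct": np.nan, "oblique_pct": np.nan}
    if np.any((a < 0) | (a > 90)):
        raise ValueError("angles must lie in [0°, 90°]")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=np.float64)[ok]
    total = w.sum()
    trans = w[a <= cone_deg].sum() / total * 100.0
    axial = w[a >= 90.0 - cone_deg].sum() / total * 100.0
    return {
        "transverse_pct": float(trans),
        "axial_pct": float(axial),
        "oblique_pct": float(100.0 - trans - axial),
    }


def voxel_step_weights(skel: np.ndarray, voxel_um: tuple[float, float, float]) -> np.ndarray:
    """Per-skeleton-voxel length weight: half the incident edge lengths.

    Summing the weights recovers the total skeleton length, making
    orientation fractions length-weighted rather than voxel-counted.
    """
    coords = np.argwhere(np.asarray(skel, bool))
    pairs, lengths = _skeleton_edges(skel, voxel_um)
    w = np.zeros(coords.shape[0])
    for (i, j), L in zip(pairs, lengths):
        w[i] += L / 2.0
        w[j] += L / 2.0
    return w


def derived_geometry(
    mean_diameter_um: float,
    length_density_um_per_um3: float,
    total_membrane_density_um2_per_um3: float | None = None,
) -> dict:
    """Cylinder arithmetic from mean diameter D̄ and length density L.

    area density = π·D̄·L (μm²/μm³); volume fraction = (π·D̄²/4)·L as % of
    cell volume; and, when the cell's total membrane density is known, the
    percentage of total cell membrane residing in TTs.
    """
    if mean_diameter_um <= 0 or length_density_um_per_um3 <= 0:
        raise ValueError("diameter and length density must be positive")
    area = np.pi * mean_diameter_um * length_density_um_per_um3
    volume_frac = np.pi * mean_diameter_um**2 / 4.0 * length_density_um_per_um3 * 100.0
    out = {
        "area_density_um2_per_um3": float(area),
        "volume_fraction_pct": float(volume_frac),
    }
    if total_membrane_density_um2_per_um3 is not None:
        if total_membrane_density_um2_per_um3 <= 0:
            raise ValueError("total membrane density must be positive")
        out["membrane_in_tt_pct"] = float(area / total_membrane_density_um2_per_um3 * 100.0)
    return out


def network_stats(
    tt_skel: np.ndarray,
    cell: np.ndarray,
    voxel_um: tuple[float, float, float],
    mean_diameter_um: float | None = None,
    long_axis: np.ndarray | None = None,
    total_membrane_density_um2_per_um3: float | None = None,
    window_um: float = 0.75,
    cone_deg: float = 15.0,
) -> NetworkStats:
    """Full network summary for one cell."""
    dens = skeleton_length_density(tt_skel, cell, voxel_um)
    if long_axis is None:
        long_axis = principal_axis(cell, voxel_um)
    _, angles, _ = local_orientation(tt_skel, voxel_um, long_axis, window_um=window_um)
    weights = voxel_step_weights(tt_skel, voxel_um)
    fr = classify_orientation(angles, weights=weights, cone_deg=cone_deg)
    stats = NetworkStats(
        length_density_um_per_um3=dens,
        transverse_pct=fr["transverse_pct"],
        axial_pct=fr["axial_pct"],
        oblique_pct=fr["oblique_pct"],
        mean_diameter_um=mean_diameter_um,
    )
    if mean_diameter_um is not None:
        derived = derived_geometry(mean_diameter_um, dens, total_membrane_density_um2_per_um3)
        stats.area_density_um2_per_um3 = derived["area_density_um2_per_um3"]
        stats.volume_fraction_pct = derived["volume_fraction_pct"]
        stats.membrane_in_tt_pct = derived.get("membrane_in_tt_pct")
    return stats
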