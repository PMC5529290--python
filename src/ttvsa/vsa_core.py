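"""The volume-to-surface-area map and its conversion to tubule diameter.

For a tubule much narrower than the PSF, the normalized luminal (volume-dye)
signal at the centerline is proportional to the cross-sectional area and the
normalized membrane signal to the perimeter, so their ratio — the V:SA — is
linear in diameter:

    V:SA = (D / (2·FWHM)) · sqrt(ln 2 / π)

with FWHM the full width at half maximum of the symmetrized (spherical)
PSF.  The same Gaussian optics give a closed form valid at any D for a
circular cylinder,

    V:SA(D) = σ (e^x − 1) / (a sqrt(2π)),   a = D/2,  x = a²/(2σ²),

whose small-D limit is the linear law; ``model="cylinder"`` inverts it
numerically and is preferred when D approaches the FWHM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .preprocess import NormalizedPair
from .psf import fwhm_to_sigma

log = logging.getLogger(__name__)


def _slope_factor() -> float:
    """sqrt(ln 2 / π) — computed, not hard-coded."""
    return float(np.sqrt(np.log(2.0) / np.pi))


def vsa_to_diameter(vsa, fwhm_um: float, model: str = "linear"):
    """Convert V:SA (dimensionless) to tubule diameter in μm.

    ``model="linear"`` applies the small-diameter law
    D = 2·FWHM·V:SA / sqrt(ln2/π).  ``model="cylinder"`` inverts the full
    blurred-cylinder expression, which matters once D is no longer small
    against the FWHM.  Scalar or array input.
    """
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    vsa_arr = np.asarray(vsa, dtype=np.float64)
    if np.any(vsa_arr < 0):
        raise ValueError("V:SA must be non-negative")
    if model == "linear":
        out = 2.0 * fwhm_um * vsa_arr / _slope_factor()
    elif model == "cylinder":
        out = np.vectorize(lambda v: _invert_cylinder(v, fwhm_um))(vsa_arr)
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(out) if np.isscalar(vsa) or np.ndim(vsa) == 0 else out


def cylinder_vsa(diameter_um: float, fwhm_um: float) -> float:
    """Forward blurred-cylinder model: centerline V:SA of a circular tubule."""
    if diameter_um == 0:
        return 0.0
    sigma = fwhm_to_sigma(fwhm_um)
    a = diameter_um / 2.0
    x = a * a / (2.0 * sigma * sigma)
    return float(sigma * np.expm1(x) / (a * np.sqrt(2.0 * np.pi)))


def _invert_cylinder(vsa: float, fwhm_um: float) -> float:
    if vsa == 0:
        return 0.0
    # bracket: the cylinder V:SA always exceeds the linear law, so the
    # linear inverse is an upper bound for D; expand downward from there
    hi = 2.0 * fwhm_um * vsa / _slope_factor()
    return float(optimize.brentq(
        lambda d: cylinder_vsa(d, fwhm_um) - vsa, 1e-9, hi * 1.0000001, xtol=1e-12
    ))


def model_slope(fwhm_um: float) -> float:
    """d(V:SA)/dD of the linear cylindrical model, per μm."""
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    return _slope_factor() / (2.0 * fwhm_um)


def calibrate_fwhm(vsa: float, diameter_um: float) -> float:
    """The FWHM implied by a known (V:SA, diameter) pair under the linear model."""
    if vsa <= 0 or diameter_um <= 0:
        raise ValueError("V:SA and diameter must be positive")
    return diameter_um * _slope_factor() / (2.0 * vsa)


def ellipse_equivalent_axes(
    vsa: float, fwhm_um: float, ellipticity: float
) -> tuple[float, float]:
    """Axes (major, minor, μm) of the elliptical cross-section matching a V:SA.

    The V:SA fixes the area-to-perimeter ratio of the cross-section: a
    circle of diameter D has A/P = D/4.  An ellipse with semi-axes (p, Ep)
    has A = πEp² and perimeter P = 4p·Ell(m) with Ell the complete elliptic
    integral of the second kind and m = 1 − E², so A/P = πEp/(4·Ell(m));
    matching D/4 gives the closed form p = D·Ell(m)/(πE).  Returns full
    axis lengths (2p, 2Ep).
    """
    if not (0.0 < ellipticity <= 1.0):
        raise ValueError("ellipticity must lie in (0, 1]")
    d_circ = vsa_to_diameter(vsa, fwhm_um)
    if ellipticity == 1.0:
        return (d_circ, d_circ)
    m = 1.0 - ellipticity**2
    e2 = float(special.ellipe(m))
    p = d_circ * e2 / (np.pi * ellipticity)
    q = ellipticity * p
    return (2.0 * p, 2.0 * q)


@dataclass
class VSAMap:
    """Per-TT-skeleton-voxel V:SA values with derived diameters.

    ``coords`` is an (n, 3) integer array of (z, y, x) voxel indices;
    ``vsa`` and ``diameter_um`` are aligned 1D arrays.  ``dropped`` counts
    skeleton voxels excluded by the membrane-signal floor.
    """

    coords: np.ndarray
    vsa: np.ndarray
    diameter_um: np.ndarray
    fwhm_um: float
    dropped: int = 0
    model: str = "linear"

    @property
    def n(self) -> int:
        return int(self.vsa.size)

    def summary(self) -> dict:
        if self.n == 0:
            raise ValueError("empty V:SA map")
        sd = float(np.std(self.vsa, ddof=1)) if self.n > 1 else 0.0
        sd_d = float(np.std(self.diameter_um, ddof=1)) if self.n > 1 else 0.0
        return {
            "n_voxels": self.n,
            "n_dropped": self.dropped,
            "vsa_mean": float(np.mean(self.vsa)),
            "vsa_sd": sd,
            "vsa_sem": sd / np.sqrt(self.n),
            "diameter_mean_um": float(np.mean(self.diameter_um)),
            "diameter_sd_um": sd_d,
            "diameter_sem_um": sd_d / np.sqrt(self.n),
            "fwhm_um": self.fwhm_um,
            "model": self.model,
        }

    def histogram(self, bin_width: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin edges) of the V:SA distribution at fixed bin width."""
        if self.n == 0:
            raise ValueError("empty V:SA map")
        lo = np.floor(self.vsa.min() / bin_width) * bin_width
        hi = np.ceil(self.vsa.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(self.vsa, bins=edges)
        return counts, edges


def vsa_map_to_csv(vsa_map: VSAMap, path) -> None:
    """Write the per-voxel map as CSV: z, y, x, vsa, diameter_um."""
    rows = np.column_stack([
        vsa_map.coords, vsa_map.vsa[:, None], vsa_map.diameter_um[:, None]
    ])
    np.savetxt(
        path, rows, fmt=["%d", "%d", "%d", "%.6g", "%.6g"],
        delimiter=",", header="z,y,x,vsa,diameter_um", comments="",
    )


def compute_vsa(
    pair: NormalizedPair,
    tt_skel: np.ndarray,
    membrane_floor: float = 0.1,
    model: str = "linear",
) -> VSAMap:
    """Evaluate V:SA at the TT-skeleton voxels of a normalized pair.

    Voxels whose normalized membrane signal falls below ``membrane_floor``
    (a fraction of the SS reference, which is 1 after normalization) are
    dropped rather than allowed to blow up the ratio; the count is kept.
    Negative normalized values are clipped to zero at this final stage.
    """
    tt_skel = np.asarray(tt_skel, bool)
    if not tt_skel.any():
        raise ValueError("TT skeleton is empty")
    coords = np.argwhere(tt_skel)
    vol = np.clip(pair.volume.data[tt_skel], 0.0, None)
    mem = pair.membrane.data[tt_skel]
    ok = mem >= membrane_floor
    dropped = int((~ok).sum())
    if dropped:
        log.info("compute_vsa: dropped %d/%d voxels below membrane floor %.3g",
                 dropped, ok.size, membrane_floor)
    vsa = vol[ok] / mem[ok]
    fwhm = pair.psf.fwhm_z
    diam = vsa_to_diameter(vsa, fwhm, model=model)
    return VSAMap(
        coords=coords[ok],
        vsa=vsa,
        diameter_um=np.asarray(diam, dtype=np.float64),
        fwhm_um=fwhm,
        dropped=dropped,
        model=model,
    )


def summarize_cell(vsa_map: VSAMap, bin_width: float = 0.01) -> dict:
    """Cell-level summary: moments plus a fixed-bin-width histogram.

    The histogram carries both axes of interest: V:SA bin edges and their
    converted diameters (the dual scale of the method's distribution plot).
    """
    out = vsa_map.summary()
    counts, edges = vsa_map.histogram(bin_width)
    out["histogram"] = {
        "bin_width": bin_width,
        "counts": counts.tolist(),
        "vsa_edges": edges.tolist(),
        "diameter_edges_um": [
            float(vsa_to_diameter(e, vsa_map.fwhm_um)) for e in edges
        ],
    }
    return out


def channel_correlation(pair: NormalizedPair, tt_skel: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of the two channels over the TT skeleton.

    Ties are mid-ranked (the standard convention).  Returns (rho, p).
    """
    tt_skel = np.asarray(tt_skel, bool)
    n = int(tt_skel.sum())
    if n < 10:
        raise ValueError(f"need >= 10 TT voxels for a correlation, got {n}")
    v = pair.volume.data[tt_skel]
    m = pair.membrane.data[tt_skel]
    if np.all(v == v.flat[0]) or np.all(m == m.flat[0]):
        raise ValueError("constant channel: correlation undefined")
    rho, p = stats.spearmanr(v, m)
    return float(rho), float(p)
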