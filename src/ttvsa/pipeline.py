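"""End-to-end orchestration: channels in, per-cell report out.

The stages mirror the measurement's flow diagram: (optionally) render a
phantom or load two co-registered stacks → obtain the PSF → build masks and
skeletons → background-subtract, symmetrize, normalize → V:SA map and
diameters → network geometry → cable properties.  Every stage failure is
re-raised with the stage name so a user can tell where a run died.

Group comparison (Mann-Whitney on per-cell means, variance-ratio F test)
lives here too, as it operates on collections of cell reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as sstats

from . import __version__
from .cable import CableParams, cable_report
from .image import VolumeImage, read_stack
from .network_geometry import network_stats
from .phantom import PhantomSpec, CellGeometry, Tubule, render_phantom
from .preprocess import normalize_pair
from .psf import PSFSpec, measure_psf, psf_from_yaml_dict
from .segmentation import build_masks
from .vsa_core import channel_correlation, compute_vsa, summarize_cell

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML.

    Either ``membrane_path``/``volume_path`` point at real stacks, or
    ``phantom`` holds a scene description rendered on the fly.  The PSF
    comes from explicit FWHMs (``psf_fwhm_um``, x-y-z order) or from a bead
    stack.
    """

    membrane_path: str | None = None
    volume_path: str | None = None
    voxel_um: tuple[float, float, float] = (0.18, 0.06, 0.06)  # (z, y, x)
    phantom: dict | None = None
    psf_fwhm_um: tuple[float, float, float] | None = None  # (x, y, z)
    bead_path: str | None = None
    bead_diameter_um: float = 0.17
    # module parameters (documented defaults)
    closing_um: float = 0.3
    min_spur_vox: int = 2
    max_normal_tilt_deg: float = 60.0
    max_curvature_per_um: float = 1.5
    median_radius_vox: int = 2
    membrane_floor: float = 0.1
    diameter_model: str = "cylinder"
    histogram_bin_width: float = 0.01
    orientation_window_um: float = 0.75
    orientation_cone_deg: float = 15.0
    long_axis: str | None = None  # "z"|"y"|"x"; default: phantom truth or mask PCA
    total_membrane_density_um2_per_um3: float | None = None
    cable: dict = field(default_factory=dict)
    symmetrize: bool = True
    subtract_background: bool = True
    out_dir: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("voxel_um", "psf_fwhm_um"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CellReport:
    """Per-cell results plus provenance; fully recomputable from the config."""

    vsa_summary: dict
    network: dict
    cable: dict
    correlation: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause} ({hint})")
        self.stage = stage


def _phantom_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "cell" in d and isinstance(d["cell"], dict):
        d["cell"] = CellGeometry(**d["cell"])
    if "tubules" in d:
        d["tubules"] = [t if isinstance(t, Tubule) else Tubule(**t) for t in d["tubules"]]
    for key in ("shape", "voxel_um"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def _resolve_inputs(config: RunConfig, psf: PSFSpec):
    if config.phantom is not None:
        spec = _phantom_from_dict(config.phantom) if isinstance(config.phantom, dict) else config.phantom
        membrane, volume, truth = render_phantom(spec, psf)
        return membrane, volume, truth
    if not (config.membrane_path and config.volume_path):
        raise ValueError("need either a phantom spec or both channel paths")
    membrane = read_stack(config.membrane_path, voxel_um=config.voxel_um)
    volume = read_stack(config.volume_path, voxel_um=config.voxel_um)
    if membrane.shape != volume.shape:
        raise ValueError(
            f"channel shapes differ: membrane {membrane.shape} vs volume {volume.shape}"
        )
    return membrane, volume, None


def _resolve_psf(config: RunConfig) -> PSFSpec:
    if config.psf_fwhm_um is not None:
        fx, fy, fz = config.psf_fwhm_um
        return PSFSpec(fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, state="raw")
    if config.bead_path:
        bead = read_stack(config.bead_path, voxel_um=config.voxel_um)
        return measure_psf(bead, config.bead_diameter_um)
    raise ValueError("config must provide psf_fwhm_um or a bead stack")


def run_pipeline(config: RunConfig) -> CellReport:
    """Execute the full measurement on one cell (real stacks or phantom)."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))

    def stage(name: str, hint: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate and re-raise
            raise StageError(name, hint, exc) from exc

    psf = stage("psf", "check psf_fwhm_um or the bead stack", _resolve_psf, config)
    membrane, volume, truth = stage(
        "inputs", "check channel paths/shapes or the phantom spec", _resolve_inputs, config, psf
    )
    masks = stage(
        "segmentation",
        "check channel contrast and mask parameters",
        build_masks,
        membrane,
        volume,
        psf,
        closing_um=config.closing_um,
        min_spur_vox=config.min_spur_vox,
        max_normal_tilt_deg=config.max_normal_tilt_deg,
        max_curvature_per_um=config.max_curvature_per_um,
    )
    pair = stage(
        "preprocess",
        "check bath/SS coverage",
        normalize_pair,
        volume,
        membrane,
        masks,
        psf,
        symmetrize=config.symmetrize,
        subtract=config.subtract_background,
        median_radius_vox=config.median_radius_vox,
    )
    vsa_map = stage(
        "vsa",
        "TT skeleton may be empty; check segmentation output",
        compute_vsa,
        pair,
        masks.tt_skeleton,
        membrane_floor=config.membrane_floor,
        model=config.diameter_model,
    )
    summary = summarize_cell(vsa_map, bin_width=config.histogram_bin_width)

    try:
        rho, pval = channel_correlation(pair, masks.tt_skeleton)
        correlation = {"spearman_rho": rho, "p_value": pval}
    except ValueError as exc:
        correlation = {"spearman_rho": None, "p_value": None, "note": str(exc)}

    axis_name = config.long_axis or (truth.long_axis if truth is not None else None)
    long_axis_vec = None
    if axis_name is not None:
        long_axis_vec = np.zeros(3)
        long_axis_vec["zyx".index(axis_name)] = 1.0
    net = stage(
        "network_geometry",
        "needs a non-empty TT skeleton and cell mask",
        network_stats,
        masks.tt_skeleton,
        masks.cell,
        membrane.voxel_um,
        long_axis=long_axis_vec,
        mean_diameter_um=summary["diameter_mean_um"],
        total_membrane_density_um2_per_um3=config.total_membrane_density_um2_per_um3,
        window_um=config.orientation_window_um,
        cone_deg=config.orientation_cone_deg,
    )
    cable_params = CableParams(**config.cable) if config.cable else CableParams()
    cab = cable_report(summary["diameter_mean_um"], cable_params)

    provenance = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "normalization": pair.provenance,
        "dropped_voxels": vsa_map.dropped,
        "truth": truth.__dict__ if truth is not None else None,
    }
    report = CellReport(
        vsa_summary=summary,
        network=net.to_dict(),
        cable=cab,
        correlation=correlation,
        provenance=provenance,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        config.to_yaml(out / "config.yaml")
    return report


def compare_groups(
    means_a: np.ndarray, means_b: np.ndarray, min_n: int = 3
) -> dict:
    """Two-group comparison of per-cell mean V:SA values.

    Mann-Whitney U (two-sided; exact for n ≤ 8 without ties, otherwise the
    normal approximation with tie correction), a variance-ratio F test, and
    group means ± SEM.
    """
    a = np.asarray(means_a, dtype=np.float64)
    b = np.asarray(means_b, dtype=np.float64)
    if a.size < min_n or b.size < min_n:
        raise ValueError(f"need >= {min_n} cells per group, got {a.size} and {b.size}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    mw = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)

    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if min(va, vb) == 0:
        f_stat, f_p = np.inf if max(va, vb) > 0 else 1.0, np.nan
    else:
        f_stat = max(va, vb) / min(va, vb)
        dfn = (a.size if va >= vb else b.size) - 1
        dfd = (b.size if va >= vb else a.size) - 1
        f_p = 2.0 * min(
            sstats.f.sf(f_stat, dfn, dfd), 1.0 - sstats.f.sf(f_stat, dfn, dfd)
        )
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0,
        "sem_b": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else 0.0,
        "mannwhitney_u": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "mannwhitney_method": method,
        "f_statistic": float(f_stat),
        "f_p": float(f_p) if np.isfinite(f_stat) else np.nan,
    }
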