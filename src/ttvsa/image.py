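"""3D intensity volumes with physical voxel sizes.

Arrays are indexed ``(z, y, x)``; voxel sizes are in micrometres per axis in
the same order.  The centre of voxel ``(k, j, i)`` sits at physical position
``((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx)``.  Intensities are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with physical voxel sizes.

    Parameters
    ----------
    data :
        Array of shape ``(nz, ny, nx)``.
    voxel_um :
        Voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.voxel_um = tuple(float(v) for v in self.voxel_um)
        if len(self.voxel_um) != 3 or any(v <= 0 for v in self.voxel_um):
            raise ValueError(f"voxel sizes must be 3 positive lengths, got {self.voxel_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_um
        return dz * dy * dx

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (μm) of voxel centres along one axis."""
        return (np.arange(self.shape[axis]) + 0.5) * self.voxel_um[axis]

    def like(self, data: np.ndarray) -> "VolumeImage":
        """A new image on the same grid."""
        return VolumeImage(data, self.voxel_um)

    def integral_um3(self) -> float:
        """Intensity integrated over the volume, in intensity·μm³."""
        return float(self.data.sum(dtype=np.float64) * self.voxel_volume_um3)


def write_stack(path: str | Path, image: VolumeImage) -> None:
    """Write a volume as a multi-page TIFF with resolution tags and a YAML sidecar.

    The TIFF resolution tags carry the lateral pixel sizes; the z spacing and
    full voxel geometry go to ``<path>.yaml`` because TIFF has no standard
    z-resolution tag.
    """
    path = Path(path)
    dz, dy, dx = image.voxel_um
    tifffile.imwrite(
        path,
        np.asarray(image.data, dtype=np.float32),
        resolution=(1.0 / dx, 1.0 / dy),
        resolutionunit="MICROMETER",
        photometric="minisblack",
        metadata={"spacing_um": dz, "axes": "ZYX"},
    )
    sidecar = {"voxel_um_zyx": list(image.voxel_um), "shape_zyx": list(image.shape)}
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_stack(path: str | Path, voxel_um: tuple[float, float, float] | None = None) -> VolumeImage:
    """Read a multi-page TIFF; voxel sizes from the sidecar unless given."""
    path = Path(path)
    data = tifffile.imread(path)
    if voxel_um is None:
        sidecar = Path(str(path) + ".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"no voxel sizes given and no sidecar {sidecar.name}; pass voxel_um explicitly"
            )
        voxel_um = tuple(yaml.safe_load(sidecar.read_text())["voxel_um_zyx"])
    return VolumeImage(np.asarray(data, dtype=np.float64), voxel_um)
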