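"""Core in-memory containers: multichannel 3D stacks and per-site metadata.

Conventions
-----------
* Voxel grids are numpy arrays indexed ``[z, y, x]``.
* Physical coordinates are voxel-center positions in micrometres; a centroid
  is reported as ``(x, y, z)`` in µm.
* Acquisition starts at the plane furthest from the coverglass and steps up
  until the tissue surface is reached, so by default the *last* z plane
  (``surface="zmax"``) is the tissue surface.  Depth-from-surface is computed
  from that end; code that needs depth refuses to guess when the orientation
  is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidMetadataError, StackFormatError

#: Channel roles used throughout the pipeline.  vGlut1 marks excitatory
#: boutons, vGAT inhibitory boutons, CB1R is the measured receptor channel and
#: lipofuscin is the autofluorescence channel used for exclusion.
CHANNEL_ROLES = ("vglut1", "vgat", "cb1r", "lipofuscin")

#: Original thickness (µm) at which sections were cut; the denominator of the
#: shrinkage correction.
ORIGINAL_THICKNESS_UM = 40.0

#: Default physical calibration: 512 px span 55 µm laterally, 0.25 µm z step.
DEFAULT_PIXEL_UM = 55.0 / 512.0
DEFAULT_ZSTEP_UM = 0.25


@dataclass
class ImageStack:
    """A four-channel 3D voxel grid with physical calibration.

    Parameters
    ----------
    channels
        Mapping channel role -> 3D array ``(nz, ny, nx)``.  Integer ADU on
        acquisition; exposure normalization produces float grids.
    pixel_um, zstep_um
        Lateral pixel pitch and axial plane spacing in µm.
    exposure_ms
        Per-channel exposure times.
    bit_depth
        Camera bit depth; ADU values never exceed ``2**bit_depth - 1``.
    surface
        Which z end is the tissue surface: ``"zmax"``, ``"zmin"`` or ``None``
        (unknown; depth-dependent steps will refuse to run).
    """

    channels: dict[str, np.ndarray]
    pixel_um: float = DEFAULT_PIXEL_UM
    zstep_um: float = DEFAULT_ZSTEP_UM
    exposure_ms: dict[str, float] = field(default_factory=dict)
    bit_depth: int = 12
    surface: str | None = "zmax"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {role: grid.shape for role, grid in self.channels.items()}
        if not shapes:
            raise StackFormatError("stack has no channels")
        first = next(iter(shapes.values()))
        if len(first) != 3 or min(first) < 1:
            raise StackFormatError(f"channel grids must be 3D and non-empty, got {first}")
        for role, shape in shapes.items():
            if shape != first:
                raise StackFormatError(
                    f"channel {role!r} has shape {shape}, expected {first}"
                )
        if self.pixel_um <= 0 or self.zstep_um <= 0:
            raise StackFormatError("pixel_um and zstep_um must be positive")

    @property
    def nz(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def ny(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def nx(self) -> int:
        return next(iter(self.channels.values())).shape[2]

    @property
    def adu_ceiling(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel (µm³)."""
        return self.pixel_um**2 * self.zstep_um

    def depth_from_surface_um(self, z_index: np.ndarray | float) -> np.ndarray | float:
        """Measured-space distance (µm) of a z index from the tissue surface."""
        from .errors import OrientationError

        if self.surface == "zmax":
            return (self.nz - 1 - np.asarray(z_index, dtype=float)) * self.zstep_um
        if self.surface == "zmin":
            return np.asarray(z_index, dtype=float) * self.zstep_um
        raise OrientationError(
            "stack does not record which z end is the tissue surface; "
            "set ImageStack.surface to 'zmax' or 'zmin'"
        )

    def copy(self) -> "ImageStack":
        return replace(
            self,
            channels={k: v.copy() for k, v in self.channels.items()},
            exposure_ms=dict(self.exposure_ms),
            provenance=list(self.provenance),
        )


@dataclass(frozen=True)
class SiteMetadata:
    """Identity and acquisition metadata for one sampled site."""

    site_id: str
    subject_id: str
    species: str
    region: str
    layer: str
    measured_thickness_um: float
    original_thickness_um: float = ORIGINAL_THICKNESS_UM

    def __post_init__(self) -> None:
        if not np.isfinite(self.measured_thickness_um) or self.measured_thickness_um <= 0:
            raise InvalidMetadataError(
                f"measured thickness must be positive, got {self.measured_thickness_um}"
            )
        if self.measured_thickness_um > self.original_thickness_um + 1e-9:
            raise InvalidMetadataError(
                "measured thickness exceeds original sectioned thickness "
                f"({self.measured_thickness_um} > {self.original_thickness_um} µm)"
            )
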