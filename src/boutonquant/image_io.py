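"""Stack and metadata I/O plus acquisition-level normalizations.

Stacks are stored as multi-page grayscale 16-bit TIFF, either one file per
channel or a single 4-channel file (axes ZCYX).  Site metadata travels in a
CSV sidecar with one row per site.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidMetadataError, MissingChannelError, StackFormatError
from .stacks import CHANNEL_ROLES, ORIGINAL_THICKNESS_UM, ImageStack, SiteMetadata

#: Columns of the metadata CSV, in order.
METADATA_COLUMNS = [
    "site_id",
    "subject",
    "species",
    "region",
    "layer",
    "measured_thickness_um",
] + [f"exposure_ms_{role}" for role in CHANNEL_ROLES]


def write_stack(stack: ImageStack, path: str | os.PathLike, multichannel: bool = True,
                roles: Sequence[str] | None = None) -> list[str]:
    """Write a stack to TIFF.

    With ``multichannel=True`` one file with axes ZCYX is written and the
    single path is returned; otherwise one file per channel role is written
    next to ``path`` (suffix ``_<role>.tif``) and all paths are returned.
    """
    roles = list(roles or stack.channels.keys())
    arrays = [np.asarray(stack.channels[r]) for r in roles]
    if any(np.issubdtype(a.dtype, np.floating) for a in arrays):
        raise StackFormatError("only integer stacks are written to TIFF; "
                               "normalized float grids are in-memory objects")
    path = os.fspath(path)
    if multichannel:
        data = np.stack([a.astype(np.uint16) for a in arrays], axis=1)  # Z,C,Y,X
        tifffile.imwrite(path, data, photometric="minisblack",
                         metadata={"axes": "ZCYX", "roles": roles})
        return [path]
    base, _ = os.path.splitext(path)
    paths = []
    for role, arr in zip(roles, arrays):
        p = f"{base}_{role}.tif"
        tifffile.imwrite(p, arr.astype(np.uint16), metadata={"axes": "ZYX"})
        paths.append(p)
    return paths


def read_stack(
    paths: str | os.PathLike | Sequence[str | os.PathLike] | Mapping[str, str | os.PathLike],
    metadata_row: Mapping | None = None,
    *,
    required_roles: Sequence[str] = CHANNEL_ROLES,
    pixel_um: float | None = None,
    zstep_um: float | None = None,
    surface: str | None = "zmax",
) -> ImageStack:
    """Read a stack from one multichannel TIFF or several per-channel TIFFs.

    ``paths`` may be a single path (4-channel file), a mapping role->path, or
    a sequence of per-channel paths ordered as :data:`CHANNEL_ROLES`.
    ``metadata_row`` (e.g. a row of the metadata CSV) supplies exposures and
    calibration overrides.
    """
    channels: dict[str, np.ndarray] = {}
    if isinstance(paths, (str, os.PathLike)):
        with tifffile.TiffFile(os.fspath(paths)) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if data.ndim != 4:
            raise StackFormatError(
                f"expected a 4D multichannel stack (ZCYX), got shape {data.shape}"
            )
        roles = list(meta.get("roles", CHANNEL_ROLES[: data.shape[1]]))
        for c, role in enumerate(roles):
            channels[role] = data[:, c]
    else:
        if isinstance(paths, Mapping):
            items = list(paths.items())
        else:
            items = list(zip(CHANNEL_ROLES, paths))
        for role, p in items:
            arr = tifffile.imread(os.fspath(p))
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3:
                raise StackFormatError(f"channel file {p} is not a z stack")
            channels[role] = arr

    shapes = {r: a.shape for r, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise StackFormatError(f"channel shapes disagree: {shapes}")
    missing = [r for r in required_roles if r not in channels]
    if missing:
        raise MissingChannelError(
            f"stack is missing required channel role(s): {missing}; "
            "pass required_roles to relax (e.g. no-lipofuscin mode)"
        )

    row = dict(metadata_row) if metadata_row is not None else {}
    exposure = {
        role: float(row.get(f"exposure_ms_{role}", row.get("exposure_ms", 100.0)))
        for role in channels
    }
    return ImageStack(
        channels=channels,
        pixel_um=float(pixel_um if pixel_um is not None else row.get("pixel_um", 55.0 / 512.0)),
        zstep_um=float(zstep_um if zstep_um is not None else row.get("zstep_um", 0.25)),
        exposure_ms=exposure,
        surface=surface,
    )


def metadata_to_frame(metas: Sequence[SiteMetadata], exposures: Mapping[str, float]) -> pd.DataFrame:
    rows = []
    for m in metas:
        row = {
            "site_id": m.site_id,
            "subject": m.subject_id,
            "species": m.species,
            "region": m.region,
            "layer": m.layer,
            "measured_thickness_um": m.measured_thickness_um,
        }
        for role in CHANNEL_ROLES:
            row[f"exposure_ms_{role}"] = exposures.get(role, 100.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def metadata_from_row(row: Mapping) -> SiteMetadata:
    return SiteMetadata(
        site_id=str(row["site_id"]),
        subject_id=str(row["subject"]),
        species=str(row["species"]),
        region=str(row["region"]),
        layer=str(row["layer"]),
        measured_thickness_um=float(row["measured_thickness_um"]),
    )


def shrinkage_factor(meta: SiteMetadata) -> float:
    """Tissue shrinkage ratio: measured thickness over the original 40 µm.

    Depths measured in the shrunken tissue are divided by this factor to
    express them in original-section coordinates.
    """
    if meta.measured_thickness_um <= 0:
        raise InvalidMetadataError("nonpositive measured thickness")
    return meta.measured_thickness_um / ORIGINAL_THICKNESS_UM


def normalize_exposure(stack: ImageStack, reference_ms: Mapping[str, float] | float) -> ImageStack:
    """Rescale every channel to a common reference exposure.

    Each channel is multiplied by ``reference / exposure`` so that intensity
    is comparable across captures taken with different exposure times.  The
    returned stack holds float grids; applying the normalization twice is a
    no-op (guarded by a provenance flag).
    """
    if any(e <= 0 for e in stack.exposure_ms.values()):
        raise InvalidMetadataError(f"nonpositive exposure in {stack.exposure_ms}")
    out = stack.copy()
    if any(p.startswith("normalize_exposure") for p in stack.provenance):
        return out
    for role, grid in out.channels.items():
        ref = reference_ms[role] if isinstance(reference_ms, Mapping) else float(reference_ms)
        if ref <= 0:
            raise InvalidMetadataError(f"nonpositive reference exposure for {role}")
        scale = ref / out.exposure_ms.get(role, ref)
        out.channels[role] = np.asarray(grid, dtype=np.float64) * scale
        out.exposure_ms[role] = ref
    out.provenance.append(f"normalize_exposure(reference_ms={reference_ms!r})")
    return out
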