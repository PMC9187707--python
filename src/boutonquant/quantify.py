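"""Exclusion filters, per-bouton CB1R reads, and the per-site summary.

Four independent exclusion predicates protect the dependent measure:

* **depth** — only objects whose centroid lies 2–4 µm from the tissue
  surface (after shrinkage correction) are analysed; antibody penetrance is
  unreliable deeper in the section.
* **edge** — objects whose centroid falls in the outer 2% of the x or y
  dimension are dropped (spherical aberration near the field edge).
* **overlap** — objects overlapping both the vGlut1 and vGAT mask sets are
  ambiguous in cell type and dropped from both sides.
* **lipofuscin** — objects overlapping a lipofuscin mask carry
  autofluorescent contamination and are dropped.

An object contributes downstream only if every flag is False.  The surviving
boutons' mean CB1R intensities are averaged per (site, cell type), which is
the study's dependent measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidParameterError, MissingChannelError
from .image_io import shrinkage_factor
from .segment import Geometry, MaskSet, iterative_segment
from .stacks import ImageStack, SiteMetadata

log = logging.getLogger(__name__)

DEPTH_LO_UM = 2.0
DEPTH_HI_UM = 4.0
EDGE_FRACTION = 0.02

ROLE_TO_TYPE = {"vglut1": "excitatory", "vgat": "inhibitory"}


@dataclass
class BoutonMeasurement:
    """One segmented bouton with its CB1R read and exclusion flags."""

    object_id: int
    site_id: str
    bouton_type: str  # marker role: vglut1 | vgat
    mean_cb1r_adu: float
    volume_um3: float
    centroid_um: tuple[float, float, float]
    centroid_vox: tuple[float, float, float]
    corrected_depth_um: float = np.nan
    edge_excluded: bool = False
    depth_excluded: bool = False
    overlap_excluded: bool = False
    lipofuscin_excluded: bool = False

    @property
    def surviving(self) -> bool:
        return not (self.edge_excluded or self.depth_excluded
                    or self.overlap_excluded or self.lipofuscin_excluded)


FLAG_NAMES = ["edge_excluded", "depth_excluded", "overlap_excluded", "lipofuscin_excluded"]


def measure_boutons(maskset: MaskSet, cb1r_deconvolved_grid: np.ndarray,
                    site_id: str = "") -> list[BoutonMeasurement]:
    """Mean CB1R intensity underneath each masked object."""
    grid = np.asarray(cb1r_deconvolved_grid, dtype=np.float64)
    if grid.shape != maskset.label_grid.shape:
        raise GeometryError("CB1R grid does not match mask geometry")
    out = []
    for obj in maskset.objects:
        assert obj.n_voxels > 0
        vz, vy, vx = obj.voxels[:, 0], obj.voxels[:, 1], obj.voxels[:, 2]
        out.append(BoutonMeasurement(
            object_id=obj.object_id,
            site_id=site_id,
            bouton_type=maskset.channel_role,
            mean_cb1r_adu=float(grid[vz, vy, vx].mean()),
            volume_um3=obj.volume_um3,
            centroid_um=obj.centroid_um,
            centroid_vox=obj.centroid_vox,
        ))
    return out


def depth_filter(measurements: list[BoutonMeasurement], stack: ImageStack,
                 meta: SiteMetadata, lo: float = DEPTH_LO_UM,
                 hi: float = DEPTH_HI_UM) -> list[BoutonMeasurement]:
    """Flag boutons outside the analysable depth band.

    Depth is the centroid's distance from the tissue-surface end of the stack
    (measured space), divided by the shrinkage factor to express it in
    original-section coordinates.  Raises if the stack orientation is unknown.
    """
    factor = shrinkage_factor(meta)
    for m in measurements:
        z_vox = m.centroid_vox[2]
        measured = float(stack.depth_from_surface_um(z_vox))
        m.corrected_depth_um = measured / factor
        m.depth_excluded = not (lo <= m.corrected_depth_um <= hi)
    return measurements


def edge_filter(measurements: list[BoutonMeasurement], nx: int, ny: int,
                fraction: float = EDGE_FRACTION) -> list[BoutonMeasurement]:
    """Flag boutons whose centroid lies in the outer ``fraction`` of x or y."""
    if not 0 < fraction < 0.5:
        raise InvalidParameterError("edge fraction must lie in (0, 0.5)")
    for m in measurements:
        x, y = m.centroid_vox[0], m.centroid_vox[1]
        m.edge_excluded = bool(
            x < fraction * nx or x > nx - 1 - fraction * nx
            or y < fraction * ny or y > ny - 1 - fraction * ny
        )
    return measurements


def _overlapping_ids(a: MaskSet, b: MaskSet) -> set[int]:
    if a.label_grid.shape != b.label_grid.shape:
        raise GeometryError("mask sets have mismatched dimensions")
    return set(np.unique(a.label_grid[(a.label_grid > 0) & (b.label_grid > 0)]).tolist())


def overlap_exclusion(vglut_set: MaskSet, vglut_measurements: list[BoutonMeasurement],
                      vgat_set: MaskSet, vgat_measurements: list[BoutonMeasurement],
                      ) -> tuple[list[BoutonMeasurement], list[BoutonMeasurement]]:
    """Flag every object sharing at least one voxel with the other marker."""
    glut_ids = _overlapping_ids(vglut_set, vgat_set)
    gat_ids = _overlapping_ids(vgat_set, vglut_set)
    for m in vglut_measurements:
        m.overlap_excluded = m.object_id in glut_ids
    for m in vgat_measurements:
        m.overlap_excluded = m.object_id in gat_ids
    return vglut_measurements, vgat_measurements


def segment_lipofuscin(dog_grid: np.ndarray, geometry: Geometry,
                       t0: float | None = None, step: float | None = None) -> MaskSet:
    """Segment the lipofuscin channel with the bouton segmenter, gate relaxed.

    Aggregates can be large, so the lower bound is dropped and the upper
    bound removed.
    """
    kwargs = {} if step is None else {"step": step}
    return iterative_segment(dog_grid, geometry, channel_role="lipofuscin",
                             t0=t0, vmin=0.0, vmax=None, **kwargs)


def lipofuscin_exclusion(bouton_sets: dict[str, tuple[MaskSet, list[BoutonMeasurement]]],
                         lipofuscin_set: MaskSet | None) -> None:
    """Flag every bouton sharing at least one voxel with a lipofuscin mask."""
    if lipofuscin_set is None:
        raise MissingChannelError(
            "lipofuscin channel absent; pass --no-lipofuscin to disable the exclusion"
        )
    for _role, (mset, measurements) in bouton_sets.items():
        flagged = _overlapping_ids(mset, lipofuscin_set)
        for m in measurements:
            m.lipofuscin_excluded = m.object_id in flagged


def measurements_frame(measurements: list[BoutonMeasurement],
                       meta: SiteMetadata) -> pd.DataFrame:
    """One row per bouton, all flags included (the boutons.csv shape)."""
    rows = []
    for m in measurements:
        rows.append({
            "site_id": m.site_id or meta.site_id,
            "subject": meta.subject_id,
            "species": meta.species,
            "region": meta.region,
            "layer": meta.layer,
            "bouton_type": m.bouton_type,
            "object_id": m.object_id,
            "mean_cb1r_adu": m.mean_cb1r_adu,
            "volume_um3": m.volume_um3,
            "centroid_x_um": m.centroid_um[0],
            "centroid_y_um": m.centroid_um[1],
            "centroid_z_um": m.centroid_um[2],
            "corrected_depth_um": m.corrected_depth_um,
            **{f: getattr(m, f) for f in FLAG_NAMES},
            "surviving": m.surviving,
        })
    return pd.DataFrame(rows)


def exclusion_counts(measurements: list[BoutonMeasurement]) -> dict[str, int]:
    """Per-filter exclusion counts plus the conservation identity terms.

    ``n_total = n_surviving + n_flagged``; an object with several flags is
    counted once in ``n_flagged`` but appears in every per-filter count.
    """
    counts = {f: sum(getattr(m, f) for m in measurements) for f in FLAG_NAMES}
    counts["n_total"] = len(measurements)
    counts["n_surviving"] = sum(m.surviving for m in measurements)
    counts["n_flagged"] = counts["n_total"] - counts["n_surviving"]
    return counts


def summarize_site(measurements: list[BoutonMeasurement],
                   meta: SiteMetadata) -> pd.DataFrame:
    """Mean CB1R over surviving boutons, one row per (site, bouton type)."""
    rows = []
    for role in ("vglut1", "vgat"):
        vals = [m.mean_cb1r_adu for m in measurements
                if m.bouton_type == role and m.surviving]
        if not vals:
            log.warning("site %s: no surviving %s boutons; no row emitted",
                        meta.site_id, role)
            continue
        rows.append({
            "site_id": meta.site_id,
            "subject": meta.subject_id,
            "species": meta.species,
            "region": meta.region,
            "layer": meta.layer,
            "bouton_type": role,
            "mean_cb1r_adu": float(np.mean(vals)),
            "n_boutons": len(vals),
        })
    return pd.DataFrame(rows, columns=["site_id", "subject", "species", "region",
                                       "layer", "bouton_type", "mean_cb1r_adu",
                                       "n_boutons"])
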