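"""Iterative combined intensity/morphological thresholding of DoG channels.

Starting from an Otsu seed threshold on the DoG channel, the threshold is
raised in fixed increments (50 gray levels by default).  At every level the
binarized grid is labeled in 3D, components are size-gated to the physical
bouton range 0.03–2.0 µm³, and survivors are merged (voxel-set union) with
the accumulated mask.  After the last level the accumulated union is
relabeled and the size gate re-applied, so no emitted object can violate the
gate.  Final masks are then bound to the *deconvolved* channel for all
intensity reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    GeometryError,
    InvalidParameterError,
)

#: Physical size gate (µm³), inclusive on both ends.
VMIN_UM3 = 0.03
VMAX_UM3 = 2.0
#: Threshold increment, in gray levels (ADU) of the DoG channel.
STEP_ADU = 50.0


@dataclass(frozen=True)
class Geometry:
    pixel_um: float
    zstep_um: float

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_um**2 * self.zstep_um


@dataclass
class ObjectMask:
    """One segmented object: a 26-connected voxel set with bookkeeping."""

    object_id: int
    channel_role: str
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (x, y, z)
    centroid_vox: tuple[float, float, float]  # (x, y, z), fractional voxels
    birth_threshold_adu: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class MaskSet:
    """All accepted objects of one channel plus the consistent label grid."""

    channel_role: str
    objects: list[ObjectMask]
    label_grid: np.ndarray  # int32, 0 = background
    geometry: Geometry
    intensity_grid: np.ndarray | None = None  # bound deconvolved channel
    pre_gate_final_components: int = 0
    provenance: list[str] = field(default_factory=list)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise InvalidParameterError("connectivity must be 6 or 26")


def otsu_threshold(grid: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximizing between-class variance.

    The histogram uses ``n_bins`` equal-width bins over the grid's observed
    range.  The returned value is the upper edge of the last background bin,
    so binarization at ``>= threshold`` separates the two classes.

    The between-class variance is maximized over bin *indices* in exact
    integer arithmetic (the maximizer is invariant under affine transforms of
    the bin centers), so the result carries no floating-point argmax
    ambiguity; ties break toward the lowest qualifying edge.
    """
    g = np.asarray(grid, dtype=np.float64).ravel()
    lo, hi = float(g.min()), float(g.max())
    if not hi > lo:
        raise DegenerateHistogramError("cannot threshold a constant grid")
    counts, edges = np.histogram(g, bins=n_bins, range=(lo, hi))
    c = [int(v) for v in counts]
    total_n = sum(c)
    total_s = sum(k * v for k, v in enumerate(c))
    # maximize (N1*S0 - N0*S1)^2 / (N0*N1) over cuts, exactly
    best_num, best_den, best_k = -1, 1, None
    n0 = s0 = 0
    for k in range(n_bins - 1):
        n0 += c[k]
        s0 += k * c[k]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        num = (n1 * s0 - n0 * (total_s - s0)) ** 2
        den = n0 * n1
        if num * best_den > best_num * den:  # exact rational comparison
            best_num, best_den, best_k = num, den, k
    return float(edges[best_k + 1])


def voxel_gate_bounds(geometry: Geometry, vmin: float = VMIN_UM3,
                      vmax: float = VMAX_UM3) -> tuple[int, int]:
    """Smallest and largest voxel counts whose volume lies inside the gate."""
    vv = geometry.voxel_volume_um3
    nmin = int(np.ceil(vmin / vv - 1e-12))
    nmax = int(np.floor(vmax / vv + 1e-12))
    return max(nmin, 1), nmax


def iterative_segment(dog_grid: np.ndarray, geometry: Geometry,
                      channel_role: str = "", t0: float | None = None,
                      step: float = STEP_ADU, vmin: float = VMIN_UM3,
                      vmax: float | None = VMAX_UM3, connectivity: int = 26,
                      n_bins: int = 256) -> MaskSet:
    """Run the iterative threshold/size-gate/merge segmentation.

    ``t0`` defaults to the Otsu threshold of ``dog_grid``.  ``vmax=None``
    disables the upper bound (used for lipofuscin aggregates).
    """
    if step <= 0:
        raise InvalidParameterError("threshold step must be positive")
    dog = np.asarray(dog_grid, dtype=np.float64)
    structure = _structure(connectivity)
    vv = geometry.voxel_volume_um3
    vmax_eff = np.inf if vmax is None else vmax

    accum = np.zeros(dog.shape, dtype=bool)
    birth = np.full(dog.shape, np.inf)
    if dog.size and dog.max() > dog.min():
        t = float(otsu_threshold(dog, n_bins)) if t0 is None else float(t0)
        peak = float(dog.max())
        while t <= peak:
            binary = dog >= t
            labels, n = ndimage.label(binary, structure=structure)
            if n:
                counts = np.bincount(labels.ravel())[1:]
                vols = counts * vv
                keep = np.flatnonzero((vols >= vmin) & (vols <= vmax_eff)) + 1
                if keep.size:
                    newly = np.isin(labels, keep) & ~accum
                    accum |= newly
                    birth[newly] = np.minimum(birth[newly], t)
            t += step

    # finalize: relabel the union and re-apply the gate
    labels, n = ndimage.label(accum, structure=structure)
    objects: list[ObjectMask] = []
    label_grid = np.zeros(dog.shape, dtype=np.int32)
    if n:
        counts = np.bincount(labels.ravel())[1:]
        vols = counts * vv
        keep = np.flatnonzero((vols >= vmin) & (vols <= vmax_eff)) + 1
        zz, yy, xx = np.nonzero(labels)
        lab = labels[zz, yy, xx]
        order = np.argsort(lab, kind="stable")
        zz, yy, xx, lab = zz[order], yy[order], xx[order], lab[order]
        bounds = np.searchsorted(lab, np.arange(1, n + 2))
        next_id = 1
        for lid in keep:
            s = slice(bounds[lid - 1], bounds[lid])
            vz, vy, vx = zz[s], yy[s], xx[s]
            cz, cy, cx = float(vz.mean()), float(vy.mean()), float(vx.mean())
            objects.append(ObjectMask(
                object_id=next_id,
                channel_role=channel_role,
                voxels=np.column_stack([vz, vy, vx]),
                volume_um3=float(len(vz) * vv),
                centroid_um=(cx * geometry.pixel_um, cy * geometry.pixel_um,
                             cz * geometry.zstep_um),
                centroid_vox=(cx, cy, cz),
                birth_threshold_adu=float(birth[vz, vy, vx].min()),
            ))
            label_grid[vz, vy, vx] = next_id
            next_id += 1
    maskset = MaskSet(
        channel_role=channel_role, objects=objects, label_grid=label_grid,
        geometry=geometry, pre_gate_final_components=int(n),
        provenance=[f"iterative_segment(t0={'otsu' if t0 is None else t0}, step={step}, "
                    f"vmin={vmin}, vmax={vmax}, connectivity={connectivity})"],
    )
    _assert_gate(maskset, vmin, vmax_eff)
    return maskset


def _assert_gate(maskset: MaskSet, vmin: float, vmax: float) -> None:
    for obj in maskset.objects:
        assert vmin <= obj.volume_um3 <= vmax, (
            f"object {obj.object_id} volume {obj.volume_um3} outside gate"
        )


def masks_to_measurements_grid(maskset: MaskSet, deconvolved_grid: np.ndarray) -> MaskSet:
    """Bind the final masks to the deconvolved channel for intensity reads.

    Segmentation ran on the DoG channel; all subsequent intensity statistics
    are taken from the deconvolved (no Gaussian subtraction) grid.
    """
    grid = np.asarray(deconvolved_grid, dtype=np.float64)
    if grid.shape != maskset.label_grid.shape:
        raise GeometryError(
            f"intensity grid shape {grid.shape} != label grid {maskset.label_grid.shape}"
        )
    maskset.intensity_grid = grid
    maskset.provenance.append("masks_to_measurements_grid(deconvolved)")
    return maskset
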