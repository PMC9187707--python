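"""Synthetic multichannel confocal stacks with known ground truth.

The generator emulates the acquisition used for cell-type-specific CB1R
quantification in postmortem cortex: four channels (vGlut1, vGAT, CB1R,
lipofuscin), 55/512 µm lateral pixel pitch, 0.25 µm z steps, a 12-bit camera,
and a factorial study design (species × region × subject × layer × site) with
planted cell-type × region effects on the CB1R channel.

Each bouton is rendered as an anisotropic Gaussian blob (the object core
convolved with a Gaussian point-spread surrogate for the 1.40 NA optics).
The CB1R channel carries a diffuse background plus, under every marker
punctum, a wider Gaussian whose amplitude is calibrated so that the expected
mean CB1R intensity over the punctum's mask equals the planted
``cb1r_mean_adu``.  Lipofuscin blobs bleed a configurable fraction of their
intensity into the CB1R channel, so the lipofuscin-exclusion filter has real
work to do.  Noise is Poisson on photon-equivalent counts plus Gaussian read
noise, quantized to integer ADU and clipped to the camera ceiling.

All randomness flows from one seeded :class:`numpy.random.Generator`;
identical (spec, seed) pairs reproduce stacks bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .stacks import (
    DEFAULT_PIXEL_UM,
    DEFAULT_ZSTEP_UM,
    ImageStack,
    SiteMetadata,
)

MARKER_ROLES = ("vglut1", "vgat")

#: Reference calibration of expected per-cell CB1R means (ADU) for the two
#: study species, keyed (cell-type role, region).  These are the generator's
#: default planted effects: inhibitory (vGAT) boutons carry more CB1R than
#: excitatory (vGlut1) boutons everywhere, with a region pattern that differs
#: between species (regional variation confined to inhibitory boutons in the
#: monkey pattern, present in both types in the human pattern).
MONKEY_EFFECT_TABLE = {
    ("vglut1", "PFC"): 480.984,
    ("vglut1", "A1"): 449.677,
    ("vglut1", "A2"): 452.872,
    ("vgat", "PFC"): 1077.951,
    ("vgat", "A1"): 1547.226,
    ("vgat", "A2"): 1187.688,
}
HUMAN_EFFECT_TABLE = {
    ("vglut1", "PFC"): 391.417,
    ("vglut1", "A1"): 621.843,
    ("vglut1", "A2"): 556.900,
    ("vgat", "PFC"): 598.244,
    ("vgat", "A1"): 948.501,
    ("vgat", "A2"): 940.308,
}
EFFECT_TABLES = {"monkey": MONKEY_EFFECT_TABLE, "human": HUMAN_EFFECT_TABLE}


@dataclass(frozen=True)
class PunctumTruth:
    """Planted ground truth for one fluorescent punctum."""

    id: int
    channel_role: str  # vglut1 | vgat | lipofuscin
    centroid_um: tuple[float, float, float]  # (x, y, z)
    radius_um: float
    peak_amplitude_adu: float
    cb1r_mean_adu: float  # expected CB1R mask mean; 0 for lipofuscin
    decoy: str | None = None  # sub_gate | supra_gate | overlap | lipofuscin_overlap

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.peak_amplitude_adu <= 0:
            raise InvalidSpecError("punctum radius and amplitude must be positive")
        if self.cb1r_mean_adu < 0:
            raise InvalidSpecError("cb1r_mean_adu must be nonnegative")


@dataclass
class NoiseModel:
    """Poisson photon noise plus Gaussian read noise, in ADU.

    ``gain_adu_per_photon = 0`` disables shot noise; ``read_noise_adu = 0``
    disables read noise (together: a noiseless render).
    """

    gain_adu_per_photon: float = 0.5
    read_noise_adu: float = 3.0


@dataclass
class StackSpec:
    """Everything needed to render one synthetic site stack."""

    nx: int = 512
    ny: int = 512
    nz: int = 25
    pixel_um: float = DEFAULT_PIXEL_UM
    zstep_um: float = DEFAULT_ZSTEP_UM
    psf_sigma_um: tuple[float, float] = (0.2, 0.5)  # (lateral, axial)
    background_adu: dict[str, float] = field(
        default_factory=lambda: {r: 100.0 for r in ("vglut1", "vgat", "cb1r", "lipofuscin")}
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    exposure_ms: dict[str, float] = field(
        default_factory=lambda: {r: 100.0 for r in ("vglut1", "vgat", "cb1r", "lipofuscin")}
    )
    nominal_exposure_ms: float = 100.0
    bit_depth: int = 12
    n_puncta: dict[str, int] = field(
        default_factory=lambda: {"vglut1": 200, "vgat": 200, "lipofuscin": 10}
    )
    decoy_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "sub_gate": 0.0,
            "supra_gate": 0.0,
            "overlap": 0.0,
            "lipofuscin_overlap": 0.0,
        }
    )
    # planted CB1R mask means per marker role and bouton-to-bouton lognormal CV
    cb1r_mean_adu: dict[str, float] = field(
        default_factory=lambda: {"vglut1": 500.0, "vgat": 1200.0}
    )
    bouton_cv: float = 0.4
    marker_amplitude_range: tuple[float, float] = (1500.0, 2500.0)
    radius_range_um: tuple[float, float] = (0.25, 0.4)
    lipofuscin_amplitude_range: tuple[float, float] = (2500.0, 3500.0)
    lipofuscin_radius_range_um: tuple[float, float] = (0.35, 0.6)
    lipofuscin_bleed: float = 0.5  # fraction of lipofuscin intensity in CB1R
    cb1r_width_scale: float = 2.6  # CB1R plateau lateral half-width / blob sigma
    cb1r_axial_scale: float = 1.7  # CB1R plateau axial half-width / blob axial sigma
    min_separation_um: float = 1.2  # lateral centre-to-centre separation
    min_separation_z_um: float = 2.0  # axial separation (PSF is elongated in z)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise InvalidSpecError("stack dimensions produce a zero-volume stack")
        if self.pixel_um <= 0 or self.zstep_um <= 0:
            raise InvalidSpecError("voxel pitch must be positive")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise InvalidSpecError("PSF sigmas must be positive")
        if any(e <= 0 for e in self.exposure_ms.values()) or self.nominal_exposure_ms <= 0:
            raise InvalidSpecError("exposures must be positive")
        if not (0 <= self.lipofuscin_bleed <= 1):
            raise InvalidSpecError("lipofuscin_bleed must lie in [0, 1]")

    @property
    def adu_ceiling(self) -> int:
        return 2**self.bit_depth - 1


# ---------------------------------------------------------------------------
# rendering


def _blob_sigmas_vox(radius_um: float, spec: StackSpec) -> tuple[float, float]:
    """Observed blob sigmas (lateral px, axial planes): object core ⊛ PSF."""
    core = radius_um / 2.0
    lat = math.hypot(core, spec.psf_sigma_um[0]) / spec.pixel_um
    ax = math.hypot(core, spec.psf_sigma_um[1]) / spec.zstep_um
    return lat, ax


def _add_blob(grid: np.ndarray, center_vox: tuple[float, float, float],
              sigma_lat: float, sigma_ax: float, peak: float) -> None:
    """Add an anisotropic Gaussian blob (peak amplitude ``peak``) in place.

    ``center_vox`` is (x, y, z) in fractional voxel indices.
    """
    if peak == 0:
        return
    cx, cy, cz = center_vox
    nz, ny, nx = grid.shape
    rx = ry = int(math.ceil(4 * sigma_lat)) + 1
    rz = int(math.ceil(4 * sigma_ax)) + 1
    x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
    y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 1)
    z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) - cx) / sigma_lat
    ys = (np.arange(y0, y1) - cy) / sigma_lat
    zs = (np.arange(z0, z1) - cz) / sigma_ax
    g = np.exp(-0.5 * (zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2))
    grid[z0:z1, y0:y1, x0:x1] += peak * g


def _add_flattop(grid: np.ndarray, center_vox: tuple[float, float, float],
                 w_lat: float, w_ax: float, peak: float) -> None:
    """Add a flat-topped (super-Gaussian, exp(-rho^6)) plateau in place.

    Models the locally uniform receptor signal under one bouton: near-constant
    over the bouton mask, negligible one plateau-width further out.
    """
    if peak == 0:
        return
    cx, cy, cz = center_vox
    nz, ny, nx = grid.shape
    rx = ry = int(math.ceil(1.7 * w_lat)) + 1
    rz = int(math.ceil(1.7 * w_ax)) + 1
    x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
    y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 1)
    z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) - cx) / w_lat
    ys = (np.arange(y0, y1) - cy) / w_lat
    zs = (np.arange(z0, z1) - cz) / w_ax
    rho2 = zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
    grid[z0:z1, y0:y1, x0:x1] += peak * np.exp(-rho2**3)


def _cb1r_calibration(sl: float, sa: float, width_scale: float, axial_scale: float,
                      psf_vox: tuple[float, float, float]) -> float:
    """Expected mask-mean of a unit-peak, PSF-blurred CB1R plateau.

    Renders the plateau for a marker blob with sigmas ``(sl, sa)`` (voxels),
    blurs it with the optical PSF, and averages over the ellipsoid the
    segmenter typically masks (~1.5 lateral sigmas, ~1.3 axial sigmas).
    Converts a target mask-mean into a plateau peak amplitude.
    """
    from scipy import ndimage as _ndi

    w_lat, w_ax = width_scale * sl, axial_scale * sa
    rl = int(math.ceil(1.7 * w_lat + 4 * psf_vox[1])) + 2
    rz = int(math.ceil(1.7 * w_ax + 4 * psf_vox[0])) + 2
    grid = np.zeros((2 * rz + 1, 2 * rl + 1, 2 * rl + 1))
    _add_flattop(grid, (rl, rl, rz), w_lat, w_ax, 1.0)
    blurred = _ndi.gaussian_filter(grid, psf_vox, mode="constant")
    z = (np.arange(grid.shape[0]) - rz) / (1.3 * sa)
    y = (np.arange(grid.shape[1]) - rl) / (1.5 * sl)
    x = (np.arange(grid.shape[2]) - rl) / (1.5 * sl)
    mask = (z[:, None, None] ** 2 + y[None, :, None] ** 2
            + x[None, None, :] ** 2) <= 1.0
    return float(blurred[mask].mean())


def _render_channels(spec: StackSpec, puncta: list[PunctumTruth]) -> dict[str, np.ndarray]:
    from scipy import ndimage as _ndi

    shape = (spec.nz, spec.ny, spec.nx)
    clean = {role: np.full(shape, float(spec.background_adu.get(role, 0.0)))
             for role in ("vglut1", "vgat", "cb1r", "lipofuscin")}
    psf_vox = (spec.psf_sigma_um[1] / spec.zstep_um,
               spec.psf_sigma_um[0] / spec.pixel_um,
               spec.psf_sigma_um[0] / spec.pixel_um)
    # CB1R plateaus accumulate unblurred, then one PSF blur models the optics,
    # so deconvolution recovers (approximately) the planted plateaus.
    cb1r_excess = np.zeros(shape)
    cal_cache: dict[tuple[float, float], float] = {}
    for p in puncta:
        sl, sa = _blob_sigmas_vox(p.radius_um, spec)
        cx = p.centroid_um[0] / spec.pixel_um
        cy = p.centroid_um[1] / spec.pixel_um
        cz = p.centroid_um[2] / spec.zstep_um
        _add_blob(clean[p.channel_role], (cx, cy, cz), sl, sa, p.peak_amplitude_adu)
        if p.channel_role == "lipofuscin":
            if spec.lipofuscin_bleed > 0:
                _add_blob(clean["cb1r"], (cx, cy, cz), sl, sa,
                          spec.lipofuscin_bleed * p.peak_amplitude_adu)
        else:
            excess = p.cb1r_mean_adu - spec.background_adu.get("cb1r", 0.0)
            if excess > 0:
                key = (round(sl, 2), round(sa, 2))
                if key not in cal_cache:
                    cal_cache[key] = _cb1r_calibration(
                        key[0], key[1], spec.cb1r_width_scale,
                        spec.cb1r_axial_scale, psf_vox)
                _add_flattop(cb1r_excess, (cx, cy, cz),
                             spec.cb1r_width_scale * sl, spec.cb1r_axial_scale * sa,
                             excess / cal_cache[key])
    if cb1r_excess.any():
        clean["cb1r"] += _ndi.gaussian_filter(cb1r_excess, psf_vox, mode="constant")
    return clean


def _apply_noise_and_digitize(clean: dict[str, np.ndarray], spec: StackSpec,
                              rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for role in ("vglut1", "vgat", "cb1r", "lipofuscin"):
        grid = clean[role] * (spec.exposure_ms.get(role, spec.nominal_exposure_ms)
                              / spec.nominal_exposure_ms)
        g = spec.noise.gain_adu_per_photon
        if g > 0:
            grid = rng.poisson(np.maximum(grid, 0.0) / g).astype(np.float64) * g
        if spec.noise.read_noise_adu > 0:
            grid = grid + rng.normal(0.0, spec.noise.read_noise_adu, size=grid.shape)
        out[role] = np.clip(np.rint(grid), 0, spec.adu_ceiling).astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# punctum placement


def _sample_positions(spec: StackSpec, rng: np.random.Generator, n: int,
                      existing: list[tuple[float, float, float]],
                      margin_um: float, z_range_um: tuple[float, float],
                      ) -> list[tuple[float, float, float]]:
    """Rejection-sample ``n`` centroids with an ellipsoidal exclusion zone.

    Centres must be at least ``min_separation_um`` apart laterally and
    ``min_separation_z_um`` axially (scaled-Euclidean criterion), so rendered
    blobs represent distinct resolvable boutons.
    """
    fx, fy = spec.nx * spec.pixel_um, spec.ny * spec.pixel_um
    pts = np.array(existing, dtype=float).reshape(-1, 3)
    scale = np.array([1.0, 1.0, spec.min_separation_um / spec.min_separation_z_um])
    out = []
    for _ in range(n):
        for _attempt in range(2000):
            q = np.array([rng.uniform(margin_um, fx - margin_um),
                          rng.uniform(margin_um, fy - margin_um),
                          rng.uniform(*z_range_um)])
            d2 = (((pts - q) * scale) ** 2).sum(axis=1) if len(pts) else np.array([np.inf])
            if d2.min() >= spec.min_separation_um**2:
                break
        else:
            warnings.warn("punctum placement could not honor the minimum separation; "
                          "field too crowded", stacklevel=2)
        pts = np.vstack([pts, q])
        out.append((float(q[0]), float(q[1]), float(q[2])))
    return out


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float,
                       cap: float = 2.5) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(n)
    s = math.sqrt(math.log(1.0 + cv**2))
    f = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)
    return np.minimum(f, cap)


def generate_stack(spec: StackSpec, truth_seed: int) -> tuple[ImageStack, list[PunctumTruth]]:
    """Render one four-channel stack and return it with its planted truth.

    Markers are placed with a minimum mutual separation so puncta represent
    distinct boutons; decoy fractions add deliberately out-of-gate objects,
    coincident vGlut1/vGAT pairs, and lipofuscin aggregates sitting on top of
    boutons (see :class:`StackSpec.decoy_fractions`).
    """
    rng = np.random.default_rng(truth_seed)
    fx, fy = spec.nx * spec.pixel_um, spec.ny * spec.pixel_um
    fz = (spec.nz - 1) * spec.zstep_um
    margin = min(0.8, 0.1 * min(fx, fy))
    z_range = (min(2 * spec.zstep_um, fz / 2), max(fz - 2 * spec.zstep_um, fz / 2))

    puncta: list[PunctumTruth] = []
    marker_pts: list[tuple[float, float, float]] = []
    next_id = 0

    def draw_marker(role: str, pos, decoy=None, radius=None, amplitude=None,
                    cb1r_factor=1.0) -> PunctumTruth:
        nonlocal next_id
        r = radius if radius is not None else rng.uniform(*spec.radius_range_um)
        a = amplitude if amplitude is not None else rng.uniform(*spec.marker_amplitude_range)
        cb1r = spec.cb1r_mean_adu.get(role, 0.0) * cb1r_factor
        p = PunctumTruth(next_id, role, pos, r, a, cb1r, decoy)
        next_id += 1
        return p

    for role in MARKER_ROLES:
        n = int(spec.n_puncta.get(role, 0))
        pos = _sample_positions(spec, rng, n, marker_pts, margin, z_range)
        marker_pts += pos
        factors = _lognormal_factors(rng, n, spec.bouton_cv)
        for q, f in zip(pos, factors):
            puncta.append(draw_marker(role, q, cb1r_factor=float(f)))

    # coincident vGlut1/vGAT decoy pairs
    n_overlap = int(round(spec.decoy_fractions.get("overlap", 0.0)
                          * min(spec.n_puncta.get("vglut1", 0), spec.n_puncta.get("vgat", 0))))
    pos = _sample_positions(spec, rng, n_overlap, marker_pts, margin, z_range)
    marker_pts += pos
    for q in pos:
        for role in MARKER_ROLES:
            f = float(_lognormal_factors(rng, 1, spec.bouton_cv)[0])
            puncta.append(draw_marker(role, q, decoy="overlap", cb1r_factor=f))

    # out-of-gate decoys: dim specks below, dim wide blobs above the gate
    for kind, rrange, arange in (
        ("sub_gate", (0.05, 0.09), (100.0, 200.0)),
        ("supra_gate", (1.0, 1.4), (300.0, 450.0)),
    ):
        for role in MARKER_ROLES:
            n_d = int(round(spec.decoy_fractions.get(kind, 0.0) * spec.n_puncta.get(role, 0)))
            pos = _sample_positions(spec, rng, n_d, marker_pts, margin, z_range)
            marker_pts += pos
            for q in pos:
                puncta.append(draw_marker(role, q, decoy=kind,
                                          radius=rng.uniform(*rrange),
                                          amplitude=rng.uniform(*arange),
                                          cb1r_factor=0.0))

    # lipofuscin: a fraction of the aggregates sit directly on boutons
    n_lipo = int(spec.n_puncta.get("lipofuscin", 0))
    n_on_boutons = int(round(spec.decoy_fractions.get("lipofuscin_overlap", 0.0) * n_lipo))
    targets = [p for p in puncta if p.channel_role in MARKER_ROLES and p.decoy is None]
    rng.shuffle(targets)
    covered = targets[:n_on_boutons]
    lipo_pos = [t.centroid_um for t in covered]
    lipo_pos += _sample_positions(spec, rng, n_lipo - len(covered), marker_pts, margin,
                                  z_range)
    for i, q in enumerate(lipo_pos):
        puncta.append(PunctumTruth(
            next_id, "lipofuscin", q,
            rng.uniform(*spec.lipofuscin_radius_range_um),
            rng.uniform(*spec.lipofuscin_amplitude_range),
            0.0, "lipofuscin_overlap" if i < len(covered) else None))
        next_id += 1
    # tag the covered boutons so downstream bookkeeping knows them
    for t in covered:
        idx = puncta.index(t)
        puncta[idx] = replace(t, decoy="lipofuscin_overlap")

    clean = _render_channels(spec, puncta)
    channels = _apply_noise_and_digitize(clean, spec, rng)
    stack = ImageStack(
        channels=channels,
        pixel_um=spec.pixel_um,
        zstep_um=spec.zstep_um,
        exposure_ms=dict(spec.exposure_ms),
        bit_depth=spec.bit_depth,
        surface="zmax",
        provenance=[f"generate_stack(seed={truth_seed})"],
    )
    return stack, puncta


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class StudyDesign:
    """Factorial design of a synthetic study.

    Defaults emulate the primate arm of the study: two subjects sampled in
    three cortical regions (PFC, primary and association auditory cortex),
    six randomly chosen sites per cortical layer, with the planted CB1R
    cell-type × region means taken from the reference calibration tables.
    """

    species: tuple[str, ...] = ("monkey",)
    regions: tuple[str, ...] = ("PFC", "A1", "A2")
    subjects_per_species: int = 2
    layers: tuple[str, ...] = ("L3",)
    sites_per_layer: int = 6
    effect_table: dict[tuple[str, str, str], float] | None = None  # (species, role, region)
    between_subject_sd: float = 300.0
    between_site_sd: float = 150.0
    bouton_cv: float = 0.4
    thickness_range_um: tuple[float, float] = (28.0, 32.0)
    stack_template: StackSpec | None = None

    def __post_init__(self) -> None:
        if not (6 <= self.sites_per_layer <= 10):
            raise InvalidSpecError("sites per layer must lie in [6, 10]")
        if self.effect_table is None:
            self.effect_table = {
                (sp, role, reg): EFFECT_TABLES[sp][(role, reg)]
                for sp in self.species for role in MARKER_ROLES for reg in self.regions
            }
        if any(v < 0 for v in self.effect_table.values()):
            raise InvalidSpecError("effect table entries must be nonnegative")
        if self.subjects_per_species < 2:
            warnings.warn("fewer than 2 subjects per species: the random subject "
                          "effect is inestimable", stacklevel=2)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    puncta: dict[str, list[PunctumTruth]]  # site_id -> planted puncta
    site_table: pd.DataFrame  # expected per-(site, type) CB1R mask means
    seed: int


def _site_rows(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the hierarchical per-(site, cell type) expected CB1R means.

    cell mean (species × type × region) + subject deviate (shared by all of a
    subject's rows: the random intercept) + an independent row-level deviate.
    The row, one site × cell type combination, is the model's exchangeable
    unit, so the "between-site" SD operates at row level.
    """
    # Site means are floored above the diffuse CB1R background: a bouton's
    # mask mean can never fall below the background the stack renders.
    floor = 150.0
    rows = []
    for sp in design.species:
        for s in range(design.subjects_per_species):
            subject = f"{sp}{s + 1}"
            delta_subj = rng.normal(0.0, design.between_subject_sd)
            for reg in design.regions:
                for lay in design.layers:
                    for k in range(design.sites_per_layer):
                        site_id = f"{subject}_{reg}_{lay}_s{k + 1}"
                        for role in MARKER_ROLES:
                            mu = (design.effect_table[(sp, role, reg)]
                                  + delta_subj
                                  + rng.normal(0.0, design.between_site_sd))
                            rows.append({
                                "site_id": site_id, "subject": subject, "species": sp,
                                "region": reg, "layer": lay, "bouton_type": role,
                                "expected_cb1r_adu": max(mu, floor),
                            })
    return pd.DataFrame(rows)


def simulate_site_table(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Stack-free mode: site-summary rows drawn directly from the hierarchy.

    Used for statistical calibration at scale (no images rendered).  Returns
    the same columns the quantification stage emits.
    """
    rng = np.random.default_rng(seed)
    df = _site_rows(design, rng)
    df = df.rename(columns={"expected_cb1r_adu": "mean_cb1r_adu"})
    df["n_boutons"] = design.stack_template.n_puncta.get("vglut1", 30) if design.stack_template else 30
    return df


def generate_study(design: StudyDesign, seed: int,
                   ) -> tuple[list[tuple[ImageStack, SiteMetadata]], GroundTruth]:
    """Render one stack per site of the factorial design.

    Returns the stacks with their site metadata, plus the full ground truth
    (per-site planted puncta and the expected site-table the hierarchy drew).
    """
    rng = np.random.default_rng(seed)
    table = _site_rows(design, rng)
    template = design.stack_template or StackSpec(
        nx=80, ny=80,
        n_puncta={"vglut1": 25, "vgat": 25, "lipofuscin": 5},
        decoy_fractions={"sub_gate": 0.0, "supra_gate": 0.0,
                         "overlap": 0.05, "lipofuscin_overlap": 0.2},
    )

    stacks: list[tuple[ImageStack, SiteMetadata]] = []
    puncta: dict[str, list[PunctumTruth]] = {}
    for site_id, grp in table.groupby("site_id", sort=True):
        meta_row = grp.iloc[0]
        thickness = rng.uniform(*design.thickness_range_um)
        nz = int(round(0.2 * thickness / template.zstep_um)) + 1
        means = dict(zip(grp["bouton_type"], grp["expected_cb1r_adu"]))
        spec = replace(template, nz=nz, cb1r_mean_adu=means, bouton_cv=design.bouton_cv)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stack, truth = generate_stack(spec, sub_seed)
        meta = SiteMetadata(
            site_id=site_id, subject_id=meta_row["subject"],
            species=meta_row["species"], region=meta_row["region"],
            layer=meta_row["layer"], measured_thickness_um=float(thickness),
        )
        stacks.append((stack, meta))
        puncta[site_id] = truth
    return stacks, GroundTruth(puncta=puncta, site_table=table, seed=seed)


def reference_primate_design(dense: bool = False) -> StudyDesign:
    """The primate-calibrated factorial study design.

    ``dense=False`` (default) uses compact 80x80 px site fields with 25
    boutons per marker channel — quick enough for repeated end-to-end runs.
    ``dense=True`` uses 112x112 px fields with 60 boutons per channel, which
    tightens per-site means for intensity-recovery checks.
    """
    if not dense:
        return StudyDesign()
    return StudyDesign(stack_template=StackSpec(
        nx=112, ny=112,
        n_puncta={"vglut1": 60, "vgat": 60, "lipofuscin": 8},
        decoy_fractions={"sub_gate": 0.0, "supra_gate": 0.0,
                         "overlap": 0.05, "lipofuscin_overlap": 0.2},
    ))


def detection_benchmark_spec() -> StackSpec:
    """Dense 256×256×16 two-marker stack used to score punctum detection.

    200 in-gate puncta per channel at the resolvable-separation floor
    (1.1 µm lateral / 1.6 µm axial between centres), compact bouton radii,
    default noise (peak SNR well above 5).
    """
    return StackSpec(
        nx=256, ny=256, nz=16,
        n_puncta={"vglut1": 200, "vgat": 200, "lipofuscin": 0},
        radius_range_um=(0.2, 0.3),
        min_separation_um=1.1, min_separation_z_um=1.6,
    )


def match_centroids(truth_um: np.ndarray, found_um: np.ndarray,
                    radius_um: float = 0.5) -> tuple[int, int, int]:
    """Greedy nearest-first matching of detected centroids to planted truth.

    Returns (true positives, false positives, false negatives); each truth
    and each detection is used at most once.
    """
    from scipy.spatial.distance import cdist

    if len(found_um) == 0 or len(truth_um) == 0:
        return 0, len(found_um), len(truth_um)
    d = cdist(found_um, truth_um)
    pairs = np.argwhere(d < radius_um)
    order = np.argsort(d[d < radius_um])
    used_f, used_t = set(), set()
    for i, j in pairs[order]:
        if i not in used_f and j not in used_t:
            used_f.add(i)
            used_t.add(j)
    tp = len(used_t)
    return tp, len(found_um) - tp, len(truth_um) - tp


def design_from_dict(d: dict) -> StudyDesign:
    """Build a StudyDesign from a plain dict (YAML-friendly)."""
    d = dict(d)
    stack = d.pop("stack", None)
    effect_table = d.pop("effect_table", None)
    kwargs = {}
    for key in ("species", "regions", "layers"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    for key in ("subjects_per_species", "sites_per_layer", "between_subject_sd",
                "between_site_sd", "bouton_cv"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "thickness_range_um" in d:
        kwargs["thickness_range_um"] = tuple(d.pop("thickness_range_um"))
    if d:
        raise InvalidSpecError(f"unknown design keys: {sorted(d)}")
    if stack is not None:
        np_ = stack.pop("n_puncta", None)
        df_ = stack.pop("decoy_fractions", None)
        spec = StackSpec(**stack)
        if np_ is not None:
            spec.n_puncta = dict(np_)
        if df_ is not None:
            spec.decoy_fractions = {**spec.decoy_fractions, **df_}
        kwargs["stack_template"] = spec
    if effect_table is not None:
        kwargs["effect_table"] = {
            (sp, role, reg): float(v)
            for sp, roles in effect_table.items()
            for role, regs in roles.items()
            for reg, v in regs.items()
        }
    return StudyDesign(**kwargs)


# ---------------------------------------------------------------------------
# constructed demonstration site for the exclusion-filter oracle


def build_filter_demo_site(t0: float = 150.0) -> tuple[ImageStack, SiteMetadata, dict, list[PunctumTruth]]:
    """A noiseless constructed site where every exclusion filter fires a known
    number of times.

    Plants, at controlled positions: in-gate boutons in the analysable depth
    band; dim sub-gate specks and dim oversized blobs (never cross the fixed
    starting threshold ``t0``, hence size-excluded); coincident vGlut1/vGAT
    pairs; lipofuscin aggregates directly atop two boutons; shallow, deep and
    edge-band boutons.  Returns the stack, metadata, the expected per-filter
    exclusion counts, and the planted truth.
    """
    spec = StackSpec(
        nx=160, ny=160, nz=32,
        noise=NoiseModel(gain_adu_per_photon=0.0, read_noise_adu=0.0),
        n_puncta={"vglut1": 0, "vgat": 0, "lipofuscin": 0},
        cb1r_mean_adu={"vglut1": 500.0, "vgat": 1200.0},
        bouton_cv=0.0,
    )
    px, zs = spec.pixel_um, spec.zstep_um
    # measured thickness 20 µm -> shrinkage factor 0.5; the corrected 2–4 µm
    # band corresponds to measured depth 1–2 µm, i.e. planes nz-9 .. nz-5.
    keep_z = [(spec.nz - 7) * zs]  # measured depth 1.5 µm -> corrected 3 µm
    shallow_z = (spec.nz - 3) * zs  # measured 0.5 -> corrected 1 µm (< 2)
    deep_z = (spec.nz - 22) * zs  # measured 5.25 -> corrected 10.5 µm (> 4)

    puncta: list[PunctumTruth] = []
    nid = 0

    def put(role, x_um, y_um, z_um, radius, amp, cb1r, decoy=None):
        nonlocal nid
        puncta.append(PunctumTruth(nid, role, (x_um, y_um, z_um), radius, amp, cb1r, decoy))
        nid += 1

    # 12 surviving boutons on a lattice well inside the field, keep band
    grid_xy = [(3.0 + 2.2 * i, 3.0 + 2.2 * j) for i in range(4) for j in range(3)]
    for k, (x, y) in enumerate(grid_xy):
        role = MARKER_ROLES[k % 2]
        put(role, x, y, keep_z[0], 0.3, 2000.0, spec.cb1r_mean_adu[role])

    # size-gate decoys: 3 dim specks + 2 dim wide blobs (DoG stays below t0)
    for x in (12.0, 13.5, 15.0):
        put("vglut1", x, 12.5, keep_z[0], 0.07, 150.0, 0.0, "sub_gate")
    for x, y in ((12.5, 15.0), (15.0, 15.0)):
        put("vgat", x, y, keep_z[0], 1.2, 400.0, 0.0, "supra_gate")

    # 2 coincident vGlut1/vGAT pairs -> 4 overlap-flagged objects
    for x in (3.0, 5.2):
        put("vglut1", x, 9.6, keep_z[0], 0.3, 2000.0, 500.0, "overlap")
        put("vgat", x, 9.6, keep_z[0], 0.3, 2000.0, 1200.0, "overlap")

    # 2 boutons covered by lipofuscin + 2 free lipofuscin aggregates
    for x in (9.0, 11.2):
        put("vgat", x, 9.6, keep_z[0], 0.3, 2000.0, 1200.0, "lipofuscin_overlap")
        put("lipofuscin", x, 9.6, keep_z[0], 0.45, 3000.0, 0.0, "lipofuscin_overlap")
    for x in (13.4, 15.2):
        put("lipofuscin", x, 9.6, keep_z[0], 0.45, 3000.0, 0.0)

    # depth decoys: 2 shallow + 2 deep boutons, center field
    put("vglut1", 7.5, 12.5, shallow_z, 0.3, 2000.0, 500.0, "shallow")
    put("vgat", 9.7, 12.5, shallow_z, 0.3, 2000.0, 1200.0, "shallow")
    put("vglut1", 3.0, 12.5, deep_z, 0.3, 2000.0, 500.0, "deep")
    put("vgat", 5.2, 12.5, deep_z, 0.3, 2000.0, 1200.0, "deep")

    # edge decoys: centroids inside the 2% band (< 0.02 * 160 px = 3.2 px)
    edge_x = 1.5 * px
    put("vglut1", edge_x, 6.0, keep_z[0], 0.3, 2000.0, 500.0, "edge")
    put("vgat", edge_x, 8.5, keep_z[0], 0.3, 2000.0, 1200.0, "edge")

    clean = _render_channels(spec, puncta)
    rng = np.random.default_rng(0)
    channels = _apply_noise_and_digitize(clean, spec, rng)
    stack = ImageStack(channels=channels, pixel_um=px, zstep_um=zs,
                       exposure_ms=dict(spec.exposure_ms), bit_depth=spec.bit_depth,
                       surface="zmax", provenance=["build_filter_demo_site"])
    meta = SiteMetadata(site_id="demo", subject_id="demo1", species="monkey",
                        region="PFC", layer="L3", measured_thickness_um=20.0)
    expected = {
        "size_excluded": 5,       # never yield an in-gate mask
        "overlap_excluded": 4,    # two coincident pairs, both channels flagged
        "lipofuscin_excluded": 2,
        "depth_excluded": 4,
        "edge_excluded": 2,
        "surviving": 12,
        "t0": t0,
    }
    return stack, meta, expected, puncta
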