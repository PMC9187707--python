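"""Pipeline orchestration: stack -> masks -> filtered boutons -> site rows -> ANOVA."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .image_io import normalize_exposure
from .preprocess import deconvolve, gaussian_psf, make_dog_channels, skip_deconvolution
from .quantify import (
    depth_filter,
    edge_filter,
    exclusion_counts,
    lipofuscin_exclusion,
    measure_boutons,
    measurements_frame,
    overlap_exclusion,
    segment_lipofuscin,
    summarize_site,
)
from .segment import Geometry, iterative_segment, masks_to_measurements_grid
from .stacks import ImageStack, SiteMetadata
from .stats import fit_mixed_anova, posthoc_decomposition, report_text
from .synthetic import StudyDesign, generate_study

log = logging.getLogger(__name__)


@dataclass
class SiteResult:
    boutons: pd.DataFrame
    sites: pd.DataFrame
    counts: dict[str, int]


def process_site(stack: ImageStack, meta: SiteMetadata,
                 config: RunConfig | None = None,
                 t0: float | None = None) -> SiteResult:
    """Run preprocessing, segmentation, filtering and summarization for one site."""
    cfg = config or RunConfig()
    stack = normalize_exposure(stack, cfg.reference_exposure_ms)

    if cfg.preprocess.deconv.skip:
        proc = skip_deconvolution(stack)
    else:
        psf = gaussian_psf(cfg.preprocess.deconv.psf_sigma_um, stack.pixel_um,
                           stack.zstep_um)
        proc = deconvolve(stack, psf, iterations=cfg.preprocess.deconv.iterations)
    make_dog_channels(proc, cfg.preprocess.sigma_small, cfg.preprocess.sigma_large,
                      cfg.preprocess.dog_mode)

    geometry = Geometry(pixel_um=stack.pixel_um, zstep_um=stack.zstep_um)
    bouton_sets = {}
    for role in ("vglut1", "vgat"):
        mset = iterative_segment(
            proc.dog[role], geometry, channel_role=role, t0=t0,
            step=cfg.segment.step_adu, vmin=cfg.segment.vmin_um3,
            vmax=cfg.segment.vmax_um3, connectivity=cfg.segment.connectivity,
            n_bins=cfg.segment.bins,
        )
        masks_to_measurements_grid(mset, proc.deconvolved["cb1r"])
        measurements = measure_boutons(mset, proc.deconvolved["cb1r"], meta.site_id)
        depth_filter(measurements, stack, meta, cfg.quantify.depth_lo_um,
                     cfg.quantify.depth_hi_um)
        edge_filter(measurements, stack.nx, stack.ny, cfg.quantify.edge_fraction)
        bouton_sets[role] = (mset, measurements)

    overlap_exclusion(bouton_sets["vglut1"][0], bouton_sets["vglut1"][1],
                      bouton_sets["vgat"][0], bouton_sets["vgat"][1])
    if cfg.quantify.lipofuscin_exclusion:
        lipo = segment_lipofuscin(proc.dog["lipofuscin"], geometry, t0=t0,
                                  step=cfg.segment.step_adu)
        lipofuscin_exclusion(bouton_sets, lipo)

    measurements = bouton_sets["vglut1"][1] + bouton_sets["vgat"][1]
    boutons = measurements_frame(measurements, meta)
    sites = summarize_site(measurements, meta)
    counts = exclusion_counts(measurements)
    log.info("site %s: %d objects, %d surviving (%s)", meta.site_id,
             counts["n_total"], counts["n_surviving"],
             {k: v for k, v in counts.items() if k.endswith("_excluded")})
    return SiteResult(boutons=boutons, sites=sites, counts=counts)


def process_study(stacks: list[tuple[ImageStack, SiteMetadata]],
                  config: RunConfig | None = None,
                  t0: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Process every site; returns (boutons, sites, per-site counts)."""
    all_boutons, all_sites, all_counts = [], [], []
    for stack, meta in stacks:
        try:
            res = process_site(stack, meta, config, t0=t0)
        except Exception as exc:  # noqa: BLE001 - annotate the failing site
            raise RuntimeError(f"processing failed at site {meta.site_id}") from exc
        all_boutons.append(res.boutons)
        all_sites.append(res.sites)
        all_counts.append({"site_id": meta.site_id, **res.counts})
    boutons = pd.concat(all_boutons, ignore_index=True) if all_boutons else pd.DataFrame()
    sites = pd.concat(all_sites, ignore_index=True) if all_sites else pd.DataFrame()
    return boutons, sites, all_counts


def analyze_sites(sites: pd.DataFrame, config: RunConfig | None = None
                  ) -> tuple[dict, pd.DataFrame, str]:
    """Fit the mixed ANOVA and post-hocs per species."""
    cfg = config or RunConfig()
    anova_out, posthoc_frames, reports = {}, [], []
    for species in sorted(sites["species"].unique()):
        res = fit_mixed_anova(sites, species, df_method=cfg.stats.df_method,
                              with_satterthwaite=cfg.stats.with_satterthwaite)
        ph = posthoc_decomposition(res, df_method=cfg.stats.df_method)
        ph.insert(0, "species", species)
        anova_out[species] = res.to_dict()
        posthoc_frames.append(ph)
        reports.append(report_text(res, ph))
    posthoc = pd.concat(posthoc_frames, ignore_index=True)
    return anova_out, posthoc, "\n\n".join(reports)


def run_pipeline(design: StudyDesign, seed: int, out_dir: str | os.PathLike,
                 config: RunConfig | None = None) -> dict:
    """simulate -> process -> stats, writing all artifacts under ``out_dir``.

    Returns a summary dict (paths and per-stage counts).  Rerunning with the
    same design/seed/config yields byte-identical CSV outputs.
    """
    cfg = config or RunConfig()
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    stacks, truth = generate_study(design, seed)
    boutons, sites, counts = process_study(stacks, cfg)
    anova, posthoc, report = analyze_sites(sites, cfg)

    boutons.to_csv(os.path.join(out, "boutons.csv"), index=False)
    sites.to_csv(os.path.join(out, "sites.csv"), index=False)
    truth.site_table.to_csv(os.path.join(out, "ground_truth_sites.csv"), index=False)
    posthoc.to_csv(os.path.join(out, "posthoc.csv"), index=False)
    with open(os.path.join(out, "anova.json"), "w") as fh:
        json.dump(anova, fh, indent=2)
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(report + "\n")
    with open(os.path.join(out, "counts.json"), "w") as fh:
        json.dump(counts, fh, indent=2)
    with open(os.path.join(out, "resolved_config.json"), "w") as fh:
        json.dump({"seed": seed, "config": cfg.model_dump()}, fh, indent=2, default=list)
    return {"out_dir": out, "n_sites": len(stacks), "counts": counts,
            "anova": anova, "n_bouton_rows": len(boutons)}
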