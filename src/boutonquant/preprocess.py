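"""Deconvolution surrogate and difference-of-Gaussians channels.

The published workflow deconvolves each channel (blind deconvolution in a
commercial package) and then builds a difference-of-Gaussians (DoG) channel
per deconvolved channel for segmentation; masks are later copied back onto
the deconvolved channel for intensity reads.  Here deconvolution is
Richardson–Lucy iterative restoration with a known (or user-supplied)
Gaussian PSF — it preserves the pipeline role of edge sharpening before DoG
— and can be skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import restoration

from .errors import InvalidParameterError
from .stacks import ImageStack


@dataclass
class ProcessedStack:
    """Deconvolved and DoG grids for every channel, with provenance."""

    deconvolved: dict[str, np.ndarray]
    dog: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)


def gaussian_psf(sigma_um: tuple[float, float], pixel_um: float, zstep_um: float,
                 truncate: float = 3.0) -> np.ndarray:
    """Anisotropic Gaussian PSF kernel (z, y, x), normalized to unit sum."""
    s_lat = sigma_um[0] / pixel_um
    s_ax = sigma_um[1] / zstep_um
    if s_lat <= 0 or s_ax <= 0:
        raise InvalidParameterError("PSF sigmas must be positive")
    rl = max(1, int(np.ceil(truncate * s_lat)))
    rz = max(1, int(np.ceil(truncate * s_ax)))
    z = np.arange(-rz, rz + 1) / s_ax
    y = np.arange(-rl, rl + 1) / s_lat
    k = np.exp(-0.5 * (z[:, None, None] ** 2 + y[None, :, None] ** 2 + y[None, None, :] ** 2))
    return k / k.sum()


def deconvolve(stack: ImageStack, psf: np.ndarray, iterations: int = 10,
               channels: list[str] | None = None) -> ProcessedStack:
    """Richardson–Lucy restoration of each channel against ``psf``.

    ``iterations=0`` returns the input unchanged (cast to float).  The PSF is
    renormalized to unit sum, so total intensity is conserved up to boundary
    effects.
    """
    if iterations < 0:
        raise InvalidParameterError("iteration count must be nonnegative")
    psf = np.asarray(psf, dtype=np.float64)
    if psf.min() < 0 or psf.sum() <= 0:
        raise InvalidParameterError("PSF must be nonnegative with positive sum")
    psf = psf / psf.sum()
    out: dict[str, np.ndarray] = {}
    for role, grid in stack.channels.items():
        if channels is not None and role not in channels:
            out[role] = np.asarray(grid, dtype=np.float64)
            continue
        g = np.asarray(grid, dtype=np.float64)
        if iterations == 0 or psf.size == 1:
            out[role] = g.copy()
            continue
        out[role] = restoration.richardson_lucy(g, psf, num_iter=iterations, clip=False)
        np.maximum(out[role], 0.0, out=out[role])
    return ProcessedStack(
        deconvolved=out,
        provenance=[f"deconvolve(richardson_lucy, iterations={iterations})"],
    )


def skip_deconvolution(stack: ImageStack) -> ProcessedStack:
    """Pass channels through unchanged (float), for --skip-deconvolution."""
    return ProcessedStack(
        deconvolved={r: np.asarray(g, dtype=np.float64) for r, g in stack.channels.items()},
        provenance=["deconvolve(skipped)"],
    )


def dog_channel(grid: np.ndarray, sigma_small: float = 0.7, sigma_large: float = 2.0,
                mode: str = "2d") -> np.ndarray:
    """Difference-of-Gaussians band-pass of one channel.

    Sigmas are in *pixels*; by default the filter runs in 2D independently on
    every z plane (the z sampling is anisotropic), with reflective boundary
    handling.  Output is ``G(sigma_small)*grid - G(sigma_large)*grid`` and may
    be negative.
    """
    if not sigma_small < sigma_large:
        raise InvalidParameterError(
            f"sigma_small must be < sigma_large, got {sigma_small} >= {sigma_large}"
        )
    g = np.asarray(grid, dtype=np.float64)
    if mode == "2d":
        sig_s = (0.0, sigma_small, sigma_small)
        sig_l = (0.0, sigma_large, sigma_large)
    elif mode == "3d":
        sig_s = (sigma_small, sigma_small, sigma_small)
        sig_l = (sigma_large, sigma_large, sigma_large)
    else:
        raise InvalidParameterError(f"unknown DoG mode {mode!r}")
    small = ndimage.gaussian_filter(g, sig_s, mode="reflect")
    large = ndimage.gaussian_filter(g, sig_l, mode="reflect")
    return small - large


def make_dog_channels(proc: ProcessedStack, sigma_small: float = 0.7,
                      sigma_large: float = 2.0, mode: str = "2d") -> ProcessedStack:
    """Populate ``proc.dog`` for every deconvolved channel."""
    for role, grid in proc.deconvolved.items():
        proc.dog[role] = dog_channel(grid, sigma_small, sigma_large, mode)
    proc.provenance.append(f"dog(sigma_small={sigma_small}, sigma_large={sigma_large}, mode={mode})")
    return proc
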