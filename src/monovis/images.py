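"""USAF-1951-style resolution targets, PSF blurring, binocular summation.

A tri-bar target is rendered deterministically (dark bars on a light
background, 4x supersampled edges), blurred by resampled bench PSFs, and
two blurred views are fused per pixel by quadratic summation
``sqrt((a^2 + b^2) / 2)`` to visualise the binocular impression of a
myopic offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage, signal

from .bench import PSF

__all__ = [
    "TargetImage",
    "BinocularImage",
    "bar_frequency_lpmm",
    "generate_usaf_target",
    "blur_with_psf",
    "quadratic_sum",
    "michelson_contrast",
    "save_png",
    "save_tiff",
    "montage",
]


def bar_frequency_lpmm(group: int, element: int) -> float:
    """Bar frequency of a chart element: ``2**(group + (element-1)/6)`` lp/mm."""
    return 2.0 ** (group + (element - 1) / 6.0)


@dataclass
class TargetImage:
    """Grayscale chart with a physical pixel scale.

    ``elements`` records, per rendered element, its group/element
    indices, bar frequency and bounding box (row0, row1, col0, col1) in
    final pixels, so bar contrast can be measured after blurring.
    Background is 1.0 (light), bars are 0.0 (dark).
    """

    pixels: np.ndarray
    pixel_scale_um: float
    elements: list[dict[str, Any]] = field(default_factory=list)
    background: float = 1.0
    foreground: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)


@dataclass
class BinocularImage:
    """Quadratically summed view of two parent images."""

    pixels: np.ndarray
    pixel_scale_um: float
    parents: tuple[str, str] = ("", "")
    normalization: str = "mean-square"
    meta: dict[str, Any] = field(default_factory=dict)


def _draw_element(
    canvas: np.ndarray,
    top: int,
    left: int,
    bar_w: int,
    bar_len: int,
) -> tuple[int, int]:
    """Draw one element (3 horizontal + 3 vertical bars) at supersampled
    resolution; returns the (height, width) footprint in canvas pixels."""
    # horizontal bars: 3 bars of bar_len x bar_w separated by bar_w gaps
    for k in range(3):
        r = top + k * 2 * bar_w
        canvas[r : r + bar_w, left : left + bar_len] = 0.0
    # vertical bars to the right, separated by a bar_len gap
    vleft = left + bar_len + bar_w
    for k in range(3):
        c = vleft + k * 2 * bar_w
        canvas[top : top + bar_len, c : c + bar_w] = 0.0
    return bar_len, bar_len + bar_w + 5 * bar_w


def generate_usaf_target(
    groups: Sequence[tuple[int, int]],
    pixel_scale_um: float,
    size_px: int,
    *,
    margin_px: int = 64,
    supersample: int = 4,
) -> TargetImage:
    """Render the requested (group, element) pairs on one chart.

    Bar width is ``0.5 / frequency`` mm (one line pair = bar + space) and
    bar length is five widths, the standard 5:1 tri-bar geometry.
    Rendering is a deterministic binary fill at ``supersample`` times the
    final resolution followed by box averaging (edge antialiasing).
    Elements are laid out top-to-bottom inside a uniform background
    margin.  Raises if a bar would fall below 2 final pixels or the
    layout does not fit.
    """
    ss = supersample
    canvas = np.ones((size_px * ss, size_px * ss))
    elements: list[dict[str, Any]] = []
    top = margin_px * ss
    left = margin_px * ss
    for group, element in groups:
        freq = bar_frequency_lpmm(group, element)
        bar_w_um = 0.5 / freq * 1000.0
        bar_w_px = bar_w_um / pixel_scale_um
        if bar_w_px < 2.0:
            raise ValueError(
                f"group {group} element {element}: bar width {bar_w_px:.2f} px "
                "below the 2-px resolvable limit"
            )
        bw = max(1, int(round(bar_w_px * ss)))
        bl = 5 * bw
        h, w = bl, bl + 6 * bw
        if top + h > (size_px - margin_px) * ss or left + w > (size_px - margin_px) * ss:
            raise ValueError("chart layout does not fit the requested size")
        _draw_element(canvas, top, left, bw, bl)
        elements.append(
            {
                "group": group,
                "element": element,
                "frequency_lpmm": freq,
                "bbox_px": (
                    top // ss,
                    -(-(top + h) // ss),
                    left // ss,
                    -(-(left + w) // ss),
                ),
            }
        )
        top += h + 2 * bw + ss * 4

    pixels = canvas.reshape(size_px, ss, size_px, ss).mean(axis=(1, 3))
    return TargetImage(
        pixels=pixels,
        pixel_scale_um=pixel_scale_um,
        elements=elements,
        meta={"supersample": ss, "margin_px": margin_px},
    )


def _resample_kernel(
    psf: PSF, pixel_scale_um: float, max_size: int, energy: float
) -> np.ndarray:
    """PSF resampled to the image pixel scale, cropped and renormalised.

    The kernel is cropped to the centred square holding ``energy`` of the
    total (capped at ``max_size``); far diffraction tails carry
    negligible energy and would otherwise force kernels larger than the
    image.  Renormalisation to unit sum preserves mean image intensity.
    """
    zoom = psf.pixel_scale_um / pixel_scale_um
    k = ndimage.zoom(psf.intensity, zoom, order=1, prefilter=False)
    k = np.clip(k, 0.0, None)
    n = min(k.shape)
    k = k[:n, :n]
    total = k.sum()
    if total <= 0:
        raise ValueError("degenerate PSF after resampling")
    c = n // 2
    # grow a centred window until it holds the requested energy
    half = 1
    while half < n // 2:
        win = k[c - half : c + half + 1, c - half : c + half + 1]
        if win.sum() >= energy * total or 2 * half + 1 >= max_size:
            break
        half += 1
    k = k[max(0, c - half) : c + half + 1, max(0, c - half) : c + half + 1]
    return k / k.sum()


def blur_with_psf(
    image: TargetImage,
    psf: PSF | np.ndarray,
    defocus_D: float | None = None,
    *,
    max_kernel_px: int = 129,
    kernel_energy: float = 0.999,
) -> TargetImage:
    """Convolve a chart with a PSF under replicate boundary handling.

    A :class:`~monovis.bench.PSF` is first resampled from its native
    image-plane sampling to the chart's pixel scale and renormalised to
    unit sum, so the mean intensity of a chart with a constant-background
    margin is conserved.  Intensities are clipped to [0, 1] only on
    output.  A bare array kernel is used as-is (it must already sum
    to 1).
    """
    if isinstance(psf, PSF):
        kernel = _resample_kernel(
            psf, image.pixel_scale_um, max_kernel_px, kernel_energy
        )
    else:
        kernel = np.asarray(psf, dtype=float)
        if abs(kernel.sum() - 1.0) > 1e-9:
            raise ValueError("array kernels must sum to 1")
    if kernel.shape[0] >= image.pixels.shape[0] or kernel.shape[1] >= image.pixels.shape[1]:
        raise ValueError("PSF kernel wider than the image")
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image.pixels, ((ph, ph), (pw, pw)), mode="edge")
    if kernel.size <= 9:  # exact direct path (delta kernels stay bit-identical)
        out = signal.convolve(padded, kernel, mode="valid", method="direct")
    else:
        out = signal.fftconvolve(padded, kernel, mode="valid")
    out = out[: image.pixels.shape[0], : image.pixels.shape[1]]
    meta = dict(image.meta)
    meta["blur"] = {
        "defocus_D": defocus_D,
        "kernel_px": kernel.shape[0],
    }
    return TargetImage(
        pixels=np.clip(out, 0.0, 1.0),
        pixel_scale_um=image.pixel_scale_um,
        elements=[dict(e) for e in image.elements],
        background=image.background,
        foreground=image.foreground,
        meta=meta,
    )


def quadratic_sum(
    img_dominant: TargetImage | BinocularImage,
    img_nondominant: TargetImage | BinocularImage,
    *,
    normalization: str = "mean-square",
) -> BinocularImage:
    """Per-pixel quadratic summation of two views.

    ``mean-square`` (default): ``sqrt((a^2 + b^2) / 2)`` -- identical
    inputs are a fixed point.  ``root-sum``: ``sqrt(a^2 + b^2)`` clipped
    to 1, the un-normalised variant.  Commutative either way.
    """
    a, b = img_dominant.pixels, img_nondominant.pixels
    if a.shape != b.shape:
        raise ValueError("shape mismatch between the two views")
    if img_dominant.pixel_scale_um != img_nondominant.pixel_scale_um:
        raise ValueError("pixel-scale mismatch between the two views")
    if normalization == "mean-square":
        out = np.sqrt((a**2 + b**2) / 2.0)
    elif normalization == "root-sum":
        out = np.clip(np.sqrt(a**2 + b**2), 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return BinocularImage(
        pixels=out,
        pixel_scale_um=img_dominant.pixel_scale_um,
        parents=(
            str(getattr(img_dominant, "meta", {}).get("blur", "")),
            str(getattr(img_nondominant, "meta", {}).get("blur", "")),
        ),
        normalization=normalization,
    )


def michelson_contrast(
    image: TargetImage | BinocularImage, bbox_px: tuple[int, int, int, int]
) -> float:
    """Michelson contrast (max-min)/(max+min) inside a bounding box."""
    r0, r1, c0, c1 = bbox_px
    patch = image.pixels[r0:r1, c0:c1]
    hi, lo = float(patch.max()), float(patch.min())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    return np.round(np.clip(pixels, 0.0, 1.0) * 65535).astype(np.uint16)


def save_png(image: TargetImage | BinocularImage, path) -> None:
    """Write 16-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(_to_uint16(image.pixels), mode="I;16").save(str(path))


def save_tiff(image: TargetImage | BinocularImage, path) -> None:
    """Write 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(str(path), _to_uint16(image.pixels))


def montage(
    panels: Sequence[np.ndarray], ncols: int, *, pad_px: int = 8, fill: float = 1.0
) -> np.ndarray:
    """Tile equally sized panels into a grid (row-major)."""
    h, w = panels[0].shape
    for p in panels:
        if p.shape != (h, w):
            raise ValueError("all panels must share one shape")
    nrows = -(-len(panels) // ncols)
    out = np.full(
        (nrows * h + (nrows + 1) * pad_px, ncols * w + (ncols + 1) * pad_px), fill
    )
    for i, p in enumerate(panels):
        r, c = divmod(i, ncols)
        r0 = pad_px + r * (h + pad_px)
        c0 = pad_px + c * (w + pad_px)
        out[r0 : r0 + h, c0 : c0 + w] = p
    return out
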