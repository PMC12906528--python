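"""Virtual optical bench for enhanced-monofocal intraocular lenses.

Builds pupil-plane wavefronts for a spherically aberrated model cornea
combined with stylised IOL designs, propagates them with scalar Fourier
optics to point-spread functions, and extracts through-focus modulation
and phase transfer functions (MTF/PTF) on the 1-150 lp/mm image-plane
frequency grid, emulating an instrument that measures an IOL behind a
model cornea over a defocus sweep at the spectacle plane.

Wavefront sign convention
-------------------------
The through-focus axis is the stimulus defocus at the spectacle plane:
negative values bring the object nearer (myopic direction).  A stimulus
defocus of ``d`` diopters (after vertex conversion to the corneal plane)
contributes the parabolic optical path ``d r^2 / 2``; a central add power
``P(r)`` contributes ``+ integral_0^r P(rho) rho drho``.  The two cancel
when ``P = -d``, so a lens with a +0.9 D central add is best corrected
near a stimulus defocus of -0.9 D, as a near-add should be.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import zernike
from .defaults import load_defaults

__all__ = [
    "ModelCornea",
    "IOLDesign",
    "BenchConfig",
    "WavefrontMap",
    "PSF",
    "TransferCurves",
    "ThroughFocusData",
    "SamplingError",
    "make_iol_design",
    "spectacle_to_corneal_defocus",
    "build_wavefront",
    "psf_from_pupil",
    "otf_from_psf",
    "through_focus_sweep",
    "emmetropic_sweep",
    "diffraction_limited_mtf",
    "photopic_wavelengths",
]

FAMILIES = ("central_add_zone", "sa_amplifying", "neutral_monofocal")

# CIE 1924 photopic luminous efficiency V(lambda) at the default
# polychromatic sample wavelengths (480-620 nm).
_PHOTOPIC_V = {
    480.0: 0.139,
    515.0: 0.608,
    546.0: 0.984,
    585.0: 0.816,
    620.0: 0.381,
}


class SamplingError(ValueError):
    """Pupil grid too coarse for the requested wavefront."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCornea:
    """Spherically aberrated model cornea of the bench.

    ``sa_coefficient_um`` is the primary-SA Zernike coefficient Z(4,0)
    specified at ``reference_diameter_mm``; evaluation at a smaller
    aperture uses the analytic concentric-scaling law.
    """

    sa_coefficient_um: float = 0.27
    reference_diameter_mm: float = 5.15

    def __post_init__(self) -> None:
        if not np.isfinite(self.sa_coefficient_um):
            raise ValueError("corneal SA coefficient must be finite")
        if self.reference_diameter_mm <= 0:
            raise ValueError("reference diameter must be positive")


@dataclass(frozen=True)
class IOLDesign:
    """Wavefront-level description of a stylised enhanced-monofocal lens.

    ``family`` selects the depth-of-focus mechanism:

    - ``central_add_zone``: a central zone of ``add_power_D`` extra power
      over ``zone_radius_mm``, decreasing linearly to zero across
      ``transition_width_mm``, monofocal beyond.
    - ``sa_amplifying``: a signed lens Z(4,0) (``sa_coefficient_um`` at
      ``sa_reference_diameter_mm``) that adds to (positive sign) or
      corrects (negative sign) the corneal spherical aberration; its
      magnitude grows by ``sa_power_slope_um_per_D`` per diopter of
      nominal power above 10 D.
    - ``neutral_monofocal``: no add, no lens SA.
    """

    name: str
    nominal_power_D: float
    family: str
    add_power_D: float = 0.0
    zone_radius_mm: float = 0.0
    transition_width_mm: float = 0.0
    sa_coefficient_um: float = 0.0
    sa_reference_diameter_mm: float = 6.0
    sa_power_slope_um_per_D: float = 0.0
    abbe_number: float = 50.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown design family {self.family!r}")
        if self.sa_power_slope_um_per_D < 0:
            raise ValueError("sa_power_slope_um_per_D must be >= 0")
        if self.zone_radius_mm < 0 or self.transition_width_mm < 0:
            raise ValueError("zone geometry must be non-negative")

    def radial_add_power(self, r_mm: np.ndarray) -> np.ndarray:
        """Add power (diopters) of the central zone at radius ``r_mm``."""
        r = np.asarray(r_mm, dtype=float)
        if self.family != "central_add_zone" or self.add_power_D == 0.0:
            return np.zeros_like(r)
        r0, t = self.zone_radius_mm, self.transition_width_mm
        if t > 0:
            frac = np.clip((r - r0) / t, 0.0, 1.0)
        else:
            frac = (r > r0).astype(float)
        return self.add_power_D * (1.0 - frac)


@dataclass(frozen=True)
class BenchConfig:
    """Settings of one virtual bench measurement run."""

    aperture_diameter_mm: float = 3.0
    wavelengths_nm: tuple[float, ...] = (546.0,)
    wavelength_weights: tuple[float, ...] = (1.0,)
    pupil_grid_n: int = 512
    defocus_start_D: float = 0.5
    defocus_stop_D: float = -2.5
    defocus_step_D: float = 0.05
    vertex_distance_mm: float = 12.0
    eye_focal_length_mm: float = 17.2
    best_focus_frequency_lpmm: float = 50.0
    frequency_max_lpmm: int = 150
    frequency_step_lpmm: int = 1
    min_samples_across_aperture: int = 64
    allow_cornea_upscale: bool = False

    def __post_init__(self) -> None:
        if self.defocus_step_D <= 0:
            raise ValueError("defocus_step_D must be positive")
        if self.pupil_grid_n & (self.pupil_grid_n - 1):
            raise ValueError("pupil_grid_n must be a power of two")
        if len(self.wavelengths_nm) != len(self.wavelength_weights):
            raise ValueError("one weight per wavelength required")
        if self.frequency_max_lpmm % self.frequency_step_lpmm:
            raise ValueError("frequency_max_lpmm must be a multiple of the step")

    def defocus_grid(self) -> np.ndarray:
        """Ascending spectacle-plane defocus grid (diopters)."""
        lo = min(self.defocus_start_D, self.defocus_stop_D)
        hi = max(self.defocus_start_D, self.defocus_stop_D)
        n = int(round((hi - lo) / self.defocus_step_D)) + 1
        return lo + self.defocus_step_D * np.arange(n)

    def frequencies_lpmm(self) -> np.ndarray:
        """Image-plane frequency grid (lp/mm), 1..150 by default."""
        step = self.frequency_step_lpmm
        return np.arange(step, self.frequency_max_lpmm + step, step, dtype=float)

    @property
    def mm_per_degree(self) -> float:
        """Image-plane millimetres subtended by one degree of visual angle."""
        return self.eye_focal_length_mm * np.tan(np.deg2rad(1.0))

    def cutoff_lpmm(self, wavelength_nm: float) -> float:
        """Incoherent diffraction cutoff at the image plane, lp/mm."""
        d_m = self.aperture_diameter_mm * 1e-3
        return d_m / (wavelength_nm * 1e-9 * self.eye_focal_length_mm * 1e-3) / 1e3


def photopic_wavelengths() -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Polychromatic wavelength sample weighted by photopic luminosity."""
    lams = tuple(sorted(_PHOTOPIC_V))
    raw = np.array([_PHOTOPIC_V[l] for l in lams])
    return lams, tuple(raw / raw.sum())


@dataclass(frozen=True)
class WavefrontMap:
    """Optical-path-difference map (micrometres) over the pupil grid."""

    opd_um: np.ndarray
    mask: np.ndarray
    pupil_radius_mm: float
    grid_step_mm: float


@dataclass(frozen=True)
class PSF:
    """Normalised point-spread-function intensity at the image plane."""

    intensity: np.ndarray
    pixel_scale_um: float
    wavelength_nm: float
    pupil_step_mm: float
    eye_focal_length_mm: float


@dataclass(frozen=True)
class TransferCurves:
    """MTF and PTF sampled on the common image-plane frequency grid."""

    frequencies_lpmm: np.ndarray
    mtf: np.ndarray
    ptf: np.ndarray
    beyond_cutoff: np.ndarray  # bool, True where the request exceeded cutoff


@dataclass
class ThroughFocusData:
    """Through-focus MTF/PTF curves with the identified best focus.

    ``mtf`` and ``ptf`` are (n_defocus, n_frequency) arrays on the
    ascending spectacle-plane defocus grid ``defocus_D``.  Defocus values
    stay on the measurement grid; the best focus is stored separately and
    the curves are never re-centred.
    """

    defocus_D: np.ndarray
    frequencies_lpmm: np.ndarray
    mtf: np.ndarray
    ptf: np.ndarray
    best_focus_D: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mtf.shape != (len(self.defocus_D), len(self.frequencies_lpmm)):
            raise ValueError("mtf shape does not match the defocus/frequency grids")
        if self.ptf.shape != self.mtf.shape:
            raise ValueError("ptf shape does not match mtf")
        if not np.any(np.isclose(self.defocus_D, self.best_focus_D)):
            raise ValueError("best_focus_D must lie on the defocus grid")

    def curves_at(self, defocus_D: float) -> TransferCurves:
        i = int(np.argmin(np.abs(self.defocus_D - defocus_D)))
        if abs(self.defocus_D[i] - defocus_D) > 1e-9:
            raise ValueError(f"defocus {defocus_D} not on the grid")
        return TransferCurves(
            self.frequencies_lpmm,
            self.mtf[i],
            self.ptf[i],
            np.zeros(len(self.frequencies_lpmm), dtype=bool),
        )


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def make_iol_design(preset: str, nominal_power_D: float) -> IOLDesign:
    """Instantiate a preset design at a nominal power.

    Presets (``quantum_like``, ``emv_like``, ``neutral_monofocal``) are
    read from the packaged defaults file.  For presets with a positive
    ``sa_power_slope_um_per_D`` the magnitude of the lens Z(4,0) grows
    linearly with nominal power above 10 D (and shrinks below, floored at
    zero), reflecting the tendency of spherical aberration to increase
    with lens power.
    """
    presets = load_defaults()["presets"]
    if preset not in presets:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(presets)}"
        )
    if not 5.0 <= nominal_power_D <= 35.0:
        raise ValueError(
            f"nominal power {nominal_power_D} D outside supported range [5, 35]"
        )
    p = dict(presets[preset])
    base_sa = float(p["sa_coefficient_um"])
    slope = float(p["sa_power_slope_um_per_D"])
    sign = 1.0 if base_sa >= 0 else -1.0
    sa = sign * max(0.0, abs(base_sa) + slope * (nominal_power_D - 10.0))
    return IOLDesign(
        name=preset,
        nominal_power_D=float(nominal_power_D),
        family=p["family"],
        add_power_D=float(p["add_power_D"]),
        zone_radius_mm=float(p["zone_radius_mm"]),
        transition_width_mm=float(p["transition_width_mm"]),
        sa_coefficient_um=sa,
        sa_reference_diameter_mm=float(p["sa_reference_diameter_mm"]),
        sa_power_slope_um_per_D=slope,
        abbe_number=float(p["abbe_number"]),
    )


def spectacle_to_corneal_defocus(d_spec: float, vertex_mm: float) -> float:
    """Propagate a spectacle-plane vergence to the corneal plane.

    Standard vergence transfer over the vertex distance ``v`` (metres):
    ``d_cornea = d_spec / (1 - v d_spec)``.
    """
    v_m = vertex_mm * 1e-3
    denom = 1.0 - v_m * d_spec
    if denom <= 0:
        raise ValueError(
            f"singular vergence transfer: 1 - v*d = {denom:.4g} for "
            f"d={d_spec} D at vertex {vertex_mm} mm"
        )
    return d_spec / denom


def _pupil_grid(cfg: BenchConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Radius map (mm), aperture mask and sample step for the embedding grid.

    The aperture spans half the embedding grid (2x zero-padding), which
    guarantees adequate frequency support for the incoherent OTF.
    """
    n = cfg.pupil_grid_n
    samples_across = n // 2
    if samples_across < cfg.min_samples_across_aperture:
        raise SamplingError(
            f"{samples_across} samples across the aperture < configured "
            f"minimum {cfg.min_samples_across_aperture}"
        )
    dx_mm = cfg.aperture_diameter_mm / samples_across
    coords = (np.arange(n) - n // 2) * dx_mm
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    r_mm = np.hypot(xx, yy)
    mask = r_mm <= cfg.aperture_diameter_mm / 2.0 * (1.0 + 1e-12)
    return r_mm, mask, dx_mm


def build_wavefront(
    design: IOLDesign,
    cornea: ModelCornea,
    cfg: BenchConfig,
    defocus_D: float,
    *,
    chromatic_offset_D: float = 0.0,
) -> WavefrontMap:
    """Pupil OPD map for cornea + lens + stimulus defocus.

    ``defocus_D`` is the stimulus vergence at the corneal plane (use
    :func:`spectacle_to_corneal_defocus` to convert spectacle-plane
    values).  Components, all in micrometres:

    - Zernike defocus ``c(2,0) = D R^2 / (4 sqrt 3)`` for the stimulus
      (plus any chromatic vergence offset),
    - the corneal Z(4,0) rescaled from its reference aperture (with the
      induced defocus cross-term of the scaling law),
    - the lens Z(4,0) rescaled from its own reference aperture,
    - the radial phase of the central add-power profile,
      ``W_add(r) = integral_0^r P_add(rho) rho drho``.

    All contributions are radial, so the map is rotationally symmetric.
    """
    radius_mm = cfg.aperture_diameter_mm / 2.0
    if design.family == "central_add_zone":
        if design.zone_radius_mm + design.transition_width_mm > radius_mm + 1e-9:
            raise ValueError(
                "add zone plus transition exceeds the aperture radius"
            )
    r_mm, mask, dx_mm = _pupil_grid(cfg)
    rho = np.clip(r_mm / radius_mm, 0.0, None)

    dc = defocus_D + chromatic_offset_D
    c20 = zernike.defocus_coefficient_um(dc, radius_mm)

    ratio_cornea = cfg.aperture_diameter_mm / cornea.reference_diameter_mm
    c40_c, c20_c = zernike.rescale_z40(
        cornea.sa_coefficient_um, ratio_cornea, allow_upscale=cfg.allow_cornea_upscale
    )
    ratio_lens = cfg.aperture_diameter_mm / design.sa_reference_diameter_mm
    c40_l, c20_l = zernike.rescale_z40(
        design.sa_coefficient_um, ratio_lens, allow_upscale=cfg.allow_cornea_upscale
    )

    opd = (c20 + c20_c + c20_l) * zernike.z20(rho)
    if c40_c or c40_l:
        opd = opd + (c40_c + c40_l) * zernike.z40(rho)

    if design.family == "central_add_zone" and design.add_power_D != 0.0:
        # W_add(r) = int_0^r P(rho) rho drho, P in diopters (1/m), r in m.
        r_fine_mm = np.linspace(0.0, radius_mm, 2049)
        p_fine = design.radial_add_power(r_fine_mm)
        w_fine_m = cumulative_trapezoid(
            p_fine * r_fine_mm * 1e-3, r_fine_mm * 1e-3, initial=0.0
        )
        opd = opd + np.interp(r_mm, r_fine_mm, w_fine_m * 1e6)

    opd = np.where(mask, opd, 0.0)
    return WavefrontMap(
        opd_um=opd, mask=mask, pupil_radius_mm=radius_mm, grid_step_mm=dx_mm
    )


def psf_from_pupil(
    wavefront: WavefrontMap,
    wavelength_nm: float,
    *,
    eye_focal_length_mm: float = 17.2,
    max_phase_step_waves: float = 0.5,
) -> PSF:
    """Incoherent PSF of a pupil wavefront by Fraunhofer propagation.

    Intensity is the squared magnitude of the discrete Fourier transform
    of ``mask * exp(i 2 pi OPD / lambda)``, normalised to unit sum.  The
    image-plane sample spacing is ``lambda f / (N dx)``.

    Raises :class:`SamplingError` when the OPD step between adjacent
    in-mask samples exceeds ``max_phase_step_waves`` wavelengths (aliased
    phase).
    """
    lam_um = wavelength_nm * 1e-3
    opd, mask = wavefront.opd_um, wavefront.mask
    both = mask[:, 1:] & mask[:, :-1]
    step = np.abs(np.diff(opd, axis=1))[both].max() if both.any() else 0.0
    bothv = mask[1:, :] & mask[:-1, :]
    if bothv.any():
        step = max(step, np.abs(np.diff(opd, axis=0))[bothv].max())
    if step > max_phase_step_waves * lam_um:
        raise SamplingError(
            f"wavefront undersampled: max OPD step {step:.3f} um exceeds "
            f"{max_phase_step_waves} waves at {wavelength_nm} nm"
        )

    pupil = np.where(mask, np.exp(2j * np.pi * opd / lam_um), 0.0)
    field = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil)))
    psf = np.abs(field) ** 2
    psf /= psf.sum()
    n = psf.shape[0]
    pixel_scale_um = (
        wavelength_nm * 1e-9 * eye_focal_length_mm * 1e-3
        / (n * wavefront.grid_step_mm * 1e-3)
    ) * 1e6
    return PSF(
        intensity=psf,
        pixel_scale_um=pixel_scale_um,
        wavelength_nm=wavelength_nm,
        pupil_step_mm=wavefront.grid_step_mm,
        eye_focal_length_mm=eye_focal_length_mm,
    )


# Imaginary OTF components below this fraction of the zero-frequency value
# are FFT round-off of a centrosymmetric PSF and are treated as exactly 0,
# so the PTF of symmetric systems is exactly 0 or pi.
_IMAG_NOISE_FLOOR = 1e-9


def _complex_otf_profile(psf: PSF) -> tuple[np.ndarray, np.ndarray]:
    """Radial complex OTF profile and its frequency axis (lp/mm)."""
    otf2 = np.fft.fft2(np.fft.ifftshift(psf.intensity))
    otf2 = otf2 / otf2[0, 0]
    n = otf2.shape[0]
    dnu_lpmm = (
        psf.pupil_step_mm * 1e-3
        / (psf.wavelength_nm * 1e-9 * psf.eye_focal_length_mm * 1e-3)
    ) / 1e3
    profile = otf2[0, : n // 2].copy()
    if np.abs(profile.imag).max() < _IMAG_NOISE_FLOOR:
        profile = profile.real.astype(complex)
    return np.arange(n // 2) * dnu_lpmm, profile


def otf_from_psf(
    psf: PSF, frequencies_lpmm: np.ndarray | None = None
) -> TransferCurves:
    """MTF and PTF on the reporting frequency grid.

    The OTF (Fourier transform of the unit-sum PSF, hence 1 at zero
    frequency) is interpolated as a complex quantity onto the requested
    image-plane frequencies; modulus and argument are extracted after
    interpolation.  Frequencies beyond the diffraction cutoff are set to
    MTF = 0, PTF = 0 and flagged.
    """
    if frequencies_lpmm is None:
        frequencies_lpmm = np.arange(1.0, 151.0)
    freqs = np.asarray(frequencies_lpmm, dtype=float)
    axis, profile = _complex_otf_profile(psf)
    re = np.interp(freqs, axis, profile.real, right=0.0)
    im = np.interp(freqs, axis, profile.imag, right=0.0)
    d_m = 2.0 * psf.pupil_step_mm * 1e-3 * (psf.intensity.shape[0] // 4)
    # cutoff from geometry: aperture diameter spans half the embedding grid
    cutoff = (
        d_m / (psf.wavelength_nm * 1e-9 * psf.eye_focal_length_mm * 1e-3) / 1e3
    )
    beyond = freqs > cutoff
    mtf = np.hypot(re, im)
    ptf = np.arctan2(im, re)
    mtf[beyond] = 0.0
    ptf[beyond] = 0.0
    if not np.all(np.isfinite(mtf)):
        raise ValueError("non-finite MTF values")
    return TransferCurves(freqs, np.clip(mtf, 0.0, 1.0), ptf, beyond)


def _chromatic_offset_D(design: IOLDesign, wavelength_nm: float) -> float:
    """Longitudinal chromatic vergence shift of the lens at ``wavelength_nm``.

    The power spread over the F-C line pair (486-656 nm) is P / V for
    Abbe number V; the shift is linear in wavelength around the 546 nm
    design point.
    """
    if wavelength_nm == 546.0:
        return 0.0
    return (
        -design.nominal_power_D
        * (wavelength_nm - 546.0)
        / (design.abbe_number * (656.0 - 486.0))
    )


def polychromatic_otf(
    design: IOLDesign,
    cornea: ModelCornea,
    cfg: BenchConfig,
    corneal_defocus_D: float,
) -> TransferCurves:
    """Luminosity-weighted OTF at one corneal-plane defocus.

    Per-wavelength complex OTFs are interpolated onto the reporting grid
    and summed with the configured weights before modulus/argument
    extraction; monochromatic configs reduce to a single term.
    """
    freqs = cfg.frequencies_lpmm()
    acc = np.zeros(len(freqs), dtype=complex)
    beyond = np.ones(len(freqs), dtype=bool)
    wsum = float(np.sum(cfg.wavelength_weights))
    for lam, w in zip(cfg.wavelengths_nm, cfg.wavelength_weights):
        wf = build_wavefront(
            design,
            cornea,
            cfg,
            corneal_defocus_D,
            chromatic_offset_D=_chromatic_offset_D(design, lam),
        )
        psf = psf_from_pupil(
            wf, lam, eye_focal_length_mm=cfg.eye_focal_length_mm
        )
        tc = otf_from_psf(psf, freqs)
        acc += (w / wsum) * tc.mtf * np.exp(1j * tc.ptf)
        beyond &= tc.beyond_cutoff
    im = acc.imag
    if np.abs(im).max() < _IMAG_NOISE_FLOOR:
        im = np.zeros_like(im)
    mtf = np.hypot(acc.real, im)
    ptf = np.arctan2(im, acc.real)
    mtf[beyond] = 0.0
    ptf[beyond] = 0.0
    return TransferCurves(freqs, np.clip(mtf, 0.0, 1.0), ptf, beyond)


def through_focus_sweep(
    design: IOLDesign,
    cornea: ModelCornea,
    cfg: BenchConfig,
    *,
    bias_D: float = 0.0,
) -> ThroughFocusData:
    """Through-focus MTF/PTF sweep over the spectacle-plane defocus grid.

    Each grid value is converted to corneal vergence before wavefront
    construction.  The best focus is the grid defocus maximising the MTF
    at ``cfg.best_focus_frequency_lpmm`` (ties broken toward 0 D); the
    curves themselves stay on the measurement grid.

    ``bias_D`` adds a constant spectacle-plane refraction to every
    stimulus before vergence conversion — the knob an emmetropia-
    targeting refraction turns (see :func:`emmetropic_sweep`).
    """
    grid = cfg.defocus_grid()
    if len(grid) == 0:
        raise ValueError("empty defocus grid")
    freqs = cfg.frequencies_lpmm()
    mtf = np.empty((len(grid), len(freqs)))
    ptf = np.empty_like(mtf)
    for i, d_spec in enumerate(grid):
        dc = spectacle_to_corneal_defocus(d_spec + bias_D, cfg.vertex_distance_mm)
        tc = polychromatic_otf(design, cornea, cfg, dc)
        mtf[i], ptf[i] = tc.mtf, tc.ptf
    if not np.all(np.isfinite(mtf)):
        raise ValueError("non-finite MTF in through-focus sweep")

    j = int(np.argmin(np.abs(freqs - cfg.best_focus_frequency_lpmm)))
    score = mtf[:, j]
    order = np.lexsort((np.abs(grid), -score))
    best = float(grid[order[0]])
    return ThroughFocusData(
        defocus_D=grid,
        frequencies_lpmm=freqs,
        mtf=mtf,
        ptf=ptf,
        best_focus_D=best,
        metadata={
            "design": design.name,
            "nominal_power_D": design.nominal_power_D,
            "aperture_mm": cfg.aperture_diameter_mm,
            "wavelengths_nm": list(cfg.wavelengths_nm),
            "vertex_distance_mm": cfg.vertex_distance_mm,
            "eye_focal_length_mm": cfg.eye_focal_length_mm,
            "best_focus_frequency_lpmm": cfg.best_focus_frequency_lpmm,
            "pupil_grid_n": cfg.pupil_grid_n,
            "bias_D": bias_D,
        },
    )


def emmetropic_sweep(
    design: IOLDesign, cornea: ModelCornea, cfg: BenchConfig
) -> ThroughFocusData:
    """Through-focus sweep of an eye refracted to emmetropia.

    Emulates the instrument procedure (and an emmetropia-targeting
    implantation): a first sweep locates the best focus, then the
    defocus grid is measured relative to it, so the reported axis is
    stimulus defocus from the eye's own far point.  With spherical
    aberration or a central add zone the best focus is not the paraxial
    zero, which is why the two-pass refraction is needed.  The pilot
    pass scans a wide symmetric grid (+/- 3 D, 0.05 D step) so the best
    focus cannot be clipped by the reporting grid.
    """
    pilot_cfg = replace(
        cfg, defocus_start_D=3.0, defocus_stop_D=-3.0, defocus_step_D=0.05
    )
    pilot = through_focus_sweep(design, cornea, pilot_cfg)
    return through_focus_sweep(design, cornea, cfg, bias_D=pilot.best_focus_D)


def diffraction_limited_mtf(
    frequencies_lpmm: np.ndarray,
    aperture_mm: float,
    wavelength_nm: float = 546.0,
    eye_focal_length_mm: float = 17.2,
) -> np.ndarray:
    """Closed-form MTF of an aberration-free circular aperture.

    ``MTF(nu) = (2/pi)(arccos nubar - nubar sqrt(1 - nubar^2))`` with
    ``nubar`` the frequency normalised by the incoherent cutoff
    ``D / (lambda f)``.
    """
    cutoff = (
        aperture_mm * 1e-3
        / (wavelength_nm * 1e-9 * eye_focal_length_mm * 1e-3)
        / 1e3
    )
    nu = np.clip(np.asarray(frequencies_lpmm, dtype=float) / cutoff, 0.0, 1.0)
    return (2.0 / np.pi) * (np.arccos(nu) - nu * np.sqrt(1.0 - nu**2))
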