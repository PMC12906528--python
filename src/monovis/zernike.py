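"""Radial Zernike terms and the concentric aperture-scaling law.

Coefficients use the Noll/ANSI normalisation for the rotationally
symmetric terms,

    Z(2,0) = sqrt(3) (2 rho^2 - 1)        (defocus)
    Z(4,0) = sqrt(5) (6 rho^4 - 6 rho^2 + 1)   (primary spherical aberration)

with ``rho`` the pupil radius normalised to 1 at the aperture edge and all
coefficients expressed in micrometres of optical path difference.
"""

from __future__ import annotations

import numpy as np

SQRT3 = np.sqrt(3.0)
SQRT5 = np.sqrt(5.0)
SQRT15 = np.sqrt(15.0)


def z20(rho: np.ndarray) -> np.ndarray:
    """Defocus polynomial Z(2,0) on the unit pupil."""
    return SQRT3 * (2.0 * rho**2 - 1.0)


def z40(rho: np.ndarray) -> np.ndarray:
    """Primary-spherical-aberration polynomial Z(4,0) on the unit pupil."""
    return SQRT5 * (6.0 * rho**4 - 6.0 * rho**2 + 1.0)


def defocus_coefficient_um(defocus_D: float, pupil_radius_mm: float) -> float:
    """Zernike defocus coefficient equivalent to a vergence error.

    A vergence error of ``D`` diopters over a pupil of radius ``R`` metres
    is the parabolic wavefront ``D r^2 / 2``, i.e. a Z(2,0) coefficient

        c(2,0) = D R^2 / (4 sqrt(3))

    (plus piston, which is irrelevant for image quality).  Returned in
    micrometres.  Positive vergence error -> positive coefficient.
    """
    r_m = pupil_radius_mm * 1e-3
    return float(defocus_D) * r_m**2 / (4.0 * SQRT3) * 1e6


def rescale_z40(
    c40_um: float, ratio: float, *, allow_upscale: bool = False
) -> tuple[float, float]:
    """Restrict a Z(4,0) coefficient to a concentric sub-aperture.

    ``ratio`` is new radius / reference radius.  Substituting
    ``rho -> ratio * rho`` into ``c40 Z40(rho)`` and re-expanding on the
    smaller pupil gives

        c40' = c40 ratio^4
        c20' = sqrt(15) c40 ratio^2 (ratio^2 - 1)   (induced defocus)

    with the piston term dropped.  Scaling *up* (``ratio > 1``)
    extrapolates beyond the aperture over which the coefficient was
    specified and must be requested explicitly.

    Returns ``(c40_new, induced_c20)`` in the units of ``c40_um``.
    """
    if not np.isfinite(c40_um):
        raise ValueError("Z(4,0) coefficient must be finite")
    if ratio <= 0:
        raise ValueError(f"aperture ratio must be positive, got {ratio}")
    if ratio > 1.0 + 1e-12 and not allow_upscale:
        raise ValueError(
            f"aperture ratio {ratio:.4f} > 1 extrapolates beyond the reference "
            "aperture; pass allow_upscale=True to permit it"
        )
    e2 = ratio**2
    return c40_um * e2 * e2, SQRT15 * c40_um * e2 * (e2 - 1.0)
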