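"""Virtual-bench unit and property tests (designs, wavefronts, PSF, OTF)."""

import numpy as np
import pytest
from dataclasses import replace

import monovis as mv
from monovis import zernike
from monovis.bench import SamplingError, polychromatic_otf


# ---------------------------------------------------------------- designs


def test_neutral_preset_has_no_add_and_no_sa():
    d = mv.make_iol_design("neutral_monofocal", 20)
    assert d.add_power_D == 0.0
    assert d.sa_coefficient_um == 0.0


def test_sa_magnitude_grows_with_power_by_slope_rule():
    lo = mv.make_iol_design("emv_like", 10)
    hi = mv.make_iol_design("emv_like", 30)
    assert abs(hi.sa_coefficient_um) == pytest.approx(
        abs(lo.sa_coefficient_um) + 20 * lo.sa_power_slope_um_per_D
    )
    assert np.sign(hi.sa_coefficient_um) == np.sign(lo.sa_coefficient_um)


def test_central_add_profile_peaks_on_axis_and_vanishes_peripherally():
    d = mv.make_iol_design("quantum_like", 20)
    r = np.linspace(0, 2.25, 500)
    p = d.radial_add_power(r)
    assert p[0] == pytest.approx(d.add_power_D)
    assert np.all(p <= d.add_power_D + 1e-12)
    outer = r >= d.zone_radius_mm + d.transition_width_mm
    assert np.allclose(p[outer], 0.0)
    # monotone non-increasing radial profile
    assert np.all(np.diff(p) <= 1e-12)


def test_unknown_preset_and_power_range_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        mv.make_iol_design("trifocal", 20)
    with pytest.raises(ValueError, match="range"):
        mv.make_iol_design("emv_like", 40)


# ----------------------------------------------------- vergence transfer


@pytest.mark.parametrize(
    "d_spec, expected",
    [(0.0, 0.0), (-2.5, -2.4272), (0.5, 0.5030)],
)
def test_spectacle_to_corneal_vergence(d_spec, expected):
    assert mv.spectacle_to_corneal_defocus(d_spec, 12.0) == pytest.approx(
        expected, abs=5e-4
    )


def test_singular_vergence_raises():
    with pytest.raises(ValueError, match="singular"):
        mv.spectacle_to_corneal_defocus(90.0, 12.0)


# ------------------------------------------------------------ wavefronts


def _fit_radial_zernikes(wf):
    """Least-squares c(0,0), c(2,0), c(4,0) of a wavefront map."""
    rho = np.hypot(*np.meshgrid(*[np.arange(wf.mask.shape[0]) - wf.mask.shape[0] // 2] * 2))
    rho = rho * wf.grid_step_mm / wf.pupil_radius_mm
    m = wf.mask
    basis = np.column_stack(
        [np.ones(m.sum()), zernike.z20(rho[m]), zernike.z40(rho[m])]
    )
    coef, *_ = np.linalg.lstsq(basis, wf.opd_um[m], rcond=None)
    return coef


def test_aberration_free_wavefront_is_flat(cfg3, cornea_perfect):
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg3, 0.0)
    assert np.abs(wf.opd_um).max() == 0.0


def test_pure_defocus_coefficient(cfg3, cornea_perfect):
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg3, 1.0)
    c0, c20, c40 = _fit_radial_zernikes(wf)
    assert c20 == pytest.approx(0.3248, abs=5e-4)
    assert c40 == pytest.approx(0.0, abs=1e-6)


def test_corneal_sa_rescaled_to_aperture(cfg3, cornea):
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea, cfg3, 0.0)
    c0, c20, c40 = _fit_radial_zernikes(wf)
    exp40, exp20 = zernike.rescale_z40(0.27, 3.0 / 5.15)
    assert c40 == pytest.approx(exp40, abs=2e-4)
    assert c20 == pytest.approx(exp20, abs=2e-3)


def test_wavefront_is_rotationally_symmetric(cfg3, cornea):
    d = mv.make_iol_design("quantum_like", 20)
    wf = mv.build_wavefront(d, cornea, cfg3, -1.0)
    # centre sits at index n/2, so symmetry is i -> n - i (drop row/col 0)
    core = wf.opd_um[1:, 1:]
    assert np.allclose(core, np.rot90(core, 2), atol=1e-12)
    assert np.allclose(wf.opd_um, wf.opd_um.T, atol=1e-12)


def test_grid_too_coarse_rejected(cornea):
    cfg = mv.BenchConfig(pupil_grid_n=64)
    d = mv.make_iol_design("neutral_monofocal", 20)
    with pytest.raises(SamplingError, match="samples across"):
        mv.build_wavefront(d, cornea, cfg, 0.0)


def test_aperture_beyond_cornea_reference_needs_override():
    cfg = mv.BenchConfig(aperture_diameter_mm=6.0)
    d = mv.make_iol_design("neutral_monofocal", 20)
    with pytest.raises(ValueError, match="allow_upscale"):
        mv.build_wavefront(d, mv.ModelCornea(), cfg, 0.0)


# ------------------------------------------------------------------- PSF


def test_psf_normalisation_and_symmetry(cfg3, cornea):
    d = mv.make_iol_design("emv_like", 20)
    wf = mv.build_wavefront(d, cornea, cfg3, -1.0)
    psf = mv.psf_from_pupil(wf, 546.0)
    assert psf.intensity.sum() == pytest.approx(1.0, abs=1e-12)
    core = psf.intensity[1:, 1:]  # centre at n/2: reflect i -> n - i
    assert np.allclose(core, np.rot90(core, 2), atol=1e-10)


def test_airy_encircled_energy(cfg3, cornea_perfect):
    """83.8% of the energy of an unaberrated PSF falls inside the first
    Airy zero at 1.22 lambda f / D (within grid resolution)."""
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg3, 0.0)
    psf = mv.psf_from_pupil(wf, 546.0)
    n = psf.intensity.shape[0]
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r_um = np.hypot(yy - c, xx - c) * psf.pixel_scale_um
    r_airy = 1.22 * 546e-9 * 17.2e-3 / 3e-3 * 1e6
    ee = psf.intensity[r_um <= r_airy].sum()
    assert ee == pytest.approx(0.838, abs=0.02)


def test_undersampled_phase_raises(cornea_perfect):
    cfg = mv.BenchConfig(pupil_grid_n=128, aperture_diameter_mm=4.5)
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg, 15.0)
    with pytest.raises(SamplingError, match="undersampled"):
        mv.psf_from_pupil(wf, 546.0)


# ------------------------------------------------------------------- OTF


@pytest.mark.parametrize("aperture", [3.0, 4.5])
def test_diffraction_limited_mtf_matches_closed_form(
    aperture, cornea_perfect
):
    cfg = mv.BenchConfig(aperture_diameter_mm=aperture)
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg, 0.0)
    psf = mv.psf_from_pupil(wf, 546.0)
    cutoff = cfg.cutoff_lpmm(546.0)
    freqs = np.linspace(1.0, 0.9 * cutoff, 200)
    tc = mv.otf_from_psf(psf, freqs)
    ref = mv.diffraction_limited_mtf(freqs, aperture)
    rms = np.sqrt(np.mean((tc.mtf - ref) ** 2))
    assert rms <= 0.01


def test_mtf_at_half_cutoff(cfg3, cornea_perfect):
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg3, 0.0)
    psf = mv.psf_from_pupil(wf, 546.0)
    tc = mv.otf_from_psf(psf, np.array([cfg3.cutoff_lpmm(546.0) / 2]))
    assert tc.mtf[0] == pytest.approx(0.3910, abs=2e-3)


def test_symmetric_wavefront_gives_real_otf(cfg3, cornea):
    d = mv.make_iol_design("quantum_like", 20)
    wf = mv.build_wavefront(d, cornea, cfg3, -2.0)
    tc = mv.otf_from_psf(mv.psf_from_pupil(wf, 546.0))
    assert np.abs(np.sin(tc.ptf)).max() < 1e-6
    assert np.all((tc.mtf >= 0) & (tc.mtf <= 1))


def test_beyond_cutoff_zeroed_and_flagged(cfg3, cornea_perfect):
    d = mv.make_iol_design("neutral_monofocal", 20)
    wf = mv.build_wavefront(d, cornea_perfect, cfg3, 0.0)
    psf = mv.psf_from_pupil(wf, 546.0)
    cutoff = cfg3.cutoff_lpmm(546.0)
    tc = mv.otf_from_psf(psf, np.array([100.0, cutoff + 10.0]))
    assert not tc.beyond_cutoff[0] and tc.beyond_cutoff[1]
    assert tc.mtf[1] == 0.0 and tc.ptf[1] == 0.0


# ---------------------------------------------------------------- sweeps


def test_sweep_cardinality_and_grid(cfg3, cornea):
    cfg = replace(cfg3, defocus_step_D=0.05)
    assert len(cfg.defocus_grid()) == 61
    d = mv.make_iol_design("emv_like", 20)
    coarse = replace(cfg3, defocus_step_D=0.5)
    tfd = mv.through_focus_sweep(d, cornea, coarse)
    assert tfd.mtf.shape == (len(coarse.defocus_grid()), 150)
    assert np.any(np.isclose(tfd.defocus_D, tfd.best_focus_D))


def test_pure_defocus_best_focus_at_zero(cornea_perfect):
    cfg = mv.BenchConfig(defocus_step_D=0.25, vertex_distance_mm=0.0)
    d = mv.make_iol_design("neutral_monofocal", 20)
    tfd = mv.through_focus_sweep(d, cornea_perfect, cfg)
    assert tfd.best_focus_D == pytest.approx(0.0)


def test_constant_power_bias_translates_best_focus(cornea_perfect):
    """A +0.5 D add over the whole aperture acts as a refraction bias:
    the through-focus peak moves to -0.5 D on the stimulus axis."""
    cfg = mv.BenchConfig(defocus_step_D=0.25, vertex_distance_mm=0.0)
    biased = mv.IOLDesign(
        name="bias", nominal_power_D=20, family="central_add_zone",
        add_power_D=0.5, zone_radius_mm=1.5, transition_width_mm=0.0,
    )
    tfd = mv.through_focus_sweep(biased, cornea_perfect, cfg)
    assert tfd.best_focus_D == pytest.approx(-0.5)


def test_emmetropic_sweep_centres_best_focus(cfg3, cornea):
    cfg = replace(cfg3, defocus_step_D=0.25)
    d = mv.make_iol_design("emv_like", 20)
    tfd = mv.emmetropic_sweep(d, cornea, cfg)
    assert abs(tfd.best_focus_D) <= 0.25 + 1e-9


def test_aberration_impact_grows_with_aperture(cornea):
    """Fixed nonzero SA hurts the best-focus MTF at 50 lp/mm more at the
    4.5-mm aperture than at 3 mm."""
    d = mv.make_iol_design("emv_like", 20)
    scores = {}
    for ap in (3.0, 4.5):
        cfg = mv.BenchConfig(aperture_diameter_mm=ap, defocus_step_D=0.25)
        tfd = mv.emmetropic_sweep(d, cornea, cfg)
        i = int(np.argmin(np.abs(tfd.defocus_D - tfd.best_focus_D)))
        scores[ap] = tfd.mtf[i, 49]
    assert scores[4.5] < scores[3.0]


def test_mtf_stable_under_grid_doubling(cornea):
    d = mv.make_iol_design("quantum_like", 20)
    vals = {}
    for n in (256, 512):
        cfg = mv.BenchConfig(pupil_grid_n=n)
        tc = polychromatic_otf(
            d, cornea, cfg, mv.spectacle_to_corneal_defocus(-1.0, 12.0)
        )
        vals[n] = tc.mtf
    assert np.abs(vals[256] - vals[512]).max() < 0.005
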