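"""End-to-end experiment driver over the design x power x aperture grid."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import acuity, bench, images, io, monovision
from .defaults import load_defaults

__all__ = ["ExperimentConfig", "run_pipeline"]

STAGES = ("bench", "curves", "monovision", "images")


@dataclass
class ExperimentConfig:
    """One reproducible comparison run.

    ``bench`` and ``acuity`` hold keyword overrides for
    :class:`~monovis.bench.BenchConfig` and
    :class:`~monovis.acuity.AcuityConfig`; unknown keys anywhere fail
    fast.  ``seed`` is reserved for stochastic extensions (the default
    pipeline is fully deterministic).
    """

    designs: tuple[str, ...] = ("quantum_like", "emv_like")
    powers_D: tuple[float, ...] = (10.0, 20.0, 30.0)
    apertures_mm: tuple[float, ...] = (3.0, 4.5)
    offsets_D: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    cutoffs_logmar: tuple[float, ...] = (0.1, 0.2)
    output_dir: str = "runs/default"
    seed: int = 0
    bench: dict[str, Any] = field(default_factory=dict)
    acuity: dict[str, Any] = field(default_factory=dict)
    images: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        for sub, target in (("bench", bench.BenchConfig), ("acuity", acuity.AcuityConfig)):
            if sub in raw and raw[sub]:
                tf = {f.name for f in fields(target)}
                bad = sorted(set(raw[sub]) - tf)
                if bad:
                    raise ValueError(
                        f"unknown {sub} config key(s): {', '.join(bad)}"
                    )
        cfg = cls(**raw)
        for name in ("designs", "powers_D", "apertures_mm", "offsets_D",
                     "cutoffs_logmar"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), "utf-8")

    def bench_config(self, aperture_mm: float) -> bench.BenchConfig:
        kw = dict(self.bench)
        for key in ("wavelengths_nm", "wavelength_weights"):
            if key in kw:
                kw[key] = tuple(kw[key])
        kw["aperture_diameter_mm"] = aperture_mm
        return bench.BenchConfig(**kw)

    def acuity_config(self) -> acuity.AcuityConfig:
        return acuity.AcuityConfig(**self.acuity)

    def image_settings(self) -> dict[str, Any]:
        d = {
            "enabled": True,
            "size_px": 576,
            "pixel_scale_um": 2.0,
            "defocus_levels_D": (0.0, -1.0, -2.0),
            "usaf_elements": ((3, 1), (4, 1), (4, 4)),
            "image_offset_D": 1.0,
        }
        d.update(self.images)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: ExperimentConfig, stages: tuple[str, ...] = STAGES
) -> dict[str, Any]:
    """Run the requested stages for every design x power x aperture.

    Artifacts per combination: through-focus CSV, binocular and monocular
    defocus-curve CSVs, per-offset binocular CSVs plus a summary table,
    and USAF panels (3-mm aperture).  A manifest listing every file with
    its SHA-256 checksum, alongside an echo of the full configuration and
    every physical constant used, is written to the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: list[Path] = [out / "config.yaml"]

    defaults = load_defaults()
    cornea = bench.ModelCornea(**defaults["physical"]["cornea"])
    acuity_cfg = config.acuity_config()
    model = monovision.BinocularEffectModel()
    summary_rows = []

    for aperture in config.apertures_mm:
        bcfg = config.bench_config(aperture)
        csf = acuity.default_csf(bcfg, acuity_cfg)
        for name in config.designs:
            for power in config.powers_D:
                design = bench.make_iol_design(name, power)
                tag = f"{name}_{power:g}D_{aperture:g}mm"
                tfd = bench.emmetropic_sweep(design, cornea, bcfg)
                if "bench" in stages:
                    p = out / f"throughfocus_{tag}.csv"
                    io.write_bench_csv(tfd, p)
                    artifacts.append(p)
                if not ({"curves", "monovision", "images"} & set(stages)):
                    continue
                curve_bin = acuity.defocus_curve(tfd, csf, acuity_cfg)
                curve_mono = acuity.to_monocular(curve_bin, acuity_cfg)
                if "curves" in stages:
                    for cal, cv in (("binocular", curve_bin), ("monocular", curve_mono)):
                        p = out / f"defocus_{cal}_{tag}.csv"
                        io.write_defocus_csv(cv, p)
                        artifacts.append(p)
                    artifacts.append(
                        _plot_curve(curve_bin, out / f"defocus_{tag}.png")
                    )
                if "monovision" in stages:
                    bias = tfd.metadata.get("bias_D", 0.0)
                    plano = monovision.combine_binocular(
                        monovision.make_scenario(curve_mono, 0.0), model
                    )
                    for off in config.offsets_D:
                        nd_far = _myopic_eye_distance_va(
                            design, cornea, bcfg, csf, acuity_cfg, off, bias
                        )
                        bc = monovision.combine_binocular(
                            monovision.make_scenario(
                                curve_mono, off,
                                nondominant_distance_va=nd_far,
                            ),
                            model,
                        )
                        p = out / f"binocular_{tag}_offset{off:g}D.csv"
                        io.write_binocular_csv(bc, p)
                        artifacts.append(p)
                        row = {
                            "design": name,
                            "power_D": power,
                            "aperture_mm": aperture,
                            "offset_D": off,
                        }
                        row.update(monovision.scenario_report(plano, bc))
                        summary_rows.append(row)
                if "images" in stages and aperture == min(config.apertures_mm):
                    artifacts.extend(
                        _image_stage(design, cornea, bcfg, config, out, tag,
                                     tfd.metadata.get("bias_D", 0.0))
                    )

    if summary_rows:
        p = out / "monovision_summary.csv"
        pd.DataFrame(summary_rows).to_csv(p, index=False, float_format="%.17g")
        artifacts.append(p)

    constants = {
        "vertex_distance_mm": defaults["physical"]["vertex_distance_mm"],
        "eye_focal_length_mm": defaults["physical"]["eye_focal_length_mm"],
        "cornea": defaults["physical"]["cornea"],
        "csf": defaults["csf"],
        "acuity": defaults["acuity"],
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "constants": constants,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str), "utf-8")
    return manifest


def _myopic_eye_distance_va(
    design, cornea, bcfg, csf, acuity_cfg, offset_D: float, bias_D: float
) -> float:
    """Monocular distance VA of the eye with a myopic target.

    One extra bench evaluation at stimulus +offset (relative to the
    emmetropic refraction), needed because offsets beyond the hyperopic
    end of the measured grid cannot be interpolated from the shifted
    curve."""
    dc = bench.spectacle_to_corneal_defocus(
        offset_D + bias_D, bcfg.vertex_distance_mm
    )
    tc = bench.polychromatic_otf(design, cornea, bcfg, dc)
    w = acuity.wotf(tc.mtf, tc.ptf, csf, acuity_cfg)
    try:
        va = acuity.simva_from_wotf(w, acuity_cfg)
    except acuity.UndefinedAcuityError:
        return float("nan")
    return float(acuity.monocular_simva(va, acuity_cfg))


def _plot_curve(curve, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.defocus_D, curve.logmar, "o-", ms=3)
    ax.invert_yaxis()
    ax.set_xlabel("defocus at spectacle plane (D)")
    ax.set_ylabel("simVA (logMAR)")
    prov = curve.provenance
    ax.set_title(
        f"{prov.get('design', '')} {prov.get('nominal_power_D', '')} D, "
        f"{prov.get('aperture_mm', '')} mm",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _image_stage(
    design, cornea, bcfg, config, out: Path, tag: str, bias_D: float = 0.0
) -> list[Path]:
    """Blurred USAF panels and their quadratic binocular sums."""
    st = config.image_settings()
    if not st["enabled"]:
        return []
    target = images.generate_usaf_target(
        tuple(tuple(e) for e in st["usaf_elements"]),
        st["pixel_scale_um"],
        st["size_px"],
    )
    off = st["image_offset_D"]
    panels, artifacts = [], []
    for d_spec in st["defocus_levels_D"]:
        pair = []
        for eye_shift in (0.0, off):
            dc = bench.spectacle_to_corneal_defocus(
                d_spec + eye_shift + bias_D, bcfg.vertex_distance_mm
            )
            wf = bench.build_wavefront(design, cornea, bcfg, dc)
            psf = bench.psf_from_pupil(
                wf, bcfg.wavelengths_nm[0],
                eye_focal_length_mm=bcfg.eye_focal_length_mm,
            )
            pair.append(images.blur_with_psf(target, psf, d_spec))
        binoc = images.quadratic_sum(pair[0], pair[1])
        panels.extend([pair[0].pixels, pair[1].pixels, binoc.pixels])
        p = out / f"usaf_{tag}_stim{d_spec:g}D_binocular.png"
        images.save_png(binoc, p)
        artifacts.append(p)
    grid = images.montage(panels, ncols=3)
    p = out / f"usaf_{tag}_montage.png"
    images.save_png(
        images.BinocularImage(grid, st["pixel_scale_um"]), p
    )
    artifacts.append(p)
    return artifacts
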