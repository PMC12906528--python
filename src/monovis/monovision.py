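"""Mini-monovision: curve shifting, binocular summation, depth of focus.

The non-dominant eye's monocular defocus curve is shifted by a small
myopic offset (0.25-1.0 D); the two eyes are combined node by node with
an empirical binocular-effect regression

    BE = 1.17 - 0.24 dVA - 0.11 avgVA - 0.07 Offset

(dVA the absolute interocular logMAR difference, avgVA the mean logMAR
at that defocus level, Offset the refractive offset in diopters), and
the factor multiplies the better eye's decimal acuity:
``logMAR_bin = min(L, R) - log10(BE)``.  Depth of focus is the width of
the defocus range kept at or below a logMAR cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .acuity import DefocusCurve

__all__ = [
    "BinocularEffectModel",
    "MonovisionScenario",
    "BinocularCurve",
    "FocusRange",
    "NodeFlag",
    "shift_defocus_curve",
    "binocular_effect",
    "make_scenario",
    "combine_binocular",
    "depth_of_focus",
    "scenario_report",
]


class NodeFlag:
    """Per-node status codes of a binocular combination."""

    OK = 0
    SINGLE_EYE = 1       # one eye missing; monocular value kept with BE = 1
    NONPOSITIVE_BE = 2   # regression factor <= 0; node undefined
    MISSING = 3          # both eyes missing


@dataclass(frozen=True)
class BinocularEffectModel:
    """The four-coefficient binocular-summation regression.

    ``offset_as_magnitude`` fixes the ambiguity of the Offset term's
    sign: by default the magnitude in diopters enters the regression, so
    a larger interocular offset always lowers the summation factor.
    """

    intercept: float = 1.17
    coef_delta_va: float = -0.24
    coef_avg_va: float = -0.11
    coef_offset: float = -0.07
    offset_as_magnitude: bool = True


@dataclass
class MonovisionScenario:
    """One myopic-offset condition: dominant eye plano, fellow eye shifted.

    ``nondominant_distance_va`` optionally carries a directly measured
    monocular distance VA of the myopic eye (its plano curve at
    +offset); when the offset exceeds the hyperopic headroom of the
    measured grid this value cannot be interpolated from the shifted
    curve and would otherwise be missing.
    """

    offset_D: float
    dominant_curve: DefocusCurve
    nondominant_curve: DefocusCurve
    nondominant_distance_va: float | None = None

    def __post_init__(self) -> None:
        if self.offset_D < 0:
            raise ValueError("offset is a non-negative magnitude in diopters")
        for c in (self.dominant_curve, self.nondominant_curve):
            if c.calibration != "monocular":
                raise ValueError(
                    "binocular combination requires monocular-calibrated curves"
                )
        if not np.array_equal(
            self.dominant_curve.defocus_D, self.nondominant_curve.defocus_D
        ):
            raise ValueError("eyes must share the defocus grid")


@dataclass
class BinocularCurve:
    """Binocular defocus curve with its per-node summation audit trail."""

    defocus_D: np.ndarray
    logmar: np.ndarray
    be_factor: np.ndarray
    delta_va: np.ndarray
    avg_va: np.ndarray
    flags: np.ndarray
    offset_D: float = 0.0
    nondominant_distance_va: float = float("nan")
    provenance: dict[str, Any] = field(default_factory=dict)

    def at(self, defocus_D: float) -> float:
        return float(
            np.interp(defocus_D, self.defocus_D, self.logmar,
                      left=np.nan, right=np.nan)
        )


@dataclass(frozen=True)
class FocusRange:
    """Defocus intervals where the curve stays at or below a cut-off."""

    cutoff_logmar: float
    intervals: tuple[tuple[float, float], ...]
    width_D: float


def shift_defocus_curve(curve: DefocusCurve, offset_D: float) -> DefocusCurve:
    """Defocus curve of an eye with a myopic refractive offset.

    The shifted eye's VA at stimulus defocus ``x`` equals the plano
    curve at ``x + offset``, so its best focus moves to ``-offset`` on
    the shared axis.  Values needing support beyond the original grid
    are NaN; the result is resampled onto the original grid by linear
    interpolation.
    """
    if not np.isfinite(offset_D):
        raise ValueError("offset must be finite")
    span = curve.defocus_D[-1] - curve.defocus_D[0]
    if abs(offset_D) > span:
        raise ValueError(
            f"offset {offset_D} D exceeds the grid span {span:.2f} D: "
            "no overlapping support"
        )
    if offset_D == 0.0:
        shifted = curve.logmar.copy()
    else:
        finite = np.isfinite(curve.logmar)
        x = curve.defocus_D + offset_D
        shifted = np.interp(
            x, curve.defocus_D, curve.logmar, left=np.nan, right=np.nan
        )
        # NaN poisoning: mark nodes whose interpolation support is missing
        if not finite.all():
            lo = np.interp(x, curve.defocus_D, finite.astype(float),
                           left=0.0, right=0.0)
            shifted[lo < 1.0] = np.nan
    prov = dict(curve.provenance)
    prov["myopic_offset_D"] = prov.get("myopic_offset_D", 0.0) + offset_D
    return DefocusCurve(
        defocus_D=curve.defocus_D.copy(),
        logmar=shifted,
        calibration=curve.calibration,
        provenance=prov,
    )


def binocular_effect(
    delta_va, avg_va, offset_D, model: BinocularEffectModel | None = None
):
    """Summation factor predicted by the regression; scalar or array."""
    model = model or BinocularEffectModel()
    d = np.asarray(delta_va, dtype=float)
    a = np.asarray(avg_va, dtype=float)
    o = np.asarray(offset_D, dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(a))
            and np.all(np.isfinite(o))):
        raise ValueError("non-finite regression inputs")
    if np.any(d < 0):
        raise ValueError("interocular VA difference is a magnitude, >= 0")
    if model.offset_as_magnitude:
        o = np.abs(o)
    be = (
        model.intercept
        + model.coef_delta_va * d
        + model.coef_avg_va * a
        + model.coef_offset * o
    )
    return float(be) if np.isscalar(delta_va) else be


def make_scenario(
    monocular_curve: DefocusCurve,
    offset_D: float,
    *,
    nondominant_distance_va: float | None = None,
) -> MonovisionScenario:
    """Bilateral-implantation scenario from one monocular plano curve."""
    return MonovisionScenario(
        offset_D=offset_D,
        dominant_curve=monocular_curve,
        nondominant_curve=shift_defocus_curve(monocular_curve, offset_D),
        nondominant_distance_va=nondominant_distance_va,
    )


def combine_binocular(
    scenario: MonovisionScenario, model: BinocularEffectModel | None = None
) -> BinocularCurve:
    """Binocular defocus curve of a monovision scenario.

    At each node: dVA = |L - R|, avgVA = (L + R)/2, BE from the
    regression, and the binocular decimal acuity is BE times the better
    eye's, i.e. ``logMAR_bin = min(L, R) - log10(BE)``.  A node with one
    missing eye falls back to the seeing eye with BE = 1 (flagged); a
    non-positive BE leaves the node undefined (flagged).
    """
    model = model or BinocularEffectModel()
    left = scenario.dominant_curve.logmar
    right = scenario.nondominant_curve.logmar
    n = len(left)
    logmar = np.full(n, np.nan)
    be = np.full(n, np.nan)
    delta = np.full(n, np.nan)
    avg = np.full(n, np.nan)
    flags = np.full(n, NodeFlag.MISSING, dtype=int)

    lf, rf = np.isfinite(left), np.isfinite(right)
    both = lf & rf
    delta[both] = np.abs(left[both] - right[both])
    avg[both] = (left[both] + right[both]) / 2.0
    be[both] = binocular_effect(delta[both], avg[both], scenario.offset_D, model)
    ok = both & (be > 0)
    logmar[ok] = np.minimum(left[ok], right[ok]) - np.log10(be[ok])
    flags[ok] = NodeFlag.OK
    flags[both & ~ok] = NodeFlag.NONPOSITIVE_BE

    single = lf ^ rf
    logmar[single] = np.where(lf[single], left[single], right[single])
    be[single] = 1.0
    flags[single] = NodeFlag.SINGLE_EYE

    if not np.any(lf | rf):
        raise ValueError("no overlapping support between the two eyes")

    if scenario.nondominant_distance_va is not None:
        nd_far = float(scenario.nondominant_distance_va)
    else:
        nd_far = float(
            np.interp(0.0, scenario.nondominant_curve.defocus_D,
                      scenario.nondominant_curve.logmar)
        )
    return BinocularCurve(
        defocus_D=scenario.dominant_curve.defocus_D.copy(),
        logmar=logmar,
        be_factor=be,
        delta_va=delta,
        avg_va=avg,
        flags=flags,
        offset_D=scenario.offset_D,
        nondominant_distance_va=nd_far,
        provenance={
            "offset_D": scenario.offset_D,
            "model": {
                "intercept": model.intercept,
                "coef_delta_va": model.coef_delta_va,
                "coef_avg_va": model.coef_avg_va,
                "coef_offset": model.coef_offset,
                "offset_as_magnitude": model.offset_as_magnitude,
            },
            **{k: v for k, v in scenario.dominant_curve.provenance.items()},
        },
    )


def depth_of_focus(
    curve: DefocusCurve | BinocularCurve, cutoff_logmar: float
) -> FocusRange:
    """Defocus range(s) with VA at or better than the cut-off.

    Crossings between grid nodes are located by linear interpolation;
    multiple sub-threshold intervals are allowed and their widths summed.
    NaN nodes count as above the cut-off.  A curve entirely above the
    cut-off yields an empty range of width 0.
    """
    if not np.isfinite(cutoff_logmar):
        raise ValueError("cutoff must be finite")
    x = np.asarray(curve.defocus_D, dtype=float)
    y = np.asarray(curve.logmar, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two nodes")
    y = np.where(np.isfinite(y), y, np.inf)
    below = y <= cutoff_logmar

    intervals: list[tuple[float, float]] = []
    start: float | None = None
    for i in range(len(x)):
        if below[i] and start is None:
            if i > 0 and np.isfinite(y[i - 1]):
                # crossing between i-1 (above) and i (below)
                t = (cutoff_logmar - y[i - 1]) / (y[i] - y[i - 1])
                start = x[i - 1] + t * (x[i] - x[i - 1])
            else:
                start = x[i]
        elif not below[i] and start is not None:
            if np.isfinite(y[i]):
                t = (cutoff_logmar - y[i - 1]) / (y[i] - y[i - 1])
                end = x[i - 1] + t * (x[i] - x[i - 1])
            else:
                end = x[i - 1]
            intervals.append((start, end))
            start = None
    if start is not None:
        intervals.append((start, x[-1]))
    width = float(sum(b - a for a, b in intervals))
    return FocusRange(cutoff_logmar, tuple(intervals), width)


REPORT_FIELDS = (
    "improvement_at_minus_2D",
    "far_distance_penalty",
    "dof_width_0p1_D",
    "dof_width_0p2_D",
    "nondominant_distance_va",
)


def scenario_report(
    plano: BinocularCurve, mono: BinocularCurve
) -> dict[str, float]:
    """Headline summary of a monovision scenario against bilateral plano.

    Fields: simVA improvement at -2.0 D (positive = monovision better),
    far-distance (0 D) penalty, binocular depth-of-focus widths at the
    0.1 and 0.2 logMAR cut-offs, and the non-dominant eye's monocular
    distance VA (its shifted curve evaluated at 0 D).
    """
    if not np.array_equal(plano.defocus_D, mono.defocus_D):
        raise ValueError("curves must share the defocus grid")
    return {
        "improvement_at_minus_2D": plano.at(-2.0) - mono.at(-2.0),
        "far_distance_penalty": mono.at(0.0) - plano.at(0.0),
        "dof_width_0p1_D": depth_of_focus(mono, 0.1).width_D,
        "dof_width_0p2_D": depth_of_focus(mono, 0.2).width_D,
        "nondominant_distance_va": mono.nondominant_distance_va,
    }
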