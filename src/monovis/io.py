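"""CSV round-tripping for bench data and curves, plus config parsing.

Bench CSV dialect: columns ``defocus_D, frequency_lpmm, mtf, ptf_rad``,
one header line, UTF-8, '.' decimal separator — the entry point for
externally measured instrument exports as well as for the synthetic
bench's own output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acuity import DefocusCurve
from .bench import ThroughFocusData
from .monovision import BinocularCurve

__all__ = [
    "SchemaError",
    "write_bench_csv",
    "read_bench_csv",
    "write_defocus_csv",
    "write_binocular_csv",
]

BENCH_COLUMNS = ("defocus_D", "frequency_lpmm", "mtf", "ptf_rad")


class SchemaError(ValueError):
    """Malformed or incomplete tabular input."""


def write_bench_csv(data: ThroughFocusData, path) -> None:
    """Write through-focus MTF/PTF in long format, full float precision."""
    nd, nf = data.mtf.shape
    df = pd.DataFrame(
        {
            "defocus_D": np.repeat(data.defocus_D, nf),
            "frequency_lpmm": np.tile(data.frequencies_lpmm, nd),
            "mtf": data.mtf.ravel(),
            "ptf_rad": data.ptf.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_bench_csv(
    path, *, best_focus_frequency_lpmm: float = 50.0
) -> ThroughFocusData:
    """Read a bench CSV back into :class:`ThroughFocusData`.

    The best focus is recomputed from the data at
    ``best_focus_frequency_lpmm`` (ties toward 0 D), since the dialect
    carries measurements only.  Malformed rows are reported with their
    line numbers.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    missing = [c for c in BENCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    bad_lines = []
    for col in BENCH_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        raise SchemaError(
            f"{path}: malformed values on line(s) {sorted(set(bad_lines))}"
        )

    defocus = np.sort(df["defocus_D"].unique())
    freqs = None
    mtf_rows, ptf_rows = [], []
    for d in defocus:
        sub = df[df["defocus_D"] == d].sort_values("frequency_lpmm")
        f = sub["frequency_lpmm"].to_numpy()
        if np.any(np.diff(f) <= 0):
            raise SchemaError(f"{path}: non-monotone frequency grid at {d} D")
        if freqs is None:
            freqs = f
        elif not np.array_equal(freqs, f):
            raise SchemaError(f"{path}: inconsistent frequency grid at {d} D")
        mtf_rows.append(sub["mtf"].to_numpy())
        ptf_rows.append(sub["ptf_rad"].to_numpy())

    mtf = np.vstack(mtf_rows)
    ptf = np.vstack(ptf_rows)
    j = int(np.argmin(np.abs(freqs - best_focus_frequency_lpmm)))
    order = np.lexsort((np.abs(defocus), -mtf[:, j]))
    return ThroughFocusData(
        defocus_D=defocus,
        frequencies_lpmm=freqs,
        mtf=mtf,
        ptf=ptf,
        best_focus_D=float(defocus[order[0]]),
        metadata={"source": str(path)},
    )


def write_defocus_csv(curve: DefocusCurve, path) -> None:
    """Write a defocus curve with its provenance labels."""
    prov = curve.provenance
    pd.DataFrame(
        {
            "defocus_D": curve.defocus_D,
            "logmar": curve.logmar,
            "calibration": curve.calibration,
            "design": prov.get("design", ""),
            "power_D": prov.get("nominal_power_D", np.nan),
            "aperture_mm": prov.get("aperture_mm", np.nan),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_binocular_csv(curve: BinocularCurve, path) -> None:
    """Write a binocular curve with its per-node summation audit columns."""
    pd.DataFrame(
        {
            "defocus_D": curve.defocus_D,
            "logmar_bin": curve.logmar,
            "be_factor": curve.be_factor,
            "delta_va": curve.delta_va,
            "avg_va": curve.avg_va,
            "flag": curve.flags,
        }
    ).to_csv(path, index=False, float_format="%.17g")
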