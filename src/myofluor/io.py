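"""CSV/JSON readers and writers for the pipeline's file formats.

All formats are plain delimited text:

- histogram CSV: columns ``time_ns,counts`` (one channel, one acquisition)
- long-format histogram CSV: ``heart_id,time_s,channel,bin_index,counts``
- IRF CSV: ``time_ns,weight``
- spectrum CSV: ``wavelength_nm,intensity``
- fit CSV: one row per (heart, time, channel) with the fitted decay
  parameters and derived metrics
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import BiExpFit, BiExpParams, DecayHistogram, InstrumentResponse
from .reflectance import AbsorbanceSpectrum, ReflectanceSpectrum

__all__ = [
    "read_histogram_csv",
    "write_histogram_csv",
    "read_long_histogram_csv",
    "read_irf_csv",
    "write_irf_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_absorbance_csv",
    "read_absorbance_csv",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
    "write_json",
]

FIT_COLUMNS = [
    "heart_id",
    "time_s",
    "channel",
    "a1",
    "a2",
    "tau1",
    "tau2",
    "background",
    "afterpulse",
    "tau_mean",
    "alpha1",
    "chi2",
    "reduced_chi2",
    "converged",
    "total_counts",
]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _check_nonnegative(df: pd.DataFrame, column: str, path: Path | str) -> None:
    bad = df.index[df[column] < 0]
    if len(bad):
        # +2 converts the 0-based data index to the 1-based file line (header on line 1)
        raise ValueError(
            f"{path}: negative {column} on line {int(bad[0]) + 2}"
        )


def read_histogram_csv(
    path: str | Path,
    period: float = 50.0,
    channel_id: str = "CH2",
    acquisition_time: float = 1.0,
) -> DecayHistogram:
    df = _read_table(path, ["time_ns", "counts"])
    _check_nonnegative(df, "counts", path)
    t = df["time_ns"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: histogram needs at least 2 bins")
    widths = np.diff(t)
    if not np.allclose(widths, widths[0]):
        raise ValueError(f"{path}: time bins must be uniform")
    return DecayHistogram(
        df["counts"].to_numpy(),
        bin_width=float(widths[0]),
        period=period,
        channel_id=channel_id,
        acquisition_time=acquisition_time,
    )


def write_histogram_csv(hist: DecayHistogram, path: str | Path) -> None:
    pd.DataFrame({"time_ns": hist.times, "counts": hist.counts}).to_csv(path, index=False)


def read_long_histogram_csv(
    path: str | Path, period: float = 50.0
) -> dict[tuple[str, float, str], DecayHistogram]:
    """Split a long-format multi-channel file into individual histograms.

    Returns a mapping (heart_id, time_s, channel) -> DecayHistogram. The
    bin width is inferred from the period and the number of bins.
    """
    df = _read_table(path, ["heart_id", "time_s", "channel", "bin_index", "counts"])
    _check_nonnegative(df, "counts", path)
    out = {}
    for (heart, t, ch), grp in df.groupby(["heart_id", "time_s", "channel"], sort=True):
        grp = grp.sort_values("bin_index")
        n = len(grp)
        if not np.array_equal(grp["bin_index"].to_numpy(), np.arange(n)):
            raise ValueError(f"{path}: non-contiguous bin_index for {heart}/{t}/{ch}")
        out[(str(heart), float(t), str(ch))] = DecayHistogram(
            grp["counts"].to_numpy(),
            bin_width=period / n,
            period=period,
            channel_id=str(ch),
        )
    return out


def read_irf_csv(path: str | Path, channel_id: str = "CH2") -> InstrumentResponse:
    df = _read_table(path, ["time_ns", "weight"])
    _check_nonnegative(df, "weight", path)
    return InstrumentResponse(df["weight"].to_numpy(dtype=float), channel_id=channel_id)


def write_irf_csv(
    irf: InstrumentResponse, path: str | Path, bin_width: float = 50.0 / 1024
) -> None:
    t = np.arange(irf.n_bins) * bin_width
    pd.DataFrame({"time_ns": t, "weight": irf.weights}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, role: str = "sample") -> ReflectanceSpectrum:
    df = _read_table(path, ["wavelength_nm", "intensity"])
    _check_nonnegative(df, "intensity", path)
    return ReflectanceSpectrum(
        df["wavelength_nm"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        role=role,
    )


def write_spectrum_csv(spec: ReflectanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}
    ).to_csv(path, index=False)


def write_absorbance_csv(spec: AbsorbanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "absorbance": spec.absorbance}
    ).to_csv(path, index=False)


def read_absorbance_csv(path: str | Path) -> AbsorbanceSpectrum:
    df = _read_table(path, ["wavelength_nm", "absorbance"])
    return AbsorbanceSpectrum(
        df["wavelength_nm"].to_numpy(dtype=float),
        df["absorbance"].to_numpy(dtype=float),
    )


def fits_to_frame(
    fits: list[tuple[str, float, str, BiExpFit, int]]
) -> pd.DataFrame:
    """Rows of (heart_id, time_s, channel, fit, total_counts) to a tidy frame."""
    rows = []
    for heart, t, ch, fit, total in fits:
        p = fit.params
        rows.append(
            {
                "heart_id": heart,
                "time_s": t,
                "channel": ch,
                "a1": p.a1,
                "a2": p.a2,
                "tau1": p.tau1,
                "tau2": p.tau2,
                "background": p.background,
                "afterpulse": p.afterpulse,
                "tau_mean": fit.tau_mean,
                "alpha1": fit.alpha1,
                "chi2": fit.chi2,
                "reduced_chi2": fit.reduced_chi2,
                "converged": fit.converged,
                "total_counts": total,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fits_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_fits_csv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, FIT_COLUMNS[:3] + ["tau_mean", "alpha1"])


def frame_to_fits(df: pd.DataFrame) -> list[tuple[str, float, str, BiExpFit, int]]:
    """Inverse of :func:`fits_to_frame`."""
    out = []
    for _, row in df.iterrows():
        params = BiExpParams(
            a1=row["a1"],
            a2=row["a2"],
            tau1=row["tau1"],
            tau2=row["tau2"],
            background=row.get("background", 0.0),
            afterpulse=row.get("afterpulse", 0.0),
        )
        fit = BiExpFit(
            params=params,
            tau_mean=row["tau_mean"],
            alpha1=row["alpha1"],
            chi2=row.get("chi2", np.nan),
            reduced_chi2=row.get("reduced_chi2", np.nan),
            converged=bool(row.get("converged", True)),
            n_iterations=0,
        )
        out.append(
            (row["heart_id"], float(row["time_s"]), row["channel"], fit,
             int(row.get("total_counts", 0)))
        )
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
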