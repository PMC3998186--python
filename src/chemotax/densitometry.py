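"""Densitometric calibration and verbascoside quantification.

A four-level standard curve relates densitometer peak area to concentration;
unknowns are quantified by inverse prediction.  The regression is fitted with
concentration as the response and area as the predictor, which is the
direction that reproduces the study-style reported tables, and reported
concentrations are rounded to one decimal by convention of those tables.

CSV dialects: standards ``level,concentration,area``; sample tracks
``sample,replicate,area,rf`` (``rf`` optional, blank allowed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "predict_concentration",
    "quantify",
    "check_specificity",
    "linearity_report",
    "read_standards",
    "read_tracks",
    "write_quant_report",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear area -> concentration map with fit diagnostics.

    slope is in concentration units per area unit; intercept and residual_sd
    are in concentration units.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_standards: int

    def predict(self, area: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(area, dtype=float) + self.intercept


def read_standards(path: str | Path) -> pd.DataFrame:
    """Read a standards CSV with columns ``level,concentration,area``."""
    df = pd.read_csv(path)
    missing = {"concentration", "area"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: standards CSV missing columns {sorted(missing)}")
    if (df["concentration"] <= 0).any() or (df["area"] <= 0).any():
        raise ValueError(f"{path}: concentrations and areas must be positive")
    return df


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a sample-tracks CSV with columns ``sample,replicate,area[,rf]``."""
    df = pd.read_csv(path)
    missing = {"sample", "area"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tracks CSV missing columns {sorted(missing)}")
    if (df["area"] <= 0).any():
        raise ValueError(f"{path}: peak areas must be positive")
    return df


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Ordinary least squares of concentration on peak area.

    Parameters
    ----------
    standards
        Frame with ``concentration`` and ``area`` columns (one row per
        measured standard; replicate rows per level are allowed).
    """
    conc = np.asarray(standards["concentration"], dtype=float)
    area = np.asarray(standards["area"], dtype=float)
    if len(conc) < 2:
        raise ValueError("calibration needs at least 2 standard points")
    if np.ptp(area) == 0:
        raise ValueError("all standard areas are equal; slope is undefined")
    fit = stats.linregress(area, conc)
    resid = conc - (fit.slope * area + fit.intercept)
    dof = max(len(conc) - 2, 1)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_standards=len(conc),
    )


def predict_concentration(
    curve: CalibrationCurve, area: float, decimals: int | None = 1
) -> float:
    """Inverse-predict a concentration from a peak area.

    Rounds to ``decimals`` (default one decimal, the reporting convention);
    pass ``decimals=None`` for the raw value.  A negative prediction is
    flagged with a below-range warning but still returned.
    """
    value = float(curve.predict(area))
    if value < 0:
        warnings.warn(
            f"predicted concentration {value:.4g} is below the calibrated range",
            stacklevel=2,
        )
    return round(value, decimals) if decimals is not None else value


def quantify(
    curve: CalibrationCurve,
    tracks: pd.DataFrame,
    decimals: int | None = 1,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample mean +/- SD concentration from replicate tracks.

    Each replicate area is converted through the calibration; the sample SD
    (ddof=1; zero for a single replicate) is computed on the unrounded
    replicate concentrations, then mean and SD are rounded for reporting.

    Returns a frame indexed by sample with columns ``mean_concentration``,
    ``sd``, ``n_replicates``, ``mean_area``.
    """
    if samples is not None:
        samples = list(samples)
        unknown = set(samples) - set(tracks["sample"])
        if unknown:
            raise ValueError(f"unknown sample id(s) in filter: {sorted(unknown)}")
        tracks = tracks[tracks["sample"].isin(samples)]
    if tracks.empty:
        raise ValueError("no tracks to quantify")
    conc = curve.predict(tracks["area"].to_numpy(dtype=float))
    work = tracks.assign(_conc=conc)
    rows = []
    for sample, grp in work.groupby("sample", sort=False):
        vals = grp["_conc"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        mean = float(np.mean(vals))
        if decimals is not None:
            mean, sd = round(mean, decimals), round(sd, decimals)
        rows.append((sample, mean, sd, len(vals), float(grp["area"].mean())))
    return pd.DataFrame(
        rows, columns=["sample", "mean_concentration", "sd", "n_replicates", "mean_area"]
    ).set_index("sample")


def check_specificity(
    sample_rf: float | np.ndarray, standard_rf: float = 0.65, tolerance: float = 0.02
) -> bool | np.ndarray:
    """Identity check: does each track's Rf match the standard's Rf?

    Passes when ``|sample_rf - standard_rf| <= tolerance``.  Rf values are
    retardation factors and must lie in [0, 1].
    """
    rf = np.asarray(sample_rf, dtype=float)
    for name, vals in (("sample", rf), ("standard", np.asarray(standard_rf))):
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{name} Rf outside [0, 1]")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ok = np.abs(rf - standard_rf) <= tolerance
    return bool(ok) if np.isscalar(sample_rf) else ok


def linearity_report(standards: pd.DataFrame) -> pd.DataFrame:
    """Back-predict each standard through the fitted curve.

    Returns one row per standard with ``nominal``, ``area``,
    ``back_predicted`` and ``residual`` (nominal minus back-predicted)
    columns; the fitted curve is attached as ``frame.attrs['curve']`` and its
    R^2 as ``frame.attrs['r_squared']``.
    """
    curve = fit_calibration(standards)
    area = standards["area"].to_numpy(dtype=float)
    nominal = standards["concentration"].to_numpy(dtype=float)
    back = np.asarray(curve.predict(area), dtype=float)
    out = pd.DataFrame(
        {
            "nominal": nominal,
            "area": area,
            "back_predicted": back,
            "residual": nominal - back,
        }
    )
    out.attrs["curve"] = curve
    out.attrs["r_squared"] = curve.r_squared
    return out


def write_quant_report(quant: pd.DataFrame, path: str | Path) -> None:
    """Write a quantification table as TSV: sample, mean area, mean +/- SD."""
    report = pd.DataFrame(
        {
            "sample": quant.index,
            "calculated_area": quant["mean_area"].round(1).to_numpy(),
            "concentration_mean": quant["mean_concentration"].to_numpy(),
            "concentration_sd": quant["sd"].to_numpy(),
            "n_replicates": quant["n_replicates"].to_numpy(),
        }
    )
    report.to_csv(path, sep="\t", index=False)
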