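"""Binned zero-intercept linear bias correction.

Regression forests compress the AGB range: low-biomass cells are
overestimated and high-biomass cells underestimated.  The correction bins
the validation pairs by the LiDAR-derived reference AGB in fixed-width
intervals (default 10 Mg ha^-1), regresses the bin-mean predictions on the
bin-mean references through the origin,

    s = sum(x_i * y_i) / sum(x_i ** 2)     over bin means (x = reference),

and rescales every prediction by 1/s.  By construction, refitting the bin
regression on corrected values gives slope exactly 1 — the fitted line then
coincides with the 1:1 line — and the correction is strictly monotone and
idempotent.  When the forest compresses the range (s < 1) the corrected
maximum exceeds the raw maximum, restoring dynamic range at the cost of
extra scatter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class BiasCorrector:
    """Fitted zero-intercept bin regression: slope and the bin table."""

    slope: float
    bin_width: float
    bin_table: pd.DataFrame  # bin_lo, bin_hi, mean_ref, mean_pred, count

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("corrector slope must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "bin_width": self.bin_width,
            "bin_table": self.bin_table.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BiasCorrector":
        d = json.loads(Path(path).read_text())
        return cls(slope=d["slope"], bin_width=d["bin_width"], bin_table=pd.DataFrame(d["bin_table"]))


def fit_corrector(predicted: np.ndarray, reference: np.ndarray, bin_width: float = 10.0) -> BiasCorrector:
    """Fit the binned zero-intercept correction from paired values.

    Bins are defined on the reference axis; empty bins are skipped.  Needs
    at least two nonempty bins.
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference must be paired")
    ok = np.isfinite(pred) & np.isfinite(ref)
    pred, ref = pred[ok], ref[ok]
    idx = np.floor(ref / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width,
                "mean_ref": ref[sel].mean(),
                "mean_pred": pred[sel].mean(),
                "count": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("need at least 2 nonempty bins to fit the corrector")
    x = table["mean_ref"].to_numpy()
    y = table["mean_pred"].to_numpy()
    slope = float(np.sum(x * y) / np.sum(x**2))
    return BiasCorrector(slope=slope, bin_width=bin_width, bin_table=table)


def apply_corrector(corrector: BiasCorrector, values: np.ndarray | float) -> np.ndarray | float:
    """Rescale predictions by 1/slope; NaN (nodata) and nonnegativity preserved."""
    out = np.asarray(values, dtype=float) / corrector.slope
    return float(out) if out.ndim == 0 else out


def correction_report(
    predicted: np.ndarray,
    corrected: np.ndarray,
    reference: np.ndarray,
    r2_rmse,
) -> dict[str, float]:
    """Pre/post metrics and extremes for the corrector's report file."""
    r2_pre, rmse_pre = r2_rmse(predicted, reference)
    r2_post, rmse_post = r2_rmse(corrected, reference)
    fin = np.isfinite(predicted)
    return {
        "r2_pre": r2_pre,
        "rmse_pre": rmse_pre,
        "r2_post": r2_post,
        "rmse_post": rmse_post,
        "max_pre": float(np.max(predicted[fin])) if fin.any() else float("nan"),
        "max_post": float(np.max(np.asarray(corrected)[fin])) if fin.any() else float("nan"),
        "max_reference": float(np.nanmax(reference)),
    }
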