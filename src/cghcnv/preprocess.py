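"""Spot/region quality control, M/A computation, and weighted-loess
normalization of two-color array intensities.

M is the log2 ratio of background-subtracted red over green foreground; A
is the companion average log2 intensity.  Normalization fits a loess curve
of M on A using only spots with -1 <= M <= 1 (weight 1; all others weight
0) and subtracts the fitted value from every spot — the "weighted loess"
scheme, which keeps genuine copy-number spots (|M| near log2(3/2) or 1)
from bending the normalization curve.  Reverse-orientation arrays are made
comparable to forward ones by negating M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess

from cghcnv.errors import PreprocessError, StructuralError
from cghcnv.simulate import ArrayScan


@dataclass
class QCParams:
    window: int = 10          # grid window side, spots
    outlier_mad: float = 3.0  # |M - window median| threshold, in global MADs
    window_flag_frac: float = 0.4


def _net(scan: ArrayScan) -> tuple[np.ndarray, np.ndarray]:
    s = scan.spots
    return (
        (s["ch_red_fg"] - s["ch_red_bg"]).to_numpy(float),
        (s["ch_green_fg"] - s["ch_green_bg"]).to_numpy(float),
    )


def quality_control(scan: ArrayScan, params: QCParams | None = None) -> ArrayScan:
    """Flag bad spots and bad chip regions.  Never unflags, never edits
    intensities.

    Spot rule: nonpositive foreground-minus-background in either channel.
    Region rule: the chip grid is tiled into ``window`` x ``window``
    blocks; a spot is an outlier when its provisional M deviates from the
    block median by more than ``outlier_mad`` global (normal-consistent)
    MADs, and a block whose outlier fraction exceeds
    ``window_flag_frac`` is flagged wholesale.
    """
    params = params or QCParams()
    net_r, net_g = _net(scan)
    flagged = (scan.spots["qc_flag"] != "pass").to_numpy()
    bad_spot = (net_r <= 0) | (net_g <= 0)
    flagged = flagged | bad_spot

    ok = ~flagged
    if ok.sum() >= 10:
        m = np.full(len(flagged), np.nan)
        m[ok] = np.log2(net_r[ok] / net_g[ok])
        global_mad = median_abs_deviation(m[ok], scale="normal")
        if global_mad > 0:
            rows = scan.spots["grid_row"].to_numpy() // params.window
            cols = scan.spots["grid_col"].to_numpy() // params.window
            block = pd.DataFrame({"b": rows * 100_000 + cols, "m": m, "ok": ok})
            for _, sub in block.groupby("b", sort=False):
                mm = sub["m"][sub["ok"]]
                if len(mm) < 3:
                    continue
                outlier = np.abs(mm - mm.median()) > params.outlier_mad * global_mad
                if outlier.mean() > params.window_flag_frac:
                    flagged[sub.index] = True

    out = scan.spots.copy()
    out["qc_flag"] = np.where(flagged, "fail", "pass")
    return ArrayScan(
        array_id=scan.array_id,
        sample_id=scan.sample_id,
        orientation=scan.orientation,
        spots=out,
    )


def compute_m_a(scan: ArrayScan) -> pd.DataFrame:
    """Per-spot M and A from background-subtracted channels.

    Returns a table (probe_id, M, A, weight, qc) in scan order; qc-fail
    spots carry NaN M/A and are excluded downstream.  M is always red over
    green on the raw channels — orientation is handled separately.
    """
    net_r, net_g = _net(scan)
    ok = (scan.spots["qc_flag"] == "pass").to_numpy() & (net_r > 0) & (net_g > 0)
    if not ok.any():
        raise PreprocessError(f"all spots qc-fail on array {scan.array_id}")
    m = np.full(len(ok), np.nan)
    a = np.full(len(ok), np.nan)
    m[ok] = np.log2(net_r[ok]) - np.log2(net_g[ok])
    a[ok] = 0.5 * (np.log2(net_r[ok]) + np.log2(net_g[ok]))
    return pd.DataFrame(
        {
            "probe_id": scan.spots["probe_id"].values,
            "M": m,
            "A": a,
            "weight": np.where(ok, 1.0, 0.0),
            "qc": np.where(ok, "pass", "fail"),
        }
    )


def loess_normalize(
    spots: pd.DataFrame, span: float = 0.3, robust_iter: int = 3
) -> pd.DataFrame:
    """Subtract an MA loess trend fitted on spots with -1 <= M <= 1.

    The fit uses binary weights (1 inside [-1, 1], 0 outside); the fitted
    curve is evaluated at every spot's A and subtracted from all M values.
    Spots beyond the ends of the weighted A range get the boundary fit
    value (constant extrapolation).
    """
    out = spots.copy()
    ok = (out["qc"] == "pass") & out["M"].notna()
    weighted = ok & (out["M"].abs() <= 1.0)
    out["weight"] = np.where(weighted, 1.0, 0.0)
    n_w = int(weighted.sum())
    if n_w < 10:
        raise PreprocessError(f"only {n_w} weighted spots; need at least 10")
    a_fit = out.loc[weighted, "A"].to_numpy()
    m_fit = out.loc[weighted, "M"].to_numpy()
    a_all = out.loc[ok, "A"].to_numpy()
    a_clip = np.clip(a_all, a_fit.min(), a_fit.max())
    trend = lowess(m_fit, a_fit, frac=span, it=robust_iter, xvals=a_clip)
    out.loc[ok, "M"] = out.loc[ok, "M"] - trend
    return out


def orient_reverse(spots: pd.DataFrame, orientation: str) -> pd.DataFrame:
    """Negate M on reverse arrays so all M are test-over-reference."""
    if orientation not in ("forward", "reverse"):
        raise StructuralError(f"unknown orientation {orientation!r}")
    out = spots.copy()
    if orientation == "reverse":
        out["M"] = -out["M"]
    return out


def preprocess_scan(
    scan: ArrayScan,
    qc_params: QCParams | None = None,
    span: float = 0.3,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full per-array chain: QC -> M/A -> weighted loess -> orientation.

    ``normalize=False`` skips the loess step (useful when the raw ratios
    are already trend-free, e.g. noise-free simulations).
    """
    scan = quality_control(scan, qc_params)
    spots = compute_m_a(scan)
    if normalize:
        spots = loess_normalize(spots, span=span)
    return orient_reverse(spots, scan.orientation)
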