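"""Per-species geographic and climatic summaries and the model design columns.

Rebuilds the predictors used by the decline model from gridded inputs: range
size (cell count x equal-area cell size), absolute latitudinal midpoint, range
means of the climate layers, body-size harmonization across two trait sources,
nearest-neighbor grid resampling, and the transform/scale step that produces
the design matrix (log-transformed size columns, z-scored climate columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TREND_LEVELS = ["increasing", "stable", "decreasing", "unknown"]
THREAT_LEVELS = ["LC", "NT", "VU", "EN", "CR", "DD"]

#: design columns in their canonical order (body size, range size, latitude,
#: temperature, temperature range, moisture, and the two prevalences)
PREDICTOR_ORDER = [
    "log_body_size",
    "log_range_size",
    "abs_lat_mid",
    "amt_mean",
    "tar_mean",
    "cmi_mean",
    "prev_amt",
    "prev_cmi",
]
LOG_SOURCE = {"log_body_size": "body_size_mm", "log_range_size": "range_size_km2"}
SCALED_COLS = ["abs_lat_mid", "amt_mean", "tar_mean", "cmi_mean",
               "prev_amt", "prev_cmi"]


# ---------------------------------------------------------------------------
# Grid resampling
# ---------------------------------------------------------------------------


def resample_nearest(fine: np.ndarray, factor: int) -> np.ndarray:
    """Coarsen a grid by an integer factor using nearest-neighbor sampling.

    Each coarse cell takes the fine-cell value nearest its center; when the
    center sits exactly between two fine cells (even factor) the tie breaks
    toward the lower index. NODATA (NaN) propagates if selected.
    """
    fine = np.asarray(fine, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fine.copy()
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"factor {factor} does not divide grid shape {fine.shape}"
        )
    # coarse center in fine coordinates: i*f + (f-1)/2; nearest fine index
    # with tie-toward-lower is i*f + (f-1)//2
    off = (factor - 1) // 2
    return fine[off::factor, off::factor].copy()


# ---------------------------------------------------------------------------
# Per-species summaries
# ---------------------------------------------------------------------------


def range_size(range_cells, cell_area: float) -> float:
    """Range area in km^2: cell count x constant cell area.

    ``None`` encodes a range too small to resolve at grid resolution
    (sub-cell); the size is then missing here and supplied, if at all, from
    the polygon-analogue area recorded by the generator.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    if range_cells is None:
        return float("nan")
    return len(range_cells) * cell_area


def lat_midpoint(range_cells, world, absolute_first: bool = False) -> float:
    """Absolute latitudinal midpoint of the range.

    On an equal-area grid the unweighted mean of cell-center latitudes is the
    area-weighted centroid latitude. By default the absolute value is taken
    after averaging, so a range straddling the equator has |lat| near 0;
    ``absolute_first`` instead averages |latitude| per cell (the alternative
    reading, under which trans-equatorial ranges score mid-latitude).
    """
    if not range_cells:
        return float("nan")
    lats = np.array([world.lat_centers[r] for r, _ in range_cells], dtype=float)
    if absolute_first:
        return float(np.mean(np.abs(lats)))
    return abs(float(np.mean(lats)))


def climate_means(range_cells, world) -> tuple[float, float, float]:
    """Mean of each climate layer over the range cells, skipping NODATA."""
    if not range_cells:
        return (float("nan"),) * 3
    out = []
    rows = np.array([r for r, _ in range_cells])
    cols = np.array([c for _, c in range_cells])
    for name in ("amt", "tar", "cmi"):
        vals = world.layers[name][rows, cols]
        vals = vals[np.isfinite(vals)]
        out.append(float(np.mean(vals)) if vals.size else float("nan"))
    return tuple(out)


def harmonize_body_size(
    source_a: pd.Series,
    source_b: pd.Series,
    ratio_threshold: float = 5.0,
) -> pd.DataFrame:
    """Merge two body-size sources (mm) into one estimate per species.

    The estimate is the mean of the available sources. Species whose sources
    disagree by more than ``ratio_threshold``-fold are flagged for manual
    review (the order-of-magnitude incongruences that occur between trait
    databases) but still averaged.
    """
    idx = source_a.index.union(source_b.index)
    a = source_a.reindex(idx)
    b = source_b.reindex(idx)
    for s, name in ((a, "source_a"), (b, "source_b")):
        if (s.dropna() <= 0).any():
            raise ValueError(f"nonpositive body size in {name}")
    both = pd.concat([a, b], axis=1)
    mean = both.mean(axis=1, skipna=True)
    ratio = both.max(axis=1) / both.min(axis=1)
    flagged = both.notna().all(axis=1) & (ratio > ratio_threshold)
    return pd.DataFrame(
        {"body_size_mm": mean, "incongruent": flagged.astype(bool)}
    )


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class PredictorMatrix:
    """Transformed design columns plus the constants to redo/undo the transform.

    Body size and range size are natural-log transformed and centered; the six
    climate/geography columns are z-scored. Centers and scales are retained so
    rows completed later by imputation can be mapped onto the identical scale.
    """

    data: pd.DataFrame
    centers: dict[str, float]
    scales: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored transform to a raw species table."""
        out = {}
        for col in PREDICTOR_ORDER:
            raw = (
                np.log(table[LOG_SOURCE[col]].astype(float))
                if col in LOG_SOURCE
                else table[col].astype(float)
            )
            out[col] = (raw - self.centers[col]) / self.scales[col]
        return pd.DataFrame(out, index=table.index)

    def inverse(self, design: pd.DataFrame) -> pd.DataFrame:
        """Undo the transform (log columns return on the raw mm/km^2 scale)."""
        out = {}
        for col in PREDICTOR_ORDER:
            v = design[col] * self.scales[col] + self.centers[col]
            if col in LOG_SOURCE:
                out[LOG_SOURCE[col]] = np.exp(v)
            else:
                out[col] = v
        return pd.DataFrame(out, index=design.index)


def build_predictors(table: pd.DataFrame) -> PredictorMatrix:
    """Transform a species table into the canonical design columns.

    Natural log + centering for body size and range size; z-scoring (mean 0,
    sd 1 over non-missing rows) for the remaining six columns. Missing raw
    values stay missing in the output; a zero-variance column is an error.
    """
    centers: dict[str, float] = {}
    scales: dict[str, float] = {}
    cols: dict[str, pd.Series] = {}
    for col in PREDICTOR_ORDER:
        if col in LOG_SOURCE:
            raw = table[LOG_SOURCE[col]].astype(float)
            if (raw.dropna() <= 0).any():
                raise ValueError(f"nonpositive values in {LOG_SOURCE[col]}")
            v = np.log(raw)
            centers[col] = float(v.mean())
            scales[col] = 1.0
        else:
            v = table[col].astype(float)
            centers[col] = float(v.mean())
            sd = float(v.std(ddof=0))
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero-variance predictor column: {col}")
            scales[col] = sd
        cols[col] = (v - centers[col]) / scales[col]
    return PredictorMatrix(pd.DataFrame(cols, index=table.index), centers, scales)


def filter_trends(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict to stable/decreasing species and binarize the trend.

    Increasing and unknown trends (and missing entries) are dropped; the
    returned table carries ``decline`` = 1 for decreasing, 0 for stable.
    Returns the filtered table and the dropped counts per category.
    """
    if "trend" not in table.columns:
        raise ValueError("table has no trend column")
    trend = table["trend"]
    keep = trend.isin(["stable", "decreasing"])
    dropped = {
        "increasing": int((trend == "increasing").sum()),
        "unknown": int((trend == "unknown").sum()),
        "missing": int(trend.isna().sum()),
    }
    out = table.loc[keep].copy()
    if out.empty:
        raise ValueError("no stable/decreasing rows survive trend filtering")
    out["decline"] = (out["trend"] == "decreasing").astype(int)
    return out, dropped
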