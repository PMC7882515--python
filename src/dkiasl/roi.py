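"""Region-of-interest protocol: mirror-symmetric bilateral ROIs, area
constraints, per-region extraction, replicate/rater averaging, and
two-rater intraclass-correlation reliability.

The default atlas enumerates the 12 bilateral regions of the study
protocol (hippocampal head/body/tail, posterior cingulate cortex,
precuneus, three dorsal-thalamus subnuclei, lenticular nucleus, caudate
head, frontal and occipital white matter) in both hemispheres: 24 ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REGION_NAMES", "ROISpec", "default_atlas_specs",
    "mirror_roi", "roi_area", "extract_roi_values",
    "average_replicates", "icc_two_rater",
    "MEASUREMENT_COLUMNS", "validate_measurement_table", "icc_report",
]

REGION_NAMES: tuple[str, ...] = (
    "Hip (h)", "Hip (b)", "Hip (t)", "PCC", "Pr",
    "DT (a)", "DT (vl)", "DT (m)", "LN", "CNC", "FLWM", "OLWM",
)

MEASUREMENT_COLUMNS = (
    "subject_id", "region", "hemisphere", "metric", "rater", "replicate", "value",
)

AREA_RANGE_MM2 = (18.0, 22.0)  # protocol constraint on in-plane ROI area


@dataclass(frozen=True)
class ROISpec:
    label_id: int
    name: str
    hemisphere: str  # "left" | "right"

    def __post_init__(self):
        if self.label_id <= 0:
            raise ValueError("label_id must be a positive integer")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere}")


def default_atlas_specs() -> list[ROISpec]:
    """The shipped 24-region spec: labels 1-12 left, 13-24 right."""
    specs = [ROISpec(i + 1, name, "left") for i, name in enumerate(REGION_NAMES)]
    specs += [ROISpec(i + 13, name, "right") for i, name in enumerate(REGION_NAMES)]
    return specs


def mirror_roi(mask: np.ndarray, flip_axis: int = 0) -> np.ndarray:
    """Left-to-right flip of a boolean ROI mask across the grid midline.

    Voxel index i along flip_axis maps to N-1-i; voxel count is preserved
    and the operation is an involution.
    """
    mask = np.asarray(mask, dtype=bool)
    return np.flip(mask, axis=flip_axis)


def roi_area(mask_slice: np.ndarray, voxel_dims: tuple[float, float]) -> tuple[float, bool]:
    """In-plane area (mm^2) of a single-slice ROI and its protocol-range flag.

    Accepts an in-plane 2-D mask, or a 3-D mask whose voxels all lie in one
    slice along the last (slice) axis; a multi-slice mask is rejected since
    the area constraint is defined per slice.
    """
    mask = np.asarray(mask_slice, dtype=bool)
    if mask.ndim == 3:
        slices = np.unique(np.nonzero(mask)[2])
        if slices.size != 1:
            raise ValueError("area check requires a single-slice mask")
        mask = mask[:, :, slices[0]]
    elif mask.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D mask, got ndim={mask.ndim}")
    area = float(mask.sum()) * float(voxel_dims[0]) * float(voxel_dims[1])
    lo, hi = AREA_RANGE_MM2
    return area, bool(lo <= area <= hi)


def extract_roi_values(param_map: np.ndarray, label_map: np.ndarray,
                       specs: list[ROISpec] | None = None) -> pd.DataFrame:
    """Per-region mean of a parameter map over non-missing (finite) voxels.

    Returns a frame with columns (label_id, region, hemisphere, n_voxels,
    n_valid, value); a region with zero valid voxels carries value NaN and
    n_valid 0 (flagged missing, never silently zero).
    """
    param_map = np.asarray(param_map, dtype=float)
    label_map = np.asarray(label_map)
    if param_map.shape != label_map.shape:
        raise ValueError(
            f"map grid {param_map.shape} != label grid {label_map.shape}"
        )
    if specs is None:
        specs = default_atlas_specs()
    rows = []
    for spec in specs:
        sel = label_map == spec.label_id
        vals = param_map[sel]
        valid = vals[np.isfinite(vals)]
        rows.append({
            "label_id": spec.label_id,
            "region": spec.name,
            "hemisphere": spec.hemisphere,
            "n_voxels": int(sel.sum()),
            "n_valid": int(valid.size),
            "value": float(valid.mean()) if valid.size else np.nan,
        })
    return pd.DataFrame(rows)


def validate_measurement_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    key = ["subject_id", "region", "hemisphere", "metric", "rater", "replicate"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (subject, region, metric, rater, replicate) cells")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite measurement values")
    return table


def average_replicates(table: pd.DataFrame, allow_missing: bool = True):
    """Replicate-then-rater averaging of a tidy measurement table.

    Within each (subject, region, hemisphere, metric, rater) cell the
    replicates are averaged; the per-rater means are then averaged across
    raters.  Returns (combined, per_rater):

    - combined: one value per (subject_id, region, hemisphere, metric)
    - per_rater: the intermediate per-rater means (the ICC input)

    With a balanced design this equals the grand mean of all replicates.
    A rater entirely missing for a target is an error; unbalanced
    replicate counts are averaged over what is available (warns unless
    ``allow_missing``).
    """
    validate_measurement_table(table)
    target = ["subject_id", "region", "hemisphere", "metric"]
    per_rater = (table.groupby(target + ["rater"], as_index=False)["value"]
                 .mean())
    counts = per_rater.groupby(target)["rater"].nunique()
    n_raters = table["rater"].nunique()
    if (counts < n_raters).any():
        raise ValueError("a rater is entirely missing for some target")
    if not allow_missing:
        reps = table.groupby(target + ["rater"])["replicate"].nunique()
        if reps.nunique() > 1:
            raise ValueError("unbalanced replicate counts with allow_missing=False")
    combined = per_rater.groupby(target, as_index=False)["value"].mean()
    return combined, per_rater


def icc_two_rater(rater1: np.ndarray, rater2: np.ndarray,
                  form: str = "consistency") -> tuple[float, bool]:
    """Two-rater intraclass correlation over paired target measurements.

    Default is the two-way mixed, single-measure, consistency form
    ICC(3,1) = (MS_T - MS_E) / (MS_T + (k-1) MS_E) with k = 2 raters
    (the raters are fixed, so a constant inter-rater offset does not
    reduce reliability).  ``form="agreement"`` gives absolute-agreement
    ICC(2,1).  Returns (icc, good_flag) with good_flag = icc > 0.75,
    the conventional reliability gate.
    """
    x = np.asarray(rater1, dtype=float)
    y = np.asarray(rater2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("raters must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 targets")
    data = np.stack([x, y], axis=1)  # n targets x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    # residual SS from the interaction residuals directly (not by subtraction,
    # which would leave round-off where the raters agree exactly)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if ms_rows + (k - 1) * ms_err == 0:
        raise ValueError("zero between-target variance: ICC undefined")
    if form == "consistency":
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    elif form == "agreement":
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
    else:
        raise ValueError(f"unknown ICC form: {form}")
    icc = float(icc)
    return icc, icc > 0.75


def icc_report(per_rater: pd.DataFrame, form: str = "consistency") -> pd.DataFrame:
    """Per (region, hemisphere, metric) two-rater ICC across subjects.

    ``per_rater`` is the second output of :func:`average_replicates`.
    """
    raters = sorted(per_rater["rater"].unique())
    if len(raters) != 2:
        raise ValueError(f"expected exactly 2 raters, got {raters}")
    wide = per_rater.pivot_table(
        index=["region", "hemisphere", "metric", "subject_id"],
        columns="rater", values="value",
    )
    rows = []
    for (region, hemi, metric), grp in wide.groupby(level=[0, 1, 2]):
        icc, good = icc_two_rater(grp[raters[0]].to_numpy(),
                                  grp[raters[1]].to_numpy(), form=form)
        rows.append({"region": region, "hemisphere": hemi, "metric": metric,
                     "icc": icc, "good": good})
    return pd.DataFrame(rows)
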