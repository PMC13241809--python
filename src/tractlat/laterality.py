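"""Tract-level feature aggregation and the lateralization index.

The lateralization index LI = (R − L)/(R + L) is a dimensionless left–right
contrast of a strictly positive tract feature: 0 means perfect symmetry,
positive values mean rightward asymmetry.  Because it normalizes within
subject, it is invariant to any global scaling that affects both hemispheres
equally, and it is strictly inside (−1, 1) for positive inputs.

Aggregation helpers reduce per-voxel scalar samples to one tract-level value
(streamline-count-weighted mean for DTI indices; volume from voxel counts;
mean streamline length for geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRACTS",
    "FEATURES",
    "laterality_index",
    "weighted_tract_mean",
    "tract_volume",
    "mean_streamline_length",
    "build_laterality_table",
    "ExclusionReport",
]

#: The 30 bilateral tract labels (association, limbic, thalamic, striatal and
#: other projection systems).
TRACTS: tuple[str, ...] = (
    "AF", "MLF", "IFOF", "ILF", "SLF_I", "SLF_II", "SLF_III",
    "CG", "UF", "FX",
    "T_PREF", "T_PREM", "T_PREC", "T_POSTC", "T_PAR", "T_OCC", "ATR",
    "ST_FO", "ST_PREF", "ST_PREM", "ST_PREC", "ST_POSTC", "ST_PAR", "ST_OCC",
    "CST", "FPT", "ICP", "OR", "POPT", "SCP",
)

#: Feature vocabulary: four DTI microstructure indices plus two macrostructure
#: measures (tract volume in mm^3, mean streamline length in mm).
FEATURES: tuple[str, ...] = ("FA", "MD", "AD", "RD", "volume", "length")


def laterality_index(left, right):
    """LI = (right − left)/(right + left) for strictly positive inputs.

    Accepts scalars or arrays (broadcast).  Raises ``ValueError`` naming the
    offending hemisphere on non-positive or non-finite input.
    """
    left_arr = np.asarray(left, dtype=float)
    right_arr = np.asarray(right, dtype=float)
    for name, arr in (("left", left_arr), ("right", right_arr)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} hemisphere value is non-finite")
        if arr.size and np.min(arr) <= 0:
            raise ValueError(
                f"{name} hemisphere value must be > 0, got min {np.min(arr)}"
            )
    li = (right_arr - left_arr) / (right_arr + left_arr)
    if li.ndim == 0:
        return float(li)
    return li


def weighted_tract_mean(values, weights) -> float:
    """Streamline-count-weighted mean of per-voxel scalar samples."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError(
            f"values and weights differ in length: {values.shape} vs {weights.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.size == 0:
        raise ValueError("empty voxel sample")
    if np.min(weights) < 0:
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float(np.dot(values, weights) / total)


def tract_volume(voxel_count: int, voxel_dims) -> float:
    """Tract volume in mm^3 from a binary-mask voxel count and voxel size."""
    if voxel_count < 0:
        raise ValueError(f"voxel_count must be >= 0, got {voxel_count}")
    dims = np.asarray(voxel_dims, dtype=float)
    if dims.shape != (3,):
        raise ValueError("voxel_dims must be an (dx, dy, dz) triplet in mm")
    if np.min(dims) <= 0:
        raise ValueError("voxel dimensions must be positive")
    return float(voxel_count * dims.prod())


def mean_streamline_length(lengths) -> float:
    """Arithmetic mean streamline length in mm."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty streamline set")
    if np.min(lengths) <= 0:
        raise ValueError("streamline lengths must be positive")
    return float(lengths.mean())


@dataclass
class ExclusionReport:
    """Rows dropped while building an LI table (non-positive hemisphere values)."""

    n_input: int = 0
    n_excluded: int = 0
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_laterality_table(
    measures: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Join bilateral measures with subject covariates and compute LI.

    ``measures`` needs columns subject_id, tract, feature, left_value,
    right_value; ``covariates`` needs subject_id, age_years, sex, cohort_id
    (handedness optional, filled with "unknown").  Rows with a non-positive
    hemisphere value are dropped and returned in the report rather than
    clamped — the LI is degenerate there and the features are positive by
    construction.  Raises ``KeyError`` for measures whose subject_id has no
    covariate record.
    """
    required_m = {"subject_id", "tract", "feature", "left_value", "right_value"}
    required_c = {"subject_id", "age_years", "sex", "cohort_id"}
    if missing := required_m - set(measures.columns):
        raise KeyError(f"measures table missing columns: {sorted(missing)}")
    if missing := required_c - set(covariates.columns):
        raise KeyError(f"covariates table missing columns: {sorted(missing)}")

    cov = covariates.copy()
    if "handedness" not in cov.columns:
        cov["handedness"] = "unknown"
    orphans = set(measures["subject_id"]) - set(cov["subject_id"])
    if orphans:
        raise KeyError(
            f"{len(orphans)} measure subject_id(s) lack covariates, "
            f"e.g. {sorted(orphans)[:3]}"
        )

    valid = (measures["left_value"] > 0) & (measures["right_value"] > 0)
    valid &= np.isfinite(measures["left_value"]) & np.isfinite(measures["right_value"])
    report = ExclusionReport(
        n_input=len(measures),
        n_excluded=int((~valid).sum()),
        excluded=measures.loc[~valid].copy(),
    )
    kept = measures.loc[
        valid, ["subject_id", "tract", "feature", "left_value", "right_value"]
    ].copy()
    kept["li"] = laterality_index(
        kept["left_value"].to_numpy(), kept["right_value"].to_numpy()
    )
    cols = ["subject_id", "age_years", "sex", "cohort_id", "handedness"]
    table = kept.merge(cov[cols], on="subject_id", how="left", validate="many_to_one")
    table = table[cols + ["tract", "feature", "li"]].reset_index(drop=True)
    return table, report
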