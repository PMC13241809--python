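"""File formats: long-format observation tables, chart arrays, summary CSVs.

Observation tables are tidy CSV/TSV, one row per subject x tract x feature,
with either bilateral columns (left_value, right_value) or a precomputed
``li`` column.  Charts are persisted three ways per tract-feature-context:
a binary ``.npy`` array (first column age, remaining columns the centile
levels in ascending order), a CSV mirror, and a JSON sidecar documenting the
layout, levels and fitted specification.  All CSV outputs start with a
comment line carrying the schema version and the provenance (config) hash,
and floats are written with 9 significant digits so round-trips are stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CentileChart
from .simulate import HANDEDNESS_LEVELS, SEXES

__all__ = [
    "SCHEMA_VERSION",
    "IngestReport",
    "read_observations",
    "write_table",
    "write_chart",
    "read_chart",
    "plot_chart",
]

SCHEMA_VERSION = "tractlat-v1"
FLOAT_FMT = "%.9g"

_BILATERAL_COLS = {"subject_id", "age_years", "sex", "cohort_id",
                   "tract", "feature", "left_value", "right_value"}
_LI_COLS = {"subject_id", "age_years", "sex", "cohort_id", "tract", "feature", "li"}


@dataclass
class IngestReport:
    """What happened while reading an observation table."""

    n_rows: int = 0
    n_rejected: int = 0
    rejected_lines: list[int] = field(default_factory=list)
    n_coerced_sex: int = 0
    n_coerced_handedness: int = 0
    kind: str = ""  # "bilateral" or "li"


def read_observations(path: str | Path) -> tuple[pd.DataFrame, IngestReport]:
    """Read a long-format observation CSV/TSV (bilateral or LI layout).

    Separator follows the extension (.tsv -> tab).  Leading ``#`` comment
    lines are skipped.  Rows with an unparseable or negative age are rejected
    and reported with their 1-based file line numbers; sex/handedness values
    outside the vocabulary are coerced to "unknown" and counted.  Raises
    ``KeyError`` when required columns are missing.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # count leading comment lines so rejected rows can be reported by file line
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    cols = set(df.columns)
    if _BILATERAL_COLS <= cols:
        kind = "bilateral"
    elif _LI_COLS <= cols:
        kind = "li"
    else:
        missing = min(_BILATERAL_COLS - cols, _LI_COLS - cols, key=len)
        raise KeyError(f"observation table missing required columns: {sorted(missing)}")

    report = IngestReport(n_rows=len(df), kind=kind)
    value_cols = ["left_value", "right_value"] if kind == "bilateral" else ["li"]
    for col in ["age_years", *value_cols]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    bad = df["age_years"].isna() | (df["age_years"] < 0)
    for col in value_cols:
        bad |= df[col].isna()
    if bad.any():
        # +2: 1-based lines plus the header row, plus any leading comments
        report.rejected_lines = [int(i) + 2 + n_comment for i in df.index[bad]]
        report.n_rejected = int(bad.sum())
        df = df.loc[~bad].reset_index(drop=True)

    coerce_sex = ~df["sex"].isin(SEXES)
    report.n_coerced_sex = int(coerce_sex.sum())
    df.loc[coerce_sex, "sex"] = "unknown"
    if "handedness" not in df.columns:
        df["handedness"] = "unknown"
    coerce_hand = ~df["handedness"].isin(HANDEDNESS_LEVELS)
    report.n_coerced_handedness = int(coerce_hand.sum())
    df.loc[coerce_hand, "handedness"] = "unknown"
    return df, report


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "",
                index: bool = False) -> Path:
    """Write a CSV with the schema/provenance header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} config={config_hash}\n")
        df.to_csv(fh, index=index, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def write_chart(chart: CentileChart, base: str | Path, config_hash: str = "") -> dict:
    """Persist a chart as ``<base>.npy`` + ``<base>.csv`` + ``<base>.json``.

    The array layout is (grid x (1 + levels)): first column age, then the
    centile levels in ascending order.  Reading the .npy back reproduces the
    chart bit-exactly.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    arr = np.column_stack([chart.age_grid, chart.values])
    npy = base.with_suffix(".npy")
    np.save(npy, arr)
    csv = base.with_suffix(".csv")
    mirror = pd.DataFrame(arr, columns=["age_years", *(f"p{p:g}" for p in chart.levels)])
    write_table(mirror, csv, config_hash)
    sidecar = {
        "schema": SCHEMA_VERSION,
        "config": config_hash,
        "tract": chart.tract,
        "feature": chart.feature,
        "context": chart.context,
        "levels": list(chart.levels),
        "layout": "columns: age_years then one column per level, ascending",
        "meta": chart.meta,
    }
    jsn = base.with_suffix(".json")
    jsn.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return {"npy": npy, "csv": csv, "json": jsn}


def read_chart(base: str | Path) -> CentileChart:
    """Reconstruct a chart from ``<base>.npy`` and its JSON sidecar."""
    base = Path(base)
    arr = np.load(base.with_suffix(".npy"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    return CentileChart(
        tract=sidecar["tract"],
        feature=sidecar["feature"],
        context=sidecar["context"],
        age_grid=arr[:, 0],
        levels=tuple(sidecar["levels"]),
        values=arr[:, 1:],
        meta=sidecar.get("meta", {}),
    )


def plot_chart(chart: CentileChart, path: str | Path) -> Path:
    """Basic centile-chart PNG (age on x, LI on y, one line per level)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for j, level in enumerate(chart.levels):
        is_median = abs(level - 50.0) < 1e-9
        ax.plot(
            chart.age_grid,
            chart.values[:, j],
            color="tab:blue" if is_median else "gray",
            lw=1.8 if is_median else 0.9,
            label=f"{level:g}th",
        )
    ax.axhline(0.0, color="k", lw=0.6, ls="--")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("lateralization index")
    ax.set_title(f"{chart.tract} {chart.feature} ({chart.context})")
    ax.legend(fontsize=7, ncol=2)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
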