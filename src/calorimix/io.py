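"""Tabular readers and writers for the pipeline's file formats.

All formats are plain text:

- IMC heat-flow CSV: ``time_h, power, unit, replicate, passage, condition``
  with power in ``uW`` or ``W`` (internal unit is W);
- heat-curve CSV: ``time_h, heat_J``;
- abundance TSV: ``time_h, strain, reads``;
- metabolite CSV: ``sample, replicate, metabolite, timepoint, conc_mM``.
"""

from __future__ import annotations

from pathlib import Path


import pandas as pd

from calorimix.calorimetry import HeatCurve, HeatFlowSeries

__all__ = [
    "read_heatflow_csv",
    "write_heatflow_csv",
    "write_heatcurve_csv",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metabolite_csv",
    "write_metabolite_csv",
]

_UNIT_TO_W = {"W": 1.0, "uW": 1e-6, "µW": 1e-6}


def read_heatflow_csv(path) -> list[HeatFlowSeries]:
    """Read an IMC export; returns one series per (replicate, passage, condition)."""
    df = pd.read_csv(path)
    required = {"time_h", "power", "unit", "replicate", "passage", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_units = set(df["unit"]) - set(_UNIT_TO_W)
    if bad_units:
        raise ValueError(f"{path}: unknown power units {sorted(bad_units)} (use uW or W)")
    out = []
    for (rep, pas, cond), grp in df.groupby(["replicate", "passage", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        power = grp["power"].to_numpy(float) * grp["unit"].map(_UNIT_TO_W).to_numpy(float)
        out.append(
            HeatFlowSeries(
                time=grp["time_h"].to_numpy(float),
                power=power,
                replicate=str(rep),
                passage=int(pas),
                condition=str(cond),
            )
        )
    return out


def write_heatflow_csv(series_list: list[HeatFlowSeries], path, unit: str = "uW") -> None:
    scale = 1.0 / _UNIT_TO_W[unit]
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": s.time,
                    "power": s.power * scale,
                    "unit": unit,
                    "replicate": s.replicate,
                    "passage": s.passage,
                    "condition": s.condition,
                }
            )
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_heatcurve_csv(curve: HeatCurve, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_h": curve.time, "heat_J": curve.cumulative_heat}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_abundance_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "strain", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    return df


def write_abundance_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_metabolite_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "replicate", "metabolite", "timepoint", "conc_mM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["conc_mM"] < 0).any():
        raise ValueError(f"{path}: negative concentrations")
    return df


def write_metabolite_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
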