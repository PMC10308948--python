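"""Plate-reader file handling.

The on-disk format is a long-format CSV with columns ``time_h, well,
isolate, context, replicate, od600, gfp`` (gfp empty for non-fluorescent
wells). Context conventions: ``fresh`` for plain medium, ``cfsm:<donor>``
for spent-medium wells, ``co:<partner>`` for coculture wells (which carry a
gfp channel), and ``blank`` for medium-only wells. A YAML sidecar records
generating parameters and seeds for synthetic panels.
"""

from __future__ import annotations

import pathlib
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .coculture import CocultureTrace
from .kinetics import GrowthCurve
from .params import SchemaError

REQUIRED_COLUMNS = ("time_h", "od600", "isolate", "context", "replicate")


def write_plate_csv(curves: Sequence[Union[GrowthCurve, CocultureTrace]],
                    path) -> None:
    """Write curves/traces as one long-format CSV."""
    frames = []
    for obj in curves:
        if isinstance(obj, CocultureTrace):
            m = obj.meta
            pair = m.get("pair", ("sp1", "sp2"))
            frames.append(pd.DataFrame({
                "time_h": obj.time,
                "well": m.get("well", ""),
                "isolate": m.get("isolate", pair[0]),
                "context": m.get("context", f"co:{pair[1]}"),
                "replicate": m.get("replicate", 1),
                "od600": obj.total_od,
                "gfp": obj.fluorescence,
            }))
        else:
            frames.append(pd.DataFrame({
                "time_h": obj.time,
                "well": obj.meta.get("well", ""),
                "isolate": obj.meta.get("isolate", ""),
                "context": obj.meta.get("context", ""),
                "replicate": obj.meta.get("replicate", 1),
                "od600": obj.od,
                "gfp": obj.fluorescence if obj.fluorescence is not None else np.nan,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_csv(path) -> list[Union[GrowthCurve, CocultureTrace]]:
    """Read a long-format plate CSV into curves and coculture traces.

    One object per (isolate, context, replicate) group, time-sorted. Groups
    whose context starts with ``co:`` and that carry a gfp channel become
    :class:`CocultureTrace`; everything else becomes :class:`GrowthCurve`.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    od = pd.to_numeric(df["od600"], errors="coerce")
    bad = od.isna() & df["od600"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"non-numeric od600 at data row {row}: "
                          f"{df['od600'].iloc[row]!r}")
    df = df.assign(od600=od)
    if "gfp" not in df.columns:
        df["gfp"] = np.nan
    out = []
    for (isolate, context, rep), g in df.groupby(
            ["isolate", "context", "replicate"], sort=True):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise SchemaError(
                f"duplicated timestamps in well {isolate}/{context}/{rep}")
        meta = {"isolate": str(isolate), "context": str(context),
                "replicate": rep}
        if "well" in g.columns and g["well"].notna().any():
            meta["well"] = str(g["well"].iloc[0])
        gfp = g["gfp"].to_numpy(dtype=float)
        if str(context).startswith("co:") and np.isfinite(gfp).all():
            meta["pair"] = (str(isolate), str(context)[3:])
            out.append(CocultureTrace(time=t, total_od=g["od600"].to_numpy(float),
                                      fluorescence=gfp, meta=meta))
        else:
            out.append(GrowthCurve(
                time=t, od=g["od600"].to_numpy(float),
                fluorescence=gfp if np.isfinite(gfp).all() else None, meta=meta))
    return out


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_sidecar(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_builtin(truth), fh, sort_keys=False)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def convert_wide_to_long(path_in, path_out, time_unit: str = "h",
                         well_map: dict | None = None) -> pd.DataFrame:
    """Convert a plate-reader matrix export (rows = time, columns = wells)
    to the long format. ``well_map`` optionally maps well ids to
    ``(isolate, context, replicate)``; unmapped wells become fresh-medium
    wells named after themselves."""
    wide = pd.read_csv(path_in)
    tcol = wide.columns[0]
    t = pd.to_numeric(wide[tcol], errors="coerce")
    if t.isna().any():
        raise SchemaError(f"non-numeric time value in column {tcol!r}")
    if time_unit == "min":
        t = t / 60.0
    elif time_unit != "h":
        raise SchemaError(f"unsupported time unit {time_unit!r}")
    rows = []
    for well in wide.columns[1:]:
        isolate, context, rep = (well_map or {}).get(well, (well, "fresh", 1))
        rows.append(pd.DataFrame({
            "time_h": t, "well": well, "isolate": isolate, "context": context,
            "replicate": rep,
            "od600": pd.to_numeric(wide[well], errors="coerce"),
            "gfp": np.nan,
        }))
    long = pd.concat(rows, ignore_index=True)
    long.to_csv(path_out, index=False)
    return long
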