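"""Readers and writers for the package's delimited-text dialects.

Canonical dialect: CSV with a header row.  TAC tables carry
``frame_start_min, frame_end_min`` then one column per region; blood tables
carry ``t_min, value, kind``.  Time columns may instead declare seconds
(``_s``) or hours (``_h``) in the header suffix and are converted to minutes
on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .curves import BloodSampleSeries, TimeActivityCurve

__all__ = [
    "ParseError",
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
]

_UNIT_TO_MIN = {"min": 1.0, "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "h": 60.0, "hr": 60.0}


class ParseError(ValueError):
    """Raised when a delimited file fails structural or numeric validation."""


def _time_columns(columns, stem: str):
    """Find '<stem>_<unit>' (or bare '<stem>') among columns; return (name, factor)."""
    for col in columns:
        if col == stem:
            return col, 1.0
        if col.startswith(stem + "_"):
            unit = col[len(stem) + 1 :]
            if unit in _UNIT_TO_MIN:
                return col, _UNIT_TO_MIN[unit]
    raise ParseError(f"missing required column '{stem}_min' (or {stem}_s / {stem}_h)")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise ParseError(f"{path}: non-numeric cell in column '{col}', row {row}")
    return out.to_numpy(dtype=float)


def read_tac_table(path, delimiter: str = ",") -> Dict[str, TimeActivityCurve]:
    """Read a TAC table into a mapping region -> TimeActivityCurve.

    Expected layout: header with frame_start_min, frame_end_min and one
    column per region; concentrations in kBq·cm⁻³, decay-corrected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, comment="#")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    start_col, f0 = _time_columns(df.columns, "frame_start")
    end_col, f1 = _time_columns(df.columns, "frame_end")
    fs = _numeric(df, start_col, path) * f0
    fe = _numeric(df, end_col, path) * f1
    bad = np.nonzero(fe <= fs)[0]
    if bad.size:
        raise ParseError(f"{path}: frame_end <= frame_start in row {int(bad[0])}")
    regions = [c for c in df.columns if c not in (start_col, end_col)]
    if not regions:
        raise ParseError(f"{path}: no region columns found")
    out = {}
    for region in regions:
        conc = _numeric(df, region, path)
        try:
            out[region] = TimeActivityCurve(region, fs, fe, conc)
        except ValueError as exc:
            raise ParseError(f"{path}: region '{region}': {exc}") from exc
    return out


def write_tac_table(tacs: Mapping[str, TimeActivityCurve], path, delimiter: str = ","):
    """Write region TACs sharing one frame grid to a delimited table."""
    tac_list = list(tacs.values())
    first = tac_list[0]
    for tac in tac_list[1:]:
        if not (
            np.allclose(tac.frame_start, first.frame_start)
            and np.allclose(tac.frame_end, first.frame_end)
        ):
            raise ValueError("all TACs must share one frame grid")
    df = pd.DataFrame(
        {"frame_start_min": first.frame_start, "frame_end_min": first.frame_end}
    )
    for name, tac in tacs.items():
        df[name] = tac.conc
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_blood_table(path, delimiter: str = ",") -> Dict[str, BloodSampleSeries]:
    """Read a blood table (t_min, value, kind) into kind -> BloodSampleSeries."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, comment="#")
    t_col, factor = _time_columns(df.columns, "t")
    for col in ("value", "kind"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    out = {}
    for kind, grp in df.groupby("kind", sort=False):
        t = _numeric(grp.reset_index(drop=True), t_col, path) * factor
        v = _numeric(grp.reset_index(drop=True), "value", path)
        order = np.argsort(t)
        try:
            out[str(kind)] = BloodSampleSeries(t[order], v[order], str(kind))
        except ValueError as exc:
            raise ParseError(f"{path}: series '{kind}': {exc}") from exc
    return out


def write_blood_table(series: Mapping[str, BloodSampleSeries], path, delimiter: str = ","):
    frames = []
    for kind, s in series.items():
        frames.append(pd.DataFrame({"t_min": s.t, "value": s.value, "kind": kind}))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=delimiter, index=False, float_format="%.10g"
    )
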