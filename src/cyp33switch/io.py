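"""Delimited-text dialects for assay data.

Titration CSV: columns ``l_total_uM, shift_ppm`` (optional ``p_total_uM``),
with ``#key=value`` metadata header lines (``p_total_uM``, ``delta_free_ppm``
required when not given per-row).  ITC CSV: ``inj_vol_uL, heat_ucal`` with
``#cell_uM=``, ``#syringe_uM=``, ``#V0_uL=`` headers.  Progress-curve CSV:
``time_s, signal`` with ``#enzyme_uM=``, ``#s_cis0_uM=`` headers.
"""
from __future__ import annotations

import io as _io
from typing import TextIO

import numpy as np
import pandas as pd

from .assays import ITCThermogram, ProgressCurve, TitrationSeries

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_itc_csv", "write_itc_csv",
    "read_progress_csv", "write_progress_csv",
    "sniff_dialect",
]


def _split_header(path) -> tuple[dict[str, float], str]:
    meta: dict[str, float] = {}
    body: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#"):
                text = line[1:].strip()
                if "=" in text:
                    k, v = text.split("=", 1)
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        pass
                continue
            body.append(line)
    return meta, "".join(body)


def _read_table(path, required: tuple[str, ...]):
    meta, body = _split_header(path)
    try:
        df = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} "
                             f"(found {list(df.columns)})")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: unparseable value at data line "
                         f"{int(np.argmax(bad.to_numpy())) + 1}")
    return meta, df


def sniff_dialect(path) -> str:
    """Identify an assay CSV by its header row."""
    _, body = _split_header(path)
    header = body.splitlines()[0] if body else ""
    cols = {c.strip() for c in header.split(",")}
    if {"l_total_uM", "shift_ppm"} <= cols:
        return "titration"
    if {"inj_vol_uL", "heat_ucal"} <= cols:
        return "itc"
    if {"time_s", "signal"} <= cols:
        return "ppiase"
    raise ValueError(f"{path}: unrecognized assay CSV header {header!r}")


# -- titration --------------------------------------------------------------

def read_titration_csv(path) -> TitrationSeries:
    meta, df = _read_table(path, ("l_total_uM", "shift_ppm"))
    if "p_total_uM" in df.columns:
        p_total = float(df["p_total_uM"].iloc[0])
    else:
        p_total = meta["p_total_uM"]
    return TitrationSeries(
        p_total=p_total,
        l_totals=df["l_total_uM"].to_numpy(float),
        observed_shifts=df["shift_ppm"].to_numpy(float),
        delta_free=meta.get("delta_free_ppm", float(df["shift_ppm"].iloc[0])),
        meta=meta,
    )


def write_titration_csv(series: TitrationSeries, path,
                        extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#p_total_uM={series.p_total}\n")
        fh.write(f"#delta_free_ppm={series.delta_free}\n")
        _write_meta(fh, {**series.meta, **(extra_meta or {})})
        fh.write("l_total_uM,shift_ppm\n")
        for l, s in zip(series.l_totals, series.observed_shifts):
            fh.write(f"{l:.6g},{s:.6f}\n")


# -- ITC --------------------------------------------------------------------

def read_itc_csv(path) -> ITCThermogram:
    meta, df = _read_table(path, ("inj_vol_uL", "heat_ucal"))
    return ITCThermogram(
        cell_volume=meta["V0_uL"], cell_conc=meta["cell_uM"],
        syringe_conc=meta["syringe_uM"],
        injection_volumes=df["inj_vol_uL"].to_numpy(float),
        heats=df["heat_ucal"].to_numpy(float), meta=meta,
    )


def write_itc_csv(tg: ITCThermogram, path, extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cell_uM={tg.cell_conc}\n")
        fh.write(f"#syringe_uM={tg.syringe_conc}\n")
        fh.write(f"#V0_uL={tg.cell_volume}\n")
        _write_meta(fh, {**tg.meta, **(extra_meta or {})})
        fh.write("inj_vol_uL,heat_ucal\n")
        for v, h in zip(tg.injection_volumes, tg.heats):
            fh.write(f"{v:.6g},{h:.6f}\n")


# -- progress curves --------------------------------------------------------

def read_progress_csv(path) -> ProgressCurve:
    meta, df = _read_table(path, ("time_s", "signal"))
    return ProgressCurve(
        enzyme_conc=meta["enzyme_uM"], substrate_cis0=meta["s_cis0_uM"],
        times=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float), meta=meta,
    )


def write_progress_csv(curve: ProgressCurve, path,
                       extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#enzyme_uM={curve.enzyme_conc}\n")
        fh.write(f"#s_cis0_uM={curve.substrate_cis0}\n")
        _write_meta(fh, {**curve.meta, **(extra_meta or {})})
        fh.write("time_s,signal\n")
        for t, s in zip(curve.times, curve.signal):
            fh.write(f"{t:.6g},{s:.6f}\n")


def _write_meta(fh: TextIO, meta: dict) -> None:
    for k, v in meta.items():
        if k in {"p_total_uM", "delta_free_ppm", "cell_uM", "syringe_uM",
                 "V0_uL", "enzyme_uM", "s_cis0_uM"}:
            continue
        fh.write(f"#{k}={v}\n")
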