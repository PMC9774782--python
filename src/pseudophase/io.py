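"""CSV input/output for traces, kinetic series, replicates, and pH series.

All files are plain CSV with optional metadata header lines of the form
``#key=value`` before the column header, e.g.::

    #AO_T=0.004
    #pH=3.65
    #oil=olive
    #antioxidant=alpha-tocopherol
    phi_I,k_obs
    0.005,0.123
    ...
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .pkm import KineticSeries
from .traces import AbsorbanceTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_kinetic_series_csv",
    "write_kinetic_series_csv",
    "read_replicates_csv",
    "read_ph_series_csv",
]


def _split_metadata(text: str):
    meta = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _read_with_metadata(path):
    text = Path(path).read_text()
    meta, body = _split_metadata(text)
    return meta, pd.read_csv(_io.StringIO(body))


def read_trace_csv(path) -> AbsorbanceTrace:
    """Read an absorbance trace (columns ``time_s``, ``absorbance``)."""
    meta, df = _read_with_metadata(path)
    for col in ("time_s", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"trace CSV must have a {col!r} column")
    return AbsorbanceTrace(
        times=df["time_s"].to_numpy(float),
        absorbances=df["absorbance"].to_numpy(float),
        label=meta.get("label", ""),
        pH=float(meta["pH"]) if "pH" in meta else None,
        phi_I=float(meta["phi_I"]) if "phi_I" in meta else None,
    )


def write_trace_csv(trace: AbsorbanceTrace, path) -> None:
    lines = []
    if trace.label:
        lines.append(f"#label={trace.label}")
    if trace.pH is not None:
        lines.append(f"#pH={trace.pH:g}")
    if trace.phi_I is not None:
        lines.append(f"#phi_I={trace.phi_I:g}")
    df = pd.DataFrame({"time_s": trace.times, "absorbance": trace.absorbances})
    header = "\n".join(lines)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_kinetic_series_csv(path) -> KineticSeries:
    """Read a kinetic series (columns ``phi_I``, ``k_obs``; optional ``phi_O``, ``sd``).

    Metadata: ``#AO_T=`` (required), ``#pH=``, ``#oil=``, ``#antioxidant=``,
    ``#phi_O=`` (used when there is no per-row phi_O column; default 0.1).
    """
    meta, df = _read_with_metadata(path)
    for col in ("phi_I", "k_obs"):
        if col not in df.columns:
            raise ValueError(f"kinetic series CSV must have a {col!r} column")
    if "AO_T" not in meta:
        raise ValueError("kinetic series CSV must carry an #AO_T= metadata line")
    if "phi_O" in df.columns:
        phi_O = df["phi_O"].to_numpy(float)
    else:
        phi_O = np.full(len(df), float(meta.get("phi_O", 0.1)))
    if "sd" in df.columns:
        obs = tuple(
            (fi, fo, k, s)
            for fi, fo, k, s in zip(
                df["phi_I"].to_numpy(float), phi_O, df["k_obs"].to_numpy(float),
                df["sd"].to_numpy(float),
            )
        )
    else:
        obs = tuple(
            (fi, fo, k)
            for fi, fo, k in zip(
                df["phi_I"].to_numpy(float), phi_O, df["k_obs"].to_numpy(float)
            )
        )
    return KineticSeries(
        observations=obs,
        AO_T=float(meta["AO_T"]),
        pH=float(meta["pH"]) if "pH" in meta else None,
        antioxidant_label=meta.get("antioxidant", ""),
        oil_label=meta.get("oil", ""),
    )


def write_kinetic_series_csv(series: KineticSeries, path) -> None:
    lines = [f"#AO_T={series.AO_T:g}"]
    if series.pH is not None:
        lines.append(f"#pH={series.pH:g}")
    if series.oil_label:
        lines.append(f"#oil={series.oil_label}")
    if series.antioxidant_label:
        lines.append(f"#antioxidant={series.antioxidant_label}")
    rows = series.observations
    has_sd = any(len(o) == 4 for o in rows)
    cols = {
        "phi_I": [o[0] for o in rows],
        "phi_O": [o[1] for o in rows],
        "k_obs": [o[2] for o in rows],
    }
    if has_sd:
        cols["sd"] = [o[3] if len(o) == 4 else float("nan") for o in rows]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_replicates_csv(path) -> np.ndarray:
    """Read replicate rate constants (column ``k_obs``)."""
    _, df = _read_with_metadata(path)
    if "k_obs" not in df.columns:
        raise ValueError("replicates CSV must have a 'k_obs' column")
    return df["k_obs"].to_numpy(float)


def read_ph_series_csv(path) -> tuple:
    """Read (pH, k_I[, se]) entries (columns ``pH``, ``k_I``, optional ``se``)."""
    _, df = _read_with_metadata(path)
    for col in ("pH", "k_I"):
        if col not in df.columns:
            raise ValueError(f"pH series CSV must have a {col!r} column")
    if "se" in df.columns:
        return tuple(
            (p, k, s)
            for p, k, s in zip(
                df["pH"].to_numpy(float), df["k_I"].to_numpy(float),
                df["se"].to_numpy(float),
            )
        )
    return tuple(
        (p, k) for p, k in zip(df["pH"].to_numpy(float), df["k_I"].to_numpy(float))
    )
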