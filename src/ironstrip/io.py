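"""Readers and writers for the pipeline's CSV/JSON/PNG interchange formats.

Tables travel as headed CSV validated against small column schemas; models
and results travel as JSON; strip images as 8-bit RGB PNG.  Validation
errors carry 1-based line numbers so bad rows can be found in an editor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import CalibrationCurve
from .errors import ConfigurationError
from .kinetics import KineticTrace
from .validation import PairedMeasurements

#: Column schemas: name -> (required columns, optional columns).
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "calibration": (("concentration_ug_dl", "absorbance_au"), ("run_id",)),
    "blanks": (("absorbance_au",), ()),
    "trace": (("time_s", "value"), ("value_kind", "iron0_mol_l", "ferene0_mol_l")),
    "pairs": (("reference_ug_dl", "test_ug_dl"), ("label",)),
    "panel": (("analyte", "concentration_mg_dl", "absorbance_au"), ()),
    "environment": (("temperature_c", "humidity_pct", "sensitivity_au_per_ug_dl"), ()),
}

_TEXT_COLUMNS = {"analyte", "label", "value_kind"}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named column schema.

    Raises :class:`ConfigurationError` naming missing columns, and collects
    every non-numeric cell with its line number before failing.
    """
    if schema not in SCHEMAS:
        raise ConfigurationError(f"unknown table schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"table file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ConfigurationError(f"{path}: table has no rows")
    required, optional = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {', '.join(missing)}")
    keep = [c for c in df.columns if c in required + optional]
    df = df[keep]
    errors = []
    for col in keep:
        if col in _TEXT_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[coerced.isna() & df[col].notna()]:
            # +2: header line plus 1-based indexing
            errors.append(f"line {idx + 2}: non-numeric value {df.at[idx, col]!r} in {col}")
        df[col] = coerced
    if errors:
        raise ConfigurationError(f"{path}: " + "; ".join(errors))
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_pairs(path) -> PairedMeasurements:
    df = read_table(path, "pairs")
    return PairedMeasurements(
        reference=df["reference_ug_dl"].to_numpy(), test=df["test_ug_dl"].to_numpy()
    )


def write_pairs(pairs: PairedMeasurements, path) -> None:
    write_table(pairs.to_frame(), path)


def write_trace(trace: KineticTrace, path) -> None:
    df = trace.to_frame()
    df["iron0_mol_l"] = trace.conditions.iron0
    df["ferene0_mol_l"] = trace.conditions.ferene0
    write_table(df, path)


def read_traces(path) -> list[KineticTrace]:
    """Read one or more kinetic traces from a single CSV.

    Traces are distinguished by their (iron0_mol_l, ferene0_mol_l) columns;
    a file without them yields a single trace with zeroed conditions.
    """
    from .kinetics import KineticConditions

    df = read_table(path, "trace")
    if "iron0_mol_l" not in df.columns:
        df["iron0_mol_l"] = 0.0
        df["ferene0_mol_l"] = 0.0
    traces = []
    for (fe, fer), group in df.groupby(["iron0_mol_l", "ferene0_mol_l"], sort=True):
        times = group["time_s"].to_numpy()
        kind = (
            str(group["value_kind"].iloc[0])
            if "value_kind" in group.columns and group["value_kind"].notna().any()
            else "concentration_mol_l"
        )
        conditions = KineticConditions(
            iron0=float(fe),
            ferene0=float(fer),
            duration=float(times[-1]) if times[-1] > 0 else 1.0,
            n_points=len(times),
        )
        traces.append(
            KineticTrace(
                times=times,
                values=group["value"].to_numpy(),
                conditions=conditions,
                value_kind=kind,
            )
        )
    return traces


def save_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def save_calibration(curve: CalibrationCurve, path) -> None:
    save_json(curve.to_dict(), path)


def load_calibration(path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(load_json(path))


def write_image(image, path) -> None:
    """Write a strip image (StripImage or (H, W, 3) uint8 array) as PNG."""
    pixels = getattr(image, "pixels", image)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
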