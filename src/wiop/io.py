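"""Reading and writing the package's text formats.

Velocity traces travel as delimited text with a header (time in ms, inward
apex velocity in mm/ms, ~140 samples over ~30 ms for device-style exports);
work ledgers as CSV time series with unit-suffixed column names; model
configuration as YAML; calibrations as JSON documents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialParams
from .events import VelocityTrace
from .geometry import EyeGeometryConfig

__all__ = ["read_velocity_trace", "write_velocity_trace", "write_events",
           "load_config", "dump_config"]


def read_velocity_trace(path, provenance: str = "clinical-style") -> VelocityTrace:
    """Read a device-style trace (columns: time_ms, velocity_mm_per_ms;
    comma, tab or whitespace separated; '#' comments allowed)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, velocity)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    return VelocityTrace(time_ms=t, velocity=v, provenance=provenance)


def write_velocity_trace(trace: VelocityTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.time_ms,
                  "velocity_mm_per_ms": trace.velocity}).to_csv(path, index=False)


def write_events(path, t_applanation_ms, t_maxvel_ms) -> None:
    """Events file: first applanation, maximum velocity and their difference."""
    diff = (np.nan if t_applanation_ms is None
            else t_maxvel_ms - t_applanation_ms)
    pd.DataFrame([{"t_applanation1_ms": t_applanation_ms,
                   "t_maxvel_ms": t_maxvel_ms,
                   "difference_ms": diff}]).to_csv(path, index=False)


def load_config(path):
    """Load a YAML model configuration.

    Recognised blocks: ``geometry`` (EyeGeometryConfig fields), ``iop_mmhg``
    and ``materials`` (per-region C10/k1/k2).  Returns
    (EyeGeometryConfig, materials dict or None, iop or None).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    geometry = EyeGeometryConfig(**doc.get("geometry", {}))
    materials = None
    if "materials" in doc:
        materials = {region: MaterialParams(**params)
                     for region, params in doc["materials"].items()}
    return geometry, materials, doc.get("iop_mmhg")


def dump_config(path, geometry: EyeGeometryConfig | None = None,
                materials: dict | None = None,
                iop_mmhg: float | None = None) -> None:
    doc = {}
    if geometry is not None:
        doc["geometry"] = {
            k: getattr(geometry, k)
            for k in ("anterior_corneal_radius", "corneal_diameter", "cct_um",
                      "limbus_width", "scleral_radius", "scleral_thickness",
                      "mesh_resolution")}
    if materials is not None:
        doc["materials"] = {
            region: {"C10": mp.C10, "k1": mp.k1, "k2": mp.k2}
            for region, mp in materials.items()}
    if iop_mmhg is not None:
        doc["iop_mmhg"] = iop_mmhg
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
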