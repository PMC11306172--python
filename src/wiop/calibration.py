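"""Calibration pipeline: parameter sweep, quadratic fits and the wIOP quartic.

The method rests on two regressions obtained from simulations of the
tonometer test across IOPs:

* pressurization calibration — IOP as a quadratic in the initial work of the
  IOP (the work accumulated on the anterior corneal surface while inflating
  from the zero-pressure configuration);
* timing calibration — initial work as a quadratic in the time of maximum
  apex velocity (measured from puff onset).

Substituting the second into the first yields a quartic polynomial mapping
the maximum-velocity time, the one quantity a clinical velocity trace
provides, directly to a pressure estimate (wIOP).  The composition is exact
polynomial algebra, independent of any simulation.

``PUBLISHED_EQ5`` / ``PUBLISHED_EQ6`` / ``PUBLISHED_WIOP_QUARTIC`` carry the
printed coefficients of the original fluid-structure-interaction study; the
sweep here re-derives its own coefficients at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SweepCase",
    "CalibrationFit",
    "table1_cases",
    "run_sweep",
    "fit_quadratic",
    "compose_wiop",
    "WiopCalibration",
    "PUBLISHED_EQ5",
    "PUBLISHED_EQ6",
    "PUBLISHED_WIOP_QUARTIC",
]

#: printed pressurization calibration: IOP [mmHg] = a W0^2 + b W0 + c, W0 in mJ
PUBLISHED_EQ5 = (-1.69e3, 4.21e2, 6.18)
#: printed timing calibration: W0 [mJ] = a t^2 + b t + c, t in ms
PUBLISHED_EQ6 = (1.09e-3, -8.28e-3, 1.19e-2)
#: printed quartic: wIOP [mmHg] = q4 t^4 + q3 t^3 + q2 t^2 + q1 t + q0
PUBLISHED_WIOP_QUARTIC = (-2.01e-3, 3.05e-2, 2.99e-1, -3.15, 10.95)

#: the sixteen-simulation design: (C10 MPa, k1 MPa, k2, IOP mmHg, CCT um);
#: rows 1-5 vary IOP, 6-13 the corneal material, 14-16 the thickness
_TABLE1 = [
    (1, 0.045, 0.027, 180.0, 10.0, 558.0),
    (2, 0.045, 0.027, 180.0, 15.0, 558.0),
    (3, 0.045, 0.027, 180.0, 20.0, 558.0),
    (4, 0.045, 0.027, 180.0, 25.0, 558.0),
    (5, 0.045, 0.027, 180.0, 30.0, 558.0),
    (6, 0.0675, 0.027, 180.0, 15.0, 558.0),
    (7, 0.0225, 0.027, 180.0, 15.0, 558.0),
    (8, 0.045, 0.0405, 180.0, 15.0, 558.0),
    (9, 0.045, 0.0135, 180.0, 15.0, 558.0),
    (10, 0.045, 0.027, 270.0, 15.0, 558.0),
    (11, 0.045, 0.027, 90.0, 15.0, 558.0),
    (12, 0.035, 0.13, 1000.0, 15.0, 558.0),
    (13, 0.01, 0.015, 100.0, 15.0, 558.0),
    (14, 0.045, 0.027, 180.0, 15.0, 484.0),
    (15, 0.045, 0.027, 180.0, 15.0, 525.0),
    (16, 0.045, 0.027, 180.0, 15.0, 600.0),
]


@dataclass
class SweepCase:
    """One row of the sweep design."""

    case_id: int
    C10: float
    k1: float
    k2: float
    iop_mmhg: float
    cct_um: float

    @property
    def varies(self) -> str:
        """Which factor this row probes relative to the baseline design."""
        if self.case_id <= 5:
            return "iop"
        if self.case_id <= 13:
            return "material"
        return "cct"


def table1_cases() -> list[SweepCase]:
    """The sixteen-case sweep design (corneal material, IOP, CCT)."""
    return [SweepCase(*row) for row in _TABLE1]


def load_cases(path) -> list[SweepCase]:
    """Read a sweep definition file (delimited text with columns case_id,
    C10, k1, k2, IOP, CCT — the design-table layout)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    required = ["case_id", "c10", "k1", "k2", "iop", "cct"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [SweepCase(int(r[cols["case_id"]]), float(r[cols["c10"]]),
                      float(r[cols["k1"]]), float(r[cols["k2"]]),
                      float(r[cols["iop"]]), float(r[cols["cct"]]))
            for _, r in df.iterrows()]


def fit_quadratic(x, y):
    """Ordinary least-squares quadratic fit.

    Returns ((a, b, c), r2) for y = a x^2 + b x + c.  Requires >= 3 points
    and a full-rank design (distinct x values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("need at least 3 matching (x, y) points")
    A = np.column_stack([x ** 2, x, np.ones_like(x)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("rank-deficient design: x values do not support a quadratic")
    coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coeffs
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return tuple(float(c) for c in coeffs), r2


def compose_wiop(eq5, eq6):
    """Exact composition of the two quadratics into the wIOP quartic.

    With eq5 = (a5, b5, c5) mapping initial work to IOP and
    eq6 = (a6, b6, c6) mapping t_maxvel to initial work:

        q4 = a5 a6^2
        q3 = 2 a5 a6 b6
        q2 = a5 (2 a6 c6 + b6^2) + b5 a6
        q1 = 2 a5 b6 c6 + b5 b6
        q0 = a5 c6^2 + b5 c6 + c5
    """
    a5, b5, c5 = eq5
    a6, b6, c6 = eq6
    return (
        a5 * a6 ** 2,
        2.0 * a5 * a6 * b6,
        a5 * (2.0 * a6 * c6 + b6 ** 2) + b5 * a6,
        2.0 * a5 * b6 * c6 + b5 * b6,
        a5 * c6 ** 2 + b5 * c6 + c5,
    )


@dataclass
class CalibrationFit:
    """Fitted calibration: both quadratics, their R^2 and the composed
    quartic, plus the maximum-velocity time range the fit covers (times in
    ms from puff onset; works in mJ; pressures in mmHg)."""

    eq5_coeffs: tuple
    eq6_coeffs: tuple
    eq5_r2: float
    eq6_r2: float
    quartic: tuple = None
    t_range: tuple = None
    source: str = "sweep"

    def __post_init__(self) -> None:
        if self.quartic is None:
            self.quartic = compose_wiop(self.eq5_coeffs, self.eq6_coeffs)

    def wiop(self, t_maxvel_ms: float) -> float:
        """Evaluate the quartic at a maximum-velocity time."""
        return float(np.polyval(self.quartic, t_maxvel_ms))

    def is_extrapolated(self, t_maxvel_ms: float) -> bool:
        if self.t_range is None:
            return False
        return not (self.t_range[0] <= t_maxvel_ms <= self.t_range[1])

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(eq5_coeffs=tuple(doc["eq5_coeffs"]),
                   eq6_coeffs=tuple(doc["eq6_coeffs"]),
                   eq5_r2=doc["eq5_r2"], eq6_r2=doc["eq6_r2"],
                   quartic=tuple(doc["quartic"]),
                   t_range=tuple(doc["t_range"]) if doc.get("t_range") else None,
                   source=doc.get("source", "sweep"))


def default_calibration() -> CalibrationFit:
    """The shipped default: the published quartic coefficients.

    The printed quartic is the rounded composition of the published
    quadratics; it is stored verbatim so estimates match the printed
    method.  The fitted validity interval was not published; a nominal
    5-11 ms window (the physiological range of maximum-velocity times) is
    used to flag extrapolation.
    """
    return CalibrationFit(
        eq5_coeffs=PUBLISHED_EQ5, eq6_coeffs=PUBLISHED_EQ6,
        eq5_r2=0.98, eq6_r2=0.98,
        quartic=PUBLISHED_WIOP_QUARTIC, t_range=(5.0, 11.0),
        source="published")


def run_sweep(cases=None, profile=None, geometry=None, materials_extra=None,
              mesh_resolution: int = 1, progress: bool = False) -> pd.DataFrame:
    """Run the air-puff scenario for each sweep case and collect the
    calibration observables.

    Returns one record per case: initial work of the IOP, apex displacement
    at end of pressurization, maximum-velocity time, first-applanation time,
    work-curve intersection time(s) and value (event times relative to puff
    onset).  Per-case failures are recorded in the ``error`` column without
    aborting the sweep.
    """
    # local imports keep the calibration module importable without the solver
    from .constitutive import MaterialParams
    from .dynamics import AirPuffProfile, run_air_puff, apex_kinematics
    from .energetics import build_work_ledger, find_intersection
    from .events import (max_velocity_time, first_applanation_time,
                        ApplanationNotReached)
    from .geometry import EyeGeometryConfig, build_eye_mesh
    from .cavity import recover_zero_pressure, pressurize

    cases = cases if cases is not None else table1_cases()
    profile = profile or AirPuffProfile()
    records = []
    for case in cases:
        rec = {"case_id": case.case_id, "C10": case.C10, "k1": case.k1,
               "k2": case.k2, "iop_mmhg": case.iop_mmhg, "cct_um": case.cct_um,
               "varies": case.varies, "error": ""}
        try:
            geo_kwargs = {} if geometry is None else dict(geometry)
            geo = EyeGeometryConfig(cct_um=case.cct_um,
                                    mesh_resolution=mesh_resolution,
                                    **geo_kwargs)
            mesh = build_eye_mesh(geo)
            corneal = MaterialParams(case.C10, case.k1, case.k2)
            mats = {"cornea": corneal, "limbus": corneal,
                    "sclera": MaterialParams(0.3)}
            if materials_extra:
                mats.update(materials_extra)
            zp = recover_zero_pressure(mesh, mats, case.iop_mmhg)
            pres = pressurize(zp, mats, case.iop_mmhg)
            traj = run_air_puff(pres, profile)
            ledger = build_work_ledger(traj, initial_work=pres.initial_work)
            trace = apex_kinematics(traj)
            inter = find_intersection(ledger)
            t_mv = max_velocity_time(trace) - profile.onset_ms
            rec.update(
                initial_work_mJ=pres.initial_work,
                apex_displacement_mm=pres.apex_displacement,
                max_anterior_displacement_mm=pres.max_anterior_displacement,
                t_maxvel_ms=t_mv,
                t_intersection_ms=(inter.primary_time - profile.onset_ms
                                   if inter.found else np.nan),
                work_at_intersection_mJ=inter.primary_value,
                intersection_ratio=inter.ratio_to_initial,
                n_intersections=len(inter.times_ms),
                max_apex_indentation_mm=float(np.max(trace.displacement)),
            )
            try:
                rec["t_applanation_ms"] = first_applanation_time(
                    traj, from_time=profile.onset_ms) - profile.onset_ms
            except ApplanationNotReached:
                rec["t_applanation_ms"] = np.nan
                rec["error"] = "applanation not reached"
        except Exception as exc:   # per-case failure must not kill the sweep
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
        if progress:
            print(f"case {case.case_id}: {rec.get('t_maxvel_ms', 'failed')}")
    return pd.DataFrame.from_records(records)


class WiopCalibration:
    """Calibration model over a completed sweep (statsmodels-style).

    Parameters
    ----------
    sweep : pandas.DataFrame
        Output of :func:`run_sweep`.
    fit_cases : sequence of int, optional
        Case ids used for the regressions.  Default: the IOP series (rows
        1-5), the subset across which IOP actually varies.
    """

    def __init__(self, sweep: pd.DataFrame, fit_cases=(1, 2, 3, 4, 5)):
        self.sweep = sweep
        self.fit_cases = tuple(fit_cases)

    def fit(self) -> "CalibrationResults":
        sub = self.sweep[self.sweep.case_id.isin(self.fit_cases)]
        sub = sub[sub.error.isin(["", "applanation not reached"])]
        if len(sub) < 3:
            raise ValueError("fewer than 3 successful cases to fit on")
        eq5, r5 = fit_quadratic(sub.initial_work_mJ, sub.iop_mmhg)
        eq6, r6 = fit_quadratic(sub.t_maxvel_ms, sub.initial_work_mJ)
        t_range = (float(sub.t_maxvel_ms.min()), float(sub.t_maxvel_ms.max()))
        fit = CalibrationFit(eq5_coeffs=eq5, eq6_coeffs=eq6,
                             eq5_r2=r5, eq6_r2=r6, t_range=t_range)
        return CalibrationResults(self, fit)


class CalibrationResults:
    """Fitted calibration with diagnostics and a summary table."""

    def __init__(self, model: WiopCalibration, fit: CalibrationFit):
        self.model = model
        self.calibration = fit

    @property
    def params(self) -> dict:
        return {"eq5": self.calibration.eq5_coeffs,
                "eq6": self.calibration.eq6_coeffs,
                "quartic": self.calibration.quartic}

    def predict(self, t_maxvel_ms) -> np.ndarray:
        return np.polyval(self.calibration.quartic, np.asarray(t_maxvel_ms))

    def intersection_spread(self) -> dict:
        """Coefficient of variation of the intersection time across the IOP
        rows vs the material/CCT rows (the material-independence check)."""
        df = self.model.sweep
        ok = df[df.error.isin(["", "applanation not reached"])]
        out = {}
        for label, mask in (("iop", ok.varies == "iop"),
                            ("material_cct", ok.varies != "iop")):
            t = ok.t_intersection_ms[mask].dropna()
            out[label] = float(t.std(ddof=1) / t.mean()) if len(t) > 1 else np.nan
        return out

    def summary(self) -> str:
        c = self.calibration
        spread = self.intersection_spread()
        lines = [
            "wIOP calibration (reduced-order sweep)",
            "=" * 54,
            "pressurization:  IOP = a W0^2 + b W0 + c",
            "  (a, b, c) = (%.4g, %.4g, %.4g)   R^2 = %.4f" % (*c.eq5_coeffs, c.eq5_r2),
            "timing:          W0 = a t^2 + b t + c",
            "  (a, b, c) = (%.4g, %.4g, %.4g)   R^2 = %.4f" % (*c.eq6_coeffs, c.eq6_r2),
            "composed quartic wIOP(t):",
            "  (q4..q0) = (%.4g, %.4g, %.4g, %.4g, %.4g)" % c.quartic,
            "fitted t_maxvel range: %.2f - %.2f ms" % c.t_range,
            "intersection-time CV: IOP rows %.3f | material/CCT rows %.3f"
            % (spread["iop"], spread["material_cct"]),
        ]
        return "\n".join(lines)
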