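"""Wall shear stress from volumetric flow via the Poiseuille relation.

For steady laminar flow of a Newtonian fluid through a straight cylindrical
vessel, the tangential stress exerted on the wall is

    tau = 4 * eta * Q / (pi * R_i**3)

with ``tau`` in dyn/cm2, blood viscosity ``eta`` in dyn.s/cm2 (poise), flow
rate ``Q`` in cm3/s, and internal radius ``R_i`` in cm.  Transit-time Doppler
probes report flow in mL/min; all conversions happen here so that callers can
stay in the instrument's units.

Pulsatile traces are reduced to their trapezoidal time-average before the
Poiseuille formula is applied: the probe reports mean flow, and a single shear
value per session is what the downstream time-course statistics consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlowTrace",
    "VesselGeometry",
    "ShearStressEstimate",
    "ML_MIN_PER_CM3_S",
    "ml_min_to_cm3_s",
    "cm3_s_to_ml_min",
    "mean_flow",
    "poiseuille_wss",
    "radius_for_wss",
    "percent_change",
    "wss_timecourse",
]

#: 1 cm3/s expressed in mL/min.
ML_MIN_PER_CM3_S = 60.0

#: Default whole-blood viscosity, dyn.s/cm2 (4 cP, typical for rat blood at
#: physiological hematocrit and shear rates).  Configurable per study.
DEFAULT_VISCOSITY = 0.04

VESSEL_LABELS = ("carotid_proximal", "fistula_vein", "draining_vein")


def ml_min_to_cm3_s(q_ml_min):
    """Convert a flow rate from mL/min to cm3/s."""
    return np.asarray(q_ml_min, dtype=float) / ML_MIN_PER_CM3_S


def cm3_s_to_ml_min(q_cm3_s):
    """Convert a flow rate from cm3/s to mL/min."""
    return np.asarray(q_cm3_s, dtype=float) * ML_MIN_PER_CM3_S


@dataclass(frozen=True)
class FlowTrace:
    """A sampled volumetric flow-rate recording for one vessel at one session.

    Parameters
    ----------
    t_s : array-like
        Sample times in seconds, strictly increasing.
    flow_ml_min : array-like
        Flow rate at each sample, mL/min.
    vessel_label : str
        One of ``carotid_proximal``, ``fistula_vein``, ``draining_vein``.
    rat_id : str
    day : int
        Study day; the pre-fistula (sham) session is coded as day -1.
    """

    t_s: np.ndarray
    flow_ml_min: np.ndarray
    vessel_label: str = "fistula_vein"
    rat_id: str = ""
    day: int = 0

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.t_s, dtype=float))
        q = np.atleast_1d(np.asarray(self.flow_ml_min, dtype=float))
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "flow_ml_min", q)
        if t.size == 0:
            raise ValueError("flow trace is empty")
        if t.size != q.size:
            raise ValueError("t_s and flow_ml_min must have the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.vessel_label not in VESSEL_LABELS:
            raise ValueError(
                f"unknown vessel_label {self.vessel_label!r}; "
                f"expected one of {VESSEL_LABELS}"
            )


@dataclass(frozen=True)
class VesselGeometry:
    """Internal radius (cm) and blood viscosity (dyn.s/cm2) of a vessel."""

    internal_radius_cm: float
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self):
        if not self.internal_radius_cm > 0:
            raise ValueError("internal radius must be > 0")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be > 0")


@dataclass(frozen=True)
class ShearStressEstimate:
    """Poiseuille wall-shear-stress estimate with its inputs echoed."""

    tau_dyn_cm2: float
    mean_flow_cm3_s: float
    geometry: VesselGeometry = field(repr=False, default=None)


def mean_flow(trace: FlowTrace) -> float:
    """Trapezoidal time-average of a flow trace, returned in cm3/s.

    A single-sample trace is returned as-is (converted) with a warning; an
    empty trace is rejected at :class:`FlowTrace` construction.
    """
    q = ml_min_to_cm3_s(trace.flow_ml_min)
    if q.size == 1:
        warnings.warn(
            "flow trace has a single sample; returning it without averaging",
            stacklevel=2,
        )
        return float(q[0])
    t = trace.t_s
    return float(np.trapezoid(q, t) / (t[-1] - t[0]))


def poiseuille_wss(q_cm3_s: float, geometry: VesselGeometry) -> ShearStressEstimate:
    """Wall shear stress tau = 4*eta*Q / (pi * R_i**3), dyn/cm2.

    Parameters
    ----------
    q_cm3_s : float
        Mean volumetric flow rate, cm3/s (must be >= 0).
    geometry : VesselGeometry
    """
    if q_cm3_s < 0:
        raise ValueError("flow rate must be >= 0")
    tau = 4.0 * geometry.viscosity * q_cm3_s / (math.pi * geometry.internal_radius_cm**3)
    return ShearStressEstimate(tau_dyn_cm2=tau, mean_flow_cm3_s=float(q_cm3_s), geometry=geometry)


def radius_for_wss(tau_dyn_cm2: float, q_cm3_s: float, viscosity: float = DEFAULT_VISCOSITY) -> float:
    """Invert the Poiseuille relation: the radius (cm) at which a given flow
    produces a target wall shear stress.

    R = (4*eta*Q / (pi*tau))**(1/3).  Used to calibrate synthetic vessel
    geometries so that the forward computation reproduces a prescribed shear
    trend exactly.
    """
    if not tau_dyn_cm2 > 0:
        raise ValueError("target wall shear stress must be > 0")
    if not q_cm3_s > 0:
        raise ValueError("flow rate must be > 0 to invert for radius")
    if not viscosity > 0:
        raise ValueError("viscosity must be > 0")
    return (4.0 * viscosity * q_cm3_s / (math.pi * tau_dyn_cm2)) ** (1.0 / 3.0)


def percent_change(value, baseline):
    """100 * (value - baseline) / baseline.  Baseline must be positive."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be > 0 for a percent change")
    return 100.0 * (np.asarray(value, dtype=float) - baseline) / baseline


def wss_timecourse(traces, geometries, fold_day: int = 0) -> pd.DataFrame:
    """Per-day group summary of wall shear stress.

    Parameters
    ----------
    traces : iterable of FlowTrace
    geometries : mapping
        ``(rat_id, day) -> VesselGeometry``.  Every trace must have a
        matching geometry.
    fold_day : int
        Day whose group mean anchors the fold change (day 0, the moment of
        fistula creation, by default; falls back to the earliest day present
        with a warning).

    Returns
    -------
    pandas.DataFrame
        Columns ``day, n, mean, se, fold_vs_day0``, one row per day.
    """
    rows = []
    for trace in traces:
        key = (trace.rat_id, trace.day)
        if key not in geometries:
            raise KeyError(f"no geometry for rat {trace.rat_id!r} day {trace.day}")
        est = poiseuille_wss(mean_flow(trace), geometries[key])
        rows.append({"rat_id": trace.rat_id, "day": trace.day, "tau": est.tau_dyn_cm2})
    if not rows:
        raise ValueError("no flow traces supplied")
    per_rat = pd.DataFrame(rows)
    grouped = per_rat.groupby("day")["tau"]
    out = pd.DataFrame(
        {
            "day": grouped.mean().index,
            "n": grouped.count().to_numpy(),
            "mean": grouped.mean().to_numpy(),
            "se": grouped.sem(ddof=1).to_numpy(),
        }
    ).reset_index(drop=True)
    days = set(out["day"])
    anchor = fold_day
    if anchor not in days:
        anchor = out["day"].min()
        warnings.warn(
            f"fold-change anchor day {fold_day} absent; using day {anchor}",
            stacklevel=2,
        )
    anchor_mean = float(out.loc[out["day"] == anchor, "mean"].iloc[0])
    out["fold_vs_day0"] = out["mean"] / anchor_mean
    return out
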